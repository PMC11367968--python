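"""Parametric graft geometry: construction, augmentation, CSA, rasterization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graftflow.exceptions import GeometryError, OcclusionError, ResolutionError
from graftflow.geometry import (
    StenosisSpec,
    augment_stenosis,
    build_graft,
    csa_profile,
    percent_csa_reduction,
    rasterize,
    severity_factor_for_csa,
    straight_tube,
)
from graftflow.io import write_stl

MM2 = 1e-6
D_BASE = 17.5e-3  # m; baseline area ~240.5 mm²


def _spec(target_mm2: float, eccentricity: float = 0.0) -> StenosisSpec:
    return StenosisSpec(
        center_position=0.030,
        axial_extent=0.045,
        target_narrowest_csa=target_mm2 * MM2,
        eccentricity=eccentricity,
    )


class TestBuildGraft:
    @pytest.mark.parametrize("eccentricity", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("target_mm2", [173.0, 136.0, 116.0, 165.0, 130.0, 93.0])
    def test_narrowest_csa_hits_target(self, target_mm2, eccentricity):
        geom = build_graft(_spec(target_mm2, eccentricity), D_BASE, 0.1)
        got = csa_profile(geom, 4000).narrowest_csa
        assert got == pytest.approx(target_mm2 * MM2, rel=5e-3)

    def test_table_pair_reduction_28pct(self):
        # 173 mm² on the ~240 mm² baseline is a 28% reduction
        geom = build_graft(_spec(173.0), 2 * math.sqrt(240.18e-6 / math.pi), 0.1)
        pct = percent_csa_reduction(geom.narrowest_csa, geom.baseline_area)
        assert pct == 28

    def test_table_pair_reduction_61pct(self):
        geom = build_graft(_spec(93.0), 2 * math.sqrt(238.5e-6 / math.pi), 0.1)
        pct = percent_csa_reduction(csa_profile(geom, 2000).narrowest_csa,
                                    geom.baseline_area)
        assert pct == 61

    def test_unstenosed_tube_constant_csa(self):
        geom = straight_tube(D_BASE, 0.1)
        prof = csa_profile(geom, 100)
        assert np.allclose(prof.areas, math.pi * (D_BASE / 2) ** 2, rtol=1e-12)

    def test_compression_profile_is_smooth(self):
        geom = build_graft(_spec(93.0), D_BASE, 0.1)
        s = np.linspace(0.0, 0.1, 5000)
        c = geom.compression_displacement(s)
        assert np.all(c >= 0)
        # zero outside the stenotic segment
        outside = (s < 0.030 - 0.0225) | (s > 0.030 + 0.0225)
        assert np.all(c[outside] == 0)
        # continuously varying: no jump larger than the local slope allows
        assert np.max(np.abs(np.diff(c))) < 5e-3 * geom.amplitude

    def test_rejects_target_at_or_above_baseline(self):
        base_area = math.pi * (D_BASE / 2) ** 2
        with pytest.raises(GeometryError):
            build_graft(_spec(base_area * 1e6), D_BASE, 0.1)
        with pytest.raises(GeometryError):
            build_graft(_spec(base_area * 1.2e6), D_BASE, 0.1)

    def test_rejects_nonpositive_target(self):
        with pytest.raises(GeometryError):
            build_graft(_spec(-10.0), D_BASE, 0.1)


class TestAugmentStenosis:
    def test_identity_factor_returns_equal_profiles(self):
        geom = build_graft(_spec(173.0), D_BASE, 0.1)
        aug = augment_stenosis(geom, 1.0)
        s = np.linspace(0, 0.1, 500)
        assert np.array_equal(
            geom.compression_displacement(s), aug.compression_displacement(s)
        )

    def test_factor_to_reach_as1_case1(self):
        geom = build_graft(_spec(173.0), D_BASE, 0.1)
        factor = severity_factor_for_csa(geom, 136.0 * MM2)
        aug = augment_stenosis(geom, factor)
        assert csa_profile(aug, 4000).narrowest_csa == pytest.approx(
            136.0 * MM2, rel=5e-3
        )

    def test_factor_to_reach_as2_case2_fine_scan(self):
        # independent fine-sampled area scan at 10x the usual station density
        geom = build_graft(_spec(165.0, eccentricity=1.0), D_BASE, 0.1)
        factor = severity_factor_for_csa(geom, 93.0 * MM2)
        aug = augment_stenosis(geom, factor)
        coarse = csa_profile(aug, 400).narrowest_csa
        fine = csa_profile(aug, 4000).narrowest_csa
        assert fine == pytest.approx(93.0 * MM2, rel=5e-3)
        assert coarse == pytest.approx(fine, rel=1e-3)

    def test_stations_outside_segment_unchanged(self):
        geom = build_graft(_spec(173.0), D_BASE, 0.1)
        aug = augment_stenosis(geom, 1.7)
        s = np.array([0.001, 0.005, 0.060, 0.095])
        assert np.array_equal(geom.area(s), aug.area(s))
        # narrowest point stays put
        assert csa_profile(aug, 4001).narrowest_station == pytest.approx(
            0.030, abs=1e-4
        )

    def test_occlusion_is_an_error(self):
        geom = build_graft(_spec(93.0), D_BASE, 0.1)
        with pytest.raises(OcclusionError):
            augment_stenosis(geom, 50.0)

    def test_factor_below_one_rejected(self):
        geom = build_graft(_spec(173.0), D_BASE, 0.1)
        with pytest.raises(GeometryError):
            augment_stenosis(geom, 0.5)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        a=st.floats(min_value=1.0, max_value=2.0),
        b=st.floats(min_value=1.0, max_value=2.0),
    )
    def test_augmentation_monotonicity(self, a, b):
        """Larger severity factor means strictly smaller narrowest CSA."""
        if abs(a - b) < 1e-9:
            return
        a, b = max(a, b), min(a, b)
        geom = build_graft(_spec(173.0), D_BASE, 0.1)
        csa_a = augment_stenosis(geom, a).narrowest_csa
        csa_b = augment_stenosis(geom, b).narrowest_csa
        assert csa_a < csa_b


class TestCsaProfile:
    def test_refinement_consistency(self):
        geom = build_graft(_spec(116.0), D_BASE, 0.1)
        m1 = csa_profile(geom, 500).narrowest_csa
        m2 = csa_profile(geom, 1000).narrowest_csa
        assert abs(m2 - m1) / m2 < 1e-3

    def test_csa_never_exceeds_baseline(self):
        geom = build_graft(_spec(93.0, eccentricity=1.0), D_BASE, 0.1)
        prof = csa_profile(geom, 500)
        assert np.all(prof.areas <= geom.baseline_area * (1 + 1e-12))

    def test_rejects_single_station(self):
        geom = straight_tube(D_BASE, 0.1)
        with pytest.raises(GeometryError):
            csa_profile(geom, 1)


class TestPercentReduction:
    @pytest.mark.parametrize(
        "narrowest,baseline,expected",
        [(173.0, 240.3, 28), (93.0, 238.5, 61), (100.0, 100.0, 0)],
    )
    def test_examples(self, narrowest, baseline, expected):
        assert percent_csa_reduction(narrowest, baseline) == expected

    def test_half_up_rounding(self):
        # clinical convention: exact halves round up (unlike banker's rounding)
        from graftflow.geometry import round_half_up

        assert round_half_up(22.5) == 23
        assert round_half_up(23.5) == 24
        assert round_half_up(-1.5) == -2

    def test_invalid_baseline(self):
        with pytest.raises(GeometryError):
            percent_csa_reduction(10.0, 0.0)


class TestRasterize:
    def test_straight_tube_constant_mask(self):
        raster = rasterize(straight_tube(D_BASE, 0.05), 16)
        assert raster.fluid.all()
        assert np.allclose(raster.open_fraction, 1.0)

    def test_throat_width_within_one_cell(self):
        geom = build_graft(_spec(173.0), D_BASE, 0.1)
        raster = rasterize(geom, 32)
        err = np.abs(raster.wall_position() - raster.radius)
        assert np.max(err) <= 0.5 * raster.dr + 1e-12

    def test_refinement_halves_wall_error_bound(self):
        geom = build_graft(_spec(136.0), D_BASE, 0.1)
        errs = {}
        for res in (16, 32):
            raster = rasterize(geom, res)
            errs[res] = np.max(np.abs(raster.wall_position() - raster.radius))
        assert errs[32] <= 0.55 * errs[16] + 1e-12

    def test_mask_area_round_trip_within_2pct(self):
        geom = build_graft(_spec(93.0), D_BASE, 0.1)
        raster = rasterize(geom, 32)
        recovered = raster.csa_from_mask()
        analytic = geom.area(recovered.stations)
        assert np.max(np.abs(recovered.areas - analytic) / analytic) < 0.02

    def test_too_coarse_is_an_error(self):
        with pytest.raises(ResolutionError):
            rasterize(straight_tube(D_BASE, 0.05), 6)
        # a throat thinner than 4 cells is rejected even at valid resolution
        tight = build_graft(_spec(15.0), D_BASE, 0.1)
        with pytest.raises(ResolutionError):
            rasterize(tight, 8)


class TestExports:
    def test_stl_and_csv_exports(self, tmp_path):
        geom = build_graft(_spec(173.0), D_BASE, 0.1)
        ascii_path = tmp_path / "graft.stl"
        bin_path = tmp_path / "graft_bin.stl"
        write_stl(geom, ascii_path, binary=False, n_axial=30, n_theta=12)
        write_stl(geom, bin_path, binary=True, n_axial=30, n_theta=12)
        text = ascii_path.read_text()
        assert text.startswith("solid") and "endsolid" in text
        assert bin_path.stat().st_size > 84
        csv_path = tmp_path / "csa.csv"
        csa_profile(geom, 50).to_csv(csv_path)
        assert "station_m,area_mm2" in csv_path.read_text().splitlines()[0]
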