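"""Radiological severity arithmetic for outflow-graft stenoses.

Imaging workups grade a graft stenosis by the preserved lumen diameter and
cross-sectional area at fixed distances (20 and 40 mm) from the graft inlet.
Each measurement records the *lost* lumen (the reduction) against its
reference value; percentages are reported as integers (half-up rounding), and
the working definition of significant extrinsic outflow-graft obstruction is
a CSA reduction strictly greater than 25%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .exceptions import GraftFlowError
from .geometry import round_half_up

__all__ = [
    "RadiologicalMeasurement",
    "EOGO_CSA_THRESHOLD_PCT",
    "percent_reduction",
    "classify_eogo",
    "radiology_report",
]

#: significant extrinsic obstruction: CSA reduction strictly above this percent
EOGO_CSA_THRESHOLD_PCT = 25.0

SIGNIFICANT = "significant"
NOT_SIGNIFICANT = "not significant"


@dataclass(frozen=True)
class RadiologicalMeasurement:
    """One measurement site: lost lumen and reference, diameter and area."""

    site_mm: float  # distance from the graft inlet
    diameter_reduction_mm: float
    reference_diameter_mm: float
    area_reduction_mm2: float
    reference_area_mm2: float

    def __post_init__(self) -> None:
        if self.reference_diameter_mm <= 0 or self.reference_area_mm2 <= 0:
            raise GraftFlowError("reference diameter and area must be positive")
        if not 0 <= self.diameter_reduction_mm <= self.reference_diameter_mm:
            raise GraftFlowError("diameter reduction must be in [0, reference]")
        if not 0 <= self.area_reduction_mm2 <= self.reference_area_mm2:
            raise GraftFlowError("area reduction must be in [0, reference]")


def percent_reduction(reduction: float, reference: float) -> int:
    """Integer percent reduction, rounded half-up: round(100 * reduction/reference)."""
    if reference <= 0:
        raise GraftFlowError("reference must be positive")
    if not 0 <= reduction <= reference:
        raise GraftFlowError("reduction must lie in [0, reference]")
    return round_half_up(100.0 * reduction / reference)


def classify_eogo(csa_reduction_pct: float) -> str:
    """Classify a CSA reduction: significant iff strictly greater than 25%."""
    if not 0 <= csa_reduction_pct <= 100:
        raise GraftFlowError("percent reduction must lie in [0, 100]")
    return SIGNIFICANT if csa_reduction_pct > EOGO_CSA_THRESHOLD_PCT else NOT_SIGNIFICANT


def radiology_report(
    measurements: Iterable[RadiologicalMeasurement],
) -> pd.DataFrame:
    """One row per measurement site, in input order.

    Columns: site_mm, diameter_reduction_pct, csa_reduction_pct,
    classification (from the CSA percentage).
    """
    measurements = list(measurements)
    if not measurements:
        raise GraftFlowError("no measurements provided")
    rows = []
    for m in measurements:
        d_pct = percent_reduction(m.diameter_reduction_mm, m.reference_diameter_mm)
        a_pct = percent_reduction(m.area_reduction_mm2, m.reference_area_mm2)
        rows.append(
            {
                "site_mm": m.site_mm,
                "diameter_reduction_pct": d_pct,
                "csa_reduction_pct": a_pct,
                "classification": classify_eogo(a_pct),
            }
        )
    return pd.DataFrame(rows)
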