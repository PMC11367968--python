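"""Severity x flow sweep and correlation analysis.

Per case, the study design is a full factorial of three stenosis severities
(OS, AS1, AS2) by three device flows (3.5, 4.5, 5.5 L/min) — nine runs per
case, eighteen for two cases. Pearson product-moment correlations pool the
nine cells of one case; two-sided P-values come from the exact small-sample
reference distribution of R under normality, t = R sqrt(n-2) / sqrt(1-R²)
with n-2 degrees of freedom. Significance is declared at P < 0.05 with no
multiple-testing correction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .cases import CaseFixture, SEVERITIES, DEVICE_FLOWS_LPM
from .exceptions import IncompleteSweepError, SolverError, ZeroVarianceError
from .geometry import rasterize
from .metrics import HaemodynamicSummary, summarize
from .solver import FluidProperties, SimulationConfig, simulate
from .units import LPM_TO_M3S

logger = logging.getLogger(__name__)

__all__ = [
    "SweepResult",
    "CorrelationResult",
    "SEVERITY_RANK",
    "enumerate_runs",
    "run_sweep",
    "pearson",
    "correlation_panel",
]

SEVERITY_RANK = {"OS": 1, "AS1": 2, "AS2": 3}
ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one variable pair."""

    pair: str
    r: float
    p: float
    n: int
    significant: bool


@dataclass
class SweepResult:
    """Grid of haemodynamic summaries for one case."""

    case_label: str
    rows: pd.DataFrame  # tidy: severity, csa_mm2, flow_lpm, gradient, ...
    summaries: dict[tuple[str, float], HaemodynamicSummary]
    failures: dict[tuple[str, float], str]

    @property
    def complete(self) -> bool:
        return not self.failures and len(self.rows) > 0

    def to_csv(self, path, config_hash: str | None = None) -> None:
        with open(path, "w", newline="") as fh:
            if config_hash:
                fh.write(f"# config_sha256={config_hash}\n")
            self.rows.to_csv(fh, index=False)


def enumerate_runs(
    cases,
    severities=SEVERITIES,
    flows_lpm=DEVICE_FLOWS_LPM,
) -> list[dict]:
    """Enumerate the (case, severity, flow) configurations of a sweep."""
    try:
        cases = list(cases)
    except TypeError:
        cases = [cases]
    return [
        {"case": getattr(c, "label", str(c)), "severity": s, "flow_lpm": float(f)}
        for c in cases
        for s in severities
        for f in flows_lpm
    ]


def _cell_hash(case: CaseFixture, severity: str, flow_lpm: float,
               config: SimulationConfig, fluid: FluidProperties) -> str:
    payload = json.dumps(
        {
            "case": asdict(case),
            "severity": severity,
            "flow_lpm": flow_lpm,
            "config": asdict(replace(config, inlet_flow_rate=0.0)),
            "fluid": asdict(fluid),
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_sweep(
    case: CaseFixture,
    config: SimulationConfig,
    fluid: FluidProperties | None = None,
    severities=SEVERITIES,
    flows_lpm=None,
    cache_dir=None,
    peak_mode: str = "time-mean",
) -> SweepResult:
    """One simulate-and-measure pass per (severity, flow) cell.

    Deterministic given the fixture and config; completed cells are cached by
    a content hash of their inputs when ``cache_dir`` is given. Failed cells
    are recorded in ``failures`` rather than silently dropped.
    """
    fluid = fluid or FluidProperties()
    flows_lpm = tuple(flows_lpm) if flows_lpm is not None else case.flows_lpm
    rows = []
    summaries: dict[tuple[str, float], HaemodynamicSummary] = {}
    failures: dict[tuple[str, float], str] = {}
    for severity in severities:
        geom = case.build_geometry(severity)
        csa_mm2 = case.severity_csa_mm2[severity]
        for flow in flows_lpm:
            key = (severity, float(flow))
            cache_file = None
            if cache_dir is not None:
                digest = _cell_hash(case, severity, float(flow), config, fluid)
                cache_file = cache_dir / f"{digest}.json"
                if cache_file.exists():
                    summaries[key] = HaemodynamicSummary.from_json(cache_file)
                    logger.debug("cache hit for %s %s", severity, flow)
            if key not in summaries:
                try:
                    raster = rasterize(geom, config.grid_resolution)
                    cfg = replace(config, inlet_flow_rate=flow * LPM_TO_M3S)
                    series = simulate(raster, fluid, cfg)
                    summaries[key] = summarize(series, fluid, peak_mode=peak_mode)
                except SolverError as exc:
                    failures[key] = str(exc)
                    logger.warning("cell %s/%s L/min failed: %s", severity, flow, exc)
                    continue
                if cache_file is not None:
                    cache_file.parent.mkdir(parents=True, exist_ok=True)
                    summaries[key].to_json(cache_file)
            s = summaries[key]
            rows.append(
                {
                    "case": case.label,
                    "severity": severity,
                    "csa_mm2": csa_mm2,
                    "flow_lpm": float(flow),
                    "gradient_mmHg": s.pressure_gradient_mmHg,
                    "peak_velocity_ms": s.peak_velocity_ms,
                    "tke_mJ": s.integrated_tke_mJ,
                }
            )
    return SweepResult(
        case_label=case.label,
        rows=pd.DataFrame(rows),
        summaries=summaries,
        failures=failures,
    )


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with exact small-sample P-value.

    Raises :class:`ZeroVarianceError` when either sample is constant (the
    correlation is undefined, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.dot(dx, dx))
    syy = float(np.dot(dy, dy))
    if sxx == 0.0 or syy == 0.0:
        raise ZeroVarianceError("correlation undefined for a constant sample")
    r = float(np.dot(dx, dy) / math.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(_scipy_stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(pair="", r=r, p=p, n=n, significant=p < ALPHA)


def _panel_entry(pair: str, x, y) -> CorrelationResult:
    try:
        res = pearson(x, y)
        return CorrelationResult(pair=pair, r=res.r, p=res.p, n=res.n,
                                 significant=res.significant)
    except ZeroVarianceError:
        # e.g. laminar runs with identically zero TKE: report as undefined
        return CorrelationResult(pair=pair, r=math.nan, p=math.nan,
                                 n=len(np.asarray(x)), significant=False)


def correlation_panel(sweep: SweepResult) -> pd.DataFrame:
    """Correlations pooled over the 9 cells of one case.

    Pressure gradient, peak velocity and TKE are each correlated against the
    narrowest CSA (mm²), the ordinal severity rank (OS=1, AS1=2, AS2=3) and
    the device flow; plus the gradient-versus-peak-velocity and
    gradient-versus-TKE panels.
    """
    if not sweep.complete:
        raise IncompleteSweepError(
            f"{sweep.case_label}: sweep incomplete ({len(sweep.failures)} failed cells)"
        )
    df = sweep.rows
    rank = df["severity"].map(SEVERITY_RANK).to_numpy(dtype=float)
    metrics = {
        "gradient_mmHg": df["gradient_mmHg"].to_numpy(),
        "peak_velocity_ms": df["peak_velocity_ms"].to_numpy(),
        "tke_mJ": df["tke_mJ"].to_numpy(),
    }
    predictors = {
        "csa_mm2": df["csa_mm2"].to_numpy(dtype=float),
        "severity_rank": rank,
        "flow_lpm": df["flow_lpm"].to_numpy(dtype=float),
    }
    entries = []
    for mname, mvals in metrics.items():
        for pname, pvals in predictors.items():
            entries.append(_panel_entry(f"{mname} vs {pname}", pvals, mvals))
    entries.append(
        _panel_entry(
            "gradient_mmHg vs peak_velocity_ms",
            metrics["peak_velocity_ms"],
            metrics["gradient_mmHg"],
        )
    )
    entries.append(
        _panel_entry("gradient_mmHg vs tke_mJ", metrics["tke_mJ"], metrics["gradient_mmHg"])
    )
    out = pd.DataFrame([asdict(e) for e in entries])
    out.insert(0, "case", sweep.case_label)
    return out
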