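"""Report assembly: tidy CSVs and summary plots for a completed sweep."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .exceptions import GraftFlowError
from .sweep import SweepResult

__all__ = ["write_report"]


def _csv_with_hash(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_sha256={config_hash}\n")
        df.to_csv(fh, index=False)


def write_report(
    sweep: SweepResult,
    correlations: pd.DataFrame,
    out_dir,
    config_hash: str = "unconfigured",
) -> dict[str, Path]:
    """Write results.csv, correlations.csv, plane_pressures.csv and plots.

    CSV outputs are byte-deterministic for identical inputs; every file
    carries the configuration hash in a leading comment line.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise GraftFlowError(f"cannot create output directory {out}: {exc}") from exc

    files: dict[str, Path] = {}

    results_csv = out / "results.csv"
    _csv_with_hash(sweep.rows, results_csv, config_hash)
    files["results"] = results_csv

    corr_csv = out / "correlations.csv"
    _csv_with_hash(correlations, corr_csv, config_hash)
    files["correlations"] = corr_csv

    plane_rows = []
    for (severity, flow), summary in sorted(sweep.summaries.items()):
        d = asdict(summary)
        for idx, (pos, press) in enumerate(
            zip(d["plane_positions_m"], d["plane_pressures_mmHg"])
        ):
            plane_rows.append(
                {
                    "case": sweep.case_label,
                    "severity": severity,
                    "flow_lpm": flow,
                    "plane_index": idx + 1,
                    "position_m": pos,
                    "mean_pressure_mmHg": press,
                }
            )
    planes_df = pd.DataFrame(plane_rows)
    planes_csv = out / "plane_pressures.csv"
    _csv_with_hash(planes_df, planes_csv, config_hash)
    files["plane_pressures"] = planes_csv

    files.update(_plots(sweep, planes_df, out))
    return files


def _plots(sweep: SweepResult, planes_df: pd.DataFrame, out: Path) -> dict[str, Path]:
    files = {}
    df = sweep.rows

    # pressure profile along the graft per severity (highest flow)
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(planes_df):
        top_flow = planes_df["flow_lpm"].max()
        for severity, grp in planes_df[planes_df["flow_lpm"] == top_flow].groupby(
            "severity"
        ):
            ax.plot(grp["position_m"] * 1e3, grp["mean_pressure_mmHg"], "o-",
                    label=severity)
        ax.set_xlabel("axial position (mm)")
        ax.set_ylabel("plane mean pressure (mmHg)")
        ax.set_title(f"{sweep.case_label}: pressure profile at {top_flow} L/min")
        ax.legend()
    path = out / "pressure_profile.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    files["pressure_profile"] = path

    # gradient versus narrowest CSA, one line per flow
    fig, ax = plt.subplots(figsize=(5, 4))
    for flow, grp in df.groupby("flow_lpm"):
        grp = grp.sort_values("csa_mm2")
        ax.plot(grp["csa_mm2"], grp["gradient_mmHg"], "o-", label=f"{flow} L/min")
    ax.set_xlabel("narrowest CSA (mm²)")
    ax.set_ylabel("pressure gradient (mmHg)")
    ax.set_title(f"{sweep.case_label}: gradient vs severity")
    ax.legend()
    path = out / "gradient_vs_csa.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    files["gradient_vs_csa"] = path

    # scatter panels: gradient vs peak velocity and vs TKE
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    markers = {"OS": "s", "AS1": "o", "AS2": "^"}
    for severity, grp in df.groupby("severity"):
        m = markers.get(severity, "o")
        axes[0].scatter(grp["peak_velocity_ms"], grp["gradient_mmHg"], marker=m,
                        label=severity)
        axes[1].scatter(grp["tke_mJ"], grp["gradient_mmHg"], marker=m, label=severity)
    axes[0].set_xlabel("peak velocity (m/s)")
    axes[1].set_xlabel("TKE (mJ)")
    for a in axes:
        a.set_ylabel("pressure gradient (mmHg)")
    axes[0].legend()
    fig.suptitle(f"{sweep.case_label}: gradient correlates")
    path = out / "gradient_scatter.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    files["gradient_scatter"] = path
    return files
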