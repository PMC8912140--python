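"""Artifact writers: fit records, decision matrices, verdicts, bootstrap
tables, mechanism rows, corpus summaries, config echo and run logs."""

from __future__ import annotations

import hashlib
import json
import platform
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap_inference import BootstrapVerdict
from .mechanism_interpretation import BetaNMap, MechanismReport
from .model_selection import (
    SelectionOutcome,
    Verdict,
    decision_matrix,
    verdict_frame,
)

__all__ = [
    "fits_frame",
    "bootstrap_wide_frame",
    "mechanism_frame",
    "write_artifacts",
    "scatter_aic_r2",
]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if np.isnan(f):
            return None
        if np.isinf(f):
            return "-inf" if f < 0 else "inf"
        return f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def fits_frame(outcomes_by_dataset: dict[str, list[SelectionOutcome]]) -> pd.DataFrame:
    """One flat row per (dataset, model): status, reason and fit statistics."""
    rows = []
    for ds_id in sorted(outcomes_by_dataset):
        for o in outcomes_by_dataset[ds_id]:
            row = {"dataset_id": ds_id, "model": o.model_name, "status": o.status,
                   "reason": o.reason}
            if o.final_fit is not None:
                rec = o.final_fit.to_record()
                rec.pop("dataset_id", None)
                rec.pop("model", None)
                row.update(rec)
            rows.append(row)
    return pd.DataFrame(rows)


def bootstrap_wide_frame(verdicts: Sequence[BootstrapVerdict]) -> pd.DataFrame:
    """Dataset x model table of bootstrap R^2 and AIC (wide layout)."""
    rows = {}
    for bv in verdicts:
        row = {}
        for name, s in bv.summaries.items():
            row[f"{name}_r2"] = s.r2_boot
            row[f"{name}_aic"] = s.aic_boot
        rows[bv.dataset_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "dataset_id"
    return frame


def mechanism_frame(
    reports: Sequence[MechanismReport], beta_n: BetaNMap | None = None
) -> pd.DataFrame:
    frame = pd.DataFrame([r.to_record() for r in reports]).set_index("dataset_id")
    if beta_n is not None:
        frame.attrs["beta_n_map"] = beta_n.__dict__
    return frame.sort_index()


def scatter_aic_r2(fits: pd.DataFrame, path: Path, criterion: str = "aic") -> None:
    """Simple per-model scatter of an information criterion against R^2."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    usable = fits.dropna(subset=["r2", criterion])
    usable = usable[np.isfinite(usable[criterion])]
    fig, ax = plt.subplots(figsize=(6, 4))
    for model, grp in usable.groupby("model"):
        ax.scatter(grp["r2"], grp[criterion], label=model, s=18, alpha=0.8)
    ax.set_xlabel("R$^2$")
    ax.set_ylabel(criterion.upper())
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_artifacts(
    out_dir: Path,
    config: dict,
    outcomes_by_dataset: dict[str, list[SelectionOutcome]],
    verdicts: Sequence[Verdict],
    summary: dict,
    bootstrap_verdicts: Sequence[BootstrapVerdict] | None = None,
    mechanism: tuple[Sequence[MechanismReport], BetaNMap | None] | None = None,
    failures: Sequence[dict] | None = None,
    timings: dict[str, float] | None = None,
    fmt: str = "csv",
    plots: bool = False,
) -> list[Path]:
    """Write every report artifact plus a provenance log; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(frame: pd.DataFrame, stem: str) -> None:
        if fmt == "csv":
            path = out_dir / f"{stem}.csv"
            frame.to_csv(path)
        else:
            path = out_dir / f"{stem}.json"
            path.write_text(
                json.dumps(_jsonable(frame.reset_index().to_dict("records")), indent=2)
            )
        written.append(path)

    fits = fits_frame(outcomes_by_dataset)
    emit(fits.set_index("dataset_id"), "fits")
    emit(decision_matrix(outcomes_by_dataset), "decision_matrix")
    emit(verdict_frame(verdicts), "verdicts")
    if bootstrap_verdicts:
        emit(bootstrap_wide_frame(bootstrap_verdicts), "bootstrap_table")
        boot_best = pd.DataFrame(
            {
                "dataset_id": [b.dataset_id for b in bootstrap_verdicts],
                "best_by_aic_boot": [b.best_by_aic for b in bootstrap_verdicts],
                "best_by_r2_boot": [b.best_by_r2 for b in bootstrap_verdicts],
            }
        ).set_index("dataset_id")
        emit(boot_best.sort_index(), "bootstrap_verdicts")
    if mechanism is not None:
        reports, beta_n = mechanism
        emit(mechanism_frame(reports), "mechanism")
        if beta_n is not None:
            path = out_dir / "beta_n_map.json"
            path.write_text(json.dumps(_jsonable(beta_n.__dict__), indent=2))
            written.append(path)

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(_jsonable(summary), indent=2))
    written.append(summary_path)

    if failures:
        fail_path = out_dir / "failures.json"
        fail_path.write_text(json.dumps(_jsonable(list(failures)), indent=2))
        written.append(fail_path)

    config_blob = json.dumps(_jsonable(config), sort_keys=True)
    config_path = out_dir / "run_config.json"
    config_path.write_text(config_blob)
    written.append(config_path)

    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "seed": config.get("seed"),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "per_dataset_seconds": timings or {},
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(_jsonable(log), indent=2))
    written.append(log_path)

    if plots:
        plot_path = out_dir / "aic_vs_r2.png"
        scatter_aic_r2(fits, plot_path)
        written.append(plot_path)
    return written
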