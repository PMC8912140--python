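"""Data model, validation and I/O for cumulative drug-release curves.

A release curve records the cumulative percentage ``Qt`` of an encapsulated
drug released into the medium by time ``t`` (hours).  Curves digitized from
dissolution assays are short (3-14 observations), monotone up to digitization
jitter, and plateau at the total release percentage ``Q_inf``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReleaseDataset",
    "read_release_table",
    "write_release_table",
    "datasets_to_json",
    "write_json",
    "validate",
]

_BOUND_TOL = 1e-9

LONG_COLUMNS = ("dataset_id", "time_h", "release_pct")


@dataclass
class ReleaseDataset:
    """One cumulative release curve plus free-form metadata.

    Parameters
    ----------
    id : str
        Short label identifying the curve.
    times : sequence of float
        Sampling times in hours, strictly increasing, non-negative.
    release : sequence of float
        Cumulative percent released at each time, each in [0, 100].
    q_inf : float, optional
        Total release percentage (the observed plateau).  Defaults to the
        maximum observed release.
    meta : dict
        Free key/value metadata (drug, polymer, LA:GA ratio, size, medium,
        source reference, simulation ground truth, ...).
    """

    id: str
    times: np.ndarray
    release: np.ndarray
    q_inf: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.release = np.asarray(self.release, dtype=float)
        if self.times.ndim != 1 or self.release.ndim != 1:
            raise ValueError("times and release must be one-dimensional")
        if len(self.times) != len(self.release):
            raise ValueError(
                f"dataset {self.id!r}: times and release differ in length"
            )
        if len(self.times) < 3:
            raise ValueError(f"dataset {self.id!r}: fewer than 3 observations")
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.release)
        ):
            raise ValueError(f"dataset {self.id!r}: non-finite values")
        if np.any(self.times < 0):
            raise ValueError(f"dataset {self.id!r}: negative times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"dataset {self.id!r}: times not strictly increasing")
        if np.any(self.release < -_BOUND_TOL) or np.any(
            self.release > 100 + _BOUND_TOL
        ):
            raise ValueError(
                f"dataset {self.id!r}: release values outside [0, 100]"
            )
        # values within numerical tolerance of the bounds are clipped
        self.release = np.clip(self.release, 0.0, 100.0)
        if self.q_inf is None:
            self.q_inf = float(np.max(self.release))
        self.q_inf = float(self.q_inf)
        if not (0.0 < self.q_inf <= 100.0):
            raise ValueError(f"dataset {self.id!r}: q_inf must be in (0, 100]")
        if self.q_inf < np.max(self.release) - _BOUND_TOL:
            raise ValueError(
                f"dataset {self.id!r}: q_inf below maximum observed release"
            )

    @property
    def n_obs(self) -> int:
        return len(self.times)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "times": self.times.tolist(),
            "release": self.release.tolist(),
            "q_inf": self.q_inf,
            "meta": dict(self.meta),
        }


def _require_numeric(frame: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    out = frame.copy()
    for col in cols:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            raise ValueError(
                f"{path}: non-numeric value(s) in column {col!r}: "
                f"{out.loc[bad, col].head().tolist()}"
            )
        out[col] = converted
    return out


def _read_metadata(path) -> dict[str, dict]:
    frame = pd.read_csv(path, dtype={"dataset_id": str})
    if "dataset_id" not in frame.columns:
        raise ValueError(f"{path}: metadata sidecar requires a dataset_id column")
    meta: dict[str, dict] = {}
    for _, row in frame.iterrows():
        record = {k: v for k, v in row.items() if k != "dataset_id" and pd.notna(v)}
        meta[str(row["dataset_id"])] = record
    return meta


def read_release_table(
    path,
    dialect: str = "long",
    metadata: str | Path | None = None,
) -> list[ReleaseDataset]:
    """Read a CSV of release curves and return validated datasets.

    The *long* dialect has exactly the columns ``dataset_id,time_h,release_pct``.
    The *wide* dialect has one ``time_h`` column and one column per dataset id;
    blank cells are skipped.  An optional metadata sidecar (CSV keyed by
    ``dataset_id``) attaches free columns to each dataset; a numeric ``q_inf``
    or ``total_release_pct`` column overrides the default plateau.

    Output is deterministic: datasets sorted by id, observations by time.
    Duplicate ``(id, time)`` pairs are an error, as are non-numeric cells,
    release values outside [0, 100] and ids with fewer than 3 points.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if dialect == "long":
        missing = [c for c in LONG_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: long dialect missing columns {missing}")
        frame = frame.loc[:, list(LONG_COLUMNS)]
        frame["dataset_id"] = frame["dataset_id"].astype(str)
        frame = _require_numeric(frame, ["time_h", "release_pct"], path)
    elif dialect == "wide":
        if "time_h" not in frame.columns:
            raise ValueError(f"{path}: wide dialect requires a time_h column")
        value_cols = [c for c in frame.columns if c != "time_h"]
        frame = _require_numeric(frame, ["time_h"] + value_cols, path)
        frame = frame.melt(
            id_vars="time_h", var_name="dataset_id", value_name="release_pct"
        ).dropna(subset=["release_pct"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if frame["release_pct"].isna().any() or frame["time_h"].isna().any():
        raise ValueError(f"{path}: missing time or release values")

    side = _read_metadata(metadata) if metadata is not None else {}

    datasets = []
    for ds_id, group in frame.groupby("dataset_id", sort=True):
        group = group.sort_values("time_h")
        if group["time_h"].duplicated().any():
            raise ValueError(f"{path}: duplicate times for dataset {ds_id!r}")
        if len(group) < 3:
            raise ValueError(
                f"{path}: dataset {ds_id!r} has fewer than 3 observations"
            )
        meta = dict(side.get(str(ds_id), {}))
        q_inf = None
        for key in ("q_inf", "total_release_pct"):
            if key in meta:
                q_inf = float(meta[key])
        datasets.append(
            ReleaseDataset(
                id=str(ds_id),
                times=group["time_h"].to_numpy(),
                release=group["release_pct"].to_numpy(),
                q_inf=q_inf,
                meta=meta,
            )
        )
    return datasets


def write_release_table(
    datasets: Iterable[ReleaseDataset], path, dialect: str = "long"
) -> None:
    """Write datasets back to CSV in the long or wide dialect."""
    datasets = sorted(datasets, key=lambda d: d.id)
    if dialect == "long":
        rows = [
            (ds.id, t, q)
            for ds in datasets
            for t, q in zip(ds.times, ds.release)
        ]
        pd.DataFrame(rows, columns=list(LONG_COLUMNS)).to_csv(path, index=False)
    elif dialect == "wide":
        series = {
            ds.id: pd.Series(ds.release, index=ds.times) for ds in datasets
        }
        frame = pd.DataFrame(series)
        frame.index.name = "time_h"
        frame.to_csv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def datasets_to_json(datasets: Iterable[ReleaseDataset]) -> list[dict]:
    return [ds.to_dict() for ds in sorted(datasets, key=lambda d: d.id)]


def write_json(datasets: Iterable[ReleaseDataset], path) -> None:
    Path(path).write_text(json.dumps(datasets_to_json(datasets), indent=2))


def validate(ds: ReleaseDataset) -> list[str]:
    """Return quality warnings (never errors) for a constructed dataset.

    Warnings flag: fewer than 8 observations (too few for firm statistical
    conclusions), non-monotone cumulative release (digitization jitter), and
    release reaching exactly 100% (such points are excluded by the Weibull
    and hyperbolic-tangent transforms).
    """
    warnings = []
    if ds.n_obs < 8:
        warnings.append(
            f"n = {ds.n_obs} < 8 observations; statistical conclusions are weak"
        )
    if np.any(np.diff(ds.release) < 0):
        warnings.append("cumulative release decreases at some time step")
    if np.any(ds.release >= 100.0):
        warnings.append(
            "release reaches 100%; such points are excluded by the Weibull "
            "and hyperbolic-tangent transforms"
        )
    return warnings
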