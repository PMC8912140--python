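"""Transport-mechanism labels from fitted shape parameters.

The Weibull shape factor beta classifies the release curve: parabolic for
beta < 1, exponential at beta = 1, sigmoidal for beta > 1.  A literature
overlay maps beta onto transport regimes: Fickian diffusion for
beta <= 0.75, anomalous transport (diffusion plus swelling) between 0.75
and 1, and relaxation/erosion-controlled (case-II type) transport at and
above 1.

The Korsmeyer-Peppas release exponent n carries the classical mechanism
reading; regressing beta on n across a corpus calibrates which beta values
correspond to the standard reference exponents (defaults are the spherical
geometry constants: n = 0.43 for Fickian diffusion, n = 0.85 for case-II
transport).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model_selection import SelectionOutcome, evaluate_model
from .release_data import ReleaseDataset

__all__ = [
    "MechanismReport",
    "BetaNMap",
    "classify_beta",
    "diffusion_regime",
    "fit_beta_n",
    "mechanism_report",
    "corpus_mechanism",
]

_BETA_TOL = 1e-9
N_FICKIAN_SPHERE = 0.43
N_CASE2_SPHERE = 0.85


@dataclass
class MechanismReport:
    dataset_id: str
    weibull_beta: float | None
    beta_class: str | None
    diffusion_class: str | None
    kp_n: float | None
    notes: str = ""

    def to_record(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "weibull_beta": self.weibull_beta,
            "beta_class": self.beta_class,
            "diffusion_class": self.diffusion_class,
            "kp_n": self.kp_n,
            "notes": self.notes,
        }


@dataclass
class BetaNMap:
    slope: float
    intercept: float
    n_fickian: float
    n_case2: float
    beta_at_fickian: float
    beta_at_case2: float
    n_datasets_used: int


def classify_beta(beta: float, tol: float = _BETA_TOL) -> str:
    """Curve-shape class of the Weibull shape factor."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if abs(beta - 1.0) <= tol:
        return "exponential"
    return "parabolic" if beta < 1.0 else "sigmoidal"


def diffusion_regime(beta: float, tol: float = _BETA_TOL) -> str:
    """Literature transport-regime overlay on the Weibull beta."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if beta <= 0.75:
        return "fickian"
    if beta < 1.0 - tol:
        return "anomalous"
    if beta <= 1.0 + tol:
        return "case_ii"
    return "super_case_ii"


def fit_beta_n(
    pairs: Iterable[tuple[float, float]],
    n_fickian: float = N_FICKIAN_SPHERE,
    n_case2: float = N_CASE2_SPHERE,
) -> BetaNMap:
    """OLS line beta = intercept + slope * n across (n, beta) pairs.

    Evaluating the line at the reference exponents translates the classical
    Korsmeyer-Peppas mechanism thresholds into corpus-specific beta values.
    Requires >= 3 finite pairs with non-zero variance in n.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, beta) tuples")
    arr = arr[np.all(np.isfinite(arr), axis=1)]
    if len(arr) < 3:
        raise ValueError("need at least 3 finite (n, beta) pairs")
    n_vals, betas = arr[:, 0], arr[:, 1]
    if np.ptp(n_vals) == 0:
        raise ValueError("zero variance in n; line is undefined")
    slope, intercept = np.polyfit(n_vals, betas, 1)
    return BetaNMap(
        slope=float(slope),
        intercept=float(intercept),
        n_fickian=float(n_fickian),
        n_case2=float(n_case2),
        beta_at_fickian=float(intercept + slope * n_fickian),
        beta_at_case2=float(intercept + slope * n_case2),
        n_datasets_used=int(len(arr)),
    )


def _slope_of(outcome: SelectionOutcome) -> float | None:
    if outcome.surviving and outcome.final_fit is not None:
        return float(outcome.final_fit.coefficients[-1])
    return None


def mechanism_report(
    ds: ReleaseDataset, alpha: float = 0.05, rule: str = "p_value"
) -> MechanismReport:
    """Weibull beta and Korsmeyer-Peppas n for one curve.

    Both shape parameters are the slopes of each model's final fit after the
    accept/recalculate pipeline (the intercept-free refit when applied).
    Fields are None, with a note, when the model did not survive.
    """
    weibull = evaluate_model(ds, "weibull", alpha, rule)
    kp = evaluate_model(ds, "korsmeyer_peppas_100", alpha, rule)
    beta = _slope_of(weibull)
    n = _slope_of(kp)
    notes = []
    if beta is None:
        notes.append(f"weibull {weibull.status}")
    if n is None:
        notes.append(f"korsmeyer_peppas_100 {kp.status}")
    return MechanismReport(
        dataset_id=ds.id,
        weibull_beta=beta,
        beta_class=classify_beta(beta) if beta is not None else None,
        diffusion_class=diffusion_regime(beta) if beta is not None else None,
        kp_n=n,
        notes="; ".join(notes),
    )


def corpus_mechanism(
    datasets: Sequence[ReleaseDataset],
    alpha: float = 0.05,
    rule: str = "p_value",
    n_fickian: float = N_FICKIAN_SPHERE,
    n_case2: float = N_CASE2_SPHERE,
) -> tuple[list[MechanismReport], BetaNMap | None]:
    """Per-dataset mechanism rows plus the corpus beta-vs-n calibration.

    The calibration is None when fewer than 3 datasets provide both shape
    parameters (or n has zero variance among them).
    """
    reports = [mechanism_report(ds, alpha, rule) for ds in datasets]
    pairs = [
        (r.kp_n, r.weibull_beta)
        for r in reports
        if r.kp_n is not None and r.weibull_beta is not None
    ]
    try:
        beta_n = fit_beta_n(pairs, n_fickian, n_case2)
    except ValueError:
        beta_n = None
    return reports, beta_n
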