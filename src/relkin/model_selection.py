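"""Per-dataset accept / recalculate / reject decisions and best-model ranking.

The decision pipeline for each (dataset, model) pair:

1. linearize (the truncated power law first restricts the curve to <= 60%);
2. fit with intercept;
3. intercept not significant -> refit through the origin ("recalculated");
4. slope (kinetic models) or highest-order term (polynomials) not
   significant -> model rejected, since a polynomial whose last term is zero
   collapses to a lower degree;
5. overall F test not significant -> rejected; otherwise accepted.

Significance follows either the exact t-distribution p-value (p <= alpha,
default) or the literal large-sample cut |t| >= 1.96; at the tiny n of
digitized dissolution curves the two can disagree.

Ranking across surviving models uses adjusted R^2 (R^2 as tiebreak) for the
fit-quality view and AIC (BIC as tiebreak) for the information-criterion
view; criteria equal to within 1e-12 fall back to parsimony (fewer
coefficients) then registry order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDesign, InsufficientData
from .kinetic_models import MODEL_REGISTRY, ModelSpec, get_model, linearize
from .linear_fit import FitResult, fit_ols, refit_zero_intercept
from .release_data import ReleaseDataset

__all__ = [
    "SelectionOutcome",
    "Verdict",
    "evaluate_model",
    "evaluate_all",
    "rank_models",
    "summarize_corpus",
    "decision_matrix",
    "verdict_frame",
]

STATUS_ACCEPTED = "accepted"
STATUS_RECALCULATED = "recalculated_then_accepted"
STATUS_REJECTED = "rejected"
STATUS_INSUFFICIENT = "insufficient_data"

_SURVIVING = (STATUS_ACCEPTED, STATUS_RECALCULATED)
_TIE_TOL = 1e-12


@dataclass
class SelectionOutcome:
    dataset_id: str
    model_name: str
    status: str
    reason: str = "none"
    final_fit: FitResult | None = None
    with_intercept_fit: FitResult | None = None

    @property
    def surviving(self) -> bool:
        return self.status in _SURVIVING

    def cell(self) -> str:
        """Decision-matrix cell code: A / RC / X / ID."""
        return {
            STATUS_ACCEPTED: "A",
            STATUS_RECALCULATED: "RC",
            STATUS_REJECTED: "X",
            STATUS_INSUFFICIENT: "ID",
        }[self.status]


@dataclass
class Verdict:
    dataset_id: str
    best_by_r2: str | None
    best_by_ic: str | None


def _significant(fit: FitResult, index: int, alpha: float, rule: str) -> bool:
    if rule == "p_value":
        p = fit.p_values[index]
        return bool(np.isfinite(p) and p <= alpha)
    if rule == "critical_1_96":
        t = fit.t_values[index]
        return bool(abs(t) >= 1.96) if not np.isnan(t) else False
    raise ValueError(f"unknown significance rule {rule!r}")


def evaluate_model(
    ds: ReleaseDataset,
    model: ModelSpec | str,
    alpha: float = 0.05,
    rule: str = "p_value",
) -> SelectionOutcome:
    """Run the accept / recalculate / reject pipeline for one model."""
    if isinstance(model, str):
        model = get_model(model)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    try:
        points = linearize(model, ds)
    except InsufficientData:
        return SelectionOutcome(ds.id, model.name, STATUS_INSUFFICIENT, "too_few_points")

    try:
        with_int = fit_ols(points, with_intercept=True)
    except (InsufficientData, DegenerateDesign):
        return SelectionOutcome(ds.id, model.name, STATUS_INSUFFICIENT, "too_few_points")

    fit = with_int
    recalculated = False
    if not _significant(with_int, 0, alpha, rule):
        try:
            fit = refit_zero_intercept(points)
            recalculated = True
        except (InsufficientData, DegenerateDesign):
            return SelectionOutcome(
                ds.id, model.name, STATUS_INSUFFICIENT, "too_few_points", None, with_int
            )

    # slope for kinetic models; highest-order term for polynomials -- in the
    # intercept-first coefficient vector both are the last entry, and they
    # remain last after dropping the intercept.
    slope_reason = "last_term_ns" if model.kind == "polynomial" else "slope_ns"
    if not _significant(fit, len(fit.coefficients) - 1, alpha, rule):
        return SelectionOutcome(
            ds.id, model.name, STATUS_REJECTED, slope_reason, fit, with_int
        )
    if not (np.isfinite(fit.f_pvalue) and fit.f_pvalue <= alpha) and not np.isinf(
        fit.f_statistic
    ):
        return SelectionOutcome(
            ds.id, model.name, STATUS_REJECTED, "f_test_ns", fit, with_int
        )

    status = STATUS_RECALCULATED if recalculated else STATUS_ACCEPTED
    return SelectionOutcome(ds.id, model.name, status, "none", fit, with_int)


def evaluate_all(
    datasets: Iterable[ReleaseDataset],
    models: Sequence[str] | None = None,
    alpha: float = 0.05,
    rule: str = "p_value",
) -> dict[str, list[SelectionOutcome]]:
    """Outcomes for every dataset x model pair, keyed by dataset id."""
    names = list(models) if models is not None else list(MODEL_REGISTRY)
    return {
        ds.id: [evaluate_model(ds, name, alpha, rule) for name in names]
        for ds in datasets
    }


def _registry_index(name: str) -> int:
    return list(MODEL_REGISTRY).index(name)


def _pick(
    survivors: list[SelectionOutcome],
    primary,
    secondary,
) -> str | None:
    """Best model by (primary, secondary) with 1e-12 ties broken by parsimony."""
    if not survivors:
        return None

    def shrink(pool: list[SelectionOutcome], key) -> list[SelectionOutcome]:
        best = min(key(o) for o in pool)
        # the equality clause keeps -inf (perfect-fit sentinel) ties together
        return [o for o in pool if key(o) == best or key(o) - best <= _TIE_TOL]

    pool = shrink(survivors, primary)
    pool = shrink(pool, secondary)
    pool.sort(
        key=lambda o: (
            MODEL_REGISTRY[o.model_name].n_params,
            _registry_index(o.model_name),
        )
    )
    return pool[0].model_name


def rank_models(outcomes: Sequence[SelectionOutcome]) -> Verdict:
    """Best surviving model under the R^2-family and the AIC-family view."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("rank_models requires at least one outcome")
    ds_id = outcomes[0].dataset_id
    survivors = [o for o in outcomes if o.surviving and o.final_fit is not None]
    best_r2 = _pick(
        survivors,
        primary=lambda o: -o.final_fit.r2_adj,
        secondary=lambda o: -o.final_fit.r2,
    )
    best_ic = _pick(
        survivors,
        primary=lambda o: o.final_fit.aic,
        secondary=lambda o: o.final_fit.bic,
    )
    return Verdict(ds_id, best_r2, best_ic)


def summarize_corpus(verdicts: Sequence[Verdict]) -> dict:
    """Corpus-level shares: per-model best counts, no-model sets, agreement.

    Percentages use the full dataset count as denominator (no-model sets
    included).  The agreement fraction is the share of datasets whose two
    criteria name the same model, excluding datasets where both are none.
    """
    verdicts = list(verdicts)
    if not verdicts:
        raise ValueError("no verdicts to summarize")
    n = len(verdicts)
    r2_counts: dict[str, int] = {}
    ic_counts: dict[str, int] = {}
    no_model_ids = []
    agree = 0
    comparable = 0
    for v in verdicts:
        if v.best_by_r2 is None and v.best_by_ic is None:
            no_model_ids.append(v.dataset_id)
        else:
            comparable += 1
            if v.best_by_r2 == v.best_by_ic:
                agree += 1
        if v.best_by_r2 is not None:
            r2_counts[v.best_by_r2] = r2_counts.get(v.best_by_r2, 0) + 1
        if v.best_by_ic is not None:
            ic_counts[v.best_by_ic] = ic_counts.get(v.best_by_ic, 0) + 1
    return {
        "n_datasets": n,
        "no_model_count": len(no_model_ids),
        "no_model_ids": sorted(no_model_ids),
        "agreement_fraction": agree / comparable if comparable else float("nan"),
        "best_by_r2_counts": dict(sorted(r2_counts.items())),
        "best_by_ic_counts": dict(sorted(ic_counts.items())),
        "best_by_r2_pct": {m: 100.0 * c / n for m, c in sorted(r2_counts.items())},
        "best_by_ic_pct": {m: 100.0 * c / n for m, c in sorted(ic_counts.items())},
    }


def decision_matrix(
    outcomes_by_dataset: dict[str, list[SelectionOutcome]]
) -> pd.DataFrame:
    """Dataset x model matrix of A / RC / X / ID cells."""
    rows = {}
    for ds_id in sorted(outcomes_by_dataset):
        rows[ds_id] = {o.model_name: o.cell() for o in outcomes_by_dataset[ds_id]}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    ordered = [m for m in MODEL_REGISTRY if m in frame.columns]
    frame = frame.loc[:, ordered]
    frame.index.name = "dataset_id"
    return frame


def verdict_frame(verdicts: Sequence[Verdict]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "dataset_id": [v.dataset_id for v in verdicts],
            "best_by_r2": [v.best_by_r2 or "no model" for v in verdicts],
            "best_by_ic": [v.best_by_ic or "no model" for v in verdicts],
        }
    ).set_index("dataset_id")
    return frame.sort_index()
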