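"""Case-resampling bootstrap for release-model fits on small curves.

Digitized dissolution curves carry as few as 3-14 observations, too few for
asymptotic inference, so observation pairs of the linearized design are
resampled with replacement at the original n and the plain with-intercept
OLS is refit per replicate (no accept/reject decisions inside the loop).
Summaries are the replicate means of the coefficients, R^2 and AIC, plus
2.5/97.5 percentile confidence intervals.

Replicates whose resampled design cannot support the fit with a residual
degree of freedom -- fewer distinct predictor values than coefficients plus
one, which covers the all-x-equal case -- are discarded and counted, never
redrawn, so the resampling distribution is not distorted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import BootstrapFailed, InsufficientData
from .kinetic_models import MODEL_REGISTRY, ModelSpec, get_model, linearize
from .release_data import ReleaseDataset

__all__ = [
    "BootstrapSummary",
    "BootstrapVerdict",
    "bootstrap_fit",
    "bootstrap_best_model",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20220310
_TIE_TOL = 1e-12
_LN_2PI = math.log(2 * math.pi)


@dataclass
class BootstrapSummary:
    dataset_id: str
    model_name: str
    n_boot: int
    param_names: tuple[str, ...]
    param_estimates: np.ndarray  # replicate means, intercept first
    param_ci95: list[tuple[float, float]]
    r2_boot: float
    aic_boot: float
    n_failed: int
    seed: int

    def to_record(self) -> dict:
        rec = {
            "dataset_id": self.dataset_id,
            "model": self.model_name,
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "r2_boot": self.r2_boot,
            "aic_boot": self.aic_boot,
        }
        for name, est, (lo, hi) in zip(
            self.param_names, self.param_estimates, self.param_ci95
        ):
            rec[f"boot_{name}"] = est
            rec[f"ci_lo_{name}"] = lo
            rec[f"ci_hi_{name}"] = hi
        return rec


@dataclass
class BootstrapVerdict:
    dataset_id: str
    best_by_aic: str | None
    best_by_r2: str | None
    summaries: dict[str, BootstrapSummary] = field(default_factory=dict)


def bootstrap_fit(
    ds: ReleaseDataset,
    model: ModelSpec | str,
    n_boot: int = 1000,
    seed: int = DEFAULT_SEED,
) -> BootstrapSummary:
    """Bootstrap the with-intercept OLS fit of one model on one curve.

    Resampling happens on the linearized points after exclusion, so every
    replicate sees the same transform domain.  Identical (dataset, model,
    n_boot, seed) inputs reproduce the summary bit for bit.
    """
    if isinstance(model, str):
        model = get_model(model)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    points = linearize(model, ds)
    X = points.design(with_intercept=True)
    y = np.asarray(points.y, dtype=float)
    n, k = X.shape
    base = points.x[:, 0] if points.x.ndim == 2 else points.x

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))

    base_sorted = np.sort(base[idx], axis=1)
    distinct = 1 + np.count_nonzero(np.diff(base_sorted, axis=1) != 0, axis=1)
    good = distinct >= k + 1
    n_failed = int(n_boot - np.count_nonzero(good))
    if n_failed == n_boot:
        raise BootstrapFailed(
            f"dataset {ds.id!r}, model {model.name}: all {n_boot} replicates degenerate"
        )

    Xb = X[idx[good]]  # (B, n, k)
    yb = y[idx[good]]  # (B, n)
    # pseudoinverse solve: stable for ill-conditioned polynomial designs
    beta = np.matmul(np.linalg.pinv(Xb), yb[..., None])[..., 0]  # (B, k)

    fitted = np.matmul(Xb, beta[..., None])[..., 0]
    resid = yb - fitted
    sse = np.sum(resid**2, axis=1)
    sst = np.sum((yb - yb.mean(axis=1, keepdims=True)) ** 2, axis=1)
    sse = np.where(sse <= 1e-12 * np.maximum(sst, 1.0), 0.0, sse)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, 1.0)
        aic = np.where(
            sse > 0,
            n * _LN_2PI + n * np.log(sse / n) + n + 2 * (k + 1),
            -np.inf,
        )

    lo, hi = np.percentile(beta, [2.5, 97.5], axis=0)
    return BootstrapSummary(
        dataset_id=ds.id,
        model_name=model.name,
        n_boot=n_boot,
        param_names=model.param_names,
        param_estimates=beta.mean(axis=0),
        param_ci95=[(float(a), float(b)) for a, b in zip(lo, hi)],
        r2_boot=float(np.mean(r2)),
        aic_boot=float(np.mean(aic)),
        n_failed=n_failed,
        seed=int(seed),
    )


def _child_seed(seed: int, index: int) -> int:
    state = np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0]
    return int(state % (2**31))


def bootstrap_best_model(
    ds: ReleaseDataset,
    models: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = DEFAULT_SEED,
) -> BootstrapVerdict:
    """Rank models on one curve by bootstrap AIC (most negative wins).

    The bootstrap path needs no significance tests, so it can adjudicate
    curves too short for the deterministic accept/reject pipeline.  The
    bootstrap R^2 ranking is reported as a secondary view.  Ties within
    1e-12 fall back to parsimony, then registry order.
    """
    names = list(models) if models is not None else list(MODEL_REGISTRY)
    summaries: dict[str, BootstrapSummary] = {}
    for i, name in enumerate(names):
        try:
            summaries[name] = bootstrap_fit(
                ds, name, n_boot=n_boot, seed=_child_seed(seed, i)
            )
        except (InsufficientData, BootstrapFailed):
            continue
    if not summaries:
        raise BootstrapFailed(f"dataset {ds.id!r}: no model yields a usable summary")

    def pick(score) -> str | None:
        usable = {m: s for m, s in summaries.items() if np.isfinite(score(s)) or score(s) == -np.inf}
        if not usable:
            return None
        best = min(score(s) for s in usable.values())
        pool = [
            m
            for m, s in usable.items()
            if score(s) == best or score(s) - best <= _TIE_TOL
        ]
        pool.sort(
            key=lambda m: (MODEL_REGISTRY[m].n_params, list(MODEL_REGISTRY).index(m))
        )
        return pool[0]

    best_aic = pick(lambda s: s.aic_boot)
    best_r2 = pick(lambda s: -s.r2_boot)
    return BootstrapVerdict(ds.id, best_aic, best_r2, summaries)
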