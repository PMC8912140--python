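"""Ordinary-least-squares engine with the full acceptance-statistic set.

Fits linearized release models and reports coefficients, standard errors,
t and two-tailed p values, the overall F test, R^2 / adjusted R^2, the sums
of squares, and Gaussian-likelihood AIC/BIC.  Regression through the origin
(used when an intercept fails its significance test) reports the uncentered
R^2, matching the convention of standard linear-model summaries for
no-intercept fits.

AIC/BIC count the error variance as a fitted parameter (k = p + 1 for p
regression coefficients):

    AIC = n ln(2 pi) + n ln(SSE / n) + n + 2 (p + 1)
    BIC = n ln(2 pi) + n ln(SSE / n) + n + ln(n) (p + 1)

An exact fit (SSE = 0) yields a -inf sentinel rather than an error, so
saturating polynomials on tiny curves rank as best-possible instead of
crashing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateDesign, InsufficientData
from .kinetic_models import LinearizedPoints

__all__ = ["FitResult", "fit_ols", "refit_zero_intercept", "information_criteria"]

# relative threshold below which a residual sum of squares counts as exact
_EXACT_TOL = 1e-12


@dataclass
class FitResult:
    """Everything a selection rule or report needs from one OLS fit."""

    model_name: str
    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    f_statistic: float
    f_pvalue: float
    r2: float
    r2_adj: float
    ssr: float  # regression (explained) sum of squares
    sse: float  # error (residual) sum of squares
    sst: float  # total sum of squares (centered iff intercept included)
    aic: float
    bic: float
    n_obs: int
    df_resid: int
    intercept_included: bool
    param_names: tuple[str, ...] = ()
    perfect_fit: bool = False
    excluded_points: list = field(default_factory=list)
    dataset_id: str | None = None

    def full_coefficients(self, n_params: int) -> np.ndarray:
        """Intercept-first coefficient vector padded with 0 for origin fits."""
        if self.intercept_included:
            return np.asarray(self.coefficients, dtype=float)
        return np.concatenate([[0.0], self.coefficients])

    def to_record(self) -> dict:
        rec = {
            "dataset_id": self.dataset_id,
            "model": self.model_name,
            "n_obs": self.n_obs,
            "df_resid": self.df_resid,
            "intercept_included": self.intercept_included,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "ssr": self.ssr,
            "sse": self.sse,
            "sst": self.sst,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "aic": self.aic,
            "bic": self.bic,
            "perfect_fit": self.perfect_fit,
            "n_excluded": len(self.excluded_points),
        }
        names = self.param_names or tuple(
            f"b{i}" for i in range(len(self.coefficients))
        )
        for name, c, se, t, p in zip(
            names, self.coefficients, self.std_errors, self.t_values, self.p_values
        ):
            rec[f"coef_{name}"] = c
            rec[f"se_{name}"] = se
            rec[f"t_{name}"] = t
            rec[f"p_{name}"] = p
        return rec


def _ic_from_sse(n: int, p: int, sse: float) -> tuple[float, float]:
    if sse <= 0.0:
        return -math.inf, -math.inf
    base = n * math.log(2 * math.pi) + n * math.log(sse / n) + n
    return base + 2 * (p + 1), base + math.log(n) * (p + 1)


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """Gaussian-likelihood AIC and BIC with the variance counted as a parameter."""
    p = len(fit.coefficients)
    return _ic_from_sse(fit.n_obs, p, 0.0 if fit.perfect_fit else fit.sse)


def fit_ols(points: LinearizedPoints, with_intercept: bool = True) -> FitResult:
    """Fit one linearized model by ordinary least squares.

    Raises :class:`InsufficientData` without a residual degree of freedom and
    :class:`DegenerateDesign` for rank-deficient designs (e.g. all predictor
    values identical).
    """
    X = points.design(with_intercept)
    y = np.asarray(points.y, dtype=float)
    n, k = X.shape
    if n < k + 1:
        raise InsufficientData(
            f"{points.model_name}: {n} points cannot support {k} coefficients "
            "with a residual degree of freedom"
        )
    if np.linalg.matrix_rank(X) < k:
        raise DegenerateDesign(
            f"{points.model_name}: design matrix is rank deficient"
        )

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    if with_intercept:
        sst = float(np.sum((y - y.mean()) ** 2))
    else:
        sst = float(y @ y)
    scale = max(sst, float(y @ y), 1.0)
    perfect = sse <= _EXACT_TOL * scale
    if perfect:
        sse = 0.0
    ssr = max(sst - sse, 0.0)

    df_resid = n - k
    if sst > 0:
        r2 = 1.0 - sse / sst
    else:
        # flat response: exact fit has r2 = 1 by convention, else undefined
        r2 = 1.0 if perfect else float("nan")
    df_int = 1 if with_intercept else 0
    r2_adj = 1.0 - (1.0 - r2) * (n - df_int) / df_resid

    sigma2 = sse / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    std_errors = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_values = beta / std_errors
    # in an exact fit a numerically-zero coefficient carries no evidence,
    # while a clearly nonzero one is infinitely significant
    beta_zero = np.abs(beta) <= 1e-10 * max(1.0, float(np.max(np.abs(beta))))
    zero_zero = (std_errors == 0) & beta_zero
    t_values = np.where(zero_zero, 0.0, t_values)
    with np.errstate(invalid="ignore"):
        t_values = np.where(
            (std_errors == 0) & ~beta_zero, np.sign(beta) * np.inf, t_values
        )
    p_values = np.where(
        np.isinf(t_values),
        0.0,
        2.0 * stats.t.sf(np.abs(t_values), df_resid),
    )
    p_values = np.where(zero_zero, 1.0, p_values)

    df_model = k - df_int
    if df_model > 0:
        if sigma2 > 0:
            f_stat = (ssr / df_model) / sigma2
            f_pvalue = float(stats.f.sf(f_stat, df_model, df_resid))
        else:
            f_stat, f_pvalue = math.inf, 0.0
    else:  # intercept-only model: no overall test
        f_stat, f_pvalue = math.nan, math.nan

    aic, bic = _ic_from_sse(n, k, sse)

    return FitResult(
        model_name=points.model_name,
        coefficients=beta,
        std_errors=std_errors,
        t_values=t_values,
        p_values=p_values,
        f_statistic=float(f_stat),
        f_pvalue=float(f_pvalue),
        r2=float(r2),
        r2_adj=float(r2_adj),
        ssr=ssr,
        sse=sse,
        sst=sst,
        aic=aic,
        bic=bic,
        n_obs=n,
        df_resid=df_resid,
        intercept_included=with_intercept,
        param_names=tuple(
            _param_names_for(points.model_name, k, with_intercept)
        ),
        perfect_fit=perfect,
        excluded_points=list(points.excluded),
        dataset_id=points.dataset_id,
    )


def _param_names_for(model_name: str, k: int, with_intercept: bool) -> tuple[str, ...]:
    from .kinetic_models import MODEL_REGISTRY

    spec = MODEL_REGISTRY.get(model_name)
    if spec is None:
        names = tuple(f"b{i}" for i in range(k + (0 if with_intercept else 1)))
    else:
        names = spec.param_names
    return names if with_intercept else names[1:]


def refit_zero_intercept(points: LinearizedPoints) -> FitResult:
    """Regression through the origin with uncentered R^2."""
    return fit_ols(points, with_intercept=False)
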