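"""Registry of candidate release models and their linearizing transforms.

Five empirical/semi-empirical kinetic laws plus second- to fifth-order
polynomials in time, each fitted by ordinary least squares on a linearized
form:

======================  =============================================
zero_order              Qt = Q0 + k0*t
first_order             ln Qt = ln Q0 + k1*t
korsmeyer_peppas_*      ln Qt = ln kKP + n*ln t   (power law)
weibull                 ln(-ln(1 - Qt/100)) = ln(alpha) + beta*ln t
hyperbolic_tangent      atanh(Qt/Q_inf) = beta + alpha*sqrt(t)
poly2..poly5            Qt = a + b*t + c*t^2 + ...
======================  =============================================

The Korsmeyer-Peppas power law is classically valid only for the first 60%
of the curve, so it enters the candidate set twice: fitted to the full curve
(``korsmeyer_peppas_100``) and to the prefix with Qt <= 60%
(``korsmeyer_peppas_60``).

Observations where a transform is undefined (log of a non-positive release,
Weibull at 100%, hyperbolic tangent at or beyond the plateau) are dropped
with machine-readable reasons rather than clipped; an optional clip mode
nudges boundary values inside the domain instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InsufficientData
from .release_data import ReleaseDataset

__all__ = [
    "ModelSpec",
    "LinearizedPoints",
    "MODEL_REGISTRY",
    "KINETIC_MODEL_NAMES",
    "POLYNOMIAL_MODEL_NAMES",
    "get_model",
    "linearize",
    "truncate_60",
    "predict",
]

_CLIP_EPS = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one candidate model.

    ``n_params`` counts regression coefficients including the intercept;
    ``min_points`` enforces at least one residual degree of freedom.
    ``param_names`` gives the intercept-first coefficient symbols.
    """

    name: str
    n_params: int
    min_points: int
    param_names: tuple[str, ...]
    kind: str  # "kinetic" or "polynomial"
    degree: int | None = None

    def __post_init__(self) -> None:
        if self.min_points < self.n_params + 1:
            raise ValueError(
                f"{self.name}: min_points must allow a residual degree of freedom"
            )


def _poly_spec(degree: int) -> ModelSpec:
    letters = "abcdef"
    return ModelSpec(
        name=f"poly{degree}",
        n_params=degree + 1,
        min_points=degree + 2,
        param_names=tuple(letters[: degree + 1]),
        kind="polynomial",
        degree=degree,
    )


MODEL_REGISTRY: dict[str, ModelSpec] = {
    spec.name: spec
    for spec in [
        ModelSpec("zero_order", 2, 3, ("Q0", "k0"), "kinetic"),
        ModelSpec("first_order", 2, 3, ("ln_Q0", "k1"), "kinetic"),
        ModelSpec("korsmeyer_peppas_100", 2, 3, ("ln_kKP", "n"), "kinetic"),
        ModelSpec("korsmeyer_peppas_60", 2, 3, ("ln_kKP", "n"), "kinetic"),
        ModelSpec("weibull", 2, 3, ("ln_alpha", "beta"), "kinetic"),
        ModelSpec("hyperbolic_tangent", 2, 3, ("beta", "alpha"), "kinetic"),
        _poly_spec(2),
        _poly_spec(3),
        _poly_spec(4),
        _poly_spec(5),
    ]
}

KINETIC_MODEL_NAMES = tuple(
    n for n, s in MODEL_REGISTRY.items() if s.kind == "kinetic"
)
POLYNOMIAL_MODEL_NAMES = tuple(
    n for n, s in MODEL_REGISTRY.items() if s.kind == "polynomial"
)


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; choose from {sorted(MODEL_REGISTRY)}"
        ) from None


@dataclass
class LinearizedPoints:
    """Transformed (x, y) pairs for one model with exclusion bookkeeping.

    ``x`` has shape (n,) for single-predictor models and (n, degree) for
    polynomials (columns t, t^2, ...); the intercept column is added by the
    fitting engine.  ``included_index`` maps rows back to the source
    observations; ``excluded`` lists (index, reason) pairs.
    """

    model_name: str
    x: np.ndarray
    y: np.ndarray
    included_index: np.ndarray
    excluded: list[tuple[int, str]] = field(default_factory=list)
    q_inf: float | None = None
    dataset_id: str | None = None

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def design(self, with_intercept: bool = True) -> np.ndarray:
        X = self.x if self.x.ndim == 2 else self.x[:, None]
        if with_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X


def truncate_60(ds: ReleaseDataset) -> ReleaseDataset:
    """Return the prefix of the curve with cumulative release <= 60%.

    The boundary is inclusive.  Raises :class:`InsufficientData` when fewer
    than 3 observations survive (curves that blow through 60% within their
    first two points cannot support the truncated power-law fit).
    """
    over = np.nonzero(ds.release > 60.0)[0]
    keep = over[0] if len(over) else ds.n_obs
    if keep < 3:
        raise InsufficientData(
            f"dataset {ds.id!r}: only {keep} point(s) at or below 60% release"
        )
    meta = dict(ds.meta)
    meta["truncated_60"] = True
    return ReleaseDataset(
        id=ds.id,
        times=ds.times[:keep].copy(),
        release=ds.release[:keep].copy(),
        q_inf=ds.q_inf,
        meta=meta,
    )


def linearize(
    model: ModelSpec | str, ds: ReleaseDataset, clip: bool = False
) -> LinearizedPoints:
    """Apply a model's linearizing transform to a release curve.

    Points where the transform is undefined are excluded with a reason
    (``clip=True`` instead nudges boundary releases inside the domain by a
    relative 1e-6).  Raises :class:`InsufficientData` when fewer than
    ``model.min_points`` observations survive.
    """
    if isinstance(model, str):
        model = get_model(model)

    if model.name == "korsmeyer_peppas_60":
        ds = truncate_60(ds)

    t = ds.times
    q = ds.release.copy()
    excluded: list[tuple[int, str]] = []

    def keep_where(mask: np.ndarray, reason: str) -> None:
        for i in np.nonzero(~mask)[0]:
            excluded.append((int(idx[i]), reason))

    idx = np.arange(ds.n_obs)

    if model.kind == "polynomial":
        x = np.column_stack([t**p for p in range(1, model.degree + 1)])
        y = q
    elif model.name == "zero_order":
        x, y = t, q
    elif model.name == "first_order":
        mask = q > 0
        keep_where(mask, "release <= 0: log undefined")
        idx, t, q = idx[mask], t[mask], q[mask]
        x, y = t, np.log(q)
    elif model.name in ("korsmeyer_peppas_100", "korsmeyer_peppas_60"):
        mask = (t > 0) & (q > 0)
        keep_where(mask, "t <= 0 or release <= 0: log undefined")
        idx, t, q = idx[mask], t[mask], q[mask]
        x, y = np.log(t), np.log(q)
    elif model.name == "weibull":
        frac = q / 100.0
        if clip:
            frac = np.clip(frac, _CLIP_EPS, 1.0 - _CLIP_EPS)
        mask = (t > 0) & (frac > 0) & (frac < 1)
        keep_where(mask, "t <= 0, release <= 0 or release >= 100%: transform undefined")
        idx, t, frac = idx[mask], t[mask], frac[mask]
        # log1p keeps the inner log accurate for releases near 0 and 100%
        x, y = np.log(t), np.log(-np.log1p(-frac))
    elif model.name == "hyperbolic_tangent":
        frac = q / ds.q_inf
        if clip:
            frac = np.clip(frac, 0.0, 1.0 - _CLIP_EPS)
        mask = (frac >= 0) & (frac < 1)
        keep_where(mask, "release at or beyond q_inf (or negative): atanh undefined")
        idx, t, frac = idx[mask], t[mask], frac[mask]
        x, y = np.sqrt(t), np.arctanh(frac)
    else:  # pragma: no cover - registry is closed
        raise KeyError(model.name)

    points = LinearizedPoints(
        model_name=model.name,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        included_index=idx,
        excluded=excluded,
        q_inf=ds.q_inf,
        dataset_id=ds.id,
    )
    if points.n_obs < model.min_points:
        raise InsufficientData(
            f"dataset {ds.id!r}, model {model.name}: "
            f"{points.n_obs} usable point(s) < min_points {model.min_points}"
        )
    if not (np.all(np.isfinite(points.x)) and np.all(np.isfinite(points.y))):
        raise FloatingPointError(
            f"non-finite transformed values for {model.name} on {ds.id!r}"
        )
    return points


def predict(
    model: ModelSpec | str,
    params: Sequence[float],
    times: Sequence[float],
    q_inf: float | None = None,
) -> np.ndarray:
    """Back-transform fitted coefficients into cumulative percent released.

    ``params`` is the intercept-first coefficient vector on the linearized
    scale (length ``model.n_params``); zero-intercept fits pass 0 for the
    intercept.  Output is clipped to [0, 100].
    """
    if isinstance(model, str):
        model = get_model(model)
    params = np.asarray(params, dtype=float)
    if params.shape != (model.n_params,):
        raise ValueError(
            f"{model.name}: expected {model.n_params} coefficients, "
            f"got shape {params.shape}"
        )
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times")

    if model.kind == "polynomial":
        out = np.polyval(params[::-1], t)
    elif model.name == "zero_order":
        out = params[0] + params[1] * t
    elif model.name == "first_order":
        out = np.exp(params[0] + params[1] * t)
    elif model.name in ("korsmeyer_peppas_100", "korsmeyer_peppas_60"):
        # kKP * t^n with t=0 -> 0 for positive exponent
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.exp(params[0]) * np.power(t, params[1])
        out = np.where(t == 0, 0.0 if params[1] > 0 else out, out)
    elif model.name == "weibull":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 100.0 * (1.0 - np.exp(-np.exp(params[0]) * np.power(t, params[1])))
        out = np.where(t == 0, 0.0 if params[1] > 0 else out, out)
    elif model.name == "hyperbolic_tangent":
        if q_inf is None:
            raise ValueError("hyperbolic_tangent prediction requires q_inf")
        out = q_inf * np.tanh(params[0] + params[1] * np.sqrt(t))
    else:  # pragma: no cover
        raise KeyError(model.name)
    return np.clip(out, 0.0, 100.0)
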