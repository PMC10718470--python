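"""A fitted "second-order" canal-area estimator.

The three fixed shapes bracket the measured area — ellipse and rectangle
overestimate, triangle underestimates — which invites combining them.
Because all three are scalar multiples of the product IPD * AP, every
linear combination of them collapses to ``c * IPD * AP`` for a single
scalar ``c``: the combined family has exactly one effective degree of
freedom.  The estimator implemented here is therefore a scale factor
``k_hat`` fitted by least squares through the origin,

    k_hat = sum(manual * product) / sum(product^2),    product = IPD * AP,

which minimises the residual sum of squares of ``manual - k * product``.
For interpretability ``k_hat`` is re-expressed as the ellipse/triangle
mixing weights ``(w_e, w_t)`` with ``w_e + w_t = 1`` and
``w_e * pi/4 + w_t * 1/2 = k_hat``; weights outside [0, 1] mean the
fitted factor lies outside the ellipse-triangle bracket and the
decomposition extrapolates.

Fitting is per level by default (the effective manual/product ratio
drifts caudally), with a pooled fit available.  Honesty about the fit is
provided by seeded, shuffled k-fold cross-validation of the RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .geometry import LEVELS, Level, shape_factor

__all__ = [
    "SecondOrderFit",
    "ShapeWeights",
    "fit_scale_factor",
    "weights_from_factor",
    "rmse",
    "cross_validate",
    "fit_level",
    "fit_cohort",
]

_W_ELLIPSE = shape_factor("ellipse")  # pi/4
_W_TRIANGLE = shape_factor("triangle")  # 1/2


class ShapeWeights(NamedTuple):
    ellipse: float
    triangle: float
    extrapolating: bool


@dataclass(frozen=True)
class SecondOrderFit:
    """Fitted scale factor for one level (or the pooled cohort)."""

    level: Level | None
    n: int
    k_hat: float
    ellipse_weight: float
    triangle_weight: float
    extrapolating: bool
    training_rmse: float
    cv_rmse: float
    cv_folds: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["level"] = self.level.value if self.level is not None else "pooled"
        return d


def _paired_arrays(products, manual_areas) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(products, dtype=float)
    a = np.asarray(manual_areas, dtype=float)
    if p.shape != a.shape:
        raise ValueError("products and manual areas must have equal length")
    return p, a


def fit_scale_factor(products, manual_areas) -> float:
    """Least-squares-through-origin scale factor k_hat.

    Minimises sum((manual - k * product)^2) over k.
    """
    p, a = _paired_arrays(products, manual_areas)
    if p.size < 2:
        raise ValueError("need at least 2 measurements to fit")
    denom = float(np.dot(p, p))
    if denom == 0.0:
        raise ValueError("all products are zero; scale factor undefined")
    return float(np.dot(a, p) / denom)


def weights_from_factor(k_hat: float) -> ShapeWeights:
    """Ellipse/triangle weights equivalent to a scale factor.

    Solves ``w_e * pi/4 + (1 - w_e) * 1/2 = k_hat``.  Weights outside
    [0, 1] are returned as-is with ``extrapolating=True``.
    """
    w_e = (k_hat - _W_TRIANGLE) / (_W_ELLIPSE - _W_TRIANGLE)
    w_t = 1.0 - w_e
    return ShapeWeights(
        ellipse=float(w_e),
        triangle=float(w_t),
        extrapolating=not (0.0 <= w_e <= 1.0),
    )


def rmse(products, manual_areas, k: float) -> float:
    """Root-mean-square error of the estimator k * product."""
    p, a = _paired_arrays(products, manual_areas)
    return float(np.sqrt(np.mean((a - k * p) ** 2)))


def cross_validate(products, manual_areas, folds: int = 5, seed: int = 0) -> float:
    """Shuffled k-fold cross-validated RMSE of the refitted scale factor.

    Deterministic given ``seed``: the permutation and fold boundaries are
    fixed by a seeded generator, k_hat is refit on each training split
    and scored on the held-out split, and the pooled RMSE over all
    held-out residuals is returned.
    """
    p, a = _paired_arrays(products, manual_areas)
    n = p.size
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"n={n} is smaller than folds={folds}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sq_errors = np.empty(n)
    for fold_idx in np.array_split(order, folds):
        train = np.setdiff1d(order, fold_idx, assume_unique=True)
        k = fit_scale_factor(p[train], a[train])
        sq_errors[fold_idx] = (a[fold_idx] - k * p[fold_idx]) ** 2
    return float(np.sqrt(np.mean(sq_errors)))


def fit_level(
    products,
    manual_areas,
    level: Level | None = None,
    folds: int = 5,
    seed: int = 0,
) -> SecondOrderFit:
    """Fit k_hat on one set of (product, manual) pairs with CV error."""
    p, a = _paired_arrays(products, manual_areas)
    k_hat = fit_scale_factor(p, a)
    weights = weights_from_factor(k_hat)
    return SecondOrderFit(
        level=Level(level) if level is not None else None,
        n=int(p.size),
        k_hat=k_hat,
        ellipse_weight=weights.ellipse,
        triangle_weight=weights.triangle,
        extrapolating=weights.extrapolating,
        training_rmse=rmse(p, a, k_hat),
        cv_rmse=cross_validate(p, a, folds=folds, seed=seed),
        cv_folds=folds,
    )


def fit_cohort(
    cohort: pd.DataFrame,
    folds: int = 5,
    seed: int = 0,
    pooled: bool = False,
) -> list[SecondOrderFit]:
    """Fit the scale factor per level (default) or pooled over levels.

    ``cohort`` uses the shared CSV schema (``level``, ``ipd_mm``,
    ``ap_mm``, ``canal_area_mm2``).
    """
    product = cohort["ipd_mm"].to_numpy(float) * cohort["ap_mm"].to_numpy(float)
    manual = cohort["canal_area_mm2"].to_numpy(float)
    if pooled:
        return [fit_level(product, manual, level=None, folds=folds, seed=seed)]
    fits: list[SecondOrderFit] = []
    level_col = cohort["level"].astype(str).to_numpy()
    for level in LEVELS:
        mask = level_col == level.value
        if not mask.any():
            continue
        fits.append(
            fit_level(product[mask], manual[mask], level=level, folds=folds, seed=seed)
        )
    if not fits:
        raise ValueError("cohort contains no rows at any recognised level")
    return fits


def fits_frame(fits: Sequence[SecondOrderFit]) -> pd.DataFrame:
    """Tidy DataFrame of second-order fits."""
    return pd.DataFrame([f.to_dict() for f in fits])
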