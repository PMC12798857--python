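"""Normalizing transforms for daily metric responses.

Two transforms are provided: the Yeo-Johnson power family with its shape
parameter chosen by profile maximum likelihood, and the Ordered Quantile
(rank-to-normal-score) map with linear interpolation inside the training
range and linear tail extrapolation on the normal-quantile scale. Both are
invertible on their training range, which the back-transformed marginal
mean predictions rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MIN_N = 10  # below this a transform fit is too unstable to trust


def yeo_johnson_forward(x: np.ndarray, lam: float) -> np.ndarray:
    """Piecewise Yeo-Johnson power transform (identity at lam = 1)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    if abs(lam) > 1e-10:
        out[pos] = ((x[pos] + 1.0) ** lam - 1.0) / lam
    else:
        out[pos] = np.log1p(x[pos])
    lam2 = 2.0 - lam
    if abs(lam2) > 1e-10:
        out[~pos] = -(((-x[~pos] + 1.0) ** lam2 - 1.0) / lam2)
    else:
        out[~pos] = -np.log1p(-x[~pos])
    return out


def yeo_johnson_inverse(y: np.ndarray, lam: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    pos = y >= 0
    if abs(lam) > 1e-10:
        out[pos] = (lam * y[pos] + 1.0) ** (1.0 / lam) - 1.0
    else:
        out[pos] = np.expm1(y[pos])
    lam2 = 2.0 - lam
    if abs(lam2) > 1e-10:
        out[~pos] = 1.0 - (-lam2 * y[~pos] + 1.0) ** (1.0 / lam2)
    else:
        out[~pos] = -np.expm1(-y[~pos])
    return out


@dataclass
class TransformSpec:
    """Fitted forward/inverse normalization map."""

    kind: str                       # "yeo_johnson" | "ordered_quantile"
    lam: float = float("nan")       # YJ shape parameter
    train_sorted: np.ndarray = field(default=None, repr=False)
    train_scores: np.ndarray = field(default=None, repr=False)

    def forward(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "yeo_johnson":
            return yeo_johnson_forward(x, self.lam)
        return _orq_forward(x, self.train_sorted, self.train_scores)

    def inverse(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.kind == "yeo_johnson":
            return yeo_johnson_inverse(y, self.lam)
        return _orq_forward(y, self.train_scores, self.train_sorted)


def _orq_forward(x: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Piecewise-linear map through (xs, ys) with linear tail extrapolation.

    Used for both directions of the Ordered Quantile transform, since the
    stored training map is monotone.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    # collapse duplicated abscissae (tied training values share a midrank score)
    ux, first = np.unique(xs, return_index=True)
    uy = ys[first]
    if ux.size == 1:
        return np.full_like(x, uy[0])
    out = np.interp(x, ux, uy)
    lo = x < ux[0]
    hi = x > ux[-1]
    slope_lo = (uy[1] - uy[0]) / (ux[1] - ux[0])
    slope_hi = (uy[-1] - uy[-2]) / (ux[-1] - ux[-2])
    out[lo] = uy[0] + (x[lo] - ux[0]) * slope_lo
    out[hi] = uy[-1] + (x[hi] - ux[-1]) * slope_hi
    return out


def fit_transform(values, kind: str) -> TransformSpec:
    """Fit a normalization transform to training data.

    ``yeo_johnson`` maximizes the profile log-likelihood of the YJ family
    over lambda in [-5, 5]; ``ordered_quantile`` maps the sorted training
    values to normal scores Phi^-1(rank/(n+1)) with midranks for ties.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < MIN_N:
        raise ValueError(f"need >= {MIN_N} values to fit a transform")
    if kind == "yeo_johnson":
        lam = float(stats.yeojohnson_normmax(x))
        lam = float(np.clip(lam, -5.0, 5.0))
        return TransformSpec(kind=kind, lam=lam)
    if kind == "ordered_quantile":
        ranks = stats.rankdata(x, method="average")
        scores = stats.norm.ppf(ranks / (x.size + 1))
        order = np.argsort(x, kind="mergesort")
        return TransformSpec(kind=kind,
                             train_sorted=x[order],
                             train_scores=scores[order])
    raise ValueError(f"unknown transform kind {kind!r}")
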