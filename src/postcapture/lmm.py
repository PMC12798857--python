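"""Gaussian linear mixed model with a single random intercept.

The model is y = X beta + Z b + e with one random intercept per group
(collar deployment), b ~ N(0, sigma_b^2), e ~ N(0, sigma_e^2). Fitting is
by maximum likelihood: the deviance is profiled over the variance ratio
gamma = sigma_b^2 / sigma_e^2 (a 1-D optimization), with generalized least
squares solved in closed form at each gamma via per-group shrinkage of
group means. Fixed factors use sum-to-zero (effects) coding throughout, so
the block Wald statistic on a term's coefficient rows is the type-III test.

Estimated marginal means average model predictions over the levels of
non-focal factors with equal weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


def _encode_factor(values: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero coding: L-1 columns; last level codes as -1 in each."""
    L = len(levels)
    idx = {lv: i for i, lv in enumerate(levels)}
    codes = np.array([idx[v] for v in values])
    X = np.zeros((len(values), L - 1))
    for j in range(L - 1):
        X[codes == j, j] = 1.0
    X[codes == L - 1, :] = -1.0
    return X


def design_matrix(df: pd.DataFrame, factors: dict[str, list],
                  terms: list[tuple[str, ...]]
                  ) -> tuple[np.ndarray, list[str], dict[tuple, np.ndarray]]:
    """Fixed-effect design matrix with intercept plus the requested terms.

    Returns (X, column names, term -> column-index map). Interaction
    columns are products of the parent factors' coding columns.
    """
    blocks = [np.ones((len(df), 1))]
    names = ["(Intercept)"]
    term_cols: dict[tuple, np.ndarray] = {}
    coded = {f: _encode_factor(df[f].to_numpy(), lv)
             for f, lv in factors.items()}
    col = 1
    for term in terms:
        mats = [coded[f] for f in term]
        cols = mats[0]
        labels = [[f"{term[0]}{j}"] for j in range(cols.shape[1])]
        for f, m in zip(term[1:], mats[1:]):
            cols = np.einsum("ni,nj->nij", cols, m).reshape(len(df), -1)
            labels = [lab + [f"{f}{j}"] for lab in labels
                      for j in range(m.shape[1])]
        blocks.append(cols)
        names.extend(":".join(lab) for lab in labels)
        term_cols[term] = np.arange(col, col + cols.shape[1])
        col += cols.shape[1]
    return np.hstack(blocks), names, term_cols


@dataclass
class LMMFit:
    beta: np.ndarray
    cov: np.ndarray
    names: list[str]
    term_cols: dict[tuple, np.ndarray]
    factors: dict[str, list]
    terms: list[tuple[str, ...]]
    sigma2_e: float
    sigma2_b: float
    gamma: float
    loglik: float
    n: int
    n_groups: int
    _emm_cache: dict = field(default_factory=dict, repr=False)

    def predict_row(self, levels: dict[str, object]) -> np.ndarray:
        """Design row for one cell of the full factor grid."""
        df1 = pd.DataFrame([levels])
        X, _, _ = design_matrix(df1, self.factors, self.terms)
        return X[0]

    def emm_vector(self, focal: dict[str, object]) -> np.ndarray:
        """Design row of the EMM at ``focal``: equal-weight average of the
        reference grid over all non-focal factor levels."""
        key = tuple(sorted((k, str(v)) for k, v in focal.items()))
        if key in self._emm_cache:
            return self._emm_cache[key]
        free = {f: lv for f, lv in self.factors.items() if f not in focal}
        rows = []
        for combo in itertools.product(*free.values()):
            cell = dict(focal)
            cell.update(dict(zip(free.keys(), combo)))
            rows.append(self.predict_row(cell))
        out = np.mean(rows, axis=0)
        self._emm_cache[key] = out
        return out

    def emm(self, focal: dict[str, object]) -> tuple[float, float]:
        L = self.emm_vector(focal)
        return float(L @ self.beta), float(np.sqrt(L @ self.cov @ L))

    def contrast(self, la: np.ndarray, lb: np.ndarray
                 ) -> tuple[float, float, float, float]:
        """Estimate, SE, z and two-sided p for the contrast la - lb."""
        L = la - lb
        est = float(L @ self.beta)
        se = float(np.sqrt(L @ self.cov @ L))
        z = est / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        return est, se, z, p


def fit_lmm(df: pd.DataFrame, response: str, group: str,
            factors: dict[str, list], terms: list[tuple[str, ...]],
            reml: bool = False,
            log_gamma_bounds: tuple[float, float] = (-12.0, 8.0)) -> LMMFit:
    """Likelihood fit of the random-intercept LMM (ML default, REML option).

    ``factors`` maps factor name -> ordered level list (levels absent from
    the data are dropped); ``terms`` lists the fixed-effect terms as factor
    tuples, e.g. ("day",), ("day", "method"). REML removes the downward
    bias of the variance components (on a balanced one-way design it
    reproduces the ANOVA method-of-moments estimators exactly).
    """
    factors = {f: [lv for lv in levels if lv in set(df[f])]
               for f, levels in factors.items()}
    X, names, term_cols = design_matrix(df, factors, terms)
    y = df[response].to_numpy(dtype=float)
    codes, _ = pd.factorize(df[group], sort=True)
    G = codes.max() + 1
    n, p = X.shape

    counts = np.bincount(codes, minlength=G).astype(float)
    Xbar = np.zeros((G, p))
    np.add.at(Xbar, codes, X)
    Xbar /= counts[:, None]
    ybar = np.bincount(codes, weights=y, minlength=G) / counts
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def gls(gamma: float):
        w = counts * gamma / (1.0 + counts * gamma)  # shrinkage weight w_i
        A = XtX - (Xbar * (w * counts)[:, None]).T @ Xbar
        b = Xty - Xbar.T @ (w * counts * ybar)
        c = yty - float(w * counts @ (ybar ** 2))
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            sv = np.linalg.svd(A, compute_uv=False)
            bad = [names[i] for i in range(p) if sv[i] < sv[0] * 1e-10]
            raise np.linalg.LinAlgError(
                f"singular fixed-effect design; aliased near columns {bad}")
        rss = max(c - float(b @ beta), 1e-300)
        return A, beta, rss

    def neg2ll(gamma: float) -> float:
        A, _, rss = gls(gamma)
        if reml:
            s2 = rss / (n - p)
            return ((n - p) * np.log(2.0 * np.pi * s2) + (n - p)
                    + float(np.sum(np.log1p(counts * gamma)))
                    + float(np.linalg.slogdet(A)[1]))
        s2 = rss / n
        return (n * np.log(2.0 * np.pi * s2) + n
                + float(np.sum(np.log1p(counts * gamma))))

    res = optimize.minimize_scalar(lambda u: neg2ll(np.exp(u)),
                                   bounds=log_gamma_bounds, method="bounded",
                                   options={"xatol": 1e-8})
    gamma = float(np.exp(res.x))
    if neg2ll(0.0) <= res.fun:  # boundary: no between-group variance
        gamma = 0.0
    A, beta, rss = gls(gamma)
    s2e = rss / (n - p) if reml else rss / n
    cov = s2e * np.linalg.inv(A)
    return LMMFit(beta=beta, cov=cov, names=names, term_cols=term_cols,
                  factors=factors, terms=terms,
                  sigma2_e=float(s2e), sigma2_b=float(gamma * s2e),
                  gamma=gamma, loglik=-0.5 * neg2ll(gamma),
                  n=n, n_groups=int(G))


def wald_type3(fit: LMMFit, term: tuple[str, ...] | str
               ) -> tuple[float, int, float]:
    """Block Wald chi-square for one model term under sum-to-zero coding."""
    if isinstance(term, str):
        term = (term,)
    if term not in fit.term_cols:
        raise KeyError(f"term {term!r} not in model")
    idx = fit.term_cols[term]
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    chi2 = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def tukey_adjust(z: np.ndarray, k: int) -> np.ndarray:
    """Tukey (studentized-range) adjustment for all pairwise z statistics
    among k means, in the large-df (normal) limit."""
    q = np.abs(np.asarray(z, dtype=float)) * np.sqrt(2.0)
    return stats.studentized_range.sf(q, k, 1e7)
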