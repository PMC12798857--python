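"""Capture-effect inference on daily movement and space-use metrics.

Each metric's daily values (plus a per-animal long-term-mean reference row)
are normalized, modeled with a random-intercept Gaussian LMM in which
day-since-capture, capture method, sex (and their interactions) are fixed
factors and capture season is a blocking factor, and then screened for
capture-altered days: days whose estimated marginal mean differs
significantly from the animal-specific long-term mean in a
treatment-vs-control framework. Contiguous altered days starting at day 1
form the altered span; the rule bridges a single embedded non-significant
day, requires the deviation to keep the sign of the initial post-capture
response, and reports stray significant days as artifacts of daily
variation rather than capture effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import LMMFit, design_matrix, fit_lmm, tukey_adjust, wald_type3
from .metrics import LTM
from .transforms import TransformSpec, fit_transform

DAY_LEVELS = [LTM] + [str(d) for d in range(1, 31)]
SEASON_LEVELS = ["spring", "summer", "autumn", "winter"]
METHOD_LEVELS = ["drop_net", "single_helicopter", "tandem_helicopter"]
SEX_LEVELS = ["F", "M"]

DEFAULT_TERMS = [("day",), ("method",), ("sex",), ("season",),
                 ("day", "method"), ("day", "sex"), ("method", "sex"),
                 ("day", "method", "sex")]

#: Transform used for each metric (the normalization that fit each response
#: best in the source analysis workflow).
METRIC_TRANSFORMS = {"distance": "yeo_johnson",
                     "displacement": "ordered_quantile",
                     "range_size": "ordered_quantile",
                     "overlap": "ordered_quantile"}


def build_model_table(series: pd.DataFrame, metadata: pd.DataFrame,
                      metric: str, transform: str | None = None
                      ) -> tuple[pd.DataFrame, TransformSpec]:
    """Model rows for one metric: 30 daily rows + 1 reference row each.

    ``series`` is the long metric table (deployment_id, metric, day, value)
    with day "ltm" rows already present; ``metadata`` supplies method, sex,
    and capture season. The response is transformed with the metric's
    configured normalization. Rows with missing values are dropped.
    """
    sub = series[series["metric"] == metric].copy()
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    sub = sub.dropna(subset=["value"])
    transform = transform or METRIC_TRANSFORMS[metric]
    spec = fit_transform(sub["value"].to_numpy(), transform)
    sub["y"] = spec.forward(sub["value"].to_numpy())
    meta_cols = metadata[["deployment_id", "method", "sex", "capture_season"]]
    rows = sub.merge(meta_cols, on="deployment_id", how="left")
    if rows[["method", "sex", "capture_season"]].isna().any().any():
        missing = rows.loc[rows["method"].isna(), "deployment_id"].unique()
        raise ValueError(f"deployments missing metadata: {list(missing)[:5]}")
    rows = rows.rename(columns={"capture_season": "season"})
    rows["day"] = rows["day"].astype(str)
    return rows.reset_index(drop=True), spec


@dataclass
class CaptureEffectFit:
    metric: str
    transform: TransformSpec
    model: LMMFit
    wald: pd.DataFrame
    contrasts: pd.DataFrame = None
    spans: dict = field(default_factory=dict)
    seasonal: pd.DataFrame = None


def fit_capture_model(rows: pd.DataFrame, metric: str,
                      transform: TransformSpec,
                      terms: list[tuple[str, ...]] | None = None
                      ) -> CaptureEffectFit:
    """Fit the LMM and the type-III Wald table for one metric."""
    terms = terms or DEFAULT_TERMS
    day_levels = [d for d in DAY_LEVELS if d in set(rows["day"])]
    factors = {"day": day_levels, "method": METHOD_LEVELS,
               "sex": SEX_LEVELS, "season": SEASON_LEVELS}
    fit = fit_lmm(rows, response="y", group="deployment_id",
                  factors=factors, terms=terms)
    wald_rows = []
    for term in fit.terms:
        chi2, df, p = wald_type3(fit, term)
        wald_rows.append({"term": ":".join(term), "chi2": chi2,
                          "df": df, "p": p})
    return CaptureEffectFit(metric=metric, transform=transform, model=fit,
                            wald=pd.DataFrame(wald_rows))


def day_contrasts(fit: CaptureEffectFit,
                  by: tuple[str, ...] = ("method",),
                  alpha: float = 0.05) -> pd.DataFrame:
    """Day-vs-reference EMM contrasts within each level of ``by``.

    For every group cell and every day, the contrast is EMM(day) -
    EMM(long-term mean) with the delta-method SE from the fixed-effect
    covariance; p-values are unadjusted z tests (treatment-vs-control
    framework at the given alpha).
    """
    model = fit.model
    model_factors = {f for t in model.terms for f in t}
    if not set(by) <= model_factors:
        raise ValueError(f"grouping {by} not in model factors")
    import itertools
    groups = itertools.product(*(model.factors[f] for f in by))
    days = [d for d in model.factors["day"] if d != LTM]
    out = []
    for combo in groups:
        focal_base = dict(zip(by, combo))
        lb = model.emm_vector({**focal_base, "day": LTM})
        for d in days:
            la = model.emm_vector({**focal_base, "day": d})
            est, se, z, p = model.contrast(la, lb)
            row = {"metric": fit.metric, "day": int(d), "estimate": est,
                   "se": se, "z": z, "p": p, "significant": p <= alpha}
            row.update(focal_base)
            out.append(row)
    return pd.DataFrame(out)


def altered_days(contrasts: pd.DataFrame,
                 by: tuple[str, ...] = ("method",)) -> dict[tuple, dict]:
    """Apply the altered-day span rule per group.

    Scanning from day 1: the span extends while days differ significantly
    from the long-term mean with the same deviation sign as day 1; a single
    non-significant day is bridged when the next day is significant in that
    direction. Day 1 non-significant means span 0. Significant days beyond
    the span are artifact days (daily variation, not capture effect).
    """
    spans: dict[tuple, dict] = {}
    for key, grp in contrasts.groupby(list(by), sort=False):
        key = key if isinstance(key, tuple) else (key,)
        g = grp.sort_values("day")
        days = g["day"].to_numpy()
        if not np.array_equal(days, np.arange(days[0], days[0] + len(days))):
            raise ValueError("non-contiguous day indexing in contrast table")
        sig = g["significant"].to_numpy()
        est = g["estimate"].to_numpy()
        span = 0
        if sig[0]:
            direction = np.sign(est[0])
            same = sig & (np.sign(est) == direction)
            span = 1
            i = 1
            while i < len(days):
                if same[i]:
                    span = i + 1
                    i += 1
                elif (not sig[i]) and i + 1 < len(days) and same[i + 1]:
                    span = i + 2  # bridge one embedded non-significant day
                    i += 2
                else:
                    break
        artifact = [int(d) for d, s in zip(days, sig) if s and d > span]
        spans[key] = {"span": int(span), "artifact_days": artifact}
    return spans


def seasonal_emms(fit: CaptureEffectFit) -> pd.DataFrame:
    """Season EMMs and all pairwise Tukey-adjusted contrasts.

    Returns one row per season (kind="emm") and one per pair
    (kind="contrast") with the studentized-range adjusted p-value.
    """
    model = fit.model
    if ("season",) not in model.term_cols:
        raise KeyError("season term not in model")
    seasons = model.factors["season"]
    rows = []
    vecs = {s: model.emm_vector({"season": s}) for s in seasons}
    for s in seasons:
        est, se = model.emm({"season": s})
        rows.append({"kind": "emm", "level": s, "estimate": est, "se": se,
                     "z": np.nan, "p": np.nan, "p_adj": np.nan})
    zstats, pairs = [], []
    for i, a in enumerate(seasons):
        for b in seasons[i + 1:]:
            est, se, z, p = model.contrast(vecs[a], vecs[b])
            pairs.append({"kind": "contrast", "level": f"{a}-{b}",
                          "estimate": est, "se": se, "z": z, "p": p})
            zstats.append(z)
    p_adj = tukey_adjust(np.array(zstats), k=len(seasons))
    for row, pa in zip(pairs, p_adj):
        row["p_adj"] = float(max(pa, row["p"]))  # adjusted >= unadjusted
    rows.extend(pairs)
    return pd.DataFrame(rows)


def back_transform_emm(fit: CaptureEffectFit, focal: dict[str, object],
                       bias_correct: bool = True) -> float:
    """EMM on the response's original scale.

    Applies the inverse transform with a second-order Taylor bias
    correction using the total random variance sigma_b^2 + sigma_e^2.
    """
    model = fit.model
    mu, _ = model.emm(focal)
    inv = lambda v: float(fit.transform.inverse(np.array([v]))[0])
    value = inv(mu)
    if bias_correct:
        s2 = model.sigma2_b + model.sigma2_e
        eps = 1e-4 * max(1.0, abs(mu))
        second = (inv(mu + eps) - 2.0 * value + inv(mu - eps)) / eps ** 2
        value += 0.5 * s2 * second
    return value


def analyze_metric(series: pd.DataFrame, metadata: pd.DataFrame, metric: str,
                   transform: str | None = None,
                   by: tuple[str, ...] = ("method",),
                   alpha: float = 0.05) -> CaptureEffectFit:
    """Full capture-effect stage for one metric.

    The grouping for day contrasts widens to method x sex when the 3-way
    day x method x sex interaction is significant, mirroring how the
    highest-order significant interaction drives reporting. If the full
    factorial is inestimable (an empty design cell, e.g. after heavy
    censoring in a small cohort), interaction terms are dropped from the
    highest order down until the model is estimable, with a warning.
    """
    import warnings as _warnings

    rows, spec = build_model_table(series, metadata, metric, transform)
    terms = list(DEFAULT_TERMS)
    while True:
        try:
            fit = fit_capture_model(rows, metric, spec, terms=terms)
            break
        except np.linalg.LinAlgError:
            drop = max(terms, key=len)
            if len(drop) == 1:
                # last resort in a degenerate cohort: release the season
                # blocking factor before giving up
                if ("season",) in terms:
                    drop = ("season",)
                else:
                    raise
            terms.remove(drop)
            _warnings.warn(
                f"{metric}: design not estimable; dropping term "
                f"{':'.join(drop)}")
    three_way = fit.wald.loc[fit.wald["term"] == "day:method:sex", "p"]
    if len(three_way) and float(three_way.iloc[0]) <= alpha:
        by = ("method", "sex")
    fit.contrasts = day_contrasts(fit, by=by, alpha=alpha)
    fit.spans = altered_days(fit.contrasts, by=by)
    if ("season",) in fit.model.term_cols:
        fit.seasonal = seasonal_emms(fit)
    return fit
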