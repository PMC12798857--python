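"""Daily movement metrics and per-individual long-term means.

Two path metrics are computed per local calendar day of the movement window
(days 1-30 after capture): total distance traveled (sum of sequential step
lengths, m/day) and mean displacement (mean Euclidean distance from each
fix to the deployment's anchor, the first retained fix of day 1). Each
eligible deployment also gets a long-term mean per metric, the arithmetic
mean of its daily values, which serves as that animal's "normal activity"
reference in the capture-effect model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .telemetry import Deployment, MOVEMENT_DAYS

LTM = "ltm"  # day label of the long-term-mean reference row

METRIC_NAMES = ("distance", "displacement", "range_size", "overlap")


def _day_index(dep: Deployment, fixes: pd.DataFrame) -> np.ndarray:
    tcol = ("timestamp_local" if "timestamp_local" in fixes.columns
            else "timestamp_utc")
    return (fixes[tcol].dt.normalize() - dep.capture_day).dt.days.to_numpy()


def daily_distance(dep: Deployment, day: int,
                   min_fixes: int = 2) -> float:
    """Distance traveled (m) on one day: sum of steps starting that day.

    Steps crossing local midnight belong to the day of their starting fix.
    NaN when the day has fewer than ``min_fixes`` fixes.
    """
    if day not in MOVEMENT_DAYS:
        raise ValueError(f"day {day} outside the movement window 1-30")
    fixes = dep.fixes
    days = _day_index(dep, fixes)
    xy = fixes[["x_m", "y_m"]].to_numpy(dtype=float)
    if (days == day).sum() < min_fixes:
        return float("nan")
    steps = np.hypot(*np.diff(xy, axis=0).T)
    start_day = days[:-1]
    return float(steps[start_day == day].sum())


def displacement_anchor(dep: Deployment) -> np.ndarray | None:
    """First retained fix of day 1 (the day following release)."""
    days = _day_index(dep, dep.fixes)
    idx = np.nonzero(days == 1)[0]
    if idx.size == 0:
        return None
    return dep.fixes[["x_m", "y_m"]].iloc[idx[0]].to_numpy(dtype=float)


def daily_displacement(dep: Deployment, day: int,
                       anchor: np.ndarray | None = None) -> float:
    """Mean distance (m) from the day's fixes to the deployment anchor."""
    if day not in MOVEMENT_DAYS:
        raise ValueError(f"day {day} outside the movement window 1-30")
    if anchor is None:
        anchor = displacement_anchor(dep)
    if anchor is None:
        return float("nan")
    days = _day_index(dep, dep.fixes)
    sel = days == day
    if not sel.any():
        return float("nan")
    xy = dep.fixes.loc[sel, ["x_m", "y_m"]].to_numpy(dtype=float)
    return float(np.mean(np.hypot(xy[:, 0] - anchor[0], xy[:, 1] - anchor[1])))


def long_term_mean(values) -> float:
    """Per-individual mean over all present daily values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no daily values to average")
    return float(v.mean())


def metric_series(dep: Deployment, metric: str,
                  daily_values: dict[int, float] | None = None) -> pd.DataFrame:
    """Tidy per-day series for one metric, with an appended long-term row.

    For the two path metrics the values are computed here; range_size and
    overlap values (from the space-use stage) are passed in precomputed.
    """
    if metric in ("distance", "displacement"):
        anchor = displacement_anchor(dep) if metric == "displacement" else None
        f = daily_distance if metric == "distance" else (
            lambda d, day: daily_displacement(d, day, anchor))
        daily_values = {day: f(dep, day) for day in MOVEMENT_DAYS}
    elif daily_values is None:
        raise ValueError(f"{metric}: precomputed daily values required")
    rows = [{"deployment_id": dep.deployment_id, "metric": metric,
             "day": str(day), "value": val}
            for day, val in sorted(daily_values.items())]
    vals = [r["value"] for r in rows]
    rows.append({"deployment_id": dep.deployment_id, "metric": metric,
                 "day": LTM, "value": long_term_mean(vals)})
    return pd.DataFrame(rows)


def movement_metric_table(deployments: list[Deployment],
                          metrics: tuple[str, ...] = ("distance", "displacement"),
                          space_use_values: dict | None = None) -> pd.DataFrame:
    """Long-format metric table for all movement-eligible deployments.

    ``space_use_values`` maps (deployment_id, metric) -> {day: value} for
    the range_size / overlap metrics when those were computed.
    """
    parts = []
    for dep in deployments:
        if not dep.eligible_movement:
            continue
        for metric in metrics:
            if metric in ("distance", "displacement"):
                parts.append(metric_series(dep, metric))
            else:
                vals = (space_use_values or {}).get(
                    (dep.deployment_id, metric))
                if vals:
                    parts.append(metric_series(dep, metric, vals))
    if not parts:
        return pd.DataFrame(columns=["deployment_id", "metric", "day", "value"])
    return pd.concat(parts, ignore_index=True)
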