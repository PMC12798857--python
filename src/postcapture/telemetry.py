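"""Collar-trajectory ingestion, cleaning, and analysis-window definition.

The cleaning stack mirrors common practice for store-on-board GPS collars:
convert UTC to local mean time, resample to a common 30-minute schedule,
derive step metrics, censor impossible positions (long-range teleports and
out-and-back spikes), detect the end of biological data (mortality or collar
drop) as the first long stationary cluster, and flag each deployment's
eligibility for the survival (days 0-30) and movement (days 1-30) analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import FIX_COLUMNS, META_COLUMNS, METHODS, SEXES, SEASONS

log = logging.getLogger(__name__)

#: Seasons pooled into the "cool" thermal class for survival modeling.
COOL_SEASONS = frozenset({"spring", "autumn", "winter"})

SURVIVAL_WINDOW_DAYS = 31   # day 0 (capture) through day 30
MOVEMENT_DAYS = range(1, 31)


class SchemaError(ValueError):
    """An input table is missing a required column or holds unknown levels."""


@dataclass
class Deployment:
    """One collar-on-animal episode with capture metadata and windows."""

    deployment_id: str
    method: str
    sex: str
    capture_season: str
    capture_time_local: pd.Timestamp
    utc_offset_hours: float
    end_date: pd.Timestamp | None = None
    eligible_movement: bool = False
    eligible_survival: bool = True
    fixes: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def thermal_season(self) -> str:
        return "cool" if self.capture_season in COOL_SEASONS else "warm"

    @property
    def capture_day(self) -> pd.Timestamp:
        return self.capture_time_local.normalize()

    def day_of(self, ts) -> int:
        """Day index relative to capture day (day 0 = capture calendar day)."""
        return int((pd.Timestamp(ts).normalize() - self.capture_day).days)


def read_collar_data(fix_csv, metadata_csv) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate fix and capture-metadata CSVs.

    Fixes are parsed, grouped per deployment, and time-sorted; duplicate
    (deployment, timestamp) rows collapse to the first occurrence.
    """
    fixes = pd.read_csv(fix_csv)
    meta = pd.read_csv(metadata_csv)
    for col in FIX_COLUMNS:
        if col not in fixes.columns:
            raise SchemaError(f"fix table is missing column {col!r}")
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise SchemaError(f"metadata table is missing column {col!r}")
    bad_method = set(meta["method"]) - set(METHODS)
    if bad_method:
        raise SchemaError(f"unknown capture method levels: {sorted(bad_method)}")
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex:
        raise SchemaError(f"unknown sex levels: {sorted(bad_sex)}")
    bad_season = set(meta["capture_season"]) - set(SEASONS)
    if bad_season:
        raise SchemaError(f"unknown season levels: {sorted(bad_season)}")
    fixes["timestamp_utc"] = pd.to_datetime(fixes["timestamp_utc"])
    meta["capture_time_utc"] = pd.to_datetime(meta["capture_time_utc"])
    n0 = len(fixes)
    fixes = (fixes.sort_values(["deployment_id", "timestamp_utc"], kind="mergesort")
                  .drop_duplicates(["deployment_id", "timestamp_utc"], keep="first")
                  .reset_index(drop=True))
    if len(fixes) < n0:
        log.warning("collapsed %d duplicate (deployment, timestamp) rows",
                    n0 - len(fixes))
    return fixes, meta


def to_local_time(fixes: pd.DataFrame, utc_offset_hours: float) -> pd.DataFrame:
    """Add a timestamp_local column (fixed per-deployment UTC offset)."""
    if abs(utc_offset_hours) > 14:
        raise ValueError("|utc_offset_hours| may not exceed 14")
    out = fixes.copy()
    out["timestamp_local"] = (out["timestamp_utc"]
                              + pd.Timedelta(hours=utc_offset_hours))
    return out


def resample_30min(fixes: pd.DataFrame, slot_min: int = 30,
                   tol_min: float = 3.0) -> pd.DataFrame:
    """Thin a trajectory to one fix per 30-minute slot (:00 and :30 local).

    The fix nearest the slot time (within ``tol_min`` minutes) is retained;
    ties break to the earlier fix. Data already on the 30-minute schedule
    pass through unchanged; unalignable fixes are dropped (count logged).
    """
    if fixes.empty:
        return fixes.copy()
    tcol = "timestamp_local" if "timestamp_local" in fixes.columns else "timestamp_utc"
    out = fixes.sort_values(tcol, kind="mergesort").reset_index(drop=True)
    t = out[tcol]
    minutes = t.dt.hour * 60 + t.dt.minute + t.dt.second / 60.0
    slot = (minutes / slot_min).round() * slot_min
    offset = np.abs(minutes - slot)
    slot_key = t.dt.normalize() + pd.to_timedelta(slot, unit="m")
    ok = offset <= tol_min
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("resample: dropped %d unalignable fixes", n_drop)
    cand = out.loc[ok].copy()
    cand["_slot"] = slot_key[ok]
    cand["_off"] = offset[ok]
    # nearest to slot wins; stable sort keeps the earlier fix on ties
    cand = cand.sort_values(["_slot", "_off"], kind="mergesort")
    keep = cand.drop_duplicates("_slot", keep="first")
    keep = keep.sort_values(tcol, kind="mergesort")
    return keep.drop(columns=["_slot", "_off"]).reset_index(drop=True)


def compute_step_metrics(fixes: pd.DataFrame) -> pd.DataFrame:
    """Populate step length, dt, velocity, net displacement, heading, turn.

    Heading is measured clockwise from geographic north; the turning angle
    is the signed change in heading wrapped to (-180, 180]. The first fix
    of a deployment has undefined step quantities (NaN, not zero).
    """
    tcol = "timestamp_local" if "timestamp_local" in fixes.columns else "timestamp_utc"
    out = fixes.reset_index(drop=True).copy()
    n = len(out)
    for col in ("step_m", "dt_min", "velocity_mpm", "net_displacement_m",
                "heading_deg", "turn_deg"):
        out[col] = np.nan
    if n < 2:
        return out
    x = out["x_m"].to_numpy(dtype=float)
    y = out["y_m"].to_numpy(dtype=float)
    dx = np.diff(x)
    dy = np.diff(y)
    step = np.hypot(dx, dy)
    dt = np.diff(out[tcol].to_numpy()).astype("timedelta64[s]").astype(float) / 60.0
    heading = np.degrees(np.arctan2(dx, dy)) % 360.0  # clockwise from north
    out.loc[1:, "step_m"] = step
    out.loc[1:, "dt_min"] = dt
    with np.errstate(divide="ignore", invalid="ignore"):
        out.loc[1:, "velocity_mpm"] = np.where(dt > 0, step / dt, np.nan)
    out.loc[1:, "net_displacement_m"] = np.hypot(x[1:] - x[0], y[1:] - y[0])
    out.loc[1:, "heading_deg"] = heading
    if n >= 3:
        turn = np.diff(heading)
        turn = -((-turn + 180.0) % 360.0 - 180.0)  # wrap into (-180, 180]
        out.loc[2:, "turn_deg"] = turn
    return out


def detect_end_date(fixes: pd.DataFrame, radius_m: float = 45.0,
                    window_h: float = 48.0) -> pd.Timestamp | None:
    """Find the start of the first long stationary cluster (death / drop).

    Scans forward windows of ``window_h`` hours; the first window whose
    fixes all lie within ``radius_m`` of the window centroid marks the
    collar-drop or mortality time, and its first fix's timestamp is
    returned. ``None`` if the animal keeps moving (or data are too short).
    """
    tcol = "timestamp_local" if "timestamp_local" in fixes.columns else "timestamp_utc"
    if fixes.empty:
        return None
    t = fixes[tcol].to_numpy()
    xy = fixes[["x_m", "y_m"]].to_numpy(dtype=float)
    n = len(t)
    horizon = np.timedelta64(int(window_h * 3600), "s")
    if t[-1] - t[0] < horizon:
        log.info("detect_end_date: trajectory shorter than window")
        return None
    j = np.searchsorted(t, t + horizon, side="left")
    for i in range(n):
        end = j[i]
        if end <= i + 1:
            continue
        if t[end - 1] - t[i] < horizon - np.timedelta64(3600, "s"):
            break  # remaining data cannot fill a window
        w = xy[i:end]
        centroid = w.mean(axis=0)
        if np.max(np.hypot(w[:, 0] - centroid[0], w[:, 1] - centroid[1])) <= radius_m:
            return pd.Timestamp(t[i])
    return None


def censor_outliers(fixes: pd.DataFrame, rule_a_km: float = 32.0,
                    rule_b_km: float = 2.0,
                    rule_b_max_gap_min: float = 30.0
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Censor impossible GPS positions; returns (clean fixes, removals).

    Rule A removes fixes farther than ``rule_a_km`` from the deployment's
    component-wise median location. Rule B removes out-and-back spikes: fix
    i with both neighbour distances >= ``rule_b_km``, both time gaps <=
    ``rule_b_max_gap_min`` minutes, and neighbours within ``rule_b_km`` of
    each other. Rules run once each, in that order; step metrics are
    recomputed on the cleaned trajectory.
    """
    tcol = "timestamp_local" if "timestamp_local" in fixes.columns else "timestamp_utc"
    out = fixes.reset_index(drop=True).copy()
    removed = []

    xy = out[["x_m", "y_m"]].to_numpy(dtype=float)
    med = np.median(xy, axis=0)
    dist_med = np.hypot(xy[:, 0] - med[0], xy[:, 1] - med[1])
    bad_a = dist_med > rule_a_km * 1000.0
    if bad_a.any():
        rem = out.loc[bad_a].copy()
        rem["censored_rule"] = "A"
        removed.append(rem)
        out = out.loc[~bad_a].reset_index(drop=True)

    if len(out) >= 3:
        xy = out[["x_m", "y_m"]].to_numpy(dtype=float)
        t = out[tcol].to_numpy()
        d_prev = np.hypot(*(xy[1:-1] - xy[:-2]).T)
        d_next = np.hypot(*(xy[2:] - xy[1:-1]).T)
        d_skip = np.hypot(*(xy[2:] - xy[:-2]).T)
        gap_prev = (t[1:-1] - t[:-2]).astype("timedelta64[s]").astype(float) / 60.0
        gap_next = (t[2:] - t[1:-1]).astype("timedelta64[s]").astype(float) / 60.0
        km = rule_b_km * 1000.0
        spike = ((d_prev >= km) & (d_next >= km) & (d_skip < km)
                 & (gap_prev <= rule_b_max_gap_min)
                 & (gap_next <= rule_b_max_gap_min))
        bad_b = np.zeros(len(out), dtype=bool)
        bad_b[1:-1] = spike
        if bad_b.any():
            rem = out.loc[bad_b].copy()
            rem["censored_rule"] = "B"
            removed.append(rem)
            out = out.loc[~bad_b].reset_index(drop=True)

    removals = (pd.concat(removed, ignore_index=True) if removed
                else pd.DataFrame(columns=list(out.columns) + ["censored_rule"]))
    if len(removals):
        log.info("censor_outliers: removed %d fixes (%s)", len(removals),
                 removals["censored_rule"].value_counts().to_dict())
    return compute_step_metrics(out), removals


def define_windows(dep: Deployment, fixes_per_day: int = 48,
                   completeness: float = 0.9) -> Deployment:
    """Flag movement- and survival-analysis eligibility for a deployment.

    The survival window is days 0-30 (31 days); the movement window is days
    1-30, requiring every day to carry at least ``completeness`` of the
    expected fixes and no detected end-of-data inside the window. Direct
    capture mortalities (no collar data) stay survival-eligible only.
    """
    if pd.isna(dep.capture_time_local):
        raise ValueError(f"{dep.deployment_id}: capture time missing")
    dep.eligible_survival = True
    if dep.fixes.empty:
        dep.eligible_movement = False
        return dep
    tcol = ("timestamp_local" if "timestamp_local" in dep.fixes.columns
            else "timestamp_utc")
    days = (dep.fixes[tcol].dt.normalize() - dep.capture_day).dt.days
    counts = days.value_counts()
    need = completeness * fixes_per_day
    complete = all(counts.get(d, 0) >= need for d in MOVEMENT_DAYS)
    end_inside = (dep.end_date is not None
                  and dep.day_of(dep.end_date) <= SURVIVAL_WINDOW_DAYS - 1)
    dep.eligible_movement = complete and not end_inside
    if not dep.eligible_movement:
        log.info("%s: movement-ineligible (complete=%s, end_inside=%s)",
                 dep.deployment_id, complete, end_inside)
    return dep


def build_deployments(fixes: pd.DataFrame, meta: pd.DataFrame,
                      radius_m: float = 45.0, window_h: float = 48.0,
                      completeness: float = 0.9,
                      fixes_per_day: int = 48) -> list[Deployment]:
    """Full cleaning stack: local time, resample, censor, end date, windows."""
    deployments = []
    grouped = dict(iter(fixes.groupby("deployment_id")))
    for _, m in meta.iterrows():
        dep_fixes = grouped.get(m["deployment_id"], pd.DataFrame(columns=fixes.columns))
        offset = float(m["utc_offset_hours"])
        capture_local = m["capture_time_utc"] + pd.Timedelta(hours=offset)
        dep = Deployment(
            deployment_id=m["deployment_id"],
            method=m["method"], sex=m["sex"],
            capture_season=m["capture_season"],
            capture_time_local=capture_local,
            utc_offset_hours=offset,
        )
        if not dep_fixes.empty:
            f = to_local_time(dep_fixes, offset)
            f = resample_30min(f)
            f, _ = censor_outliers(f)
            dep.fixes = f
            dep.end_date = detect_end_date(f, radius_m=radius_m,
                                           window_h=window_h)
        deployments.append(define_windows(dep, fixes_per_day=fixes_per_day,
                                          completeness=completeness))
    return deployments
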