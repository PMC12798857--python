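"""Synthetic GPS-collar cohorts with known ground truth.

Generates fix tables for a method x sex capture design in which each animal
follows a stationary Ornstein-Uhlenbeck (OU) home-ranging process, with

* a method-specific release translocation away from the activity center,
* a method-specific post-release movement suppression (scaled step
  innovations) lasting a known number of days,
* optional mortality (collar goes stationary at a known day), and
* optional GPS artifacts (long-range teleports, out-and-back spikes) and
  missing fixes,

all recorded in a truth table so downstream cleaning, metric, and inference
stages can be validated against known answers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

METHODS = ("drop_net", "single_helicopter", "tandem_helicopter")
SEXES = ("F", "M")
SEASONS = ("spring", "summer", "autumn", "winter")

#: First month of a capture window per meteorological season.
_SEASON_MONTHS = {"spring": (3, 4, 5), "summer": (6, 7, 8),
                  "autumn": (9, 10, 11), "winter": (12, 1, 2)}

FIX_COLUMNS = ["deployment_id", "timestamp_utc", "x_m", "y_m"]
META_COLUMNS = ["deployment_id", "animal_id", "method", "sex",
                "capture_time_utc", "utc_offset_hours", "capture_season"]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate 30-minute fixes over a 31-day deployment (capture day
    plus 30 full days) with home-ranging movement calibrated to long-term
    daily distances near 2.4-2.8 km and long-term displacements near
    0.6-0.9 km; see docs/methods.md for what the position-OU model can and
    cannot reproduce about daily range geometry.
    """

    n_per_cell: int = 5
    fix_interval: int = 30            # minutes between fixes
    days: int = 31                    # capture day + 30 full days
    ou_center: tuple[float, float] = (500_000.0, 3_300_000.0)  # UTM-like m
    ou_sd: float = 410.0              # stationary positional SD per axis, m
    ou_tau: float = 96.0              # positional autocorrelation time, h
    daily_activity_sd: float = 0.35   # lognormal SD of per-day step scale
    season_activity: dict[str, float] = field(default_factory=lambda: {
        "spring": 0.85, "summer": 1.0, "autumn": 1.3, "winter": 1.0})
    suppression_days: dict[str, int] = field(default_factory=lambda: {
        "drop_net": 0, "single_helicopter": 9, "tandem_helicopter": 5})
    suppression_factor: float = 0.3
    translocation_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "drop_net": (0.0, 0.0),
            "single_helicopter": (0.5, 3.1),
            "tandem_helicopter": (0.0, 0.5)})   # km
    mortality_prob: float = 13.0 / 190.0
    gps_noise_sd: float = 10.0        # stationary-collar emission SD, m
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    utc_offset_hours: float = -6.0    # CST
    seed: int = 1

    def __post_init__(self) -> None:
        if 1440 % self.fix_interval != 0:
            raise ValueError("fix_interval must divide 1440 minutes")
        if self.ou_sd <= 0 or self.ou_tau <= 0:
            raise ValueError("ou_sd and ou_tau must be positive")
        if not (0 < self.suppression_factor <= 1):
            raise ValueError("suppression_factor must be in (0, 1]")
        for m, (lo, hi) in self.translocation_range.items():
            if lo > hi or lo < 0:
                raise ValueError(f"bad translocation_range for {m}")
        for m, d in self.suppression_days.items():
            if d < 0:
                raise ValueError(f"suppression_days[{m}] must be >= 0")
        for p in (self.mortality_prob, self.missing_rate, self.outlier_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def fixes_per_day(self) -> int:
        return 1440 // self.fix_interval

    def phi(self) -> float:
        """One-step OU autoregression coefficient exp(-dt/tau)."""
        return float(np.exp(-(self.fix_interval / 60.0) / self.ou_tau))


def _ou_path(cfg: SimulationConfig, n: int, rng: np.random.Generator,
             x0: np.ndarray | None = None,
             step_scale: np.ndarray | None = None) -> np.ndarray:
    """Recursively propagate the discrete OU process for n fixes.

    step_scale optionally multiplies each innovation (per-fix), which is how
    suppression and daily activity variation enter the process.
    """
    phi = cfg.phi()
    sd_innov = cfg.ou_sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, sd_innov, size=(n, 2))
    if step_scale is not None:
        eps *= step_scale[:, None]
    center = np.asarray(cfg.ou_center)
    if x0 is None:
        dev0 = rng.normal(0.0, cfg.ou_sd, size=2)
    else:
        dev0 = np.asarray(x0, dtype=float) - center
    # deviations follow dev_t = phi * dev_{t-1} + eps_t; lfilter runs the
    # recursion in C. First fix is dev0 itself (eps_0 unused).
    dev = np.empty((n, 2))
    for ax in range(2):
        zi = np.array([phi * dev0[ax]])
        filtered, _ = lfilter([1.0], [1.0, -phi], eps[1:, ax], zi=zi)
        dev[0, ax] = dev0[ax]
        dev[1:, ax] = filtered
    return center + dev


def _timestamps(cfg: SimulationConfig, capture_local: pd.Timestamp) -> pd.DatetimeIndex:
    """Local fix times from capture through the end of day days-1."""
    step = pd.Timedelta(minutes=cfg.fix_interval)
    # snap the first fix to the next fix-interval boundary after capture
    base = capture_local.ceil(f"{cfg.fix_interval}min")
    end = (capture_local.normalize() + pd.Timedelta(days=cfg.days))
    n = int((end - base) / step)
    return pd.DatetimeIndex([base + i * step for i in range(n)])


def simulate_movement(cfg: SimulationConfig, deployment_id: str,
                      capture_local: pd.Timestamp,
                      rng: np.random.Generator,
                      season: str = "summer") -> pd.DataFrame:
    """Simulate an undisturbed OU trajectory sampled at the fix interval.

    Returns a fix table with local day-scale activity variation but no
    capture effect, mortality, or artifacts. Timestamps are UTC.
    """
    times = _timestamps(cfg, capture_local)
    n = len(times)
    day_index = np.asarray((times.normalize() - capture_local.normalize()).days)
    day_mult = rng.lognormal(mean=-0.5 * cfg.daily_activity_sd ** 2,
                             sigma=cfg.daily_activity_sd, size=cfg.days)
    scale = day_mult[day_index] * cfg.season_activity.get(season, 1.0)
    xy = _ou_path(cfg, n, rng, step_scale=scale)
    utc = times - pd.Timedelta(hours=cfg.utc_offset_hours)
    return pd.DataFrame({
        "deployment_id": deployment_id,
        "timestamp_utc": utc,
        "x_m": xy[:, 0],
        "y_m": xy[:, 1],
    })


def _innovations(cfg: SimulationConfig, xy: np.ndarray) -> np.ndarray:
    """Recover the innovation sequence of an OU path (inverse of _ou_path)."""
    phi = cfg.phi()
    dev = xy - np.asarray(cfg.ou_center)
    eps = np.zeros_like(dev)
    eps[1:] = dev[1:] - phi * dev[:-1]
    return eps


def apply_capture_effect(fixes: pd.DataFrame, cfg: SimulationConfig,
                         method: str, rng: np.random.Generator,
                         capture_local: pd.Timestamp) -> tuple[pd.DataFrame, dict]:
    """Impose release translocation and post-release movement suppression.

    The release point is displaced from the activity center by a uniform
    draw within the method's translocation range (uniform direction); for
    ``suppression_days[method]`` full days after the capture day, step
    innovations are multiplied by ``suppression_factor`` while mean
    reversion keeps pulling the animal toward its activity center.
    """
    if method not in METHODS:
        raise ValueError(f"unknown capture method: {method!r}")
    xy = fixes[["x_m", "y_m"]].to_numpy(dtype=float)
    eps = _innovations(cfg, xy)
    center = np.asarray(cfg.ou_center)

    lo, hi = cfg.translocation_range[method]
    if hi > 0:
        r = rng.uniform(lo, hi) * 1000.0
        theta = rng.uniform(0, 2 * np.pi)
        release = center + r * np.array([np.cos(theta), np.sin(theta)])
    else:
        release = xy[0]  # zero translocation: release where the animal was

    local = fixes["timestamp_utc"] + pd.Timedelta(hours=cfg.utc_offset_hours)
    day = np.asarray((local.dt.normalize() - capture_local.normalize()).dt.days)
    n_sup = cfg.suppression_days[method]
    suppressed = day <= n_sup if n_sup > 0 else day < 1
    # capture day itself is always disturbed; with 0 suppression days only
    # the remainder of day 0 is affected (movement window starts at day 1)
    scale = np.where(suppressed, cfg.suppression_factor, 1.0)
    if n_sup == 0 and cfg.suppression_factor == 1.0 and hi == 0:
        return fixes.copy(), {"release_x": release[0], "release_y": release[1],
                              "suppression_days": n_sup}

    phi = cfg.phi()
    dev = np.empty_like(xy)
    dev0 = release - center
    eps_s = eps * scale[:, None]
    for ax in range(2):
        zi = np.array([phi * dev0[ax]])
        filtered, _ = lfilter([1.0], [1.0, -phi], eps_s[1:, ax], zi=zi)
        dev[0, ax] = dev0[ax]
        dev[1:, ax] = filtered
    out = fixes.copy()
    out[["x_m", "y_m"]] = center + dev
    return out, {"release_x": release[0], "release_y": release[1],
                 "suppression_days": n_sup}


def apply_mortality(fixes: pd.DataFrame, cfg: SimulationConfig,
                    rng: np.random.Generator,
                    capture_local: pd.Timestamp) -> tuple[pd.DataFrame, int | None]:
    """With probability ``mortality_prob`` make the collar go stationary.

    A death day is drawn uniformly in [0, days-1]; all fixes from local noon
    of that day onward are replaced by a fixed point plus GPS noise.
    Returns the (possibly unchanged) fixes and the death day or ``None``.
    """
    if rng.uniform() >= cfg.mortality_prob:
        return fixes, None
    death_day = int(rng.integers(0, cfg.days - 1))
    local = fixes["timestamp_utc"] + pd.Timedelta(hours=cfg.utc_offset_hours)
    day = np.asarray((local.dt.normalize() - capture_local.normalize()).dt.days)
    frac = rng.uniform(0.0, 1.0)  # time of death within the day
    minute = local.dt.hour * 60 + local.dt.minute
    dead = (day > death_day) | ((day == death_day) & (minute >= frac * 1440))
    if not dead.any():  # death before first fix of a partial capture day
        dead = np.ones(len(fixes), dtype=bool)
    out = fixes.copy()
    idx = np.where(dead)[0]
    site = out.loc[out.index[idx[0]], ["x_m", "y_m"]].to_numpy(dtype=float)
    noise = rng.normal(0.0, cfg.gps_noise_sd, size=(len(idx), 2))
    out.iloc[idx, out.columns.get_loc("x_m")] = site[0] + noise[:, 0]
    out.iloc[idx, out.columns.get_loc("y_m")] = site[1] + noise[:, 1]
    return out, death_day


def inject_artifacts(fixes: pd.DataFrame, cfg: SimulationConfig,
                     rng: np.random.Generator) -> tuple[pd.DataFrame, list[int]]:
    """Corrupt the trajectory with teleports and spikes; drop missing fixes.

    A fraction ``outlier_rate`` of fixes is replaced, half by teleports
    33-100 km from the trajectory median (long-range censoring rule) and
    half by out-and-back spikes >= 2 km from both temporal neighbours
    (spike censoring rule). A fraction ``missing_rate`` of the remaining
    fixes is deleted. Returns the corrupted table (index reset) and the
    positional indices of surviving artifact fixes.
    """
    if not (0 <= cfg.outlier_rate <= 1 and 0 <= cfg.missing_rate <= 1):
        raise ValueError("artifact rates must lie in [0, 1]")
    n = len(fixes)
    out = fixes.reset_index(drop=True).copy()
    artifact_pos: list[int] = []
    n_out = int(round(cfg.outlier_rate * n))
    if n_out > 0:
        med = out[["x_m", "y_m"]].median().to_numpy()
        # interior, pairwise non-adjacent indices so spikes keep clean neighbours
        candidates = rng.permutation(np.arange(2, n - 2))
        chosen: list[int] = []
        taken = np.zeros(n, dtype=bool)
        for i in candidates:
            if len(chosen) == n_out:
                break
            if not (taken[i - 1] or taken[i] or taken[i + 1]):
                chosen.append(int(i))
                taken[i] = True
        for k, i in enumerate(chosen):
            theta = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(theta), np.sin(theta)])
            if k % 2 == 0:  # teleport far beyond the 32-km rule
                dist = rng.uniform(33_000.0, 100_000.0)
                out.loc[i, ["x_m", "y_m"]] = med + dist * u
            else:  # out-and-back spike >= 2 km from both neighbours
                dist = rng.uniform(2_500.0, 8_000.0)
                base = fixes[["x_m", "y_m"]].iloc[i].to_numpy(dtype=float)
                out.loc[i, ["x_m", "y_m"]] = base + dist * u
            artifact_pos.append(i)
    if cfg.missing_rate > 0:
        keep = rng.uniform(size=len(out)) >= cfg.missing_rate
        keep[artifact_pos] = True  # artifacts stay, so recovery is measurable
        old_pos = np.where(keep)[0]
        out = out.loc[keep].reset_index(drop=True)
        remap = {int(p): i for i, p in enumerate(old_pos)}
        artifact_pos = [remap[p] for p in artifact_pos]
    return out, sorted(artifact_pos)


def _capture_time(season: str, rng: np.random.Generator) -> pd.Timestamp:
    """Capture during daylight processing hours in a month of the season."""
    month = int(rng.choice(_SEASON_MONTHS[season]))
    year = int(rng.integers(2011, 2016))
    day = int(rng.integers(1, 29))
    hour = int(rng.integers(7, 11))
    minute = int(rng.integers(0, 60))
    return pd.Timestamp(year=year, month=month, day=day, hour=hour, minute=minute)


@dataclass
class CohortData:
    fixes: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame

    def write(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        fx = self.fixes.copy()
        fx["timestamp_utc"] = fx["timestamp_utc"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        fx.to_csv(d / "fixes.csv", index=False)
        md = self.metadata.copy()
        md["capture_time_utc"] = pd.to_datetime(
            md["capture_time_utc"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        md.to_csv(d / "metadata.csv", index=False)
        self.truth.to_csv(d / "truth.csv", index=False)


def simulate_cohort(cfg: SimulationConfig,
                    seasons: tuple[str, ...] | None = None) -> CohortData:
    """Simulate a balanced method x sex cohort with full ground truth.

    Each deployment draws its capture season from ``seasons`` (default: all
    four, cycled so the design stays balanced across seasons too).
    """
    if cfg.n_per_cell <= 0:
        raise ValueError("n_per_cell must be positive")
    seasons = seasons or SEASONS
    root = np.random.SeedSequence(cfg.seed)
    fixes_parts, meta_rows, truth_rows = [], [], []
    cell_id = 0
    for method in METHODS:
        for sex in SEXES:
            for k in range(cfg.n_per_cell):
                child = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(cell_id,))
                rng = np.random.default_rng(child)
                dep_id = f"D{cell_id:04d}"
                season = seasons[cell_id % len(seasons)]
                capture_local = _capture_time(season, rng)
                fixes = simulate_movement(cfg, dep_id, capture_local, rng,
                                          season=season)
                fixes, effect = apply_capture_effect(
                    fixes, cfg, method, rng, capture_local)
                fixes, death_day = apply_mortality(
                    fixes, cfg, rng, capture_local)
                fixes, artifacts = inject_artifacts(fixes, cfg, rng)
                fixes_parts.append(fixes)
                meta_rows.append({
                    "deployment_id": dep_id,
                    "animal_id": f"A{cell_id:04d}",
                    "method": method,
                    "sex": sex,
                    "capture_time_utc":
                        capture_local - pd.Timedelta(hours=cfg.utc_offset_hours),
                    "utc_offset_hours": cfg.utc_offset_hours,
                    "capture_season": season,
                })
                truth_rows.append({
                    "deployment_id": dep_id,
                    "suppression_days": effect["suppression_days"],
                    "death_day": death_day if death_day is not None else -1,
                    "release_x": effect["release_x"],
                    "release_y": effect["release_y"],
                    "center_x": cfg.ou_center[0],
                    "center_y": cfg.ou_center[1],
                    "artifact_indices":
                        ";".join(str(i) for i in artifacts) if artifacts else "",
                })
                cell_id += 1
    return CohortData(
        fixes=pd.concat(fixes_parts, ignore_index=True),
        metadata=pd.DataFrame(meta_rows),
        truth=pd.DataFrame(truth_rows),
    )
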