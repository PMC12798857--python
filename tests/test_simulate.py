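"""Synthetic-cohort generator: determinism, process properties, effects."""

import numpy as np
import pandas as pd
import pytest

from postcapture.simulate import (METHODS, SimulationConfig,
                                  apply_capture_effect, apply_mortality,
                                  inject_artifacts, simulate_cohort,
                                  simulate_movement, _ou_path)
from conftest import NO_EFFECT


@pytest.mark.parametrize("bad", [
    dict(fix_interval=37),
    dict(ou_sd=0.0),
    dict(ou_tau=-1.0),
    dict(suppression_factor=0.0),
    dict(suppression_factor=1.5),
    dict(mortality_prob=1.2),
    dict(missing_rate=-0.1),
    dict(n_per_cell=5, translocation_range={"drop_net": (2.0, 1.0)}),
    dict(suppression_days={"drop_net": -1}),
])
def test_config_validation_rejects(bad):
    with pytest.raises(ValueError):
        SimulationConfig(**bad)


def test_cohort_determinism():
    """Identical seed reproduces the dataset byte-for-byte."""
    cfg = SimulationConfig(n_per_cell=1, seed=42, outlier_rate=0.02,
                           missing_rate=0.02, mortality_prob=0.3)
    a = simulate_cohort(cfg)
    b = simulate_cohort(SimulationConfig(n_per_cell=1, seed=42,
                                         outlier_rate=0.02,
                                         missing_rate=0.02,
                                         mortality_prob=0.3))
    pd.testing.assert_frame_equal(a.fixes, b.fixes)
    pd.testing.assert_frame_equal(a.metadata, b.metadata)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_cohort_design_counts():
    cfg = SimulationConfig(n_per_cell=1, **NO_EFFECT)
    cohort = simulate_cohort(cfg)
    assert len(cohort.metadata) == 6  # 3 methods x 2 sexes
    # 30 full days at 30-minute fixes: 1,440 fixes plus the capture-day tail
    for dep_id, grp in cohort.fixes.groupby("deployment_id"):
        local = grp["timestamp_utc"] + pd.Timedelta(hours=-6)
        cap = cohort.metadata.set_index("deployment_id").loc[
            dep_id, "capture_time_utc"] + pd.Timedelta(hours=-6)
        day = (local.dt.normalize() - cap.normalize()).dt.days
        assert (day.between(1, 30)).sum() == 1440
        assert (day == 0).sum() > 0


def test_degenerate_variance_collapses_to_center():
    cfg = SimulationConfig(ou_sd=1e-9, **NO_EFFECT)
    rng = np.random.default_rng(0)
    fixes = simulate_movement(cfg, "D0", pd.Timestamp("2012-06-01 09:00"), rng)
    xy = fixes[["x_m", "y_m"]].to_numpy()
    assert np.allclose(xy, np.asarray(cfg.ou_center), atol=1e-6)


def test_autoregression_continuity():
    """phi -> 1 as the fix interval shrinks (process continuity)."""
    assert SimulationConfig(fix_interval=1).phi() > 0.999
    assert SimulationConfig(fix_interval=1).phi() < 1.0


def test_ou_stationary_sd():
    """Empirical positional SD over a long run matches ou_sd within 5%."""
    cfg = SimulationConfig(ou_sd=500.0, ou_tau=4.0)
    rng = np.random.default_rng(1)
    xy = _ou_path(cfg, 100_000, rng)
    sd = (xy - np.asarray(cfg.ou_center)).std(axis=0)
    assert np.all(np.abs(sd - 500.0) / 500.0 < 0.05)


def test_mean_daily_distance_calibration():
    """Monte-Carlo mean daily distance of ~100 animals in 2,000-3,500 m."""
    cfg = SimulationConfig(n_per_cell=17, seed=1, **NO_EFFECT)
    cohort = simulate_cohort(cfg)
    means = []
    meta = cohort.metadata.set_index("deployment_id")
    for dep_id, grp in cohort.fixes.groupby("deployment_id"):
        local = grp["timestamp_utc"] + pd.Timedelta(hours=-6)
        cap = meta.loc[dep_id, "capture_time_utc"] + pd.Timedelta(hours=-6)
        day = (local.dt.normalize() - cap.normalize()).dt.days.to_numpy()
        xy = grp[["x_m", "y_m"]].to_numpy()
        steps = np.hypot(*np.diff(xy, axis=0).T)
        sel = (day[:-1] >= 1) & (day[:-1] <= 30)
        means.append(steps[sel].sum() / 30.0)
    assert 2000.0 < np.mean(means) < 3500.0


def test_zero_translocation_zero_suppression_is_identity(clean_cohort):
    cfg, _ = clean_cohort
    rng = np.random.default_rng(5)
    cap = pd.Timestamp("2012-06-01 09:00")
    fixes = simulate_movement(cfg, "D0", cap, np.random.default_rng(2))
    cfg_id = SimulationConfig(suppression_factor=1.0, **NO_EFFECT)
    out, info = apply_capture_effect(fixes, cfg_id, "drop_net", rng, cap)
    pd.testing.assert_frame_equal(out, fixes)
    assert info["release_x"] == fixes["x_m"].iloc[0]


def test_translocation_bounds_single_helicopter():
    """Release displacement of single-helicopter captures spans 0.5-3.1 km."""
    cfg = SimulationConfig()
    cap = pd.Timestamp("2012-06-01 09:00")
    base = simulate_movement(cfg, "D0", cap, np.random.default_rng(3)).iloc[:4]
    rng = np.random.default_rng(4)
    center = np.asarray(cfg.ou_center)
    d = []
    for _ in range(10_000):
        _, info = apply_capture_effect(base, cfg, "single_helicopter", rng, cap)
        d.append(np.hypot(info["release_x"] - center[0],
                          info["release_y"] - center[1]))
    d = np.array(d) / 1000.0
    assert d.min() >= 0.5 and d.max() <= 3.1
    assert d.min() < 0.55 and d.max() > 3.0  # bounds are attained


def test_unknown_method_rejected():
    cfg = SimulationConfig()
    fixes = simulate_movement(cfg, "D0", pd.Timestamp("2012-06-01 09:00"),
                              np.random.default_rng(0)).iloc[:4]
    with pytest.raises(ValueError, match="method"):
        apply_capture_effect(fixes, cfg, "cannon_net",
                             np.random.default_rng(0),
                             pd.Timestamp("2012-06-01 09:00"))


def test_suppression_reduces_daily_distance():
    """Suppressed days travel less than post-suppression days (factor 0.3),
    checked per deployment over >= 50 replicates."""
    sup = {m: 5 for m in METHODS}
    cfg = SimulationConfig(n_per_cell=9, seed=6, mortality_prob=0.0,
                           suppression_days=sup, suppression_factor=0.3)
    cohort = simulate_cohort(cfg)
    meta = cohort.metadata.set_index("deployment_id")
    wins = tot = 0
    for dep_id, grp in cohort.fixes.groupby("deployment_id"):
        local = grp["timestamp_utc"] + pd.Timedelta(hours=-6)
        cap = meta.loc[dep_id, "capture_time_utc"] + pd.Timedelta(hours=-6)
        day = (local.dt.normalize() - cap.normalize()).dt.days.to_numpy()
        xy = grp[["x_m", "y_m"]].to_numpy()
        steps = np.hypot(*np.diff(xy, axis=0).T)
        d0 = day[:-1]
        during = steps[(d0 >= 1) & (d0 <= 5)].sum() / 5
        after = steps[(d0 >= 6) & (d0 <= 30)].sum() / 25
        wins += during < after
        tot += 1
    assert tot >= 50
    assert wins == tot


def test_mortality_off_is_noop():
    cfg = SimulationConfig(mortality_prob=0.0)
    cap = pd.Timestamp("2012-06-01 09:00")
    fixes = simulate_movement(cfg, "D0", cap, np.random.default_rng(7)).iloc[:50]
    out, death = apply_mortality(fixes, cfg, np.random.default_rng(8), cap)
    assert death is None
    pd.testing.assert_frame_equal(out, fixes)


def test_mortality_cluster_is_tight():
    """Post-death fixes collapse to a stationary cluster (within 60 m)."""
    cfg = SimulationConfig(mortality_prob=1.0)
    cap = pd.Timestamp("2012-06-01 09:00")
    fixes = simulate_movement(cfg, "D0", cap, np.random.default_rng(9))
    out, death = apply_mortality(fixes, cfg, np.random.default_rng(10), cap)
    assert death is not None and 0 <= death <= cfg.days - 1
    local = out["timestamp_utc"] + pd.Timedelta(hours=-6)
    day = (local.dt.normalize() - cap.normalize()).dt.days.to_numpy()
    dead = out.loc[day > death, ["x_m", "y_m"]].to_numpy()
    centroid = dead.mean(axis=0)
    assert np.hypot(*(dead - centroid).T).max() < 60.0


def test_mortality_rate_matches_binomial():
    """Death count in a 190-animal cohort matches the binomial oracle."""
    cfg = SimulationConfig(mortality_prob=13.0 / 190.0, days=2,
                           fix_interval=360)
    cap = pd.Timestamp("2012-06-01 09:00")
    fixes = simulate_movement(cfg, "D0", cap, np.random.default_rng(11))
    rng = np.random.default_rng(12)
    reps, n = 200, 190
    counts = []
    for _ in range(reps):
        deaths = sum(apply_mortality(fixes, cfg, rng, cap)[1] is not None
                     for _ in range(n))
        counts.append(deaths)
    se_mean = np.sqrt(n * (13 / 190) * (1 - 13 / 190) / reps)
    assert abs(np.mean(counts) - 13.0) < 4 * se_mean


def test_artifacts_identity_at_zero_rates():
    cfg = SimulationConfig(outlier_rate=0.0, missing_rate=0.0)
    cap = pd.Timestamp("2012-06-01 09:00")
    fixes = simulate_movement(cfg, "D0", cap, np.random.default_rng(13))
    out, idx = inject_artifacts(fixes, cfg, np.random.default_rng(14))
    assert idx == []
    pd.testing.assert_frame_equal(out, fixes.reset_index(drop=True))


def test_teleport_artifacts_beyond_rule_distance():
    """Every teleport artifact lies > 32 km from the clean median."""
    cfg = SimulationConfig(outlier_rate=0.02)
    cap = pd.Timestamp("2012-06-01 09:00")
    fixes = simulate_movement(cfg, "D0", cap, np.random.default_rng(15))
    med = fixes[["x_m", "y_m"]].median().to_numpy()
    out, idx = inject_artifacts(fixes, cfg, np.random.default_rng(16))
    assert len(idx) == round(0.02 * len(fixes))
    art = out.iloc[idx][["x_m", "y_m"]].to_numpy()
    orig = fixes.iloc[idx][["x_m", "y_m"]].to_numpy()
    dist_med = np.hypot(art[:, 0] - med[0], art[:, 1] - med[1])
    dist_orig = np.hypot(*(art - orig).T)
    teleport = dist_med > 32_000
    # every artifact is either a long-range teleport or a >= 2 km spike,
    # and both kinds are present in roughly equal numbers
    assert np.all(teleport | (dist_orig >= 2_000))
    assert abs(teleport.sum() - (~teleport).sum()) <= 1
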