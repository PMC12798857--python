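"""Trajectory cleaning stack: ingestion, resampling, censoring, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from postcapture.simulate import SimulationConfig, simulate_cohort
from postcapture.telemetry import (Deployment, SchemaError, build_deployments,
                                   censor_outliers, compute_step_metrics,
                                   detect_end_date, define_windows,
                                   read_collar_data, resample_30min,
                                   to_local_time)
from postcapture.survival import build_survival_records
from conftest import make_deployment


# ---------------------------------------------------------------- ingestion

def test_read_collar_data_roundtrip(tmp_path, messy_cohort):
    """Write-then-read of a synthetic cohort is lossless."""
    _, cohort = messy_cohort
    cohort.write(tmp_path)
    fixes, meta = read_collar_data(tmp_path / "fixes.csv",
                                   tmp_path / "metadata.csv")
    assert len(fixes) == len(cohort.fixes)
    assert set(fixes["deployment_id"]) == set(cohort.metadata["deployment_id"])
    orig = cohort.fixes.sort_values(["deployment_id", "timestamp_utc"])
    np.testing.assert_allclose(fixes["x_m"].to_numpy(),
                               orig["x_m"].to_numpy(), rtol=0, atol=1e-6)


def test_read_collar_data_schema_errors(tmp_path):
    pd.DataFrame({"deployment_id": [], "timestamp_utc": []}).to_csv(
        tmp_path / "f.csv", index=False)
    pd.DataFrame({c: [] for c in
                  ("deployment_id", "animal_id", "method", "sex",
                   "capture_time_utc", "utc_offset_hours",
                   "capture_season")}).to_csv(tmp_path / "m.csv", index=False)
    with pytest.raises(SchemaError, match="x_m"):
        read_collar_data(tmp_path / "f.csv", tmp_path / "m.csv")


def test_read_collar_data_unknown_level(tmp_path):
    pd.DataFrame({"deployment_id": ["a"],
                  "timestamp_utc": ["2012-01-01T00:00:00"],
                  "x_m": [0.0], "y_m": [0.0]}).to_csv(
        tmp_path / "f.csv", index=False)
    pd.DataFrame({"deployment_id": ["a"], "animal_id": ["a"],
                  "method": ["cannon_net"], "sex": ["F"],
                  "capture_time_utc": ["2012-01-01T00:00:00"],
                  "utc_offset_hours": [-6], "capture_season": ["winter"]}
                 ).to_csv(tmp_path / "m.csv", index=False)
    with pytest.raises(SchemaError, match="method"):
        read_collar_data(tmp_path / "f.csv", tmp_path / "m.csv")


def test_read_sorts_and_deduplicates(tmp_path):
    rows = [("b", "2012-01-01T01:00:00", 1.0, 0.0),
            ("a", "2012-01-01T01:00:00", 2.0, 0.0),
            ("b", "2012-01-01T00:00:00", 3.0, 0.0),
            ("a", "2012-01-01T01:00:00", 9.0, 0.0),  # duplicate: dropped
            ("a", "2012-01-01T00:30:00", 4.0, 0.0)]
    pd.DataFrame(rows, columns=["deployment_id", "timestamp_utc",
                                "x_m", "y_m"]).to_csv(tmp_path / "f.csv",
                                                      index=False)
    meta = pd.DataFrame({
        "deployment_id": ["a", "b"], "animal_id": ["a", "b"],
        "method": ["drop_net", "drop_net"], "sex": ["F", "M"],
        "capture_time_utc": ["2012-01-01T00:00:00"] * 2,
        "utc_offset_hours": [-6, -6], "capture_season": ["winter", "winter"]})
    meta.to_csv(tmp_path / "m.csv", index=False)
    fixes, _ = read_collar_data(tmp_path / "f.csv", tmp_path / "m.csv")
    assert len(fixes) == 4
    a = fixes[fixes["deployment_id"] == "a"]
    assert a["timestamp_utc"].is_monotonic_increasing
    assert a["x_m"].tolist() == [4.0, 2.0]  # first occurrence kept


# --------------------------------------------------------------- local time

def test_to_local_time_offset_zero_is_identity():
    f = pd.DataFrame({"timestamp_utc": pd.to_datetime(["2012-07-01T03:00"])})
    out = to_local_time(f, 0.0)
    assert (out["timestamp_local"] == out["timestamp_utc"]).all()


def test_to_local_time_crosses_midnight():
    f = pd.DataFrame({"timestamp_utc": pd.to_datetime(["2012-07-01T03:00"])})
    out = to_local_time(f, -5.0)
    assert out["timestamp_local"].iloc[0] == pd.Timestamp("2012-06-30T22:00")


def test_to_local_time_inverse():
    f = pd.DataFrame({"timestamp_utc": pd.date_range("2012-07-01", periods=5,
                                                     freq="30min")})
    fwd = to_local_time(f, -6.0)
    back = fwd["timestamp_local"] + pd.Timedelta(hours=6.0)
    assert (back == f["timestamp_utc"]).all()


def test_to_local_time_rejects_extreme_offset():
    with pytest.raises(ValueError):
        to_local_time(pd.DataFrame({"timestamp_utc": []}), 15.0)


# --------------------------------------------------------------- resampling

def _fix_frame(times, x=None):
    times = pd.DatetimeIndex(times)
    return pd.DataFrame({"deployment_id": "d",
                         "timestamp_local": times,
                         "x_m": x if x is not None else np.arange(len(times), dtype=float),
                         "y_m": 0.0})


def test_resample_full_day_15min_to_48():
    f = _fix_frame(pd.date_range("2012-07-01 00:00", periods=96, freq="15min"))
    out = resample_30min(f)
    assert len(out) == 48


def test_resample_30min_input_unchanged():
    f = _fix_frame(pd.date_range("2012-07-01 00:00", periods=48, freq="30min"))
    out = resample_30min(f)
    pd.testing.assert_frame_equal(out, f)


def test_resample_keeps_nearest_to_slot():
    f = _fix_frame(pd.to_datetime(["2012-07-01 08:00", "2012-07-01 08:14"]))
    out = resample_30min(f)
    assert len(out) == 1
    assert out["timestamp_local"].iloc[0] == pd.Timestamp("2012-07-01 08:00")


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.lists(st.integers(0, 1439), min_size=1, max_size=200, unique=True))
def test_resample_idempotent(minutes):
    base = pd.Timestamp("2012-07-01")
    f = _fix_frame([base + pd.Timedelta(minutes=m) for m in sorted(minutes)])
    once = resample_30min(f)
    twice = resample_30min(once)
    pd.testing.assert_frame_equal(twice, once)


# ------------------------------------------------------------- step metrics

def test_step_metrics_collinear():
    xy = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]])
    out = compute_step_metrics(_fix_frame(
        pd.date_range("2012-07-01", periods=3, freq="30min"),
        x=xy[:, 0]))
    assert out["step_m"].iloc[1:].tolist() == [100.0, 100.0]
    assert out["turn_deg"].iloc[2] == 0.0
    assert np.isnan(out["step_m"].iloc[0])  # first fix flagged, not zero


def test_step_metrics_right_angle():
    f = pd.DataFrame({"deployment_id": "d",
                      "timestamp_local": pd.date_range("2012-07-01",
                                                       periods=3, freq="30min"),
                      "x_m": [0.0, 100.0, 100.0],
                      "y_m": [0.0, 0.0, 100.0]})
    out = compute_step_metrics(f)
    assert out["heading_deg"].iloc[1] == pytest.approx(90.0)  # due east
    assert out["heading_deg"].iloc[2] == pytest.approx(0.0)   # due north
    assert out["turn_deg"].iloc[2] == pytest.approx(-90.0)
    assert out["dt_min"].iloc[1] == 30.0
    assert out["velocity_mpm"].iloc[1] == pytest.approx(100.0 / 30.0)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_net_displacement_bounded_by_path(seed):
    rng = np.random.default_rng(seed)
    xy = np.cumsum(rng.normal(0, 50, size=(20, 2)), axis=0)
    f = pd.DataFrame({"deployment_id": "d",
                      "timestamp_local": pd.date_range("2012-07-01",
                                                       periods=20,
                                                       freq="30min"),
                      "x_m": xy[:, 0], "y_m": xy[:, 1]})
    out = compute_step_metrics(f)
    assert (out["net_displacement_m"].iloc[-1]
            <= out["step_m"].iloc[1:].sum() + 1e-9)


# ---------------------------------------------------------------- end date

def test_detect_end_date_moving_returns_none():
    rng = np.random.default_rng(0)
    xy = np.cumsum(rng.normal(0, 200, size=(200, 2)), axis=0)
    dep = make_deployment(xy)
    assert detect_end_date(dep.fixes) is None


def test_detect_end_date_stationary_from_k():
    rng = np.random.default_rng(1)
    k = 60
    moving = np.cumsum(rng.normal(0, 200, size=(k, 2)), axis=0)
    # the animal dies 400 m from its last live position
    dead = moving[-1] + [400.0, 0.0] + rng.normal(0, 5, size=(200, 2))
    dep = make_deployment(np.vstack([moving, dead]))
    end = detect_end_date(dep.fixes)
    assert end == dep.fixes["timestamp_local"].iloc[k]


def test_detect_end_date_short_trajectory():
    dep = make_deployment(np.zeros((10, 2)))
    assert detect_end_date(dep.fixes, window_h=48.0) is None


def test_mortality_detection_against_truth():
    """Detected end day equals the true death day for >= 95% of deaths."""
    cfg = SimulationConfig(n_per_cell=15, seed=7, mortality_prob=0.3)
    cohort = simulate_cohort(cfg)
    deps = build_deployments(cohort.fixes, cohort.metadata)
    truth = cohort.truth.set_index("deployment_id")
    hits = tot = 0
    for d in deps:
        td = int(truth.loc[d.deployment_id, "death_day"])
        if td < 0:
            continue
        tot += 1
        det = d.day_of(d.end_date) if d.end_date is not None else None
        hits += det == td
    assert tot >= 20
    assert hits / tot >= 0.95


# ---------------------------------------------------------------- censoring

def test_censor_clean_trajectory_no_removals(clean_deployments):
    """The cleaning stack is the identity on artifact-free data."""
    dep = clean_deployments[0]
    _, removed = censor_outliers(dep.fixes)
    assert len(removed) == 0


def test_censor_rule_a_teleport():
    rng = np.random.default_rng(2)
    xy = rng.normal(0, 200, size=(100, 2))
    xy[40] = [40_000.0, 0.0]
    dep = make_deployment(xy)
    clean, removed = censor_outliers(dep.fixes)
    assert removed["censored_rule"].tolist() == ["A"]
    assert len(clean) == 99


def test_censor_rule_b_spike():
    rng = np.random.default_rng(3)
    xy = rng.normal(0, 100, size=(100, 2))
    xy[50] = xy[49] + [2_500.0, 0.0]  # out-and-back within 30-min gaps
    dep = make_deployment(xy)
    clean, removed = censor_outliers(dep.fixes)
    assert removed["censored_rule"].tolist() == ["B"]
    assert len(clean) == 99


def test_censor_idempotent_and_order_preserving(messy_cohort):
    _, cohort = messy_cohort
    grp = cohort.fixes[cohort.fixes["deployment_id"] == "D0000"]
    f = to_local_time(grp.reset_index(drop=True), -6.0)
    once, _ = censor_outliers(f)
    twice, removed2 = censor_outliers(once)
    assert len(removed2) == 0
    assert once["timestamp_local"].is_monotonic_increasing


def test_censor_recovers_injected_artifacts():
    """>= 99% of injected artifacts are recovered on a seeded cohort."""
    cfg = SimulationConfig(n_per_cell=5, seed=7, mortality_prob=0.0,
                           outlier_rate=0.02)
    cohort = simulate_cohort(cfg)
    truth = cohort.truth.set_index("deployment_id")
    recovered = total = 0
    for dep_id, grp in cohort.fixes.groupby("deployment_id"):
        idx = truth.loc[dep_id, "artifact_indices"]
        art = [int(i) for i in idx.split(";")] if idx else []
        ts = grp.reset_index(drop=True)["timestamp_utc"]
        art_ts = set(ts.iloc[art])
        f = to_local_time(grp.reset_index(drop=True), -6.0)
        _, removed = censor_outliers(f)
        recovered += len(art_ts & set(removed["timestamp_utc"]))
        total += len(art_ts)
    assert total > 100
    assert recovered / total >= 0.99


# ------------------------------------------------------------------ windows

def test_windows_complete_deployment_eligible(clean_deployments):
    dep = clean_deployments[0]
    assert dep.eligible_movement and dep.eligible_survival


def test_windows_death_mid_window():
    """Death on day 10: survival event at day 10, movement-ineligible."""
    rng = np.random.default_rng(4)
    n_live = 10 * 48
    live = np.cumsum(rng.normal(0, 150, size=(n_live, 2)), axis=0)
    dead = live[-1] + [400.0, 0.0] + rng.normal(0, 10, size=(21 * 48, 2))
    dep = make_deployment(np.vstack([live, dead]), start="2013-03-02 00:00")
    dep.end_date = detect_end_date(dep.fixes)
    dep = define_windows(dep)
    assert not dep.eligible_movement
    rec = build_survival_records([dep])
    assert rec["event"].iloc[0] == 1
    assert rec["time"].iloc[0] == 10.0


def test_windows_short_collar_censored_at_last_day():
    """29 days of data, no death: survival-censored early, movement-out."""
    rng = np.random.default_rng(5)
    xy = np.cumsum(rng.normal(0, 150, size=(29 * 48, 2)), axis=0)
    dep = make_deployment(xy, start="2013-03-02 00:00")
    dep.end_date = detect_end_date(dep.fixes)
    dep = define_windows(dep)
    assert dep.eligible_survival and not dep.eligible_movement
    rec = build_survival_records([dep])
    assert rec["event"].iloc[0] == 0
    assert rec["time"].iloc[0] < 31.0


def test_windows_requires_capture_time():
    dep = make_deployment(np.zeros((4, 2)))
    dep.capture_time_local = pd.NaT
    with pytest.raises(ValueError, match="capture time"):
        define_windows(dep)
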