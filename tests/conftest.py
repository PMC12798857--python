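"""Shared fixtures: small seeded cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from postcapture.simulate import SimulationConfig, simulate_cohort
from postcapture.telemetry import Deployment, build_deployments

NO_EFFECT = dict(
    mortality_prob=0.0,
    suppression_days={m: 0 for m in
                      ("drop_net", "single_helicopter", "tandem_helicopter")},
    translocation_range={m: (0.0, 0.0) for m in
                         ("drop_net", "single_helicopter", "tandem_helicopter")},
)


@pytest.fixture(scope="session")
def clean_cohort():
    """12 undisturbed deployments: no capture effect, deaths, or artifacts."""
    cfg = SimulationConfig(n_per_cell=2, seed=3, **NO_EFFECT)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_deployments(clean_cohort):
    cfg, cohort = clean_cohort
    return build_deployments(cohort.fixes, cohort.metadata)


@pytest.fixture(scope="session")
def messy_cohort():
    """Cohort with defaults-level capture effects plus deaths and artifacts."""
    cfg = SimulationConfig(n_per_cell=2, seed=11, mortality_prob=0.2,
                           outlier_rate=0.01, missing_rate=0.01)
    return cfg, simulate_cohort(cfg)


def make_deployment(xy: np.ndarray, start="2013-03-02 08:00",
                    freq_min: int = 30, method="drop_net", sex="F",
                    season="spring") -> Deployment:
    """Deployment wrapper around a raw coordinate array (30-min schedule)."""
    n = len(xy)
    start = pd.Timestamp(start)
    times = pd.date_range(start, periods=n, freq=f"{freq_min}min")
    fixes = pd.DataFrame({
        "deployment_id": "T1",
        "timestamp_utc": times + pd.Timedelta(hours=6),
        "timestamp_local": times,
        "x_m": xy[:, 0], "y_m": xy[:, 1],
    })
    return Deployment(deployment_id="T1", method=method, sex=sex,
                      capture_season=season,
                      capture_time_local=start,
                      utc_offset_hours=-6.0, fixes=fixes,
                      eligible_movement=True)
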