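"""Clean the simulated collar data and define analysis windows.

Resamples to the 30-minute schedule, censors impossible positions, detects
end-of-data (mortality / collar drop), and flags each deployment's
eligibility for the movement and survival analyses.
"""

import pandas as pd

from common import CONFIG
from postcapture.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_dict({**CONFIG.to_dict(), "stages": ["clean"]})
out = run_pipeline(cfg)

deps = pd.read_csv(out / "deployments.csv")
n = len(deps)
print(f"{n} deployments cleaned")
print(f"movement-eligible: {deps['eligible_movement'].sum()}/{n} "
      f"(ineligible: detected end date or incomplete days)")
print(f"detected end dates: {(deps['end_date'].notna() & (deps['end_date'] != '')).sum()}")
truth = pd.read_csv(out / "truth.csv")
merged = deps.merge(truth, on="deployment_id")
true_deaths = merged["death_day"] >= 0
det = merged["end_date"].fillna("") != ""
print(f"end-date detection vs truth: {int((true_deaths & det).sum())}"
      f"/{int(true_deaths.sum())} deaths detected, "
      f"{int((det & ~true_deaths).sum())} false alarms")
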