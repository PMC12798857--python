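"""Compute daily distance traveled and daily displacement per deployment.

Emits the long-format metric table (30 daily values plus the per-animal
long-term mean) and summarizes the long-term means by capture method.
"""

import pandas as pd

from common import CONFIG
from postcapture.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_dict({**CONFIG.to_dict(), "stages": ["metrics"]})
out = run_pipeline(cfg)

tab = pd.read_csv(out / "metrics.csv", dtype={"day": str})
meta = pd.read_csv(out / "metadata.csv")
ltm = tab[tab["day"] == "ltm"].merge(meta, on="deployment_id")
print(f"{tab['deployment_id'].nunique()} movement-eligible deployments")
for metric, grp in ltm.groupby("metric"):
    by = grp.groupby("method")["value"].mean().round(0).to_dict()
    print(f"long-term mean {metric} (m): {by}")
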