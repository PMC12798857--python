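"""Estimate daily 99% kernel ranges (100-m grid, reference bandwidth) and
consecutive-day range overlap for every movement-eligible deployment."""

import pandas as pd

from common import CONFIG
from postcapture.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_dict({**CONFIG.to_dict(), "stages": ["spaceuse"]})
out = run_pipeline(cfg)

tab = pd.read_csv(out / "spaceuse.csv", dtype={"day": str})
ltm = tab[tab["day"] == "ltm"]
for metric, grp in ltm.groupby("metric"):
    unit = "ha" if metric == "range_size" else "proportion"
    print(f"long-term mean {metric}: {grp['value'].mean():.2f} {unit} "
          f"(n={len(grp)} deployments)")
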