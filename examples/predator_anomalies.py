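"""Standardized predator anomalies, encounter rates, and percent change.

Shows the small index utilities: z-standardization of survey densities
by season and region, >2 SD extreme flagging, whale encounter rates,
and the percent-change summary.
"""

import numpy as np
import pandas as pd

from pelagic_sync import indices as ix

rng = np.random.default_rng(1)
years = list(range(2006, 2020))
df = pd.DataFrame(
    {
        "season": "fall",
        "region": "PWS",
        "year": years,
        "value": rng.gamma(2.0, 5.0, len(years)),
    }
)
df.loc[df.year == 2014, "value"] *= 6  # inshore influx during the warm years
out = ix.standardize(df, group_cols=("season", "region"))
out["extreme"] = ix.flag_extremes(out["z"], threshold=2.0)
print(out[["year", "value", "z", "extreme"]].round(2).to_string(index=False))
print("flagged years:", out.loc[out.extreme, "year"].tolist())

rate = ix.encounter_rate(12, 60.0)
print(f"whale encounter rate: 12 whales / 60 km = {rate:.2f} km^-1")
print(f"spawning index 100 -> 27 is a {ix.percent_change(100, 27):.0f}% decline")
# Anomalies are mean-0, SD-1 within each season x region across years,
# so indices from different platforms plot on a common scale.
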