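"""Permeability index across leak rates, and trend-test behaviour.

Simulates time-lapses at leak rates 0 / 0.1 / 0.5 gray levels per minute and
reports the per-time aggregated index and the across-time ANOVA decision.
Writes results/permeability_trend.csv.
"""

from pathlib import Path

import pandas as pd

from glycovivo import LeakSpec, permeability_index, simulate_leak_series, trend_test

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for rate in (0.0, 0.1, 0.5):
    series, _ = simulate_leak_series(LeakSpec(leak_rate=rate, noise_sd=2.0,
                                              seed=4))
    idx = permeability_index(series)
    res = trend_test(idx)
    for _, r in idx[idx.roi_id == -1].iterrows():
        rows.append({"leak_rate": rate, "t_min": r["t_min"],
                     "mean_index": r["index"],
                     "anova_F": res.F, "anova_p": res.p,
                     "significant": res.p < 0.05})

df = pd.DataFrame(rows)
df.to_csv(OUT / "permeability_trend.csv", index=False, float_format="%.6g")
print(df.to_string(index=False))
print("\nzero leak stays flat and non-significant; "
      "0.5 gl/min rises ~15 gray levels per 30-min frame and is detected")
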