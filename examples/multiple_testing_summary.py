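"""Bonferroni summaries of a multi-trait, multi-gene p-value table.

Mirrors a three-trait genome scan: per-trait thresholds alpha/m_t and an
overall threshold alpha/(total tests).
"""

import numpy as np
import pandas as pd

import nrvat

rng = np.random.default_rng(9)
counts = {"SZ": 288, "BP": 161, "CL": 281}
table = pd.DataFrame({
    "set_id": [f"gene{i}" for i in range(sum(counts.values()))],
    "trait": np.repeat(list(counts), list(counts.values())),
    "p_value": rng.uniform(size=sum(counts.values())),
})
table.loc[0, "p_value"] = 1e-6   # one strong signal

sig, thr = nrvat.summarize_multiple_testing(table, alpha=0.05,
                                            scheme="bonferroni_per_trait")
print("per-trait thresholds:", {t: f"{v:.3g}" for t, v in thr.items()})
print("significant:", sig[["set_id", "trait", "p_value"]].to_string(index=False))

_, thr_all = nrvat.summarize_multiple_testing(table, alpha=0.05,
                                              scheme="bonferroni_overall")
print(f"overall threshold 0.05/{len(table)} = {thr_all['SZ']:.3g}")
# With 288+161+281 = 730 tests the overall Bonferroni cutoff is 6.85e-5;
# only p-values below it survive correction across all three traits.
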