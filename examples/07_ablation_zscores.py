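"""Ablation statistics: pooled Z-score normalization and top-tier testing.

Mimics comparing model configurations across tasks with different metrics:
scores are pooled per task over all configurations and seeds (regression
scores Fisher-transformed first), standardized, averaged into per-config Zs,
and each configuration is tested against the reference with a one-sided
Welch t-test (p > 0.05 -> statistically in the top tier).
"""

import numpy as np

from rnaclr import ProbeResult, zscore_normalize
from rnaclr.probing import top_tier_flags

rng = np.random.default_rng(0)
configs = {"full_model": 0.70, "no_orthology": 0.64, "masking_only": 0.52}
results = []
for task, kind in (("halflife_like", "regression"), ("class_like", "classification")):
    for cfg, base in configs.items():
        scores = np.clip(base + 0.02 * rng.normal(size=10), 0.01, 0.95)
        results.append(ProbeResult(task, cfg, kind, list(scores)))

table = zscore_normalize(results)
flags = top_tier_flags(results, "full_model")

print(f"{'configuration':<14} {'aggregate Z':>11}   top tier per task")
for cfg in configs:
    tiers = ", ".join(
        f"{t}={'yes' if flags[(cfg, t)] else 'no'}" for t in ("halflife_like", "class_like")
    )
    print(f"{cfg:<14} {table.aggregate[cfg]:>11.3f}   {tiers}")
print("\nAn aggregate Z of +1 means the configuration sits one pooled standard")
print("deviation above the mean of all configurations, averaged over tasks.")
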