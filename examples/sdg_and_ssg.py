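"""Beyond markers: subtype-downregulated genes and subtype signatures.

A subtype-downregulated gene (SDG) is silent in exactly one subtype and
expressed in all others — the complement of a marker.  A subtype signature
gene (SSG) is scored for one chosen subtype by the per-subtype cosine
without requiring cross-subtype uniqueness.
"""

import numpy as np

import cosmarker as cm

patterns = np.array(
    [
        [0.0, 8.0, 8.0],   # ideal SDG of subtype 1
        [9.0, 0.0, 0.0],   # ideal marker of subtype 1
        [5.0, 5.0, 5.0],   # housekeeping-like
        [1.0, 7.0, 6.5],   # near-SDG of subtype 1
    ]
)
names = ["ideal_sdg", "ideal_mg", "flat", "near_sdg"]

print("feature      MG statistic       SDG statistic")
for name, s in zip(names, patterns):
    k_mg, t_mg = cm.cot_score(s)
    k_sdg, t_sdg = cm.sdg_score(s)
    print(f"{name:12s} k={k_mg + 1} t={t_mg:.4f}      k={k_sdg + 1} t={t_sdg:.4f}")
print()
print("SSG scores for subtype 2 (per-subtype cosine, no uniqueness required):")
for name, s in zip(names, patterns):
    print(f"  {name:12s} {cm.cot_score_for_subtype(s, 1):.4f}")
# The SDG statistic is 1 exactly when a feature is constant off one subtype
# and zero there; the MG statistic is 1 exactly on scaled unit vectors.
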