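"""Marker-guided deconvolution: why good markers matter.

For an ideal marker row of subtype k, the bulk mixture value is
proportional to subtype k's mixing proportion alone, which makes the
proportions identifiable by non-negative least squares restricted to
marker rows.  This script mixes three synthetic pure profiles into 100
noisy bulk samples and compares deconvolution accuracy using an ideal
marker set versus a non-specific ("corrupted") candidate set.
"""

import numpy as np

import cosmarker as cm

rng = np.random.default_rng(0)
k, n_ideal = 3, 5
ideal = np.zeros((n_ideal * k, k))
for j in range(k):
    ideal[j * n_ideal : (j + 1) * n_ideal, j] = rng.uniform(5, 50, n_ideal)
other = rng.uniform(0.5, 20, size=(60, k))
pure = np.vstack([ideal, other])

experiment = cm.make_mixtures(pure, n_bulk=100, noise_cv=0.05, seed=1)
table = cm.compare_mg_sets(
    experiment,
    {
        "ideal_markers": np.arange(n_ideal * k),
        "corrupted_markers": np.arange(len(pure) - 15, len(pure)),
    },
)
print(table.round(4).to_string(index=False))
# rmse: root-mean-square error between true and estimated mixing
# proportions; samplewise_correlation: mean Pearson r per bulk sample.
# Ideal markers give near-exact recovery; non-specific rows do not.
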