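"""Fuzzy data augmentation on a small attribute table.

Fuzzy C-means assigns each record fractional cluster memberships; the
alpha-cut keeps records whose membership in their own cluster is at least
alpha, and their cluster-center rows are appended as augmented records.
"""

import numpy as np

from gazetune import alpha_cut_filter, augment_table, fcm_fit

rng = np.random.default_rng(0)
X = np.vstack([rng.normal(c, 1.5, size=(40, 2))
               for c in ([0, 0], [5, 0], [0, 5])])  # overlapping clusters
labels = np.repeat([0, 1, 2], 40)

partition = fcm_fit(X, c=3, m=2.0, seed=0)
print("membership columns sum to 1:",
      bool(np.allclose(partition.U.sum(axis=0), 1.0)))

for alpha in (0.25, 0.5, 0.9):
    retained = alpha_cut_filter(partition, alpha)
    print(f"alpha = {alpha:.2f}: {len(retained):3d} of {len(X)} records retained")

aug = augment_table(X, partition, alpha=0.5, labels=labels)
print(f"augmented dataset: {aug.report()}")
# ratio = retained / original rows; each augmented row is a cluster center
# labeled by the majority class of its cluster.
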