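"""Descriptor cleaning and normalization.

Molecular-descriptor tables arrive with dead columns (all-zero) and
near-constant columns that carry no signal; the canonical pipeline drops
both and min-max normalizes the survivors to [0, 1].
"""

import numpy as np
import pandas as pd

from dockselect import (
    FeatureTable,
    apply_minmax,
    combine_feature_sets,
    drop_near_constant,
    drop_zero_features,
    fit_minmax,
)

rng = np.random.default_rng(0)
m = 100
frame = pd.DataFrame(
    {
        "NumRotatableBonds": rng.integers(0, 12, m).astype(float),
        "BalabanJ": rng.uniform(1.0, 4.0, m),
        "dead_descriptor": np.zeros(m),          # zero for every ligand
        "near_constant": np.r_[np.full(m - 1, 7.0), 8.0],  # 99% one value
    },
    index=[f"lig{i}" for i in range(m)],
)
table = FeatureTable.from_frame(frame, kind="md")
print(f"raw table: {table.n_features} descriptors")

table = drop_zero_features(table)
table = drop_near_constant(table, dominance=0.99)
print(f"after zero + near-constant filters: {table.n_features} -> {table.feature_names}")

params = fit_minmax(table)
normalized = apply_minmax(table, params)
print("\nnormalized ranges (min, max per descriptor):")
print(normalized.to_frame().agg(["min", "max"]).round(3))

# fingerprints stay binary and combine with descriptors into a mixed table
bits = (rng.random((m, 8)) < 0.3).astype(float)
fingerprints = FeatureTable(
    values=bits,
    row_ids=normalized.row_ids,
    feature_names=tuple(f"fp{b}" for b in range(8)),
    kind="sf",
)
combined = combine_feature_sets(normalized, fingerprints)
print(f"\ncombined table: {combined.n_features} features, kind={combined.kind!r}")
# In the canonical setup the fingerprint block is 881 bits wide.
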