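"""Tenfold cross-validated evaluation against SBS/VBS/random baselines.

Each held-out instance gets one selected algorithm; its achieved energy is
ranked jointly with the n standalone energies (n+1 entries, average ties).
The virtual best solver (per-instance oracle) bounds the selector from
below; beating the single best solver is the point of per-instance
selection.
"""

from dockselect import (
    SelectorConfig,
    SyntheticConfig,
    compare_feature_sets,
    end_to_end_recovery,
    kfold_split,
)

config = SyntheticConfig(
    n_instances=150, n_algorithms=10, n_clusters=4, n_runs=10,
    run_noise_sd=0.5, cluster_gap=2.0, seed=3,
)
selector_config = SelectorConfig(k=5, n_trees=100, seed=3)
result = end_to_end_recovery(config, selector_config, n_folds=10)

print(f"selection accuracy vs planted winners: {result.selection_accuracy:.3f}")
print("\nmean joint rank (1 best, over 11 entries):")
summary = result.report.summary
for method in ["selector", "sbs", "vbs", "random"]:
    row = summary.loc[method]
    print(f"  {method:<9} {row.mean_rank:5.2f} +- {row.sd_rank:.2f}")
print("\nbest three standalone algorithms:")
standalone = summary.drop(index=["selector", "sbs", "vbs", "random"])
print(standalone.nsmallest(3, "mean_rank").round(2))

# feature-set comparison with shared folds: informative descriptors vs
# fingerprints (both encode the planted clusters here)
folds = kfold_split(result.perf.row_ids, n_folds=10, seed=3)
table = compare_feature_sets(
    result.perf,
    {
        "descriptors": result.benchmark.descriptor_features,
        "fingerprints": result.benchmark.fingerprint_features,
    },
    selector_config,
    folds,
)
print("\nselector mean rank per feature set:")
print(table.round(2))
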