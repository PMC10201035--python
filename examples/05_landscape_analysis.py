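"""Landscape analyses: algorithm similarity, portfolio reduction, instance space.

Hierarchical clustering on the SVD latent factors shows which LGA
configurations behave interchangeably (candidates for pruning); PCA/t-SNE
embeddings and a silhouette-scanned k-means describe the instance space.
"""

import numpy as np

from dockselect import (
    SyntheticConfig,
    aggregate_runs,
    cluster_algorithms,
    cluster_instances,
    cluster_profiles,
    embed_instances,
    factorize,
    generate_benchmark,
    rank_transform,
    reduce_portfolio,
    summarize_mean_ranks,
)

config = SyntheticConfig(
    n_instances=160, n_algorithms=10, n_clusters=4, n_runs=8,
    run_noise_sd=0.3, cluster_gap=2.0, seed=5,
)
bench = generate_benchmark(config)
perf = aggregate_runs(
    bench.run_records, "AVG", row_order=bench.instance_ids, col_order=bench.algorithm_ids
)
ranks = rank_transform(perf)
latent = factorize(ranks, k=5)

link = cluster_algorithms(latent)
print("algorithm merge tree (first merges = most similar configurations):")
print(link.merge_list().head(4).round(3))

mean_ranks = summarize_mean_ranks(ranks)["mean_rank"]
reduced = reduce_portfolio(link, mean_ranks, level="lowest_pairs")
print(f"\nreduced portfolio ({len(reduced)} of {len(link.algorithm_ids)}): {reduced}")

pca = embed_instances(bench.descriptor_features, method="pca")
tsne = embed_instances(bench.descriptor_features, method="tsne", seed=5)
print(f"\nPCA coords shape {pca.coords.shape}; t-SNE params {tsne.params}")

report = cluster_instances(bench.descriptor_features, k_range=(2, 15), seed=5)
print(f"silhouette-selected k = {report.best_k} "
      f"(planted clusters: {config.n_clusters})")
print(report.silhouettes.round(3).head(5))

profiles = cluster_profiles(bench.descriptor_features, report.labels)
one = profiles[profiles["feature"] == "desc_inf1"]
print("\nper-cluster distribution of one informative feature:")
print(one[["cluster", "median", "q1", "q3", "n_outliers"]].round(3).to_string(index=False))
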