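"""Post-hoc landscape analyses: importance, algorithm similarity, instance space.

These operations interrogate a fitted selector and its latent factors:

* Gini feature importance of the forest (which descriptors drive selection),
* hierarchical clustering of algorithms on their SVD latent factors (which
  LGA configurations behave alike, hence which are redundant),
* portfolio reduction (keep one representative per similar cluster),
* 2-D instance embeddings (PCA / t-SNE) and k-means clustering of the
  instance space with silhouette-based model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.exceptions import NotFittedError
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

from .features import FeatureTable
from .selector import LatentModel, SelectorModel


def feature_importance(model: SelectorModel) -> pd.Series:
    """Gini (mean impurity-decrease) importances of the fitted forest.

    Importances are aggregated across trees (and across the k latent
    outputs), normalized to sum 1, and returned sorted descending.
    """
    try:
        if isinstance(model.regressor, list):
            for rf in model.regressor:
                check_is_fitted(rf)
            raw = np.mean([rf.feature_importances_ for rf in model.regressor], axis=0)
        else:
            check_is_fitted(model.regressor)
            raw = np.asarray(model.regressor.feature_importances_, dtype=float)
    except (NotFittedError, AttributeError) as exc:
        raise ValueError("feature_importance requires a fitted ensemble model") from exc
    total = raw.sum()
    gini = raw / total if total > 0 else np.full_like(raw, 1.0 / raw.size)
    series = pd.Series(gini, index=list(model.feature_names), name="gini")
    return series.sort_values(ascending=False, kind="stable")


@dataclass(frozen=True)
class AlgorithmLinkage:
    """Agglomerative merge tree over algorithms (scipy linkage encoding)."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    algorithm_ids: tuple[str, ...]
    metric: str = "euclidean"
    method: str = "average"

    @property
    def n(self) -> int:
        return len(self.algorithm_ids)

    def merge_list(self) -> pd.DataFrame:
        """The merge tree as (left, right, height, size) rows."""
        return pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        ).astype({"left": int, "right": int, "size": int})


def cluster_algorithms(
    latent: LatentModel, metric: str = "euclidean", method: str = "average"
) -> AlgorithmLinkage:
    """Hierarchically cluster algorithms on their latent-factor rows.

    Rows are weighted by the singular values (V diag(s)), so each latent
    axis counts in proportion to the rank variation it explains; directions
    with zero singular value — whose orthonormal factors are arbitrary —
    then contribute nothing, and identical rank columns coincide exactly.
    """
    n = latent.algorithm_factors.shape[0]
    if n < 2:
        raise ValueError("need at least 2 algorithms to cluster")
    weighted = latent.algorithm_factors * latent.singular_values
    merges = scipy_linkage(weighted, method=method, metric=metric)
    return AlgorithmLinkage(
        merges=merges, algorithm_ids=latent.col_ids, metric=metric, method=method
    )


def _linkage_clusters(link: AlgorithmLinkage, level: str) -> list[list[int]]:
    n = link.n
    Z = link.merges
    left = Z[:, 0].astype(int)
    right = Z[:, 1].astype(int)
    # pair nodes: merges of two leaves — the "highly similar" groups at the
    # lowest dendrogram level
    pair_rows = [r for r in range(n - 1) if left[r] < n and right[r] < n]
    if level == "lowest_pairs":
        unit_rows = set(pair_rows)
    elif level == "one_higher":
        # additionally absorb merges whose children are each a leaf or a
        # pair node, growing clusters one dendrogram level beyond the pairs
        pair_nodes = {r + n for r in pair_rows}
        unit_rows = set(pair_rows)
        for r in range(n - 1):
            if r in unit_rows:
                continue
            ok_child = lambda c: c < n or c in pair_nodes
            if ok_child(left[r]) and ok_child(right[r]):
                unit_rows.add(r)
    else:
        raise ValueError(f"unknown reduction level {level!r}")

    # resolve each kept merge row to its leaf set; drop rows subsumed by a
    # kept ancestor row
    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        r = node - n
        return leaves(left[r]) + leaves(right[r])

    kept = []
    subsumed: set[int] = set()
    for r in sorted(unit_rows, key=lambda r: -Z[r, 2]):
        members = leaves(r + n)
        if any(x in subsumed for x in members):
            continue
        subsumed.update(members)
        kept.append(sorted(members))
    singletons = [[i] for i in range(n) if i not in subsumed]
    return sorted(kept + singletons)


def reduce_portfolio(
    link: AlgorithmLinkage,
    mean_ranks: pd.Series | dict[str, float],
    level: str = "lowest_pairs",
) -> list[str]:
    """Keep one representative per similar-algorithm cluster.

    ``level="lowest_pairs"`` cuts at the leaf-leaf merges (the mutually
    most-similar pairs); ``"one_higher"`` additionally merges one dendrogram
    level above them.  The representative of each cluster is the member with
    the lowest training mean rank, ties resolved by portfolio order.
    """
    ranks = dict(mean_ranks.items() if hasattr(mean_ranks, "items") else mean_ranks)
    missing = [a for a in link.algorithm_ids if a not in ranks]
    if missing:
        raise ValueError(f"mean_ranks missing algorithms: {missing[:5]}")
    reps = []
    for cluster in _linkage_clusters(link, level):
        best = min(cluster, key=lambda i: (ranks[link.algorithm_ids[i]], i))
        reps.append(best)
    return [link.algorithm_ids[i] for i in sorted(reps)]


@dataclass(frozen=True)
class InstanceEmbedding:
    """2-D instance coordinates from PCA or t-SNE."""

    coords: np.ndarray  # m x 2
    row_ids: tuple[str, ...]
    method: str
    source: str = ""
    params: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=list(self.row_ids), columns=["dim1", "dim2"])


def embed_instances(
    features: FeatureTable, method: str = "pca", seed: int = 0, source: str = ""
) -> InstanceEmbedding:
    """Project instances into 2-D with PCA (deterministic) or seeded t-SNE."""
    if features.n_features < 2:
        raise ValueError("need at least 2 features to embed into 2-D")
    X = features.values
    if method == "pca":
        coords = PCA(n_components=2, random_state=0).fit_transform(X)
        params: dict = {}
    elif method == "tsne":
        perplexity = min(30.0, max(2.0, (len(features.row_ids) - 1) / 3.0))
        tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
        coords = np.asarray(tsne.fit_transform(X), dtype=float)
        params = {"perplexity": perplexity, "init": "pca"}
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    if not np.isfinite(coords).all():
        raise ValueError("embedding produced non-finite coordinates")
    return InstanceEmbedding(
        coords=coords, row_ids=features.row_ids, method=method, source=source, params=params
    )


@dataclass(frozen=True)
class ClusteringReport:
    """Silhouette scan over candidate k values and the winning partition."""

    silhouettes: pd.Series  # index k, value mean silhouette coefficient
    best_k: int
    labels: np.ndarray  # labels for best_k, one per instance
    row_ids: tuple[str, ...]


def cluster_instances(
    features: FeatureTable,
    k_range: tuple[int, int] = (2, 15),
    seed: int = 0,
) -> ClusteringReport:
    """k-means over k in ``k_range`` with silhouette-based selection of k."""
    k_lo, k_hi = k_range
    m = len(features.row_ids)
    if m <= k_hi:
        raise ValueError(f"need more than {k_hi} instances, got {m}")
    X = features.values
    sils = {}
    labels_by_k = {}
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(X)
        labels_by_k[k] = labels
        sils[k] = float(silhouette_score(X, labels)) if len(set(labels)) > 1 else -1.0
    silhouettes = pd.Series(sils, name="silhouette")
    silhouettes.index.name = "k"
    best_k = int(silhouettes.idxmax())
    return ClusteringReport(
        silhouettes=silhouettes,
        best_k=best_k,
        labels=labels_by_k[best_k],
        row_ids=features.row_ids,
    )


def cluster_profiles(features: FeatureTable, labels: np.ndarray) -> pd.DataFrame:
    """Boxplot backbone: five-number summaries per (cluster, feature).

    Whiskers extend to the most extreme data point within 1.5 IQR of the
    quartiles; points beyond are counted as outliers.
    """
    labels = np.asarray(labels)
    if labels.shape != (len(features.row_ids),):
        raise ValueError("labels must cover every instance exactly once")
    rows = []
    for cluster in np.unique(labels):
        sub = features.values[labels == cluster]
        for j, name in enumerate(features.feature_names):
            col = np.sort(sub[:, j])
            q1, med, q3 = np.percentile(col, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = col[(col >= lo_fence) & (col <= hi_fence)]
            rows.append(
                {
                    "cluster": cluster,
                    "feature": name,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_low": inside.min() if inside.size else np.nan,
                    "whisker_high": inside.max() if inside.size else np.nan,
                    "n_outliers": int(col.size - inside.size),
                    "n": int(col.size),
                }
            )
    return pd.DataFrame(rows)
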