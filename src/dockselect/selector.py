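"""The rank-prediction selector: SVD latent factors + feature regression.

The selector treats algorithm selection as collaborative filtering:
instances are users, algorithms are items, and the row-wise rank matrix is
the rating table.  A truncated SVD of the (uncentered) rank matrix R ~
U_k S_k V_k' yields instance latent factors X = U_k S_k and algorithm
latent factors V = V_k.  A random-forest regressor is then trained to map
hand-crafted instance features to X, so that for an unseen instance with
feature vector x the predicted rank row is f(x) V'; the selected algorithm
is the argmin of that row (lower predicted rank = better).

The singular-value scale is folded into the instance factors (U S), leaving
the algorithm factors orthonormal; regression targets then carry the
magnitude information and rank prediction is a plain inner product.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .features import FeatureTable
from .performance import RankMatrix


@dataclass(frozen=True)
class SelectorConfig:
    """Hyperparameters of the selector.

    ``k`` is the truncation rank of the SVD (default 5) and ``n_trees`` the
    forest size (default 100, the scikit-learn default).  With
    ``per_output=True`` one forest is fitted per latent dimension instead of
    a single multi-output forest.  All randomness flows from ``seed``.
    """

    k: int = 5
    n_trees: int = 100
    seed: int = 0
    per_output: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")


@dataclass(frozen=True)
class LatentModel:
    """Truncated-SVD factors of a rank matrix."""

    instance_factors: np.ndarray  # m x k, U_k S_k
    algorithm_factors: np.ndarray  # n x k, V_k (orthonormal columns)
    singular_values: np.ndarray  # k, non-increasing
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    source_mode: str = "AVG"

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=float)
        if (s < 0).any() or (np.diff(s) > 1e-9).any():
            raise ValueError("singular values must be non-negative and non-increasing")

    @property
    def k(self) -> int:
        return self.singular_values.size

    def reconstruct(self) -> np.ndarray:
        """Rank-k approximation of the factorized rank matrix."""
        return self.instance_factors @ self.algorithm_factors.T


def factorize(ranks: RankMatrix, k: int, source_mode: str = "AVG") -> LatentModel:
    """Truncated SVD of the uncentered rank matrix.

    No centering is applied: rank rows share the common mean (n+1)/2, which
    the leading singular component absorbs.
    """
    m, n = ranks.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k must be in [1, {min(m, n)}], got {k}")
    u, s, vt = np.linalg.svd(ranks.ranks, full_matrices=False)
    return LatentModel(
        instance_factors=u[:, :k] * s[:k],
        algorithm_factors=vt[:k].T.copy(),
        singular_values=s[:k].copy(),
        row_ids=ranks.row_ids,
        col_ids=ranks.col_ids,
        source_mode=source_mode,
    )


@dataclass
class SelectorModel:
    """A fitted selector: feature-to-latent regressor plus algorithm factors.

    ``regressor`` is any object with ``predict(X) -> (n_samples, k)``; the
    canonical fit uses a :class:`RandomForestRegressor` (or a list of them
    in per-output mode).  ``train_mean_ranks`` (per-algorithm mean rank on
    the training instances) is the tie-break key for selection.
    """

    regressor: object
    algorithm_factors: np.ndarray
    feature_names: tuple[str, ...]
    algorithm_ids: tuple[str, ...]
    train_mean_ranks: np.ndarray
    config: SelectorConfig

    @property
    def n_algorithms(self) -> int:
        return len(self.algorithm_ids)

    def _predict_latent(self, X: np.ndarray) -> np.ndarray:
        if isinstance(self.regressor, list):
            cols = [r.predict(X) for r in self.regressor]
            return np.column_stack(cols)
        out = np.asarray(self.regressor.predict(X))
        if out.ndim == 1:
            out = out[:, None]
        return out


def fit_selector(
    features: FeatureTable, ranks: RankMatrix, config: SelectorConfig
) -> SelectorModel:
    """Fit the selector on aligned feature and rank matrices.

    Features are expected normalized upstream.  The forest maps each
    instance's feature row to its k instance latent factors.
    """
    if features.row_ids != ranks.row_ids:
        raise ValueError("features and ranks are not aligned on the same instances")
    m, n = ranks.shape
    if config.k > min(m, n):
        raise ValueError(f"k={config.k} exceeds min(m, n)={min(m, n)}")
    latent = factorize(ranks, config.k)
    X, Y = features.values, latent.instance_factors
    if config.per_output:
        regressor: object = []
        for j in range(config.k):
            rf = RandomForestRegressor(
                n_estimators=config.n_trees, random_state=config.seed + j
            )
            rf.fit(X, Y[:, j])
            regressor.append(rf)
    else:
        regressor = RandomForestRegressor(
            n_estimators=config.n_trees, random_state=config.seed
        )
        regressor.fit(X, Y)
    return SelectorModel(
        regressor=regressor,
        algorithm_factors=latent.algorithm_factors,
        feature_names=features.feature_names,
        algorithm_ids=ranks.col_ids,
        train_mean_ranks=ranks.ranks.mean(axis=0),
        config=config,
    )


def _check_vector(model: SelectorModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != len(model.feature_names):
        raise ValueError(
            f"feature vector has length {x.size}, model expects {len(model.feature_names)}"
        )
    return x


def predict_ranks(model: SelectorModel, x: np.ndarray) -> np.ndarray:
    """Predicted rank scores for one instance; lower = predicted better."""
    x = _check_vector(model, x)
    return model._predict_latent(x[None, :])[0] @ model.algorithm_factors.T


def predict_ranks_matrix(model: SelectorModel, features: FeatureTable) -> np.ndarray:
    """Predicted rank-score rows for a whole feature table (m x n)."""
    if features.feature_names != model.feature_names:
        raise ValueError("feature table columns do not match the fitted model")
    return model._predict_latent(features.values) @ model.algorithm_factors.T


def _argmin_with_tiebreak(model: SelectorModel, scores: np.ndarray) -> int:
    # primary: score; tie: lower training mean rank; then portfolio order
    order = np.lexsort(
        (np.arange(scores.size), model.train_mean_ranks, scores)
    )
    return int(order[0])


def select_algorithm(model: SelectorModel, x: np.ndarray) -> str:
    """The selected algorithm id: argmin of predicted rank scores."""
    scores = predict_ranks(model, x)
    return model.algorithm_ids[_argmin_with_tiebreak(model, scores)]


def select_algorithms(model: SelectorModel, features: FeatureTable) -> list[str]:
    """Batch selection: one algorithm id per feature-table row."""
    scores = predict_ranks_matrix(model, features)
    return [model.algorithm_ids[_argmin_with_tiebreak(model, row)] for row in scores]


def save_model(model: SelectorModel, path: str | Path) -> None:
    """Serialize a fitted selector to a single archive file."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> SelectorModel:
    """Load a selector archive; predictions reproduce the saved model's."""
    model = joblib.load(path)
    if not isinstance(model, SelectorModel):
        raise TypeError(f"{path} does not contain a SelectorModel")
    return model
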