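"""Instance feature tables: cleaning, min-max normalization, subsetting.

Two feature families characterize a docking instance (a ligand, for a fixed
receptor): continuous molecular descriptors (``md``; e.g. rotatable-bond
count, Balaban J, Kappa shape indices) and binary substructure fingerprints
(``sf``; the canonical PubChem fingerprint is 881 bits).  Preprocessing
follows a fixed order: drop all-zero descriptors, drop near-constant
descriptors, then min-max normalize each surviving feature to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FEATURE_KINDS = ("md", "sf", "mixed")
CANONICAL_FINGERPRINT_LENGTH = 881


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min and max fitted on a (training) table."""

    feature_names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        mins = np.asarray(self.mins, dtype=float)
        maxs = np.asarray(self.maxs, dtype=float)
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if not (len(self.feature_names) == mins.size == maxs.size):
            raise ValueError("feature_names, mins and maxs must have equal length")
        if (maxs < mins).any():
            raise ValueError("max < min for some feature")


@dataclass(frozen=True)
class FeatureTable:
    """m x d instance-by-feature matrix with named rows and columns."""

    values: np.ndarray
    row_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    kind: str = "md"
    normalization: NormalizationParams | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", tuple(str(r) for r in self.row_ids))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        if values.ndim != 2 or values.shape != (len(self.row_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.feature_names)} features"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate instance ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}, got {self.kind!r}")
        if self.kind == "sf" and self.normalization is None:
            if values.size and not np.isin(values, (0.0, 1.0)).all():
                raise ValueError("substructure-fingerprint tables must be binary (0/1)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_ids), columns=list(self.feature_names)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str = "md") -> "FeatureTable":
        return cls(
            values=frame.to_numpy(dtype=float),
            row_ids=tuple(str(i) for i in frame.index),
            feature_names=tuple(str(c) for c in frame.columns),
            kind=kind,
        )

    def subset_rows(self, ids: Sequence[str]) -> "FeatureTable":
        pos = {r: i for i, r in enumerate(self.row_ids)}
        try:
            idx = np.array([pos[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown instance id {exc.args[0]!r}") from None
        return replace(self, values=self.values[idx], row_ids=tuple(ids))

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        pos = {f: j for j, f in enumerate(self.feature_names)}
        try:
            idx = np.array([pos[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown feature {exc.args[0]!r}") from None
        if idx.size == 0:
            return replace(
                self, values=self.values[:, :0], feature_names=(), normalization=None
            )
        return replace(
            self, values=self.values[:, idx], feature_names=tuple(names), normalization=None
        )


def is_canonical_fingerprint(t: FeatureTable) -> bool:
    """True when ``t`` is a binary sf table of the canonical 881-bit width."""
    return (
        t.kind == "sf"
        and t.n_features == CANONICAL_FINGERPRINT_LENGTH
        and bool(np.isin(t.values, (0.0, 1.0)).all())
    )


def drop_zero_features(t: FeatureTable) -> FeatureTable:
    """Remove every feature that is exactly 0 for all instances."""
    keep = (t.values != 0).any(axis=0)
    if not keep.any():
        log.info("drop_zero_features: all %d features dropped", t.n_features)
    names = tuple(f for f, k in zip(t.feature_names, keep) if k)
    return replace(t, values=t.values[:, keep], feature_names=names, normalization=None)


def near_constant_features(t: FeatureTable, dominance: float = 0.99) -> list[str]:
    """Names of features whose most frequent value covers >= dominance of rows."""
    if not 0.5 < dominance <= 1.0:
        raise ValueError(f"dominance must be in (0.5, 1], got {dominance}")
    m = len(t.row_ids)
    dropped = []
    for j, name in enumerate(t.feature_names):
        _, counts = np.unique(t.values[:, j], return_counts=True)
        if counts.max() >= dominance * m:
            dropped.append(name)
    return dropped


def drop_near_constant(t: FeatureTable, dominance: float = 0.99) -> FeatureTable:
    """Remove features dominated by a single value in >= ``dominance`` of rows."""
    dropped = set(near_constant_features(t, dominance))
    if dropped:
        log.info("drop_near_constant: dropping %s", sorted(dropped))
    names = tuple(f for f in t.feature_names if f not in dropped)
    return t.subset_features(names)


def fit_minmax(t: FeatureTable) -> NormalizationParams:
    """Fit per-feature min and max on ``t`` (typically the training rows)."""
    return NormalizationParams(
        feature_names=t.feature_names,
        mins=t.values.min(axis=0) if len(t.row_ids) else np.zeros(t.n_features),
        maxs=t.values.max(axis=0) if len(t.row_ids) else np.zeros(t.n_features),
    )


def apply_minmax(t: FeatureTable, p: NormalizationParams) -> FeatureTable:
    """Map each feature through x -> (x - min) / (max - min).

    Constant features (max == min) map to 0.  Values from a table other
    than the one ``p`` was fitted on may fall outside [0, 1]; they are not
    clipped.
    """
    pos = {f: j for j, f in enumerate(p.feature_names)}
    for name in t.feature_names:
        if name not in pos:
            raise ValueError(f"normalization parameters missing feature {name!r}")
    idx = np.array([pos[name] for name in t.feature_names], dtype=int)
    mins = p.mins[idx]
    span = p.maxs[idx] - mins
    out = np.zeros_like(t.values)
    nonconst = span > 0
    out[:, nonconst] = (t.values[:, nonconst] - mins[nonconst]) / span[nonconst]
    return replace(t, values=out, normalization=p)


def select_top_features(
    t: FeatureTable,
    importances: Mapping[str, float] | pd.Series,
    *,
    cutoff: float | None = None,
    top_n: int | None = None,
) -> FeatureTable:
    """Subset features by an importance score (e.g. Gini importance).

    Exactly one of ``cutoff`` (keep scores >= cutoff) or ``top_n`` (keep the
    n largest, ties broken by name order) must be given.  Survivors keep the
    table's original column order.
    """
    if (cutoff is None) == (top_n is None):
        raise ValueError("exactly one of cutoff or top_n must be given")
    scores = dict(importances.items() if hasattr(importances, "items") else importances)
    missing = [f for f in t.feature_names if f not in scores]
    if missing:
        raise ValueError(f"importances missing features: {missing[:5]}")
    if cutoff is not None:
        keep = {f for f in t.feature_names if scores[f] >= cutoff}
    else:
        if top_n > t.n_features:
            raise ValueError(f"top_n={top_n} exceeds feature count {t.n_features}")
        ordered = sorted(t.feature_names, key=lambda f: (-scores[f], f))
        keep = set(ordered[:top_n])
    return t.subset_features([f for f in t.feature_names if f in keep])


def combine_feature_sets(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Horizontally concatenate two aligned feature tables.

    Rows must be identical and in identical order.  Colliding feature names
    are prefixed by their table's kind.  An empty ``b`` returns ``a``
    unchanged; otherwise the result has ``kind="mixed"``.
    """
    if a.row_ids != b.row_ids:
        raise ValueError("feature tables are not aligned on the same instances")
    if b.n_features == 0:
        return a
    if a.n_features == 0:
        return b
    collisions = set(a.feature_names) & set(b.feature_names)
    a_names = tuple(f"{a.kind}_{f}" if f in collisions else f for f in a.feature_names)
    b_names = tuple(f"{b.kind}_{f}" if f in collisions else f for f in b.feature_names)
    return FeatureTable(
        values=np.hstack([a.values, b.values]),
        row_ids=a.row_ids,
        feature_names=a_names + b_names,
        kind="mixed",
    )


def preprocess_descriptors(
    t: FeatureTable, dominance: float = 0.99, normalize: bool = True
) -> FeatureTable:
    """Canonical descriptor pipeline: zero filter, near-constant filter, min-max."""
    t = drop_near_constant(drop_zero_features(t), dominance)
    if normalize:
        t = apply_minmax(t, fit_minmax(t))
    return t
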