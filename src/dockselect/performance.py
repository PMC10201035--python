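"""Docking-run aggregation, performance matrices and rank transforms.

A docking campaign produces many repeated runs per (ligand instance,
algorithm) pair because the LGA is stochastic.  Runs are aggregated into a
complete instance x algorithm performance matrix of binding energies
(kcal/mol, lower is better), either as the per-pair mean (``AVG``) or the
per-pair minimum (``BEST``; the best pose found in any run).  The selector
consumes row-wise ranks of that matrix: rank 1 is the best algorithm on an
instance, ties receive the average of the ranks they span, so every row of
an n-column rank matrix sums to n(n+1)/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

AGGREGATION_MODES = ("AVG", "BEST", "MEDIAN")


@dataclass(frozen=True)
class RunRecord:
    """One docking run outcome: a final estimated free energy of binding."""

    instance_id: str
    algorithm_id: str
    run_index: int
    binding_energy: float

    def __post_init__(self) -> None:
        if self.run_index < 1:
            raise ValueError(f"run_index must be >= 1, got {self.run_index}")
        if not math.isfinite(self.binding_energy):
            raise ValueError(
                f"binding_energy must be finite, got {self.binding_energy!r} "
                f"for ({self.instance_id}, {self.algorithm_id}, run {self.run_index})"
            )


def _check_ids(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what}")
    return ids


@dataclass(frozen=True)
class PerformanceMatrix:
    """Complete m x n matrix of aggregated binding energies (kcal/mol)."""

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    mode: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", _check_ids(self.row_ids, "instance ids"))
        object.__setattr__(self, "col_ids", _check_ids(self.col_ids, "algorithm ids"))
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        if values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {values.shape} does not match {len(self.row_ids)} instances "
                f"x {len(self.col_ids)} algorithms"
            )
        if not np.isfinite(values).all():
            bad = int(np.size(values) - np.isfinite(values).sum())
            raise ValueError(f"performance matrix contains {bad} non-finite cells")
        if self.mode not in AGGREGATION_MODES:
            raise ValueError(f"mode must be one of {AGGREGATION_MODES}, got {self.mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids), columns=list(self.col_ids))

    def row_indexer(self, ids: Iterable[str]) -> np.ndarray:
        pos = {r: i for i, r in enumerate(self.row_ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown instance id {exc.args[0]!r}") from None

    def subset_rows(self, ids: Sequence[str]) -> "PerformanceMatrix":
        idx = self.row_indexer(ids)
        return replace(self, values=self.values[idx], row_ids=tuple(ids))


@dataclass(frozen=True)
class RankMatrix:
    """Row-wise ranks of a performance matrix; rank 1 = best, average ties."""

    ranks: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    tie_policy: str = "average"

    def __post_init__(self) -> None:
        ranks = np.asarray(self.ranks, dtype=float)
        object.__setattr__(self, "ranks", ranks)
        object.__setattr__(self, "row_ids", _check_ids(self.row_ids, "instance ids"))
        object.__setattr__(self, "col_ids", _check_ids(self.col_ids, "algorithm ids"))
        if ranks.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("rank matrix shape does not match its ids")
        n = len(self.col_ids)
        if ranks.size and (ranks.min() < 1 or ranks.max() > n):
            raise ValueError(f"ranks must lie in [1, {n}]")
        if self.tie_policy != "average":
            raise ValueError("only the average-rank tie policy is supported")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ranks.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranks, index=list(self.row_ids), columns=list(self.col_ids))

    def subset_rows(self, ids: Sequence[str]) -> "RankMatrix":
        pos = {r: i for i, r in enumerate(self.row_ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return replace(self, ranks=self.ranks[idx], row_ids=tuple(ids))


def aggregate_runs(
    records: Iterable[RunRecord],
    mode: str = "AVG",
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> PerformanceMatrix:
    """Aggregate repeated docking runs into a complete performance matrix.

    ``AVG`` takes the arithmetic mean of each pair's run energies, ``BEST``
    the minimum (best pose over runs), ``MEDIAN`` the median.  Rows and
    columns follow first appearance in ``records`` unless explicit orderings
    are supplied.  The full instance x algorithm grid must be covered; any
    missing (instance, algorithm) pair is an error.
    """
    mode = mode.upper()
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"mode must be one of {AGGREGATION_MODES}, got {mode!r}")

    energies: dict[tuple[str, str], list[float]] = {}
    seen_runs: set[tuple[str, str, int]] = set()
    row_seen: dict[str, None] = {}
    col_seen: dict[str, None] = {}
    for rec in records:
        key = (rec.instance_id, rec.algorithm_id, rec.run_index)
        if key in seen_runs:
            raise ValueError(f"duplicate run record {key}")
        seen_runs.add(key)
        energies.setdefault((rec.instance_id, rec.algorithm_id), []).append(rec.binding_energy)
        row_seen.setdefault(rec.instance_id)
        col_seen.setdefault(rec.algorithm_id)
    if not energies:
        raise ValueError("no run records supplied")

    rows = tuple(row_order) if row_order is not None else tuple(row_seen)
    cols = tuple(col_order) if col_order is not None else tuple(col_seen)
    missing = [(r, c) for r in rows for c in cols if (r, c) not in energies]
    if missing:
        raise ValueError(
            f"{len(missing)} (instance, algorithm) pairs have no runs: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )

    agg = {"AVG": np.mean, "BEST": np.min, "MEDIAN": np.median}[mode]
    values = np.array([[agg(energies[(r, c)]) for c in cols] for r in rows], dtype=float)
    return PerformanceMatrix(values=values, row_ids=rows, col_ids=cols, mode=mode)


def rank_transform(perf: PerformanceMatrix) -> RankMatrix:
    """Rank algorithms within each instance row; rank 1 = lowest energy."""
    values = perf.values
    if not np.isfinite(values).all():
        raise ValueError("cannot rank a matrix with non-finite cells")
    ranks = rankdata(values, method="average", axis=1)
    return RankMatrix(ranks=ranks, row_ids=perf.row_ids, col_ids=perf.col_ids)


def summarize_mean_ranks(ranks: RankMatrix) -> pd.DataFrame:
    """Per-algorithm mean and population SD of ranks across instances.

    Returns a DataFrame indexed by algorithm id, in the matrix's column
    order, with columns ``mean_rank`` and ``sd_rank``.
    """
    if ranks.shape[0] < 1:
        raise ValueError("cannot summarize an empty rank matrix")
    mean = ranks.ranks.mean(axis=0)
    sd = ranks.ranks.std(axis=0, ddof=0)
    return pd.DataFrame(
        {"mean_rank": mean, "sd_rank": sd}, index=pd.Index(ranks.col_ids, name="algorithm")
    )
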