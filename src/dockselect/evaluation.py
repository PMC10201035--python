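"""Cross-validated evaluation of the selector against its portfolio.

The protocol mirrors a solver-portfolio study: tenfold cross-validation in
which the selector is fitted on nine folds (feature normalization fitted on
training rows only) and selects one algorithm per held-out instance.  The
achieved energy — the true aggregated energy of the chosen algorithm on
that instance — is then ranked *jointly* with the n standalone energies
(n+1 entries, average-rank ties; the selector always ties its chosen
algorithm).  Baselines on the same scale:

* SBS (single best solver): the algorithm with the best training mean rank,
  applied to every test instance;
* VBS (virtual best solver): the per-instance oracle argmin, a lower bound;
* random: a uniform pick, averaged over many seeded draws.

Standalone algorithms' reported ranks come from the selector's joint list,
so the report mirrors a table listing all n algorithms plus the selector on
one rank scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import FeatureTable, apply_minmax, fit_minmax
from .performance import PerformanceMatrix, rank_transform
from .selector import SelectorConfig, fit_selector, select_algorithms

META_METHODS = ("selector", "sbs", "vbs", "random")


@dataclass(frozen=True)
class FoldAssignment:
    """A seeded partition of instances into folds of near-equal size."""

    fold_of: dict[str, int]
    n_folds: int
    seed: int

    def test_ids(self, fold: int, order: Sequence[str]) -> list[str]:
        return [i for i in order if self.fold_of[i] == fold]

    def train_ids(self, fold: int, order: Sequence[str]) -> list[str]:
        return [i for i in order if self.fold_of[i] != fold]


@dataclass(frozen=True)
class EvaluationReport:
    """Per-method rank summary plus the selector's per-instance choices."""

    summary: pd.DataFrame  # index: method; columns: mean_rank, sd_rank
    selections: pd.DataFrame  # instance_id, fold, chosen_algorithm, achieved_energy
    mode: str
    n_entries: int  # entries per joint ranking


def kfold_split(
    instance_ids: Sequence[str], n_folds: int = 10, seed: int = 0
) -> FoldAssignment:
    """Seeded shuffle then contiguous partition into balanced folds (1-based)."""
    ids = list(instance_ids)
    m = len(ids)
    if n_folds > m:
        raise ValueError(f"n_folds={n_folds} exceeds instance count {m}")
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    fold_of: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(perm, n_folds), start=1):
        for idx in chunk:
            fold_of[ids[idx]] = fold
    return FoldAssignment(fold_of=fold_of, n_folds=n_folds, seed=seed)


def _joint_rank(energies: np.ndarray, extra: float) -> tuple[float, np.ndarray]:
    """Average-tie ranks of (standalone energies + one meta entry).

    Returns the meta entry's rank and the standalone ranks from the same
    (n+1)-entry list.
    """
    joint = rankdata(np.append(energies, extra), method="average")
    return float(joint[-1]), joint[:-1]


def rank_achieved(perf: PerformanceMatrix, achieved: np.ndarray) -> pd.Series:
    """Mean/SD joint rank of a method given its per-instance achieved energy."""
    achieved = np.asarray(achieved, dtype=float)
    if achieved.shape != (perf.shape[0],):
        raise ValueError("achieved energies must have one entry per instance")
    r = np.array([_joint_rank(perf.values[i], achieved[i])[0] for i in range(len(achieved))])
    return pd.Series({"mean_rank": r.mean(), "sd_rank": r.std(ddof=0)})


def _best_column(mean_ranks: np.ndarray) -> int:
    # lowest mean rank; ties resolved by portfolio (column) order
    return int(np.argmin(mean_ranks))


def evaluate_selector(
    perf: PerformanceMatrix,
    features: FeatureTable,
    config: SelectorConfig,
    folds: FoldAssignment,
    *,
    joint: bool = True,
    normalization: str = "per_fold",
    random_draws: int = 1000,
) -> EvaluationReport:
    """Tenfold-CV evaluation of the selector with SBS/VBS/random baselines.

    ``normalization`` is ``"per_fold"`` (min-max fitted on training rows,
    applied unclipped to test rows), ``"global"`` (fitted once on all rows,
    replicating a whole-data normalization) or ``"none"``.  With
    ``joint=False`` each method is instead scored by its chosen algorithm's
    rank among the n standalone energies only.
    """
    if set(folds.fold_of) != set(perf.row_ids):
        raise ValueError("fold assignment does not cover the performance matrix instances")
    if features.row_ids != perf.row_ids:
        raise ValueError("features and performance matrix are not aligned")
    if normalization not in ("per_fold", "global", "none"):
        raise ValueError(f"unknown normalization mode {normalization!r}")

    m, n = perf.shape
    row_pos = {r: i for i, r in enumerate(perf.row_ids)}
    col_pos = {c: j for j, c in enumerate(perf.col_ids)}
    chosen_col = np.full(m, -1, dtype=int)
    sbs_col = np.full(m, -1, dtype=int)
    fold_label = np.zeros(m, dtype=int)

    global_params = fit_minmax(features) if normalization == "global" else None

    for fold in range(1, folds.n_folds + 1):
        test_ids = folds.test_ids(fold, perf.row_ids)
        train_ids = folds.train_ids(fold, perf.row_ids)
        if not test_ids:
            continue
        feat_train = features.subset_rows(train_ids)
        feat_test = features.subset_rows(test_ids)
        if normalization == "per_fold":
            params = fit_minmax(feat_train)
            feat_train = apply_minmax(feat_train, params)
            feat_test = apply_minmax(feat_test, params)
        elif normalization == "global":
            feat_train = apply_minmax(feat_train, global_params)
            feat_test = apply_minmax(feat_test, global_params)
        ranks_train = rank_transform(perf.subset_rows(train_ids))
        model = fit_selector(feat_train, ranks_train, config)
        picks = select_algorithms(model, feat_test)
        sbs_pick = _best_column(ranks_train.ranks.mean(axis=0))
        for inst, pick in zip(test_ids, picks):
            i = row_pos[inst]
            chosen_col[i] = col_pos[pick]
            sbs_col[i] = sbs_pick
            fold_label[i] = fold

    values = perf.values
    idx = np.arange(m)
    chosen_energy = values[idx, chosen_col]
    sbs_energy = values[idx, sbs_col]
    vbs_energy = values.min(axis=1)

    rng = np.random.default_rng([abs(int(config.seed)), abs(int(folds.seed))])
    draws = rng.integers(0, n, size=(m, random_draws))

    sel_rank = np.empty(m)
    sbs_rank = np.empty(m)
    vbs_rank = np.empty(m)
    rnd_rank = np.empty(m)
    standalone = np.empty((m, n))
    for i in range(m):
        e = values[i]
        if joint:
            sel_rank[i], standalone[i] = _joint_rank(e, chosen_energy[i])
            sbs_rank[i], _ = _joint_rank(e, sbs_energy[i])
            vbs_rank[i], _ = _joint_rank(e, vbs_energy[i])
            dup = np.array([_joint_rank(e, e[j])[0] for j in range(n)])
        else:
            base = rankdata(e, method="average")
            standalone[i] = base
            sel_rank[i] = base[chosen_col[i]]
            sbs_rank[i] = base[sbs_col[i]]
            vbs_rank[i] = base.min()
            dup = base
        rnd_rank[i] = dup[draws[i]].mean()

    rows = {c: standalone[:, j] for j, c in enumerate(perf.col_ids)}
    rows["selector"] = sel_rank
    rows["sbs"] = sbs_rank
    rows["vbs"] = vbs_rank
    rows["random"] = rnd_rank
    summary = pd.DataFrame(
        {
            "mean_rank": {k: v.mean() for k, v in rows.items()},
            "sd_rank": {k: v.std(ddof=0) for k, v in rows.items()},
        }
    ).loc[list(perf.col_ids) + list(META_METHODS)]
    summary.index.name = "method"

    selections = pd.DataFrame(
        {
            "instance_id": list(perf.row_ids),
            "fold": fold_label,
            "chosen_algorithm": [perf.col_ids[j] for j in chosen_col],
            "achieved_energy": chosen_energy,
        }
    )
    return EvaluationReport(
        summary=summary,
        selections=selections,
        mode=perf.mode,
        n_entries=n + 1 if joint else n,
    )


def baseline_metrics(
    perf: PerformanceMatrix,
    *,
    joint: bool = True,
    random_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Whole-data SBS/VBS/random summaries (no cross-validation).

    SBS here is determined on the full matrix, replicating a whole-data
    single-best summary; the CV-honest SBS lives in
    :func:`evaluate_selector`.
    """
    m, n = perf.shape
    ranks = rank_transform(perf)
    sbs_j = _best_column(ranks.ranks.mean(axis=0))
    values = perf.values
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n, size=(m, random_draws))
    out = {k: np.empty(m) for k in ("sbs", "vbs", "random")}
    for i in range(m):
        e = values[i]
        if joint:
            out["sbs"][i], _ = _joint_rank(e, e[sbs_j])
            out["vbs"][i], _ = _joint_rank(e, e.min())
            dup = np.array([_joint_rank(e, e[j])[0] for j in range(n)])
        else:
            base = rankdata(e, method="average")
            out["sbs"][i] = base[sbs_j]
            out["vbs"][i] = base.min()
            dup = base
        out["random"][i] = dup[draws[i]].mean()
    frame = pd.DataFrame(
        {
            "mean_rank": {k: v.mean() for k, v in out.items()},
            "sd_rank": {k: v.std(ddof=0) for k, v in out.items()},
        }
    )
    frame.index.name = "method"
    return frame


def compare_feature_sets(
    perf: PerformanceMatrix,
    feature_sets: Mapping[str, FeatureTable],
    config: SelectorConfig,
    folds: FoldAssignment,
    **kwargs,
) -> pd.DataFrame:
    """Run the CV evaluation once per named feature set with shared folds.

    Returns one row per feature set with the selector's mean/SD joint rank —
    the shape of a feature-set comparison table.
    """
    rows = {}
    for name, table in feature_sets.items():
        report = evaluate_selector(perf, table, config, folds, **kwargs)
        rows[name] = report.summary.loc["selector"]
    frame = pd.DataFrame(rows).T
    frame.index.name = "feature_set"
    return frame
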