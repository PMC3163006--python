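"""Cross-validated subset sweep and pattern selection.

The selection protocol:

1. Build one stratified k-fold plan (default k=3) and hold it fixed.
2. For each rank-prefix subset of the t-ranked candidate list (sizes 2
   through k_max, nine subsets at the default k_max = 10), cross-validate
   the boosted ensemble on the shared plan and pool the held-out
   predictions into a single confusion matrix.
3. Choose the subset with the highest pooled CV accuracy; ties go to the
   smaller subset (the fewer biomarkers a bedside pattern needs, the
   better).
4. Refit on the full cohort with the chosen subset; the resulting ensemble
   is the deployable diagnosis pattern. Its resubstitution (training-set)
   confusion matrix is reported alongside but never used for selection.

A single fold plan across the sweep makes the subset comparisons paired,
which removes fold-assignment noise from the accuracy differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .boosting import BoostEnsemble, predict, train
from .cohort import CohortTable
from .exceptions import ConfigurationError, TrainingError
from .metrics import ConfusionMatrix, MetricSet, confusion, metrics
from .ranking import RankedFeature

__all__ = [
    "FoldPlan",
    "SweepRecord",
    "SweepResult",
    "make_folds",
    "cross_validate",
    "sweep",
    "finalize_pattern",
]


@dataclass(frozen=True)
class FoldPlan:
    """Per-sample fold assignments for one k-fold split."""

    k: int
    assignments: np.ndarray
    seed: int

    def fold_sizes(self) -> list[int]:
        return [int((self.assignments == f).sum()) for f in range(self.k)]


@dataclass(frozen=True)
class SweepRecord:
    subset_size: int
    features: list[str]
    pooled_cm: ConfusionMatrix
    metric_set: MetricSet


@dataclass(frozen=True)
class SweepResult:
    records: list[SweepRecord]
    chosen: SweepRecord


def make_folds(
    labels, k: int = 3, seed: int = 0, stratified: bool = True
) -> FoldPlan:
    """Seeded shuffle then round-robin fold assignment.

    Stratified (the default) round-robins within each class, so fold class
    ratios track the cohort's; with 39 positives and 13 negatives at k=3
    this gives positives {13,13,13} and negatives {5,4,4}. Fold sizes never
    differ by more than 1.
    """
    y = np.asarray(labels, dtype=int)
    m = y.size
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    if m < k:
        raise ConfigurationError(f"cannot make {k} folds from {m} samples")
    rng = np.random.default_rng(seed)
    assignments = np.empty(m, dtype=int)
    if stratified:
        # larger class first so the leftover samples of the two classes
        # land in different folds, keeping totals within 1
        offset = 0
        classes = sorted(set(y.tolist()), key=lambda c: -(y == c).sum())
        for cls in classes:
            idx = np.nonzero(y == cls)[0]
            if idx.size < k:
                raise ConfigurationError(
                    f"class {cls:+d} has only {idx.size} samples, fewer than "
                    f"k={k} folds; use fewer folds or stratified=False"
                )
            perm = rng.permutation(idx)
            assignments[perm] = (np.arange(perm.size) + offset) % k
            offset += perm.size
    else:
        perm = rng.permutation(m)
        assignments[perm] = np.arange(m) % k
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def cross_validate(
    table: CohortTable,
    subset: list[str],
    plan: FoldPlan,
    n_rounds: int = 50,
    max_depth: int = 1,
) -> ConfusionMatrix:
    """Pooled held-out confusion matrix over all folds of the plan.

    Each fold is predicted by an ensemble trained on the remaining folds,
    so every sample is tested exactly once and the counts sum to the cohort
    size. A fold whose training fails (no weak learner beats chance) falls
    back to the training fold's majority label, with a warning.
    """
    if plan.assignments.shape != (table.n_samples,):
        raise ConfigurationError(
            "fold plan does not match the cohort's sample count"
        )
    preds = np.empty(table.n_samples, dtype=int)
    for f in range(plan.k):
        held = np.nonzero(plan.assignments == f)[0]
        rest = np.nonzero(plan.assignments != f)[0]
        train_tbl = table.take(rest)
        test_tbl = table.take(held)
        try:
            ens = train(train_tbl, subset, n_rounds=n_rounds, max_depth=max_depth)
            preds[held] = predict(ens, test_tbl)
        except TrainingError:
            majority = 1 if (train_tbl.labels == 1).sum() >= (train_tbl.labels == -1).sum() else -1
            warnings.warn(
                f"fold {f}: boosting failed to beat chance; predicting the "
                f"majority class {majority:+d} for its held-out samples",
                stacklevel=2,
            )
            preds[held] = majority
    return confusion(table.labels, preds)


def sweep(
    table: CohortTable,
    ranked: list[RankedFeature],
    k_max: int = 10,
    plan: FoldPlan | None = None,
    n_rounds: int = 50,
    max_depth: int = 1,
    seed: int = 0,
) -> SweepResult:
    """Cross-validate every rank-prefix subset of sizes 2..k_max.

    All subsets share one fold plan. The chosen record maximises pooled CV
    accuracy; exact ties (identical correct counts over the same samples)
    go to the smaller subset.
    """
    names_in_rank = [rf.name for rf in sorted(ranked, key=lambda r: r.rank)]
    if not 2 <= k_max <= len(names_in_rank):
        raise ConfigurationError(
            f"k_max must be in 2..{len(names_in_rank)}, got {k_max}"
        )
    if plan is None:
        plan = make_folds(table.labels, k=3, seed=seed)

    records: list[SweepRecord] = []
    for size in range(2, k_max + 1):
        subset = names_in_rank[:size]
        cm = cross_validate(table, subset, plan, n_rounds=n_rounds, max_depth=max_depth)
        records.append(
            SweepRecord(subset_size=size, features=subset, pooled_cm=cm,
                        metric_set=metrics(cm))
        )

    chosen = records[0]
    for rec in records[1:]:
        # integer comparison: pooled totals are identical across records
        if rec.pooled_cm.tp + rec.pooled_cm.tn > chosen.pooled_cm.tp + chosen.pooled_cm.tn:
            chosen = rec
    return SweepResult(records=records, chosen=chosen)


def finalize_pattern(
    table: CohortTable,
    chosen_subset: list[str],
    n_rounds: int = 50,
    max_depth: int = 1,
) -> tuple[BoostEnsemble, ConfusionMatrix]:
    """Train the deployable ensemble on the full cohort.

    Returns the ensemble and its resubstitution confusion matrix — the
    model's performance on its own training data, an optimistic bound that
    is reported for transparency but plays no role in selection.
    """
    ens = train(table, chosen_subset, n_rounds=n_rounds, max_depth=max_depth)
    resub = confusion(table.labels, predict(ens, table))
    return ens, resub
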