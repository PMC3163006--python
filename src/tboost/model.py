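"""Model/Results interface over the full pipeline.

:class:`TTestAdaBoost` bundles the whole protocol — t-rank the biomarkers,
take the top-k candidates, sweep the rank-prefix subsets under a shared
stratified k-fold plan, pick the smallest subset with the best pooled CV
accuracy, and refit that pattern on the full cohort. ``fit()`` returns a
:class:`TTestAdaBoostResults` carrying the ranking, the sweep diagnostics,
the chosen pattern and the deployable ensemble, with ``summary()``,
``predict()``, ``evaluate()`` and ``plot_sweep()`` hanging off it.

    >>> from tboost import TTestAdaBoost, simulate
    >>> cohort = simulate.generate(simulate.GeneratorSpec(seed=7))
    >>> res = TTestAdaBoost(cohort, seed=7).fit()
    >>> res.pattern          # doctest: +SKIP
    ['MCH', 'CHO', ...]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boosting import BoostEnsemble, predict
from .cohort import CohortTable, read_cohort
from .exceptions import ConfigurationError
from .metrics import ConfusionMatrix, MetricSet, confusion, metrics
from .ranking import RankedFeature, candidate_subset, rank_features
from .selection import FoldPlan, SweepResult, finalize_pattern, make_folds, sweep

__all__ = ["TTestAdaBoost", "TTestAdaBoostResults"]


class TTestAdaBoost:
    """t-statistic-ranked AdaBoost pattern-discovery model.

    Parameters
    ----------
    cohort : CohortTable
        Discovery cohort; both classes must be present.
    n_rounds : int
        Maximum boosting rounds per ensemble (default 50).
    max_depth : int
        Weak-learner tree depth (default 1, decision stumps).
    k_candidates : int
        Size of the t-ranked candidate list entering the sweep (default 10).
    k_folds : int
        Cross-validation folds (default 3).
    stratified : bool
        Stratify the folds by class (default True; with 13 controls and
        3 folds, unstratified splits can starve a fold of controls).
    seed : int
        Fold-plan shuffle seed. The rest of the pipeline is deterministic.
    """

    def __init__(
        self,
        cohort: CohortTable,
        n_rounds: int = 50,
        max_depth: int = 1,
        k_candidates: int = 10,
        k_folds: int = 3,
        stratified: bool = True,
        seed: int = 0,
    ) -> None:
        cohort.require_both_classes()
        if k_candidates > cohort.n_features:
            raise ConfigurationError(
                f"k_candidates={k_candidates} exceeds the cohort's "
                f"{cohort.n_features} features"
            )
        self.cohort = cohort
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.k_candidates = k_candidates
        self.k_folds = k_folds
        self.stratified = stratified
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str = "label",
        positive_label="1",
        id_column: str | None = "sample_id",
        **kwargs,
    ) -> "TTestAdaBoost":
        """Build from a pandas DataFrame (columns: optional id, biomarkers, label)."""
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        cohort = read_cohort(buf, label_column=label_column,
                             positive_label=str(positive_label),
                             id_column=id_column)
        return cls(cohort, **kwargs)

    @classmethod
    def from_csv(cls, path, label_column: str = "label", positive_label: str = "1",
                 id_column: str | None = "sample_id", **kwargs) -> "TTestAdaBoost":
        cohort = read_cohort(path, label_column=label_column,
                             positive_label=positive_label, id_column=id_column)
        return cls(cohort, **kwargs)

    def fit(self) -> "TTestAdaBoostResults":
        """Run ranking, sweep, selection and the final full-cohort refit."""
        ranking = rank_features(self.cohort)
        candidates = candidate_subset(ranking, self.k_candidates)
        plan = make_folds(self.cohort.labels, k=self.k_folds, seed=self.seed,
                          stratified=self.stratified)
        sweep_result = sweep(
            self.cohort, ranking, k_max=self.k_candidates, plan=plan,
            n_rounds=self.n_rounds, max_depth=self.max_depth,
        )
        ensemble, resub_cm = finalize_pattern(
            self.cohort, sweep_result.chosen.features,
            n_rounds=self.n_rounds, max_depth=self.max_depth,
        )
        return TTestAdaBoostResults(
            model=self,
            ranking=ranking,
            candidates=candidates,
            fold_plan=plan,
            sweep_result=sweep_result,
            ensemble=ensemble,
            resubstitution_cm=resub_cm,
        )


@dataclass
class TTestAdaBoostResults:
    """Fitted pattern, its cross-validated performance and diagnostics."""

    model: TTestAdaBoost
    ranking: list[RankedFeature]
    candidates: list[str]
    fold_plan: FoldPlan
    sweep_result: SweepResult
    ensemble: BoostEnsemble
    resubstitution_cm: ConfusionMatrix

    # -- headline views ---------------------------------------------------

    @property
    def pattern(self) -> list[str]:
        """The selected diagnosis pattern (biomarker names, rank order)."""
        return list(self.sweep_result.chosen.features)

    @property
    def cv_confusion(self) -> ConfusionMatrix:
        return self.sweep_result.chosen.pooled_cm

    @property
    def cv_metrics(self) -> MetricSet:
        return self.sweep_result.chosen.metric_set

    @property
    def resubstitution_metrics(self) -> MetricSet:
        return metrics(self.resubstitution_cm)

    def ranking_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"name": r.name, "t": r.t_value, "abs_t": r.abs_t, "df": r.df,
                 "p": r.p_value, "rank": r.rank}
                for r in self.ranking
            ]
        )

    def sweep_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.sweep_result.records:
            cm, ms = rec.pooled_cm, rec.metric_set
            rows.append(
                {
                    "subset_size": rec.subset_size,
                    "features": "|".join(rec.features),
                    "TP": cm.tp, "FN": cm.fn, "FP": cm.fp, "TN": cm.tn,
                    "sensitivity_pct": ms.sensitivity_pct,
                    "specificity_pct": ms.specificity_pct,
                    "accuracy_pct": ms.accuracy_pct,
                    "chosen": rec is self.sweep_result.chosen,
                }
            )
        return pd.DataFrame(rows)

    # -- downstream use ---------------------------------------------------

    def predict(self, cohort: CohortTable) -> np.ndarray:
        """+1/-1 labels for new samples (must carry the pattern's features)."""
        return predict(self.ensemble, cohort)

    def evaluate(self, cohort: CohortTable) -> tuple[ConfusionMatrix, MetricSet]:
        """Confusion matrix and metrics of the pattern on a labelled cohort."""
        cm = confusion(cohort.labels, self.predict(cohort))
        return cm, metrics(cm)

    def summary(self) -> str:
        """Plain-text report: ranking, sweep, chosen pattern, CV and
        resubstitution performance."""
        lines = []
        m = self.model
        lines.append("t-ranked AdaBoost pattern discovery")
        lines.append("=" * 60)
        lines.append(
            f"Cohort: {m.cohort.n_samples} samples "
            f"({m.cohort.n_positive} positive / {m.cohort.n_negative} negative), "
            f"{m.cohort.n_features} biomarkers"
        )
        lines.append(
            f"Config: {m.k_folds}-fold CV (stratified={m.stratified}, seed={m.seed}), "
            f"N={m.n_rounds} rounds, depth={m.max_depth}, "
            f"top-{m.k_candidates} candidates"
        )
        lines.append("")
        lines.append("Top-ranked biomarkers (|t| descending):")
        lines.append("  rank  name      t        df   p")
        for r in sorted(self.ranking, key=lambda r: r.rank)[: m.k_candidates]:
            lines.append(
                f"  {r.rank:>4}  {r.name:<8}  {r.t_value:>7.3f}  {r.df:>3}  {r.p_value:.4f}"
            )
        lines.append("")
        lines.append("Subset sweep (pooled CV confusion per rank-prefix subset):")
        lines.append("  size  TP  FN  FP  TN  Sens%  Spec%  Acc%")
        for rec in self.sweep_result.records:
            cm, ms = rec.pooled_cm, rec.metric_set
            mark = " <- chosen" if rec is self.sweep_result.chosen else ""
            lines.append(
                f"  {rec.subset_size:>4}  {cm.tp:>2}  {cm.fn:>2}  {cm.fp:>2}  {cm.tn:>2}"
                f"  {ms.sensitivity_pct:>5.1f}  {ms.specificity_pct:>5.1f}"
                f"  {ms.accuracy_pct:>5.1f}{mark}"
            )
        lines.append("")
        lines.append(f"Chosen pattern ({len(self.pattern)} biomarkers): "
                     + ", ".join(self.pattern))
        cm, ms = self.cv_confusion, self.cv_metrics
        lines.append(
            f"Pooled CV:        TP={cm.tp} FN={cm.fn} FP={cm.fp} TN={cm.tn}  "
            f"Sens={ms.sensitivity_pct}% Spec={ms.specificity_pct}% "
            f"Acc={ms.accuracy_pct}%"
        )
        cm, ms = self.resubstitution_cm, self.resubstitution_metrics
        lines.append(
            f"Resubstitution:   TP={cm.tp} FN={cm.fn} FP={cm.fp} TN={cm.tn}  "
            f"Sens={ms.sensitivity_pct}% Spec={ms.specificity_pct}% "
            f"Acc={ms.accuracy_pct}%  (training data; optimistic)"
        )
        lines.append(
            f"Boosting: {self.ensemble.n_rounds}/{self.ensemble.n_requested} rounds, "
            f"stop={self.ensemble.stop_reason}"
        )
        return "\n".join(lines)

    def plot_sweep(self, ax=None):
        """Pooled CV accuracy against subset size, chosen size marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sizes = [r.subset_size for r in self.sweep_result.records]
        accs = [r.metric_set.accuracy_pct for r in self.sweep_result.records]
        ax.plot(sizes, accs, marker="o")
        chosen = self.sweep_result.chosen
        ax.axvline(chosen.subset_size, linestyle="--", color="grey")
        ax.annotate(
            f"chosen: {chosen.subset_size}",
            (chosen.subset_size, chosen.metric_set.accuracy_pct),
            textcoords="offset points", xytext=(5, 5),
        )
        ax.set_xlabel("subset size (rank prefix)")
        ax.set_ylabel("pooled CV accuracy (%)")
        ax.set_title("Cross-validated subset sweep")
        return ax
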