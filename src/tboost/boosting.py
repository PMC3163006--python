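"""AdaBoost over weighted decision trees.

The discrete AdaBoost loop: starting from uniform instance weights
W_1(i) = 1/M, each round t fits a weak learner C_t on the current
distribution, measures its weighted error

    beta_t = sum_i W_t(i) [y_i != C_t(x_i)],

stops if beta_t >= 0.5 (the learner no longer beats weighted chance),
otherwise assigns the round the vote weight

    alpha_t = 1/2 ln((1 - beta_t) / beta_t)

and reweights W_{t+1}(i) = W_t(i) exp(-alpha_t y_i C_t(x_i)) / Z_t, with
Z_t restoring a probability distribution. The trained classifier is the
sign of the alpha-weighted vote, C(x) = sign(sum_t alpha_t C_t(x)).

A perfect round (beta_t = 0) would make alpha infinite; beta is clamped to
BETA_FLOOR = 1e-10 and training stops after that round, since no weight
update can follow a perfect fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import CohortTable
from .exceptions import ConfigurationError, DataError, TrainingError
from .tree import (TreeNode, fit_tree, predict_many, tree_from_dict,
                   tree_to_dict)

__all__ = [
    "BoostRound",
    "BoostEnsemble",
    "init_weights",
    "weighted_error",
    "alpha_from_beta",
    "update_weights",
    "train",
    "predict",
    "decision_scores",
    "save_ensemble",
    "load_ensemble",
    "BETA_FLOOR",
]

BETA_FLOOR = 1e-10


@dataclass
class BoostRound:
    alpha: float
    tree: TreeNode
    beta: float          # raw weighted error, before any clamping
    clamped: bool = False


@dataclass
class BoostEnsemble:
    """Ordered (alpha_t, C_t) pairs plus the stopping diagnostics."""

    rounds: list[BoostRound]
    n_requested: int
    stopped_early: bool
    stop_reason: str                   # "max_rounds" | "perfect" | "beta_ge_half"
    feature_subset: list[str] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    @property
    def beta_trace(self) -> list[float]:
        return [r.beta for r in self.rounds]


def init_weights(m: int) -> np.ndarray:
    """Uniform starting distribution W_1(i) = 1/M."""
    if m < 2:
        raise ConfigurationError(f"need at least 2 samples to boost, got {m}")
    return np.full(m, 1.0 / m)


def weighted_error(tree: TreeNode, table: CohortTable, w: np.ndarray) -> float:
    """Weight mass the tree misclassifies on the cohort."""
    preds = predict_many(tree, table)
    return float(np.asarray(w)[preds != table.labels].sum())


def alpha_from_beta(beta: float) -> float:
    """Round vote weight, 1/2 ln((1-beta)/beta); beta <= 0 clamps to BETA_FLOOR."""
    if beta >= 0.5:
        raise ConfigurationError(
            f"beta={beta} >= 0.5 is a stop signal, not an alpha input"
        )
    beta = max(beta, BETA_FLOOR)
    return 0.5 * math.log((1.0 - beta) / beta)


def update_weights(
    w: np.ndarray, alpha: float, labels: np.ndarray, predictions: np.ndarray
) -> np.ndarray:
    """Exponential reweighting followed by Z_t normalisation.

    Misclassified samples gain weight (factor e^alpha), correct ones lose
    (e^-alpha); the result sums to 1.
    """
    w = np.asarray(w, dtype=float)
    y = np.asarray(labels, dtype=int)
    c = np.asarray(predictions, dtype=int)
    if not (w.shape == y.shape == c.shape):
        raise DataError("weights, labels and predictions must share one length")
    if alpha < 0:
        raise ConfigurationError(f"alpha must be >= 0, got {alpha}")
    new = w * np.exp(-alpha * y * c)
    z = new.sum()
    if z <= 0:
        raise DataError("degenerate weight update: normaliser is zero")
    return new / z


def train(
    table: CohortTable,
    subset: list[str],
    n_rounds: int = 50,
    max_depth: int = 1,
) -> BoostEnsemble:
    """Run up to ``n_rounds`` boosting rounds on the given feature subset.

    Stops early when a round is perfect (beta at the clamp floor) or when
    no weak learner beats weighted chance (beta >= 0.5). If even the first
    round fails to beat chance, raises :class:`TrainingError`.
    """
    if n_rounds < 1:
        raise ConfigurationError(f"n_rounds must be >= 1, got {n_rounds}")
    if not subset:
        raise ConfigurationError("feature subset must be non-empty")
    sub = table.select_features(subset)
    sub.require_both_classes()

    w = init_weights(sub.n_samples)
    rounds: list[BoostRound] = []
    stop_reason = "max_rounds"
    for _t in range(n_rounds):
        tree = fit_tree(sub, w, max_depth=max_depth)
        preds = predict_many(tree, sub)
        beta = float(w[preds != sub.labels].sum())
        if beta >= 0.5:
            if not rounds:
                raise TrainingError(
                    f"first weak learner has weighted error {beta:.3f} >= 0.5; "
                    "no learner beats chance on this cohort/subset"
                )
            stop_reason = "beta_ge_half"
            break
        clamped = beta < BETA_FLOOR
        alpha = alpha_from_beta(beta)
        rounds.append(BoostRound(alpha=alpha, tree=tree, beta=beta, clamped=clamped))
        if clamped:
            stop_reason = "perfect"
            break
        w = update_weights(w, alpha, sub.labels, preds)

    return BoostEnsemble(
        rounds=rounds,
        n_requested=n_rounds,
        stopped_early=stop_reason != "max_rounds",
        stop_reason=stop_reason,
        feature_subset=list(subset),
    )


def decision_scores(ensemble: BoostEnsemble, table: CohortTable) -> np.ndarray:
    """The real-valued vote sum_t alpha_t C_t(x) per sample."""
    sub = table.select_features(ensemble.feature_subset)
    scores = np.zeros(sub.n_samples)
    for rnd in ensemble.rounds:
        scores += rnd.alpha * predict_many(rnd.tree, sub)
    return scores


def predict(ensemble: BoostEnsemble, table: CohortTable) -> np.ndarray:
    """Hard +1/-1 labels: sign of the weighted vote; an exact 0 votes +1."""
    scores = decision_scores(ensemble, table)
    return np.where(scores >= 0, 1, -1)


def predict_sample(ensemble: BoostEnsemble, sample: dict[str, float]) -> int:
    """Classify one feature-name -> value mapping."""
    missing = [f for f in ensemble.feature_subset if f not in sample]
    if missing:
        raise DataError(f"sample is missing features {missing}")
    from .tree import predict_tree

    score = sum(r.alpha * predict_tree(r.tree, sample) for r in ensemble.rounds)
    return 1 if score >= 0 else -1


# -- persistence (plain JSON text) ------------------------------------------

def ensemble_to_dict(ensemble: BoostEnsemble) -> dict:
    return {
        "feature_subset": ensemble.feature_subset,
        "n_requested": ensemble.n_requested,
        "stopped_early": ensemble.stopped_early,
        "stop_reason": ensemble.stop_reason,
        "rounds": [
            {
                "alpha": r.alpha,
                "beta": r.beta,
                "clamped": r.clamped,
                "tree": tree_to_dict(r.tree),
            }
            for r in ensemble.rounds
        ],
    }


def save_ensemble(ensemble: BoostEnsemble, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(ensemble_to_dict(ensemble), indent=2, sort_keys=True) + "\n"
    )


def load_ensemble(path: str | Path) -> BoostEnsemble:
    d = json.loads(Path(path).read_text())
    return BoostEnsemble(
        rounds=[
            BoostRound(
                alpha=float(r["alpha"]),
                beta=float(r["beta"]),
                clamped=bool(r["clamped"]),
                tree=tree_from_dict(r["tree"]),
            )
            for r in d["rounds"]
        ],
        n_requested=int(d["n_requested"]),
        stopped_early=bool(d["stopped_early"]),
        stop_reason=str(d["stop_reason"]),
        feature_subset=list(d["feature_subset"]),
    )
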