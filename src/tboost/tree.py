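"""Weighted-instance decision tree on continuous features.

The base classifier inside the boosting loop. Splits are axis-aligned
thresholds chosen by weighted gain ratio (entropy-based, the C4.5
criterion); candidate thresholds are the midpoints between consecutive
distinct sorted values of each feature. Leaves vote the weighted majority
class, so the tree always outputs a hard +1/-1 label — the boosting weight
update needs hard labels.

Conventions, all deterministic:
  * value <= threshold routes left, value > threshold routes right;
  * gain-ratio ties break toward the lower feature index, then the lower
    threshold;
  * a weighted-majority tie at a leaf votes +1.

Default depth is 1 (a decision stump), the canonical AdaBoost weak
learner; deeper trees are available via ``max_depth``. No pruning: the
boosting reweighting supplies the capacity control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

import numpy as np

from .cohort import CohortTable
from .exceptions import ConfigurationError, DataError

__all__ = ["TreeNode", "fit_tree", "predict_tree", "predict_many",
           "tree_to_dict", "tree_from_dict"]

_GAIN_TOL = 1e-12   # a split must improve entropy by more than this
_TIE_TOL = 1e-12    # score differences below this are ties

Criterion = Literal["gain_ratio", "info_gain"]


@dataclass
class TreeNode:
    """Internal node (feature, threshold, children) or leaf (vote)."""

    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    vote: Optional[int] = None
    weight_mass: float = 0.0
    # weighted misclassification rate on the training distribution,
    # populated on the root by fit_tree
    training_error: Optional[float] = field(default=None, compare=False)

    @property
    def is_leaf(self) -> bool:
        return self.vote is not None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


def _entropy(wpos: np.ndarray, wneg: np.ndarray) -> np.ndarray:
    """Weighted binary entropy in bits; vectorised, 0*log0 := 0."""
    wpos = np.asarray(wpos, dtype=float)
    wneg = np.asarray(wneg, dtype=float)
    tot = wpos + wneg
    out = np.zeros_like(tot)
    ok = tot > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        for part in (wpos, wneg):
            q = np.where(ok, part / np.where(ok, tot, 1.0), 0.0)
            term = np.where(q > 0, -q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
            out = out + term
    return out


def _best_split(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, criterion: Criterion
) -> Optional[tuple[int, float]]:
    """Exhaustive search over feature x midpoint candidates.

    Returns (feature index, threshold) of the best-scoring admissible split,
    or None when no candidate improves entropy. Candidates that would put
    zero weight on a side are inadmissible (their split information is 0).
    """
    total_w = w.sum()
    wpos_tot = w[y == 1].sum()
    wneg_tot = total_w - wpos_tot
    h_parent = float(_entropy(wpos_tot, wneg_tot))

    best_score = -np.inf
    best: Optional[tuple[int, float]] = None
    for j in range(X.shape[1]):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs, ws, ys = x[order], w[order], y[order]
        cut = np.nonzero(np.diff(xs) > 0)[0]
        if cut.size == 0:
            continue
        cum_w = np.cumsum(ws)
        cum_pos = np.cumsum(ws * (ys == 1))
        wl = cum_w[cut]
        pl = cum_pos[cut]
        wr = total_w - wl
        pr = wpos_tot - pl

        h_left = _entropy(pl, wl - pl)
        h_right = _entropy(pr, wr - pr)
        gain = h_parent - (wl * h_left + wr * h_right) / total_w

        fl = wl / total_w
        fr = wr / total_w
        admissible = (fl > 0) & (fr > 0) & (gain > _GAIN_TOL)
        if not admissible.any():
            continue
        if criterion == "gain_ratio":
            with np.errstate(divide="ignore", invalid="ignore"):
                split_info = _entropy(wl, wr)
            score = np.where(admissible, gain / np.where(split_info > 0, split_info, np.inf), -np.inf)
        else:
            score = np.where(admissible, gain, -np.inf)

        m = score.max()
        if m <= -np.inf:
            continue
        # lowest threshold among within-tolerance ties for this feature
        i = int(np.nonzero(score >= m - _TIE_TOL)[0][0])
        thr = float((xs[cut[i]] + xs[cut[i] + 1]) / 2.0)
        # strictly-better comparison across features: earlier feature wins ties
        if m > best_score + _TIE_TOL:
            best_score = float(m)
            best = (j, thr)
    return best


def _leaf(wpos: float, wneg: float) -> TreeNode:
    vote = 1 if wpos >= wneg else -1
    return TreeNode(vote=vote, weight_mass=float(wpos + wneg))


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    names: list[str],
    depth_left: int,
    criterion: Criterion,
) -> TreeNode:
    wpos = float(w[y == 1].sum())
    wneg = float(w[y == -1].sum())
    if depth_left == 0 or wpos == 0.0 or wneg == 0.0:
        return _leaf(wpos, wneg)
    split = _best_split(X, y, w, criterion)
    if split is None:
        return _leaf(wpos, wneg)
    j, thr = split
    go_left = X[:, j] <= thr
    node = TreeNode(feature=names[j], threshold=thr, weight_mass=float(wpos + wneg))
    node.left = _grow(X[go_left], y[go_left], w[go_left], names, depth_left - 1, criterion)
    node.right = _grow(X[~go_left], y[~go_left], w[~go_left], names, depth_left - 1, criterion)
    return node


def fit_tree(
    table: CohortTable,
    weights: np.ndarray,
    max_depth: int = 1,
    criterion: Criterion = "gain_ratio",
) -> TreeNode:
    """Fit a depth-limited weighted decision tree.

    ``weights`` must be non-negative and sum to 1 within 1e-9. The returned
    root carries ``training_error``, the weight mass it misclassifies.
    Degenerate inputs (all weight on one sample, single-class labels, all
    rows identical) yield a single majority leaf, never an error.
    """
    if max_depth < 1:
        raise ConfigurationError(f"max_depth must be >= 1, got {max_depth}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (table.n_samples,):
        raise DataError(
            f"weights shape {w.shape} does not match {table.n_samples} samples"
        )
    if (w < 0).any():
        raise DataError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise DataError(f"weights must sum to 1 within 1e-9, got {w.sum()!r}")

    root = _grow(table.values, table.labels, w, table.feature_names,
                 max_depth, criterion)
    preds = predict_many(root, table)
    root.training_error = float(w[preds != table.labels].sum())
    return root


def predict_tree(node: TreeNode, sample: Mapping[str, float]) -> int:
    """Route one feature-name -> value mapping to a leaf vote."""
    while not node.is_leaf:
        if node.feature not in sample:
            raise DataError(f"sample is missing feature {node.feature!r}")
        node = node.left if sample[node.feature] <= node.threshold else node.right
    return int(node.vote)


def predict_many(node: TreeNode, table: CohortTable) -> np.ndarray:
    """Vectorised prediction over a cohort's rows."""
    out = np.empty(table.n_samples, dtype=int)

    def descend(nd: TreeNode, rows: np.ndarray) -> None:
        if rows.size == 0:
            return
        if nd.is_leaf:
            out[rows] = nd.vote
            return
        x = table.values[rows, table.feature_index(nd.feature)]
        go_left = x <= nd.threshold
        descend(nd.left, rows[go_left])
        descend(nd.right, rows[~go_left])

    descend(node, np.arange(table.n_samples))
    return out


# -- plain-text persistence -------------------------------------------------

def tree_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"vote": int(node.vote), "weight_mass": node.weight_mass}
    return {
        "feature": node.feature,
        "threshold": node.threshold,
        "left": tree_to_dict(node.left),
        "right": tree_to_dict(node.right),
    }


def tree_from_dict(d: dict) -> TreeNode:
    if "vote" in d:
        return TreeNode(vote=int(d["vote"]), weight_mass=float(d.get("weight_mass", 0.0)))
    return TreeNode(
        feature=d["feature"],
        threshold=float(d["threshold"]),
        left=tree_from_dict(d["left"]),
        right=tree_from_dict(d["right"]),
    )
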