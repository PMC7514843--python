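"""Depth-limited, unpruned credal decision trees with a forcible root.

:class:`CredalDecisionTreeClassifier` is a scikit-learn style estimator for a
binary severity class coded 1 (slight) / 2 (fatal).  It grows an unpruned
tree of at most ``max_depth`` split levels (default 4, so extracted rules
have at most four antecedent conditions), selecting at each node the
criterion-maximising predictor not already used on the path.  A split is
admissible only when at least two children receive at least
``min_leaf_weight`` (weighted) instances, the J48 default convention.

Missing values follow C4.5: a record missing the split variable descends
every branch with its weight scaled by the branch's share of the observed
weight, and split criteria are evaluated on observed weight only, scaled by
the observed fraction.

When the root is forced (the root-variation ensemble forces every predictor
in turn) the root is split regardless of its score under the info-gain
ratio, while a strictly negative imprecise score (IIG / A-NPIM) vetoes the
whole tree: the estimator is marked empty and contributes no rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .criteria import _plogp, max_entropy_binary
from .schema import AccidentDataset, FATAL, SLIGHT

__all__ = [
    "TreeNode",
    "IRNVConfig",
    "CredalDecisionTreeClassifier",
    "build_tree",
    "classify_instance",
    "tree_depth",
    "iter_leaves",
    "tree_to_text",
    "tree_to_dict",
]

_TOL = 1e-12

CRITERIA = ("igr", "iig", "anpim")
_IMPRECISE = {"iig": "idm", "anpim": "npi"}


@dataclass
class TreeNode:
    """One node of a fitted tree.

    ``class_counts`` is the (slight, fatal) training weight reaching the
    node, fractional pieces included; ``branch_shares`` records each
    branch's share of the observed weight, used both for descending missing
    values and as the missing-value split ratio at induction time.
    """

    split_variable: str | None
    branches: dict[int, "TreeNode"]
    leaf_class: int | None
    class_counts: tuple[float, float]
    depth: int
    branch_shares: dict[int, float] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None

    @property
    def majority_class(self) -> int:
        return SLIGHT if self.class_counts[0] >= self.class_counts[1] else FATAL


@dataclass
class IRNVConfig:
    """Induction settings shared by single trees and the ensemble."""

    criteria: tuple[str, ...] = CRITERIA
    s: float = 1.0
    max_depth: int = 4
    min_leaf_weight: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_leaf_weight < 1:
            raise ValueError("min_leaf_weight must be >= 1")
        bad = set(self.criteria) - set(CRITERIA)
        if bad:
            raise ValueError(f"unknown criteria {sorted(bad)}")


class CredalDecisionTreeClassifier(BaseEstimator, ClassifierMixin):
    """Decision tree over categorical codes with credal split criteria.

    Parameters
    ----------
    criterion : {"igr", "iig", "anpim"}
        Split criterion: info-gain ratio, imprecise info-gain (IDM) or the
        approximate nonparametric predictive inference criterion.
    s : float
        IDM hyperparameter (IIG only).
    max_depth : int
        Maximum number of split levels on any root-to-leaf path.
    min_leaf_weight : float
        A split must give at least two children this much weight.
    root_variable : str or None
        Force the root split onto this predictor.

    Attributes
    ----------
    tree_ : TreeNode or None
        Fitted tree; ``None`` when the tree was vetoed (``is_empty_``).
    is_empty_ : bool
        True when a forced root had strictly negative imprecise gain.
    root_score_ : float or None
        Criterion value of the forced root on the training data.
    """

    def __init__(
        self,
        criterion: str = "igr",
        s: float = 1.0,
        max_depth: int = 4,
        min_leaf_weight: float = 2.0,
        root_variable: str | None = None,
    ):
        self.criterion = criterion
        self.s = s
        self.max_depth = max_depth
        self.min_leaf_weight = min_leaf_weight
        self.root_variable = root_variable

    # ------------------------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        codes, names = _as_codes(X)
        y = np.asarray(y, dtype=np.int64)
        if codes.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        if not np.isin(y, (SLIGHT, FATAL)).all():
            raise ValueError("y must be coded 1 (slight) / 2 (fatal)")
        w = (
            np.ones(len(y))
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("sample_weight must be non-negative with positive total")

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = codes.shape[1]
        self.classes_ = np.array([SLIGHT, FATAL])
        self._codes = codes
        self._y2 = y == FATAL
        self._nbins = int(codes.max(initial=0)) + 2  # shifted codes 0..max+1
        self._offsets = np.arange(self.n_features_in_, dtype=np.int64) * self._nbins

        self.is_empty_ = False
        self.root_score_ = None
        root_j = None
        if self.root_variable is not None:
            matches = np.nonzero(self.feature_names_in_ == self.root_variable)[0]
            if len(matches) == 0:
                raise KeyError(self.root_variable)
            root_j = int(matches[0])

        idx = np.arange(len(y))
        if root_j is not None:
            scores, _, variation = self._score_node(idx, w)
            if variation[root_j]:
                self.root_score_ = float(scores[root_j])
            if (
                self.criterion in _IMPRECISE
                and self.root_score_ is not None
                and self.root_score_ < -_TOL
            ):
                self.is_empty_ = True
                self.tree_ = None
                self.majority_ = SLIGHT if (w[~self._y2].sum() >= w[self._y2].sum()) else FATAL
                del self._codes, self._y2
                return self

        used = np.zeros(self.n_features_in_, dtype=bool)
        self.tree_ = self._grow(idx, w, 0, used, root_j)
        self.majority_ = self.tree_.majority_class
        del self._codes, self._y2
        return self

    # ------------------------------------------------------------------
    def _score_node(self, idx, w):
        """Score every feature at one node in a single vectorised pass.

        Returns ``(scores, admissible, variation)``: criterion values
        (``-inf`` when undefined), whether at least two children would get
        ``min_leaf_weight``, and whether the feature has >= 2 observed
        values at this node.
        """
        c, nb = self.n_features_in_, self._nbins
        sub = self._codes[idx]
        y2 = self._y2[idx]
        w1 = np.where(y2, 0.0, w)
        w2 = np.where(y2, w, 0.0)
        flat = (sub.astype(np.int64) + 1 + self._offsets).ravel()
        minlength = c * nb
        cnt1 = np.bincount(flat, weights=np.repeat(w1, c), minlength=minlength)
        cnt2 = np.bincount(flat, weights=np.repeat(w2, c), minlength=minlength)
        cnt1 = cnt1.reshape(c, nb)[:, 1:]  # drop the missing bin
        cnt2 = cnt2.reshape(c, nb)[:, 1:]
        tot = cnt1 + cnt2
        w_obs = tot.sum(axis=1)
        w_all = float(w.sum())
        variation = (tot > 0).sum(axis=1) >= 2

        with np.errstate(divide="ignore", invalid="ignore"):
            child_w = tot * np.where(w_obs > 0, w_all / w_obs, 0.0)[:, None]
        admissible = ((child_w >= self.min_leaf_weight) & (tot > 0)).sum(axis=1) >= 2

        m1 = cnt1.sum(axis=1)
        m2 = cnt2.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_branch = np.where(w_obs[:, None] > 0, tot / w_obs[:, None], 0.0)
        frac = np.where(w_obs > 0, w_obs / w_all, 0.0)

        if self.criterion == "igr":
            h_marg = _binary_entropy(m1, m2)
            h_cell = _binary_entropy(cnt1, cnt2)
            h_cond = (p_branch * h_cell).sum(axis=1)
            h_x = _plogp(p_branch).sum(axis=1)
            gain = frac * (h_marg - h_cond)
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.where(h_x > _TOL, gain / np.where(h_x > 0, h_x, 1.0), -np.inf)
            scores[~variation] = -np.inf
        else:
            model = _IMPRECISE[self.criterion]
            h_marg = max_entropy_binary(m1, m2, model, self.s)
            h_cell = max_entropy_binary(cnt1, cnt2, model, self.s)
            h_cond = (p_branch * h_cell).sum(axis=1)
            scores = frac * (h_marg - h_cond)
            scores[w_obs <= 0] = -np.inf
        return scores, admissible, variation

    def _grow(self, idx, w, depth, used, forced_j):
        y2 = self._y2[idx]
        counts = (float(w[~y2].sum()), float(w[y2].sum()))
        node = TreeNode(
            split_variable=None,
            branches={},
            leaf_class=None,
            class_counts=counts,
            depth=depth,
        )
        pure = min(counts) <= _TOL
        if depth >= self.max_depth or (pure and forced_j is None):
            node.leaf_class = node.majority_class
            return node

        scores, admissible, variation = self._score_node(idx, w)
        if forced_j is not None:
            j = forced_j
            if not (variation[j] and admissible[j]):
                node.leaf_class = node.majority_class
                return node
        else:
            ok = variation & admissible & ~used & (scores > _TOL)
            if not ok.any():
                node.leaf_class = node.majority_class
                return node
            masked = np.where(ok, scores, -np.inf)
            j = int(np.argmax(masked))  # first max = schema column order

        col = self._codes[idx, j]
        obs = col >= 0
        idx_obs, w_rows = idx[obs], w[obs]
        idx_miss, w_miss = idx[~obs], w[~obs]
        col_obs = col[obs]
        w_obs_total = float(w_rows.sum())
        child_used = used.copy()
        child_used[j] = True

        node.split_variable = str(self.feature_names_in_[j])
        for v in np.unique(col_obs):
            sel = col_obs == v
            share = float(w_rows[sel].sum()) / w_obs_total
            if share <= 0:
                continue
            child_idx = np.concatenate([idx_obs[sel], idx_miss])
            child_w = np.concatenate([w_rows[sel], w_miss * share])
            node.branch_shares[int(v)] = share
            node.branches[int(v)] = self._grow(child_idx, child_w, depth + 1, child_used, None)
        if not node.branches:  # all weight missing: degenerate, close as leaf
            node.split_variable = None
            node.leaf_class = node.majority_class
        return node

    # ------------------------------------------------------------------
    def predict(self, X):
        codes, names = _as_codes(X)
        order = self._column_order(names)
        out = np.empty(len(codes), dtype=np.int64)
        for i, row in enumerate(codes):
            out[i] = self._predict_row(row, order)
        return out

    def predict_proba(self, X):
        codes, names = _as_codes(X)
        order = self._column_order(names)
        out = np.empty((len(codes), 2))
        for i, row in enumerate(codes):
            mass = self._row_mass(row, order)
            tot = mass.sum()
            out[i] = mass / tot if tot > 0 else (0.5, 0.5)
        return out

    def _column_order(self, names):
        pos = {n: j for j, n in enumerate(names)}
        return {str(n): pos[str(n)] for n in self.feature_names_in_ if str(n) in pos}

    def _predict_row(self, row, order) -> int:
        if self.tree_ is None:
            return self.majority_
        mass = _class_mass(self.tree_, row, order)
        return SLIGHT if mass[0] >= mass[1] else FATAL

    def _row_mass(self, row, order):
        if self.tree_ is None:
            return np.array([1.0, 0.0]) if self.majority_ == SLIGHT else np.array([0.0, 1.0])
        return _class_mass(self.tree_, row, order)


def _binary_entropy(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(t > 0, a / np.where(t > 0, t, 1.0), 0.0)
    return _plogp(p) + _plogp(1.0 - p)


def _class_mass(node: TreeNode, row, order) -> np.ndarray:
    """Recursive class-count mass of one record; missing values fan out
    across branches by training share, unseen values stop at the node's
    majority class."""
    if node.is_leaf:
        return np.asarray(node.class_counts)
    j = order.get(node.split_variable)
    v = int(row[j]) if j is not None else -1
    if v == -1:
        mass = np.zeros(2)
        for val, child in node.branches.items():
            mass += node.branch_shares[val] * _class_mass(child, row, order)
        return mass
    if v in node.branches:
        return _class_mass(node.branches[v], row, order)
    out = np.zeros(2)
    out[0 if node.majority_class == SLIGHT else 1] = max(sum(node.class_counts), 1.0)
    return out


def _as_codes(X) -> tuple[np.ndarray, list[str]]:
    """Coerce a dataset/frame/array into an int16 code matrix (-1 missing)."""
    if isinstance(X, AccidentDataset):
        return X.codes(), X.variable_names
    if isinstance(X, pd.DataFrame):
        out = np.full(X.shape, -1, dtype=np.int16)
        for j, c in enumerate(X.columns):
            out[:, j] = pd.Series(X[c]).fillna(-1).to_numpy(dtype=np.int64)
        return out, [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    codes = np.where(np.isnan(arr), -1, arr).astype(np.int16)
    return codes, [f"x{j}" for j in range(codes.shape[1])]


# ---------------------------------------------------------------------------
# functional wrappers and tree utilities


def build_tree(
    dataset: AccidentDataset,
    root_variable: str,
    criterion: str,
    config: IRNVConfig | None = None,
) -> CredalDecisionTreeClassifier:
    """Fit one tree with a forced root on an :class:`AccidentDataset`."""
    config = config or IRNVConfig()
    clf = CredalDecisionTreeClassifier(
        criterion=criterion,
        s=config.s,
        max_depth=config.max_depth,
        min_leaf_weight=config.min_leaf_weight,
        root_variable=root_variable,
    )
    return clf.fit(dataset, dataset.severity, sample_weight=dataset.weights)


def classify_instance(tree, record) -> int:
    """Severity class of one record (mapping or Series of variable codes)."""
    if isinstance(tree, CredalDecisionTreeClassifier):
        clf = tree
    else:
        raise TypeError("pass a fitted CredalDecisionTreeClassifier")
    row = np.full(len(clf.feature_names_in_), -1, dtype=np.int16)
    for j, name in enumerate(clf.feature_names_in_):
        v = record.get(str(name)) if hasattr(record, "get") else record[str(name)]
        if v is not None and not pd.isna(v):
            row[j] = int(v)
    order = {str(n): j for j, n in enumerate(clf.feature_names_in_)}
    return clf._predict_row(row, order)


def iter_leaves(node: TreeNode):
    """Yield ``(path, leaf)`` pairs; a path is a tuple of (variable, value)."""
    stack = [((), node)]
    while stack:
        path, cur = stack.pop()
        if cur.is_leaf:
            yield path, cur
        else:
            for v in sorted(cur.branches, reverse=True):
                stack.append((path + ((cur.split_variable, v),), cur.branches[v]))


def tree_depth(node: TreeNode | None) -> int:
    """Number of split levels on the deepest root-to-leaf path."""
    if node is None or node.is_leaf:
        return 0
    return 1 + max(tree_depth(child) for child in node.branches.values())


def tree_to_dict(node: TreeNode | None) -> dict | None:
    if node is None:
        return None
    d = {
        "class_counts": [round(c, 9) for c in node.class_counts],
        "depth": node.depth,
    }
    if node.is_leaf:
        d["leaf_class"] = node.leaf_class
    else:
        d["split_variable"] = node.split_variable
        d["branches"] = {str(v): tree_to_dict(c) for v, c in sorted(node.branches.items())}
    return d


def tree_to_text(node: TreeNode | None, indent: str = "") -> str:
    if node is None:
        return indent + "(empty tree)\n"
    if node.is_leaf:
        return (
            f"{indent}-> class {node.leaf_class} "
            f"(slight={node.class_counts[0]:.2f}, fatal={node.class_counts[1]:.2f})\n"
        )
    out = []
    for v, child in sorted(node.branches.items()):
        out.append(f"{indent}{node.split_variable} = {v}:\n")
        out.append(tree_to_text(child, indent + "    "))
    return "".join(out)
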