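"""Information root node variation (IRNV): one tree per root per criterion.

A single decision tree only yields rules in the direction of its root
variable.  IRNV ranks the ``m`` predictors by a split criterion, builds one
tree with each predictor forced as root, extracts every tree's rules and
pools them; the procedure repeats per criterion (info-gain ratio, IIG,
A-NPIM by default) so at most ``3 m`` trees are built.  For the imprecise
criteria a root whose criterion value is strictly negative contributes an
empty rule set — such a predictor worsens the information on the class.

:class:`IRNVRuleMiner` runs the whole chain (ranking, trees, extraction,
scoring, threshold selection) as one scikit-learn style estimator.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .rules import (
    DecisionRule,
    SelectionThresholds,
    dedupe_rules,
    extract_rules,
    select_rules,
)
from .schema import AccidentDataset, CategoricalVariableSpec
from .tree import (
    CRITERIA,
    CredalDecisionTreeClassifier,
    IRNVConfig,
    _as_codes,
)

__all__ = ["IRNVRuleMiner", "rank_variables", "run_irnv"]

_TOL = 1e-12


def _as_dataset(X, y=None, sample_weight=None) -> AccidentDataset:
    """Accept an AccidentDataset directly or a frame/array plus labels."""
    if isinstance(X, AccidentDataset):
        if sample_weight is not None:
            return AccidentDataset(
                variables=X.variables,
                frame=X.frame,
                severity=X.severity,
                weights=np.asarray(sample_weight, dtype=float),
            )
        return X
    if y is None:
        raise ValueError("y is required unless X is an AccidentDataset")
    import pandas as pd

    frame = (
        X.astype("Int64")
        if isinstance(X, pd.DataFrame)
        else pd.DataFrame(np.asarray(X)).astype("Int64")
    )
    frame.columns = [str(c) for c in frame.columns]
    variables = [
        CategoricalVariableSpec(
            name=c,
            values=tuple(sorted(int(v) for v in frame[c].dropna().unique()) or (0,)),
            missing_allowed=True,
        )
        for c in frame.columns
    ]
    weights = np.ones(len(frame)) if sample_weight is None else np.asarray(sample_weight)
    return AccidentDataset(
        variables=variables,
        frame=frame.reset_index(drop=True),
        severity=np.asarray(y),
        weights=weights,
    )


class IRNVRuleMiner(BaseEstimator):
    """Root-variation credal-tree rule miner.

    Parameters mirror the tree estimator plus the selection thresholds.

    Attributes (after :meth:`fit`)
    ------------------------------
    rankings_ : dict[str, list[tuple[str, float]]]
        Per-criterion variable importance ranking (descending score);
        variables with no observed variation are unrankable and excluded.
    trees_ : dict[tuple[str, str], CredalDecisionTreeClassifier]
        Fitted trees keyed by (criterion, root variable).  Vetoed roots
        (negative imprecise score) carry an empty tree.
    n_trees_ : int
        Number of non-empty trees built (<= #criteria * m).
    candidate_rules_ : list[DecisionRule]
        Pooled, deduplicated rules before scoring/selection.
    rules_ : list[DecisionRule]
        Scored, threshold-selected, sorted rules (fatal consequent).
    """

    def __init__(
        self,
        criteria: tuple[str, ...] = CRITERIA,
        s: float = 1.0,
        max_depth: int = 4,
        min_leaf_weight: float = 2.0,
        min_probability: float = 0.10,
        min_support: float = 0.001,
    ):
        self.criteria = criteria
        self.s = s
        self.max_depth = max_depth
        self.min_leaf_weight = min_leaf_weight
        self.min_probability = min_probability
        self.min_support = min_support

    def fit(self, X, y=None, sample_weight=None):
        dataset = _as_dataset(X, y, sample_weight)
        thresholds = SelectionThresholds(self.min_probability, self.min_support)

        self.rankings_ = {}
        self.trees_ = {}
        self.n_trees_ = 0
        pooled: list[DecisionRule] = []
        for criterion in self.criteria:
            ranking = rank_variables(
                dataset, criterion, s=self.s, min_leaf_weight=self.min_leaf_weight
            )
            self.rankings_[criterion] = ranking
            for root, score in ranking:
                if criterion != "igr" and score < -_TOL:
                    continue  # negative imprecise gain: empty rule set
                clf = CredalDecisionTreeClassifier(
                    criterion=criterion,
                    s=self.s,
                    max_depth=self.max_depth,
                    min_leaf_weight=self.min_leaf_weight,
                    root_variable=root,
                ).fit(dataset, dataset.severity, sample_weight=dataset.weights)
                self.trees_[(criterion, root)] = clf
                if not clf.is_empty_:
                    self.n_trees_ += 1
                pooled.extend(extract_rules(clf))

        self.candidate_rules_ = dedupe_rules(pooled)
        # S and Pr are computed on the original unit-weight records
        scoring = AccidentDataset(
            variables=dataset.variables,
            frame=dataset.frame,
            severity=dataset.severity,
            weights=np.ones(dataset.n),
        )
        self.rules_ = select_rules(self.candidate_rules_, scoring, thresholds)
        return self

    def to_frame(self):
        from .rules import rules_to_frame

        return rules_to_frame(self.rules_)


def rank_variables(
    dataset: AccidentDataset,
    criterion: str,
    s: float = 1.0,
    min_leaf_weight: float = 2.0,
) -> list[tuple[str, float]]:
    """Variables sorted by criterion value on the full dataset, descending.

    Variables without observed variation (constant or fully missing) are
    excluded; ties keep schema column order.
    """
    if dataset.n == 0:
        raise ValueError("empty dataset")
    probe = CredalDecisionTreeClassifier(
        criterion=criterion, s=s, max_depth=1, min_leaf_weight=min_leaf_weight
    )
    codes, names = _as_codes(dataset)
    probe.feature_names_in_ = np.asarray(names, dtype=object)
    probe.n_features_in_ = codes.shape[1]
    probe._codes = codes
    probe._y2 = dataset.severity == 2
    probe._nbins = int(codes.max(initial=0)) + 2
    probe._offsets = np.arange(probe.n_features_in_, dtype=np.int64) * probe._nbins
    scores, _, variation = probe._score_node(
        np.arange(dataset.n), np.asarray(dataset.weights, dtype=float)
    )
    ranked = [
        (names[j], float(scores[j]))
        for j in range(len(names))
        if variation[j] and np.isfinite(scores[j])
    ]
    ranked.sort(key=lambda t: -t[1])  # stable: ties keep schema order
    return ranked


def run_irnv(dataset: AccidentDataset, config: IRNVConfig | None = None) -> IRNVRuleMiner:
    """Fit the full root-variation ensemble on a dataset; returns the miner
    whose ``candidate_rules_`` is the pooled union of all per-root rule sets
    and ``rules_`` the threshold-selected subset."""
    config = config or IRNVConfig()
    miner = IRNVRuleMiner(
        criteria=tuple(config.criteria),
        s=config.s,
        max_depth=config.max_depth,
        min_leaf_weight=config.min_leaf_weight,
    )
    return miner.fit(dataset)
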