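"""Decision-rule extraction, support/probability scoring and selection.

Every leaf of a fitted tree yields one rule ``IF A THEN B``: the antecedent
``A`` is the set of (variable = value) conditions on the root-to-leaf path
(1 to 4 conditions at the default depth), the consequent ``B`` the leaf's
majority severity.  Rules are scored on the induction dataset itself:

* **support** ``S`` — fraction of all records matching both the antecedent
  and the consequent; a record matches a condition only when the variable
  is observed and equal (missing never matches);
* **probability** ``Pr`` — ``P(B | A) = P(A, B) / P(A)`` on the same
  matching convention, so ``Pr >= S`` always.

Selection keeps rules with a fatal consequent whose probability and support
clear the configured thresholds (defaults 10% and 0.1%, chosen for heavily
imbalanced data), collapses duplicate antecedents and sorts by probability.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import AccidentDataset, FATAL, SLIGHT
from .tree import CredalDecisionTreeClassifier, TreeNode, iter_leaves

__all__ = [
    "DecisionRule",
    "SelectionThresholds",
    "extract_rules",
    "compute_support",
    "compute_probability",
    "evaluate_rules",
    "apply_thresholds",
    "select_rules",
    "rules_to_frame",
    "write_rule_table",
    "read_rule_table",
    "reference_rule_stats",
]

_CO = {SLIGHT: "SI", FATAL: "FI"}
_CO_INV = {v: k for k, v in _CO.items()}


@dataclass(frozen=True)
class DecisionRule:
    """``IF antecedent THEN consequent`` with optional S / Pr scores."""

    antecedent: tuple[tuple[str, int], ...]
    consequent: int
    support: float | None = None
    probability: float | None = None

    def __post_init__(self) -> None:
        names = [v for v, _ in self.antecedent]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate antecedent variable in {self.antecedent}")
        if self.consequent not in (SLIGHT, FATAL):
            raise ValueError(f"bad consequent {self.consequent}")
        object.__setattr__(self, "antecedent", tuple(sorted(self.antecedent)))

    @property
    def key(self):
        return (self.antecedent, self.consequent)

    def with_scores(self, support: float, probability: float) -> "DecisionRule":
        return DecisionRule(self.antecedent, self.consequent, support, probability)

    def __str__(self) -> str:
        conds = " AND ".join(f"{v} = {c}" for v, c in self.antecedent)
        return f"IF {conds} THEN {_CO[self.consequent]}"


@dataclass(frozen=True)
class SelectionThresholds:
    """Minimum probability / support and the consequent of interest."""

    min_probability: float = 0.10
    min_support: float = 0.001
    consequent_filter: int = FATAL

    def __post_init__(self) -> None:
        for name in ("min_probability", "min_support"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def extract_rules(tree) -> list[DecisionRule]:
    """One unscored rule per leaf; single-leaf (empty-path) trees yield none."""
    if isinstance(tree, CredalDecisionTreeClassifier):
        if getattr(tree, "is_empty_", False) or tree.tree_ is None:
            return []
        root = tree.tree_
    elif isinstance(tree, TreeNode):
        root = tree
    elif tree is None:
        return []
    else:
        raise TypeError(f"cannot extract rules from {type(tree)!r}")
    out = []
    for path, leaf in iter_leaves(root):
        if path:
            out.append(DecisionRule(tuple(path), leaf.leaf_class))
    return out


class _MatchIndex:
    """Bit-packed condition masks for fast support counting."""

    def __init__(self, dataset: AccidentDataset):
        self.n = dataset.n
        self._packed: dict[tuple[str, int], np.ndarray] = {}
        self._frame = dataset.frame
        self.fatal = np.packbits((dataset.severity == FATAL).astype(np.uint8))
        self.slight = np.packbits((dataset.severity == SLIGHT).astype(np.uint8))

    def condition(self, var: str, value: int) -> np.ndarray:
        key = (var, value)
        if key not in self._packed:
            if var not in self._frame.columns:
                raise KeyError(var)
            mask = (self._frame[var] == value).fillna(False).to_numpy(dtype=bool)
            self._packed[key] = np.packbits(mask.astype(np.uint8))
        return self._packed[key]

    def counts(self, rule: DecisionRule) -> tuple[int, int]:
        """(antecedent matches, antecedent-and-consequent matches)."""
        m = None
        for var, value in rule.antecedent:
            cond = self.condition(var, value)
            m = cond if m is None else (m & cond)
        if m is None:  # empty antecedent matches everything
            n_a = self.n
            co = self.fatal if rule.consequent == FATAL else self.slight
            return n_a, int(np.bitwise_count(co).sum())
        n_a = int(np.bitwise_count(m).sum())
        co = self.fatal if rule.consequent == FATAL else self.slight
        n_ab = int(np.bitwise_count(m & co).sum())
        return n_a, n_ab


def compute_support(rule: DecisionRule, dataset: AccidentDataset) -> float:
    """Fraction of records matching antecedent and consequent."""
    if dataset.n == 0:
        raise ValueError("empty dataset: support undefined")
    _, n_ab = _MatchIndex(dataset).counts(rule)
    return n_ab / dataset.n


def compute_probability(rule: DecisionRule, dataset: AccidentDataset) -> float:
    """``P(consequent | antecedent)``; undefined when nothing matches A."""
    n_a, n_ab = _MatchIndex(dataset).counts(rule)
    if n_a == 0:
        raise ValueError("no records match the antecedent: probability undefined")
    return n_ab / n_a


def evaluate_rules(
    rules: list[DecisionRule], dataset: AccidentDataset
) -> list[DecisionRule]:
    """Attach S and Pr to every rule; rules matching no record are dropped."""
    if dataset.n == 0:
        raise ValueError("empty dataset")
    index = _MatchIndex(dataset)
    out = []
    for rule in rules:
        n_a, n_ab = index.counts(rule)
        if n_a == 0:
            continue
        out.append(rule.with_scores(n_ab / dataset.n, n_ab / n_a))
    return out


def apply_thresholds(
    rules: list[DecisionRule], thresholds: SelectionThresholds | None = None
) -> list[DecisionRule]:
    """Keep scored rules with the target consequent clearing both thresholds."""
    thresholds = thresholds or SelectionThresholds()
    eps = 1e-12
    return [
        r
        for r in rules
        if r.consequent == thresholds.consequent_filter
        and r.probability is not None
        and r.support is not None
        and r.probability >= thresholds.min_probability - eps
        and r.support >= thresholds.min_support - eps
    ]


def _sort_key(rule: DecisionRule):
    return (-rule.probability, -rule.support, rule.antecedent)


def dedupe_rules(rules: list[DecisionRule]) -> list[DecisionRule]:
    seen: dict = {}
    for r in rules:
        seen.setdefault(r.key, r)
    return list(seen.values())


def select_rules(
    rules: list[DecisionRule],
    dataset: AccidentDataset,
    thresholds: SelectionThresholds | None = None,
) -> list[DecisionRule]:
    """Score, filter, deduplicate and sort a pooled rule set.

    Sorted by probability descending, ties by support descending, then by
    antecedent lexicographic order — fully deterministic.
    """
    thresholds = thresholds or SelectionThresholds()
    scored = evaluate_rules(dedupe_rules(rules), dataset)
    kept = apply_thresholds(scored, thresholds)
    return sorted(kept, key=_sort_key)


# ---------------------------------------------------------------------------
# rule-table I/O: columns NR, A1..A4, Co, S, Pr


def rules_to_frame(rules: list[DecisionRule], max_conditions: int = 4) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(rules, start=1):
        conds = [f"{v} = {c}" for v, c in r.antecedent]
        conds += [""] * (max_conditions - len(conds))
        rows.append(
            {
                "NR": i,
                **{f"A{j + 1}": conds[j] for j in range(max_conditions)},
                "Co": _CO[r.consequent],
                "S": f"{100 * r.support:.4f}%" if r.support is not None else "",
                "Pr": f"{100 * r.probability:.2f}%" if r.probability is not None else "",
            }
        )
    cols = ["NR"] + [f"A{j + 1}" for j in range(max_conditions)] + ["Co", "S", "Pr"]
    return pd.DataFrame(rows, columns=cols)


def write_rule_table(rules: list[DecisionRule], path) -> None:
    rules_to_frame(rules).to_csv(path, index=False)


def _parse_condition(text: str) -> tuple[str, int] | None:
    text = str(text).strip()
    if not text or text.lower() == "nan":
        return None
    var, _, val = text.partition("=")
    return var.strip(), int(val.strip())


def _parse_pct(text) -> float | None:
    text = str(text).strip().rstrip("%")
    if not text or text.lower() == "nan":
        return None
    return float(text) / 100.0


def read_rule_table(path) -> list[DecisionRule]:
    frame = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, row in frame.iterrows():
        conds = []
        for col in ("A1", "A2", "A3", "A4"):
            if col in row:
                parsed = _parse_condition(row[col])
                if parsed:
                    conds.append(parsed)
        out.append(
            DecisionRule(
                tuple(conds),
                _CO_INV[row["Co"].strip()],
                _parse_pct(row.get("S", "")),
                _parse_pct(row.get("Pr", "")),
            )
        )
    return out


def reference_rule_stats() -> pd.DataFrame:
    """Previously reported fatal-injury rules for the Spanish DGT
    novice-driver urban cohort (intersection and non-intersection tables),
    with their published support and probability percentages.  Used as a
    fixture for the selection thresholds, not as data to reproduce."""
    ref = importlib.resources.files("irnv.data").joinpath("reference_rule_stats.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def reference_rules() -> list[DecisionRule]:
    """The reference table as scored :class:`DecisionRule` objects."""
    frame = reference_rule_stats()
    out = []
    for _, row in frame.iterrows():
        conds = [
            _parse_condition(row[c])
            for c in ("A1", "A2", "A3", "A4")
            if str(row[c]).strip()
        ]
        out.append(
            DecisionRule(
                tuple(c for c in conds if c),
                FATAL,
                _parse_pct(row["S"]),
                _parse_pct(row["Pr"]),
            )
        )
    return out
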