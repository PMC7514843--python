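"""Synthetic DGT-like accident data with planted fatal-injury rules.

The generator emulates the *preprocessed* novice-driver urban cohort: about
30,000 categorical records on the 22-variable schema, heavy class imbalance
(base fatal rate 7%, below the <10% observed), per-variable missingness,
and an intersection/non-intersection indicator.  Default per-variable
marginals and missingness rates are rounded from the published per-value
instance counts of the cohort's variable table — they are editable defaults
that reproduce the qualitative skews (e.g. road surface dominated by
"dry and clean", drivers mostly men), not fitted values.

Ground-truth structure is *planted*: for each :class:`PlantedRule` a chosen
share of records is overwritten to match the rule's antecedent exactly and
their severity is redrawn with the rule's fatal probability; everything else
is conditionally independent of the class.  A truth log records planted
memberships and realized rates so recovery by the mining pipeline can be
checked without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    INTERSECTION,
    INTERSECTION_INDICATOR,
    NON_INTERSECTION,
    AccidentDataset,
    CategoricalVariableSpec,
    FATAL,
    SLIGHT,
    indicator_spec,
    predictor_specs,
)

__all__ = [
    "PlantedRule",
    "SyntheticConfig",
    "generate_dataset",
    "make_fixture",
    "DEFAULT_MARGINALS",
    "DEFAULT_MISSINGNESS",
]

# per-value marginal probabilities over observed records (normalised at use)
DEFAULT_MARGINALS: dict[str, dict[int, float]] = {
    "SE": {1: 0.24, 2: 0.25, 3: 0.24, 4: 0.27},
    "F_T": {1: 0.08, 2: 0.25, 3: 0.38, 4: 0.29},
    "S_W": {1: 0.14, 2: 0.17, 3: 0.45, 4: 0.24},
    "I_L": {1: 0.12, 2: 0.88},
    "TR_N_INT": {1: 0.92, 2: 0.08},
    "I_T": {1: 0.235, 2: 0.596, 3: 0.152, 4: 0.017},
    "PR": {1: 0.002, 2: 0.277, 3: 0.239, 4: 0.303, 5: 0.102, 6: 0.050, 7: 0.027},
    "RO_SU": {1: 0.905, 2: 0.002, 3: 0.085, 4: 0.001, 5: 0.007},
    "LUM": {1: 0.657, 2: 0.043, 3: 0.298, 4: 0.002},
    "WE_CO": {1: 0.925, 2: 0.002, 3: 0.063, 4: 0.010},
    "RES_VIS": {1: 0.911, 2: 0.004, 3: 0.008, 4: 0.008, 5: 0.006, 6: 0.005, 7: 0.058},
    "PAV": {0: 0.974, 1: 0.026},
    "ACT_TY": {1: 0.837, 2: 0.066, 3: 0.017, 4: 0.050, 5: 0.030},
    "AG_FR": {1: 0.246, 2: 0.356, 3: 0.380, 4: 0.018},
    "SEX": {1: 0.738, 2: 0.262},
    "MAN": {1: 0.262, 2: 0.018, 3: 0.084, 4: 0.025, 5: 0.077, 6: 0.003, 7: 0.013, 8: 0.518},
    "SP_IN": {1: 0.043, 2: 0.001, 3: 0.956},
    "DR_INFR": {0: 0.523, 1: 0.124, 2: 0.006, 3: 0.006, 4: 0.017, 5: 0.324},
    "OL_VEH": {1: 0.166, 2: 0.834},
    "VEH_TY": {1: 0.364, 2: 0.618, 3: 0.014, 4: 0.004},
    "AN": {1: 0.990, 2: 0.010},
    "O_L": {1: 0.687, 2: 0.145, 3: 0.168},
}

# fraction of applicable records with the variable unrecorded
DEFAULT_MISSINGNESS: dict[str, float] = {
    "TR_N_INT": 0.18,
    "PR": 0.60,
    "RO_SU": 0.07,
    "WE_CO": 0.08,
    "RES_VIS": 0.75,
    "PAV": 0.01,
    "SEX": 0.001,
    "MAN": 0.045,
    "SP_IN": 0.29,
    "DR_INFR": 0.11,
    "OL_VEH": 0.46,
    "VEH_TY": 0.002,
    "AN": 0.18,
}


@dataclass(frozen=True)
class PlantedRule:
    """An antecedent -> fatal association planted into the generated data."""

    antecedent: tuple[tuple[str, int], ...]
    fatal_probability: float
    target_prevalence: float

    def __post_init__(self) -> None:
        names = [v for v, _ in self.antecedent]
        if not names or len(set(names)) != len(names):
            raise ValueError(f"antecedent variables must be distinct and non-empty: {names}")
        if not 0 < self.fatal_probability <= 1:
            raise ValueError("fatal_probability must lie in (0, 1]")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")


@dataclass
class SyntheticConfig:
    """Study-condition settings for one generated dataset."""

    n_records: int = 30_000
    base_fatal_rate: float = 0.07
    missingness: dict[str, float] | None = None
    planted: tuple[PlantedRule, ...] = ()
    intersection_fraction: float = 0.5
    non_cohort_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if not 0 < self.base_fatal_rate < 0.10:
            raise ValueError("base_fatal_rate must be below the 10% imbalance bound")
        if not 0 < self.intersection_fraction < 1:
            raise ValueError("intersection_fraction must lie in (0, 1)")
        assigned: dict[str, int] = {}
        for rule in self.planted:
            for var, val in rule.antecedent:
                if assigned.setdefault(var, val) != val:
                    raise ValueError(
                        f"conflicting planted antecedents on variable {var!r}"
                    )


def _applicable(spec: CategoricalVariableSpec, at_intersection: np.ndarray) -> np.ndarray:
    if spec.applies_to == INTERSECTION:
        return at_intersection
    if spec.applies_to == NON_INTERSECTION:
        return ~at_intersection
    return np.ones_like(at_intersection)


def generate_dataset(config: SyntheticConfig) -> tuple[AccidentDataset, dict]:
    """Generate one dataset plus its truth log.

    Draw order (fixed for determinism): intersection indicator, per-variable
    codes, planted overwrites, severity, missingness.  Missingness is never
    applied to the severity or the indicator.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    specs = {v.name: v for v in predictor_specs()}
    missingness = DEFAULT_MISSINGNESS if config.missingness is None else config.missingness

    at_inter = rng.random(n) < config.intersection_fraction
    columns: dict[str, np.ndarray] = {}
    for name, spec in specs.items():
        marg = DEFAULT_MARGINALS[name]
        values = np.array(list(marg), dtype=np.int64)
        probs = np.array(list(marg.values()), dtype=float)
        probs = probs / probs.sum()
        col = np.full(n, -1, dtype=np.int64)
        mask = _applicable(spec, at_inter)
        col[mask] = rng.choice(values, size=int(mask.sum()), p=probs)
        columns[name] = col

    # plant antecedents on disjoint record sets drawn from applicable rows
    taken = np.zeros(n, dtype=bool)
    planted_log = []
    planted_rows_by_rule: list[np.ndarray] = []
    for rule in config.planted:
        eligible = ~taken
        for var, val in rule.antecedent:
            spec = specs.get(var)
            if spec is None:
                raise ValueError(f"planted rule uses unknown variable {var!r}")
            if val not in spec.values:
                raise ValueError(f"planted value {var}={val} outside the value set")
            eligible &= _applicable(spec, at_inter)
        n_plant = int(round(rule.target_prevalence * n))
        pool = np.nonzero(eligible)[0]
        if len(pool) < n_plant:
            raise ValueError(
                f"only {len(pool)} records eligible for planted rule {rule.antecedent}"
            )
        rows = rng.choice(pool, size=n_plant, replace=False)
        rows.sort()
        taken[rows] = True
        for var, val in rule.antecedent:
            columns[var][rows] = val
        planted_rows_by_rule.append(rows)

    severity = np.where(rng.random(n) < config.base_fatal_rate, FATAL, SLIGHT)
    for rule, rows in zip(config.planted, planted_rows_by_rule):
        severity[rows] = np.where(
            rng.random(len(rows)) < rule.fatal_probability, FATAL, SLIGHT
        )

    for rule, rows in zip(config.planted, planted_rows_by_rule):
        planted_log.append(
            {
                "antecedent": [[v, int(c)] for v, c in rule.antecedent],
                "fatal_probability": rule.fatal_probability,
                "target_prevalence": rule.target_prevalence,
                "rows": rows.tolist(),
                "n_planted": int(len(rows)),
                "realized_fatal_rate": float((severity[rows] == FATAL).mean())
                if len(rows)
                else None,
            }
        )

    realized_missing = {}
    for name, spec in specs.items():
        rate = float(missingness.get(name, 0.0))
        if rate > 0:
            if not spec.missing_allowed:
                raise ValueError(f"{name} does not allow missing values")
            mask = (columns[name] >= 0) & (rng.random(n) < rate)
            columns[name][mask] = -1
        app = _applicable(spec, at_inter)
        realized_missing[name] = float((columns[name][app] < 0).mean()) if app.any() else 0.0

    frame = pd.DataFrame(
        {name: pd.array(col, dtype="Int64") for name, col in columns.items()}
    )
    frame = frame.mask(frame == -1)
    frame[INTERSECTION_INDICATOR] = pd.array(at_inter.astype(np.int64), dtype="Int64")

    variables = list(predictor_specs()) + [indicator_spec()]
    n_cohort = n
    if config.non_cohort_fraction > 0:
        # raw-schema mode: emit cohort columns with some non-cohort records
        # (experienced drivers or non-urban zones) for the filtering stage
        non = rng.random(n) < config.non_cohort_fraction
        experienced = non & (rng.random(n) < 0.5)
        driver_type = np.where(experienced, 2, 1)
        zone = np.where(non & ~experienced, 2, 1)
        frame["driver_type"] = pd.array(driver_type, dtype="Int64")
        frame["zone"] = pd.array(zone, dtype="Int64")
        variables = variables + [
            CategoricalVariableSpec("driver_type", (1, 2), {1: "novice", 2: "experienced"}),
            CategoricalVariableSpec("zone", (1, 2), {1: "urban", 2: "non-urban"}),
        ]
        n_cohort = int((~non).sum())
    dataset = AccidentDataset(
        variables=variables,
        frame=frame[[v.name for v in variables]],
        severity=severity,
        weights=np.ones(n),
    )

    truth = {
        "seed": config.seed,
        "n_records": n,
        "base_fatal_rate": config.base_fatal_rate,
        "realized_base_fatal_rate": float((severity[~taken] == FATAL).mean()),
        "realized_fatal_rate": float((severity == FATAL).mean()),
        "n_intersection": int(at_inter.sum()),
        "n_non_intersection": int((~at_inter).sum()),
        "n_cohort": n_cohort,
        "realized_missingness": realized_missing,
        "planted": planted_log,
    }
    return dataset, truth


def write_truth_log(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# hand-built unit-test fixtures


def _tiny(frame_cols: dict[str, list], severity: list[int]) -> AccidentDataset:
    variables = [
        CategoricalVariableSpec(
            name=k, values=tuple(sorted({v for v in col if v is not None}))
        )
        for k, col in frame_cols.items()
    ]
    frame = pd.DataFrame({k: pd.array(v, dtype="Int64") for k, v in frame_cols.items()})
    return AccidentDataset(
        variables=variables,
        frame=frame,
        severity=np.asarray(severity),
        weights=np.ones(len(severity)),
    )


def make_fixture(name: str) -> AccidentDataset:
    """Catalogued hand-built datasets used across the test suite.

    ``iig_negative``
        10 records, class counts (8, 2); a balanced binary ``X`` whose two
        branches both count (4, 1).  Info-gain is exactly zero while the
        imprecise info-gain (s=1) is negative: the credal intervals widen
        on the 5-record branches relative to the 10-record margin.
    ``pure_split``
        ``X1`` copies the class exactly (12 records, 6/6).
    ``forced_root``
        12 records; ``X1`` separates the class perfectly, ``X2`` is
        independent noise, so a tree rooted at ``X2`` must recover ``X1``
        at the second level.
    ``support_toy``
        10 records; 4 match the antecedent (X1=1, X2=1) of which 3 are
        fatal: support 0.30, probability 0.75.
    """
    if name == "iig_negative":
        return _tiny(
            {"X": [1] * 5 + [2] * 5},
            [SLIGHT] * 4 + [FATAL] + [SLIGHT] * 4 + [FATAL],
        )
    if name == "pure_split":
        return _tiny(
            {"X1": [1] * 6 + [2] * 6},
            [SLIGHT] * 6 + [FATAL] * 6,
        )
    if name == "forced_root":
        x1 = [1, 1, 1, 2, 2, 2] * 2
        x2 = [1] * 6 + [2] * 6
        sev = [SLIGHT if v == 1 else FATAL for v in x1]
        return _tiny({"X1": x1, "X2": x2}, sev)
    if name == "support_toy":
        x1 = [1, 1, 1, 1, 1, 2, 2, 2, 2, 2]
        x2 = [1, 1, 1, 1, 2, 1, 2, 2, 2, 2]
        sev = [FATAL, FATAL, FATAL, SLIGHT, SLIGHT, SLIGHT, SLIGHT, SLIGHT, SLIGHT, SLIGHT]
        return _tiny({"X1": x1, "X2": x2}, sev)
    raise KeyError(f"unknown fixture {name!r}")
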