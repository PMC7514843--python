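"""Categorical accident schema, cohort filtering and the intersection split.

The analysed records follow the preprocessed Spanish DGT (Direccion General
de Trafico) accident schema: 22 categorical predictors plus a binary severity
class ``SEV`` (1 = slight injury, 2 = fatal injury, i.e. killed or seriously
injured within 30 days).  Two of the predictors only apply to accidents at
intersections (``I_T``, ``PR``) and one only away from intersections
(``TR_N_INT``); the two partitions are analysed separately because
intersection accidents have different characteristics.

Records are held in an :class:`AccidentDataset`: a pandas frame of integer
codes (nullable ``Int64``; ``NA`` is the single reserved missing marker),
a severity vector and per-record non-negative weights.  Files are plain
comma-separated text with a header row of variable codes and empty cells for
missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SLIGHT = 1
FATAL = 2

#: ``applies_to`` states
BOTH = "both"
INTERSECTION = "intersection"
NON_INTERSECTION = "non_intersection"

#: name of the intersection-indicator column emitted by the generator
INTERSECTION_INDICATOR = "INT"

#: cohort columns consumed (and dropped) by :func:`filter_cohort`
DRIVER_TYPE = "driver_type"
ZONE = "zone"
NOVICE = 1  # three or fewer years of licensure
URBAN = 1


@dataclass(frozen=True)
class CategoricalVariableSpec:
    """A finite-valued categorical variable of the accident schema."""

    name: str
    values: tuple[int, ...]
    labels: dict[int, str] = field(default_factory=dict)
    applies_to: str = BOTH
    missing_allowed: bool = False

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"{self.name}: empty value set")
        if len(set(self.values)) != len(self.values):
            raise ValueError(f"{self.name}: duplicate codes")
        if self.applies_to not in (BOTH, INTERSECTION, NON_INTERSECTION):
            raise ValueError(f"{self.name}: bad applies_to {self.applies_to!r}")


def _spec(name, labels, applies_to=BOTH, missing_allowed=False):
    return CategoricalVariableSpec(
        name=name,
        values=tuple(labels),
        labels=dict(labels),
        applies_to=applies_to,
        missing_allowed=missing_allowed,
    )


def table1_schema() -> list[CategoricalVariableSpec]:
    """The 22 predictor variables plus ``SEV`` of the preprocessed schema.

    Value codes and meanings follow the published variable table of the
    novice-driver urban-accident study; ``I_T`` and ``PR`` are recorded only
    at intersections, ``TR_N_INT`` only away from them.
    """
    return [
        _spec("SE", {1: "winter", 2: "spring", 3: "summer", 4: "autumn"}),
        _spec("F_T", {1: "0:01-6:00", 2: "6:01-12:00", 3: "12:01-18:00", 4: "18:01-0:00"}),
        _spec("S_W", {1: "Monday", 2: "Friday", 3: "Tuesday-Thursday", 4: "weekend"}),
        _spec("I_L", {1: "one vehicle", 2: "more than one vehicle"}),
        _spec(
            "TR_N_INT",
            {1: "straight line", 2: "curve"},
            applies_to=NON_INTERSECTION,
            missing_allowed=True,
        ),
        _spec(
            "I_T",
            {1: "T or X", 2: "X or +", 3: "roundabout", 4: "exit or entrance link"},
            applies_to=INTERSECTION,
        ),
        _spec(
            "PR",
            {
                1: "traffic officer directions",
                2: "semaphore",
                3: "stop signal",
                4: "pedestrian crossing signal",
                5: "road signs",
                6: "general rule",
                7: "other",
            },
            applies_to=INTERSECTION,
            missing_allowed=True,
        ),
        _spec(
            "RO_SU",
            {1: "dry and clean", 2: "wet", 3: "snowy/frozen", 4: "oily", 5: "other"},
            missing_allowed=True,
        ),
        _spec(
            "LUM",
            {
                1: "broad daylight",
                2: "twilight",
                3: "night, sufficient illumination",
                4: "night, insufficient illumination",
            },
        ),
        _spec(
            "WE_CO",
            {1: "good", 2: "fog", 3: "light rain", 4: "adverse"},
            missing_allowed=True,
        ),
        _spec(
            "RES_VIS",
            {
                1: "no restrictions",
                2: "buildings",
                3: "land configuration",
                4: "weather",
                5: "glare",
                6: "dust",
                7: "other",
            },
            missing_allowed=True,
        ),
        _spec("PAV", {0: "pavements", 1: "no pavements"}, missing_allowed=True),
        _spec(
            "ACT_TY",
            {
                1: "collision",
                2: "running over a pedestrian",
                3: "overturn",
                4: "road exit",
                5: "other",
            },
        ),
        _spec("AG_FR", {1: "<=20", 2: "21-27", 3: "28-59", 4: "60+"}),
        _spec("SEX", {1: "man", 2: "woman"}, missing_allowed=True),
        _spec(
            "MAN",
            {
                1: "following the road",
                2: "overtaking",
                3: "turning",
                4: "entering from another road",
                5: "crossing an intersection",
                6: "reversing",
                7: "abrupt gear shift",
                8: "other maneuver",
            },
            missing_allowed=True,
        ),
        _spec(
            "SP_IN",
            {1: "too fast", 2: "too slow", 3: "appropriate speed"},
            missing_allowed=True,
        ),
        _spec(
            "DR_INFR",
            {
                0: "no violation",
                1: "failed to observe a traffic sign",
                2: "wrong side of the road",
                3: "forbidden overtaking",
                4: "failed to keep security distance",
                5: "other infraction",
            },
            missing_allowed=True,
        ),
        _spec("OL_VEH", {1: "<=2 years old", 2: ">=3 years old"}, missing_allowed=True),
        _spec(
            "VEH_TY",
            {1: "motorbike", 2: "car", 3: "heavy vehicle", 4: "other"},
            missing_allowed=True,
        ),
        _spec("AN", {1: "no anomaly", 2: "anomaly"}, missing_allowed=True),
        _spec("O_L", {1: "only the driver", 2: "two", 3: "more than two"}),
        _spec("SEV", {SLIGHT: "slight injury", FATAL: "fatal injury"}),
    ]


def predictor_specs(
    schema: list[CategoricalVariableSpec] | None = None,
) -> list[CategoricalVariableSpec]:
    """Schema specs without the class variable ``SEV``."""
    schema = table1_schema() if schema is None else schema
    return [v for v in schema if v.name != "SEV"]


@dataclass(frozen=True)
class RawSeverityCounts:
    """Per-accident casualty counts from which the severity class derives."""

    killed: int
    serious: int
    slight: int = 0

    def __post_init__(self) -> None:
        for name in ("killed", "serious", "slight"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


def derive_severity(counts: RawSeverityCounts) -> int:
    """Binary severity: fatal (2) iff anyone was killed or seriously injured."""
    return FATAL if counts.killed > 0 or counts.serious > 0 else SLIGHT


class SchemaError(ValueError):
    """A record violates the categorical schema; carries per-row detail."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems[:20]))


@dataclass
class AccidentDataset:
    """Weighted categorical records with a binary severity class.

    ``frame`` holds one nullable-``Int64`` column per predictor (``pd.NA`` is
    the single missing marker); ``severity`` and ``weights`` are aligned
    per-row arrays.
    """

    variables: list[CategoricalVariableSpec]
    frame: pd.DataFrame
    severity: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        sev = np.asarray(self.severity)
        if pd.isna(sev).any():
            raise SchemaError(["severity contains missing values"])
        self.severity = sev.astype(np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        variables: list[CategoricalVariableSpec] | None = None,
        weights: np.ndarray | None = None,
    ) -> "AccidentDataset":
        """Build from a frame that includes a ``SEV`` column."""
        if "SEV" not in frame.columns:
            raise SchemaError(["missing SEV column"])
        if variables is None:
            variables = [v for v in table1_schema() if v.name in frame.columns]
        names = [v.name for v in variables if v.name != "SEV"]
        sev = frame["SEV"].to_numpy()
        pred = frame[names].astype("Int64")
        if weights is None:
            weights = np.ones(len(frame))
        return cls(
            variables=[v for v in variables if v.name != "SEV"],
            frame=pred.reset_index(drop=True),
            severity=sev,
            weights=np.asarray(weights, dtype=float),
        )

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        names = [v.name for v in self.variables]
        if list(self.frame.columns) != names:
            problems.append(f"columns {list(self.frame.columns)} != schema {names}")
        n = len(self.frame)
        if len(self.severity) != n or len(self.weights) != n:
            problems.append("severity/weights length mismatch")
        if pd.isna(self.severity).any():
            problems.append("severity contains missing values")
        bad_sev = ~np.isin(self.severity, (SLIGHT, FATAL))
        if bad_sev.any():
            problems.append(f"invalid severity at rows {np.nonzero(bad_sev)[0][:10].tolist()}")
        if (self.weights < 0).any():
            problems.append("negative weights")
        if n and self.weights.sum() <= 0:
            problems.append("total weight is zero")
        for spec in self.variables:
            col = self.frame[spec.name]
            obs = col.dropna()
            bad = ~obs.isin(spec.values)
            if bad.any():
                rows = obs.index[bad][:10].tolist()
                problems.append(f"{spec.name}: codes outside value set at rows {rows}")
        if problems:
            raise SchemaError(problems)

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def codes(self) -> np.ndarray:
        """Integer code matrix with ``-1`` as the missing sentinel."""
        out = np.full((self.n, len(self.variables)), -1, dtype=np.int16)
        for j, name in enumerate(self.variable_names):
            col = self.frame[name]
            out[:, j] = col.fillna(-1).to_numpy(dtype=np.int64)
        return out

    def subset(self, mask: np.ndarray) -> "AccidentDataset":
        mask = np.asarray(mask, dtype=bool)
        return AccidentDataset(
            variables=list(self.variables),
            frame=self.frame.loc[mask].reset_index(drop=True),
            severity=self.severity[mask],
            weights=self.weights[mask],
        )

    def drop_variables(self, names: set[str]) -> "AccidentDataset":
        keep = [v for v in self.variables if v.name not in names]
        return AccidentDataset(
            variables=keep,
            frame=self.frame[[v.name for v in keep]],
            severity=self.severity,
            weights=self.weights,
        )

    # -- delimited I/O -----------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["SEV"] = self.severity
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls, path, variables: list[CategoricalVariableSpec] | None = None
    ) -> "AccidentDataset":
        frame = pd.read_csv(path, dtype="Int64")
        if variables is None:
            known = {v.name: v for v in table1_schema()}
            variables = [known[c] for c in frame.columns if c in known and c != "SEV"]
            extra = [c for c in frame.columns if c not in known and c != "SEV"]
            for c in extra:
                obs = frame[c].dropna().unique()
                variables.append(
                    CategoricalVariableSpec(
                        name=c, values=tuple(sorted(int(v) for v in obs) or (0,)),
                        missing_allowed=True,
                    )
                )
        return cls.from_frame(frame, variables=variables)


def save_schema(schema: list[CategoricalVariableSpec], path) -> None:
    """Write a YAML schema file for user-supplied dialects."""
    doc = [
        {
            "name": v.name,
            "values": list(v.values),
            "labels": {int(k): s for k, s in v.labels.items()},
            "applies_to": v.applies_to,
            "missing_allowed": v.missing_allowed,
        }
        for v in schema
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_schema(path) -> list[CategoricalVariableSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [
        CategoricalVariableSpec(
            name=d["name"],
            values=tuple(int(v) for v in d["values"]),
            labels={int(k): s for k, s in d.get("labels", {}).items()},
            applies_to=d.get("applies_to", BOTH),
            missing_allowed=bool(d.get("missing_allowed", False)),
        )
        for d in doc
    ]


def filter_cohort(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep novice-driver (``driver_type`` = 1) urban (``zone`` = 1) records.

    The two cohort columns are dropped from the result.  Records with a
    missing ``driver_type`` are excluded with a logged warning.
    """
    for col in (DRIVER_TYPE, ZONE):
        if col not in frame.columns:
            raise SchemaError([f"missing cohort column {col!r}"])
    missing = frame[DRIVER_TYPE].isna()
    if missing.any():
        logger.warning(
            "excluding %d records with missing %s", int(missing.sum()), DRIVER_TYPE
        )
    keep = (~missing) & (frame[DRIVER_TYPE] == NOVICE) & (frame[ZONE] == URBAN)
    return frame.loc[keep].drop(columns=[DRIVER_TYPE, ZONE]).reset_index(drop=True)


def split_by_intersection(
    dataset: AccidentDataset,
) -> tuple[AccidentDataset, AccidentDataset]:
    """Exhaustive, disjoint partition on the intersection indicator.

    The intersection partition drops ``TR_N_INT`` (and the indicator); the
    non-intersection partition drops ``I_T`` and ``PR``.  Records with a
    missing indicator are excluded with a logged warning.
    """
    if INTERSECTION_INDICATOR not in dataset.variable_names:
        raise SchemaError([f"missing indicator {INTERSECTION_INDICATOR!r}"])
    ind = dataset.frame[INTERSECTION_INDICATOR]
    missing = ind.isna().to_numpy()
    if missing.any():
        logger.warning(
            "excluding %d records with missing intersection indicator",
            int(missing.sum()),
        )
    at = (ind == 1).to_numpy() & ~missing
    away = (ind == 0).to_numpy() & ~missing
    inter = dataset.subset(at).drop_variables({INTERSECTION_INDICATOR, "TR_N_INT"})
    non_inter = dataset.subset(away).drop_variables(
        {INTERSECTION_INDICATOR, "I_T", "PR"}
    )
    return inter, non_inter


def indicator_spec() -> CategoricalVariableSpec:
    """Spec for the intersection-indicator column the generator emits."""
    return _spec(
        INTERSECTION_INDICATOR, {0: "not at an intersection", 1: "at an intersection"}
    )
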