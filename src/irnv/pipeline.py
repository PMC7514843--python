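"""End-to-end driver: data in, per-partition rule tables out.

A run loads a delimited dataset (or generates a synthetic one), applies the
novice-urban cohort filter when raw cohort columns are present, partitions
the records into intersection and non-intersection accidents, mines each
partition with the root-variation ensemble, and writes one selected rule
table per partition plus a structured run report.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import schema as _schema
from .ensemble import IRNVRuleMiner
from .rules import SelectionThresholds, write_rule_table
from .schema import AccidentDataset, filter_cohort, split_by_intersection
from .synthetic import PlantedRule, SyntheticConfig, generate_dataset, write_truth_log
from .tree import CRITERIA

__all__ = ["PipelineConfig", "PipelineRun", "run_pipeline", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    outdir: str = "irnv_out"
    criteria: tuple[str, ...] = CRITERIA
    s: float = 1.0
    max_depth: int = 4
    min_leaf_weight: float = 2.0
    min_probability: float = 0.10
    min_support: float = 0.001
    seed: int = 0
    write_dataset: bool = False


@dataclass
class PipelineRun:
    """Summary of one pipeline execution."""

    config: PipelineConfig
    n_records: int
    n_intersection: int
    n_non_intersection: int
    tree_counts: dict[str, int]
    rule_counts_before: dict[str, int]
    rule_counts_after: dict[str, int]
    table_paths: dict[str, str]
    report_path: str
    miners: dict[str, IRNVRuleMiner] = field(default_factory=dict, repr=False)
    truth: dict | None = field(default=None, repr=False)
    recovered_planted: list = field(default_factory=list)


def _mine_partition(dataset: AccidentDataset, config: PipelineConfig) -> IRNVRuleMiner:
    miner = IRNVRuleMiner(
        criteria=tuple(config.criteria),
        s=config.s,
        max_depth=config.max_depth,
        min_leaf_weight=config.min_leaf_weight,
        min_probability=config.min_probability,
        min_support=config.min_support,
    )
    return miner.fit(dataset)


def _subset_matches(selected, planted_antecedent) -> list:
    """Selected rules whose antecedent is a subset of a planted antecedent."""
    planted = set(map(tuple, planted_antecedent))
    out = []
    for rule in selected:
        if rule.antecedent and set(rule.antecedent) <= planted:
            out.append(rule)
    return out


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.input_csv is not None:
        dataset = AccidentDataset.read_csv(config.input_csv)
    else:
        syn = config.synthetic or SyntheticConfig(seed=config.seed)
        dataset, truth = generate_dataset(syn)
        if config.write_dataset:
            dataset.to_csv(outdir / "dataset.csv")
        write_truth_log(truth, outdir / "truth.json")

    if _schema.DRIVER_TYPE in dataset.variable_names:
        frame = dataset.frame.copy()
        frame["SEV"] = dataset.severity
        frame = filter_cohort(frame)
        keep = [
            v
            for v in dataset.variables
            if v.name not in (_schema.DRIVER_TYPE, _schema.ZONE)
        ]
        dataset = AccidentDataset.from_frame(frame, variables=keep + [])

    inter, non_inter = split_by_intersection(dataset)
    partitions = {"intersection": inter, "non_intersection": non_inter}

    miners, table_paths = {}, {}
    tree_counts, before, after = {}, {}, {}
    for name, part in partitions.items():
        if part.n == 0:
            continue
        miner = _mine_partition(part, config)
        miners[name] = miner
        tree_counts[name] = miner.n_trees_
        before[name] = len(miner.candidate_rules_)
        after[name] = len(miner.rules_)
        path = outdir / f"rules_{name}.csv"
        write_rule_table(miner.rules_, path)
        table_paths[name] = str(path)

    recovered = []
    if truth:
        pooled = [r for m in miners.values() for r in m.rules_]
        for planted in truth["planted"]:
            matches = _subset_matches(pooled, planted["antecedent"])
            recovered.append(
                {
                    "planted_antecedent": planted["antecedent"],
                    "fatal_probability": planted["fatal_probability"],
                    "matches": [
                        {
                            "antecedent": list(map(list, r.antecedent)),
                            "support": r.support,
                            "probability": r.probability,
                        }
                        for r in sorted(
                            matches, key=lambda r: (-len(r.antecedent), -r.probability)
                        )
                    ],
                }
            )

    report_path = outdir / "report.json"
    report = {
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "seed": config.seed,
        "criteria": list(config.criteria),
        "s": config.s,
        "max_depth": config.max_depth,
        "min_leaf_weight": config.min_leaf_weight,
        "thresholds": {
            "min_probability": config.min_probability,
            "min_support": config.min_support,
        },
        "n_records": dataset.n,
        "partitions": {
            name: {
                "n_records": partitions[name].n,
                "n_predictors": len(partitions[name].variables),
                "trees_built": tree_counts.get(name, 0),
                "rules_before_selection": before.get(name, 0),
                "rules_after_selection": after.get(name, 0),
                "table": table_paths.get(name),
            }
            for name in partitions
        },
        "recovered_planted": recovered,
    }
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1)

    return PipelineRun(
        config=config,
        n_records=dataset.n,
        n_intersection=inter.n,
        n_non_intersection=non_inter.n,
        tree_counts=tree_counts,
        rule_counts_before=before,
        rule_counts_after=after,
        table_paths=table_paths,
        report_path=str(report_path),
        miners=miners,
        truth=truth,
        recovered_planted=recovered,
    )


def load_pipeline_config(path) -> PipelineConfig:
    """Read a YAML pipeline configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    syn = None
    if "synthetic" in doc:
        sd = dict(doc["synthetic"] or {})
        planted = tuple(
            PlantedRule(
                antecedent=tuple((str(v), int(c)) for v, c in p["antecedent"]),
                fatal_probability=float(p["fatal_probability"]),
                target_prevalence=float(p["target_prevalence"]),
            )
            for p in sd.pop("planted", [])
        )
        syn = SyntheticConfig(planted=planted, **sd)
    known = {
        k: doc[k]
        for k in (
            "input_csv",
            "outdir",
            "s",
            "max_depth",
            "min_leaf_weight",
            "min_probability",
            "min_support",
            "seed",
            "write_dataset",
        )
        if k in doc
    }
    if "criteria" in doc:
        known["criteria"] = tuple(doc["criteria"])
    return PipelineConfig(synthetic=syn, **known)
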