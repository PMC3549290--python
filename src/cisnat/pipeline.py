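"""End-to-end orchestration: detect -> network -> profile -> express -> report.

The run configuration carries every threshold the analysis uses (nothing is
hard-coded downstream), and the run log records record counts at each filter
step so narrative numbers like "candidates before/after biotype exclusion"
stay auditable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import io as cio
from .core import AnnotationSet, CisNatGroup, CisNatPair, SiRnaProfile, ValidationError
from .detect import (
    detect_candidate_pairs,
    enumerate_antisense_pairs,
    pairs_to_table,
    select_representatives,
)
from .expression import (
    coexpression_sets,
    classify_subgroup,
    domain_enrichment,
    fisher_exact_deg,
    pair_expression,
    stress_preferential,
)
from .network import build_groups, groups_to_table, split_one_to_one
from .reports import summarize_expression, summarize_pairs
from .sirna import build_profile, filter_small_rnas, profiles_to_table


@dataclass
class RunConfig:
    """Inputs, output directory and every analysis threshold."""

    gff3: str
    bed_by_condition: dict[str, str]
    expression_tsv: str
    out_dir: str
    control_condition: str
    domain_map: Optional[str] = None
    min_overlap: int = 25
    bias_fold_strong: float = 5.0
    bias_fold_weak: float = 2.0
    enrichment_threshold: float = 5.0
    exclusivity_min_unique: int = 5  # "more than five" unique reads
    deg_fc: float = 2.0
    deg_p: float = 1e-3
    subgroup_fc: float = 2.0
    epsilon: float = 0.1
    flank_bp: int = 1000
    smallrna_min_len: int = 18
    smallrna_max_len: int = 34

    def __post_init__(self) -> None:
        for name in (
            "min_overlap", "bias_fold_strong", "bias_fold_weak",
            "enrichment_threshold", "deg_fc", "deg_p", "subgroup_fc",
            "epsilon", "flank_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        if self.control_condition not in self.bed_by_condition:
            raise ValidationError(
                f"control condition {self.control_condition!r} has no BED input"
            )

    @property
    def conditions(self) -> list[str]:
        ordered = [self.control_condition]
        ordered += sorted(c for c in self.bed_by_condition if c != self.control_condition)
        return ordered


@dataclass
class RunResult:
    ann: AnnotationSet
    candidates: list[CisNatPair]
    pairs: list[CisNatPair]
    representatives: list[CisNatPair]
    groups: list[CisNatGroup]
    one_to_one: list[CisNatGroup]
    many_to_many: list[CisNatGroup]
    profiles: dict[tuple[str, str], SiRnaProfile]
    pair_expr: dict[tuple[str, str], object]
    expressed: dict[str, set[str]]
    coexpression: object
    subgroups: dict[tuple[str, str], str]
    degs: list[object]
    stress_flags: dict[str, dict[str, bool]]
    enrichment: Optional[pd.DataFrame]
    log: dict = field(default_factory=dict)


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis and write all reports under ``out_dir``."""
    log: dict = {"thresholds": {
        "min_overlap": config.min_overlap,
        "bias_fold_strong": config.bias_fold_strong,
        "bias_fold_weak": config.bias_fold_weak,
        "enrichment_threshold": config.enrichment_threshold,
        "exclusivity_min_unique": config.exclusivity_min_unique,
        "deg_fc": config.deg_fc,
        "deg_p": config.deg_p,
        "subgroup_fc": config.subgroup_fc,
        "epsilon": config.epsilon,
        "flank_bp": config.flank_bp,
    }, "stages": []}

    def stage(name: str, n_in: int, n_out: int) -> None:
        log["stages"].append({"stage": name, "records_in": n_in, "records_out": n_out})

    # --- detection -----------------------------------------------------------
    ann = cio.read_gff3(config.gff3)
    candidates = enumerate_antisense_pairs(ann, min_overlap=config.min_overlap)
    pairs = detect_candidate_pairs(ann, min_overlap=config.min_overlap)
    stage("biotype_exclusion", len(candidates), len(pairs))
    reps = select_representatives(pairs, ann)
    stage("representative_selection", len(pairs), len(reps))

    # --- networks ------------------------------------------------------------
    groups = build_groups(reps)
    ones, many = split_one_to_one(groups)
    stage("network_grouping", len(reps), len(groups))

    # --- small-RNA profiles ----------------------------------------------------
    profiles: dict[tuple[str, str], SiRnaProfile] = {}
    for cond in config.conditions:
        path = config.bed_by_condition[cond]
        if not os.path.exists(path):
            raise ValidationError(f"missing small-RNA BED for condition {cond!r}: {path}")
        raw = cio.read_smallrna_bed(path, cond)
        reads = filter_small_rnas(
            raw, ann, min_len=config.smallrna_min_len, max_len=config.smallrna_max_len
        )
        stage(f"smallrna_filter[{cond}]", len(raw), len(reads))
        for pair in reps:
            profiles[(pair.pair_id, cond)] = build_profile(
                pair, reads, cond, ann,
                bias_fold=config.bias_fold_strong,
                enrichment_threshold=config.enrichment_threshold,
                exclusivity_min_unique=config.exclusivity_min_unique,
            )

    # --- expression ------------------------------------------------------------
    expr = cio.read_expression_table(config.expression_tsv)
    pair_expr = {}
    expressed: dict[str, set[str]] = {c: set() for c in config.conditions}
    one_to_one_pairs = [g.pairs[0] for g in ones]
    for pair in reps:
        for cond in config.conditions:
            pe = pair_expression(
                pair, expr, profiles[(pair.pair_id, cond)], cond, epsilon=config.epsilon
            )
            pair_expr[(pair.pair_id, cond)] = pe
            if pe.expressed:
                expressed[cond].add(pair.pair_id)
    coexp = coexpression_sets(expressed)

    stresses = [c for c in config.conditions if c != config.control_condition]
    subgroups: dict[tuple[str, str], str] = {}
    for pair in one_to_one_pairs:
        pid = pair.pair_id
        for cond in stresses:
            if pid in expressed[config.control_condition] and pid in expressed[cond]:
                ctrl = pair_expr[(pid, config.control_condition)]
                strs = pair_expr[(pid, cond)]
                subgroups[(pid, cond)] = classify_subgroup(
                    ctrl.fpkm_plus, ctrl.fpkm_minus, strs.fpkm_plus, strs.fpkm_minus,
                    fc_threshold=config.subgroup_fc, epsilon=config.epsilon,
                )

    degs = []
    seen_tx = set()
    for pair in one_to_one_pairs:
        for tid in (pair.plus_transcript, pair.minus_transcript):
            if tid in seen_tx:
                continue
            seen_tx.add(tid)
            ctrl = expr.get(tid, config.control_condition)
            for cond in stresses:
                strs = expr.get(tid, cond)
                degs.append(
                    fisher_exact_deg(
                        strs.fragment_count, strs.library_size,
                        ctrl.fragment_count, ctrl.library_size,
                        strs.fpkm, ctrl.fpkm,
                        transcript_id=tid,
                        stress_condition=cond,
                        control_condition=config.control_condition,
                        epsilon=config.epsilon,
                        fc_threshold=config.deg_fc,
                        p_threshold=config.deg_p,
                    )
                )

    stress_flags = {}
    for pair in one_to_one_pairs:
        pid = pair.pair_id
        by_cond = {c: pid in expressed[c] for c in config.conditions}
        stress_flags[pid] = stress_preferential(by_cond, config.control_condition)

    # Domain enrichment: for each expression subgroup, the sense members of
    # its pairs are contrasted against all domain-annotated transcripts.
    enrichment = None
    if config.domain_map:
        domain_map = cio.read_domain_map(config.domain_map)
        background = sorted(domain_map)
        sense_by_subgroup: dict[str, set[str]] = {}
        for (pid, _cond), label in subgroups.items():
            plus_tx = pid.split("|")[0]
            if plus_tx in domain_map:
                sense_by_subgroup.setdefault(label, set()).add(plus_tx)
        frames = []
        for label in sorted(sense_by_subgroup):
            df = domain_enrichment(
                sorted(sense_by_subgroup[label]), background, domain_map,
                p_threshold=config.deg_p,
            )
            df.insert(0, "subgroup", label)
            frames.append(df)
        if frames:
            enrichment = pd.concat(frames, ignore_index=True)

    result = RunResult(
        ann=ann, candidates=candidates, pairs=pairs, representatives=reps,
        groups=groups, one_to_one=ones, many_to_many=many,
        profiles=profiles, pair_expr=pair_expr, expressed=expressed,
        coexpression=coexp, subgroups=subgroups, degs=degs,
        stress_flags=stress_flags, enrichment=enrichment, log=log,
    )
    _write_reports(config, result)
    return result


def _write_reports(config: RunConfig, res: RunResult) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)

    pairs_to_table(res.representatives, res.ann).to_csv(out("pairs.tsv"), sep="\t", index=False)
    groups_to_table(res.groups).to_csv(out("groups.tsv"), sep="\t", index=False)
    profiles_to_table(
        [res.profiles[k] for k in sorted(res.profiles)]
    ).to_csv(out("profiles.tsv"), sep="\t", index=False)

    summarize_pairs(res.representatives, res.ann).to_csv(
        out("pair_summary.tsv"), sep="\t", index=False
    )

    exclusive = {
        c: {pid for (pid, cc), p in res.profiles.items() if cc == c and p.exclusive}
        for c in config.conditions
    }
    enriched = {
        c: {pid for (pid, cc), p in res.profiles.items() if cc == c and p.enriched}
        for c in config.conditions
    }
    summarize_expression(res.expressed, exclusive, enriched, config.conditions).to_csv(
        out("expression_summary.tsv"), sep="\t", index=False
    )

    rows = []
    for (pid, cond) in sorted(res.pair_expr):
        pe = res.pair_expr[(pid, cond)]
        rows.append(
            {
                "pair_id": pid, "condition": cond,
                "fpkm_plus": round(pe.fpkm_plus, 4),
                "fpkm_minus": round(pe.fpkm_minus, 4),
                "n_sirna": pe.n_sirna, "expressed": pe.expressed,
                "log_ratio": round(pe.log_ratio, 4),
                "subgroup": res.subgroups.get((pid, cond), ""),
            }
        )
    pd.DataFrame(rows).to_csv(out("expressed.tsv"), sep="\t", index=False)

    deg_rows = [
        {
            "transcript_id": d.transcript_id,
            "stress": d.stress_condition,
            "fold_change": round(d.fold_change, 4),
            "p_value": f"{d.p_value:.6g}",
            "is_deg": d.is_deg,
        }
        for d in res.degs
    ]
    pd.DataFrame(deg_rows).to_csv(out("degs.tsv"), sep="\t", index=False)

    if res.enrichment is not None:
        res.enrichment.to_csv(out("domain_enrichment.tsv"), sep="\t", index=False)

    with open(out("run_log.json"), "w") as fh:
        json.dump(res.log, fh, sort_keys=True, indent=1)
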