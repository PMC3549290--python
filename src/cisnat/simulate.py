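"""Synthetic fixture generator with planted ground truth.

The generator works truth-first: antisense pairs are placed so that each
realises a requested orientation class and exonic overlap length exactly,
network groups realise a requested topology, and small-RNA reads and
expression values are drawn around planted strand-bias classes, density
ratios, subgroup memberships and differential-expression effects.  Decoys
(same-strand overlaps, overlaps of exactly the threshold length,
excluded-biotype partners, competing isoforms, structural RNAs, organelle and
out-of-range reads) exercise every filter in the pipeline.

Everything is driven by integer-seeded NumPy generators, one stream per file
role, so a fixed master seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import io as cio
from .core import (
    AnnotationSet,
    ExpressionRecord,
    ExpressionTable,
    GenomeInterval,
    SmallRnaRead,
    TranscriptModel,
    ValidationError,
)
from .detect import exonic_overlap
from .sirna import _merge, _subtract

PAIRABLE_BIOTYPES = ("CDS-p", "CDS-n", "ncRNA")

PARTNER_CLASS_CYCLE = (
    ("CDS-p", "ncRNA"),
    ("CDS-p", "CDS-n"),
    ("CDS-p", "CDS-p"),
    ("CDS-n", "ncRNA"),
    ("CDS-n", "CDS-n"),
    ("ncRNA", "ncRNA"),
)

BIAS_CYCLE = (
    "plus-biased",
    "minus-biased",
    "balanced",
    "one-strand-plus",
    "one-strand-minus",
)

#: Fraction of nat-siRNA reads drawn on the plus strand for each planted
#: strand-bias class.  0.9 against the 5-fold calling threshold leaves a
#: comfortable stochastic margin at 100 reads per pair (the chance that a
#: Binomial(100, 0.1) minority count reaches the 1:5 boundary is ~1%%).
BIAS_PLUS_FRACTION = {
    "plus-biased": 0.9,
    "minus-biased": 0.1,
    "balanced": 0.5,
    "one-strand-plus": 1.0,
    "one-strand-minus": 0.0,
}

SUBGROUP_CYCLE = ("1", "2", "3", "4", "5")

#: (sense multiplier, antisense multiplier) applied under every stress.
SUBGROUP_EFFECTS = {
    "1": (1.0, 1.0),
    "2": (4.0, 0.25),
    "3": (0.25, 4.0),
    "4": (4.0, 4.0),
    "5": (0.25, 0.25),
}

DOMAIN_TERMS = (
    "PPR",
    "protein-kinase",
    "LRR",
    "NB-ARC",
    "UDP-glycosyltransferase",
    "aspartyl-protease",
    "glycosyl-hydrolase",
    "F-box",
)

_LENGTH_WEIGHTS = {
    **{n: 1.0 for n in range(18, 35)},
    21: 4.0,
    22: 3.0,
    23: 3.0,
    24: 6.0,
    25: 2.0,
}


@dataclass
class SimulationConfig:
    """All knobs of the fixture generator (defaults are the study conditions)."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 250_000
    organelle_chrom: str = "chrM"
    organelle_length: int = 2_000
    intergenic_reserve: int = 15_000
    conditions: tuple[str, ...] = ("control", "salt", "cold", "drought")
    control_condition: str = "control"
    # planted one-to-one pairs per orientation class
    n_enclosed: int = 18
    n_convergent: int = 18
    n_divergent: int = 18
    # planted networks
    one_to_two_subtypes: tuple[str, ...] = (
        "enclosed+enclosed",
        "enclosed+enclosed",
        "enclosed+convergent",
        "enclosed+divergent",
        "convergent+divergent",
        "convergent+convergent",
    )
    n_one_to_three: int = 2
    n_two_to_two: int = 1
    n_one_to_four: int = 1
    # decoys
    n_same_strand_decoys: int = 3
    n_threshold_decoys: int = 3
    n_excluded_biotype_decoys: int = 4
    n_isoform_decoys: int = 4
    n_structural_rnas: int = 8
    n_transposons: int = 4
    # geometry
    min_overlap: int = 25
    overlap_range: tuple[int, int] = (60, 400)
    pad_range: tuple[int, int] = (120, 400)
    # stress-exclusive / exclusivity / enrichment plans (indices mod these)
    stress_exclusive_every: int = 18
    exclusive_every: int = 9
    enriched_every: int = 9  # offset by 4 against exclusive
    # small-RNA parameters
    reads_per_pair: int = 100
    first_nt_weights: tuple[float, float, float, float] = (0.5, 0.15, 0.2, 0.15)
    copy_mean: float = 2.0
    target_ratio_plain: float = 2.0
    target_ratio_enriched: float = 12.0
    n_background_reads: int = 50
    n_excluded_reads: int = 40
    n_out_of_range_reads: int = 10
    n_organelle_reads: int = 10
    # expression parameters
    fpkm_log_mean: float = math.log(8.0)
    fpkm_log_sigma: float = 1.0
    noise_log_sigma: float = 0.15
    planted_baseline_fpkm: float = 25.0
    library_size: int = 20_000_000
    # domain map
    enriched_term: str = "PPR"
    enriched_term_rate: float = 0.9
    background_term_rate: float = 0.05

    @classmethod
    def from_file(cls, path: str) -> "SimulationConfig":
        """Read a flat ``key = value`` file (ints/floats parsed, rest strings)."""
        kwargs = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValidationError(f"{path}:{lineno}: expected key = value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in valid:
                    raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
                try:
                    parsed: object = int(value)
                except ValueError:
                    try:
                        parsed = float(value)
                    except ValueError:
                        parsed = value
                kwargs[key] = parsed
        return cls(**kwargs)


@dataclass
class PairTruth:
    pair_id: str
    plus_id: str
    minus_id: str
    chrom: str
    orientation: str
    partner_class: str
    overlap_length: int
    one_to_one: bool
    group: Optional[str] = None
    bias_class: Optional[str] = None
    exclusive: bool = False
    enriched: bool = False
    stress_exclusive: bool = False
    subgroup: Optional[str] = None
    expressed: dict[str, bool] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Planted labels, consistent with the emitted files by construction."""

    pairs: dict[str, PairTruth] = field(default_factory=dict)
    groups: dict[str, dict] = field(default_factory=dict)
    deg_transcripts: dict[str, bool] = field(default_factory=dict)
    n_decoy_antisense: int = 0

    def one_to_one_pairs(self) -> list[PairTruth]:
        return [p for p in self.pairs.values() if p.one_to_one]

    def to_json(self) -> str:
        payload = {
            "pairs": {k: dataclasses.asdict(v) for k, v in self.pairs.items()},
            "groups": self.groups,
            "deg_transcripts": self.deg_transcripts,
            "n_decoy_antisense": self.n_decoy_antisense,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


class _Layout:
    """Sequential, collision-free placement of feature blocks on chromosomes."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
        self.cursor = {c: 500 for c in self.chroms}
        self.limit = config.chromosome_length - config.intergenic_reserve

    def place(self, width: int) -> tuple[str, int]:
        chrom = min(self.chroms, key=lambda c: (self.cursor[c], c))
        start = self.cursor[chrom] + int(self.rng.integers(1500, 2500))
        if start + width > self.limit:
            raise ValidationError(
                "chromosome_length too small for the requested feature counts"
            )
        self.cursor[chrom] = start + width
        return chrom, start


def _exons_for_span(
    rng: np.random.Generator,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    protect: tuple[int, int],
) -> list[GenomeInterval]:
    """1-2 exons covering [start, end); any intron avoids the protected window."""
    left = protect[0] - start
    right = end - protect[1]
    if left >= 180 and rng.random() < 0.6:
        i0 = start + int(rng.integers(40, left - 120))
        ilen = int(rng.integers(40, 80))
        return [
            GenomeInterval(chrom, start, i0, strand),
            GenomeInterval(chrom, i0 + ilen, end, strand),
        ]
    if right >= 180 and rng.random() < 0.6:
        i0 = protect[1] + int(rng.integers(40, right - 120))
        ilen = int(rng.integers(40, 80))
        return [
            GenomeInterval(chrom, start, i0, strand),
            GenomeInterval(chrom, i0 + ilen, end, strand),
        ]
    return [GenomeInterval(chrom, start, end, strand)]


def _pair_geometry(
    rng: np.random.Generator, orientation: str, ov: int, pad_range: tuple[int, int]
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int], int]:
    """Relative (plus span, minus span, overlap zone, block width)."""
    lo, hi = pad_range
    pad = lambda: int(rng.integers(lo, hi))
    if orientation == "enclosed":
        pad_l, pad_r = pad(), pad()
        outer = (0, pad_l + ov + pad_r)
        inner = (pad_l, pad_l + ov)
        if rng.random() < 0.5:
            plus, minus = outer, inner
        else:
            plus, minus = inner, outer
        return plus, minus, inner, outer[1]
    if orientation == "convergent":
        lp = pad() + ov
        lm = ov + pad()
        plus = (0, lp)
        minus = (lp - ov, lp - ov + lm)
        return plus, minus, (lp - ov, lp), minus[1]
    if orientation == "divergent":
        lm = pad() + ov
        lp = ov + pad()
        minus = (0, lm)
        plus = (lm - ov, lm - ov + lp)
        return plus, minus, (lm - ov, lm), plus[1]
    raise ValidationError(f"unknown orientation {orientation!r}")


def _partner_label(bt_a: str, bt_b: str) -> str:
    rank = {"CDS-p": 0, "CDS-n": 1, "ncRNA": 2}
    a, b = sorted((bt_a, bt_b), key=rank.__getitem__)
    return f"{a} vs {b}"


def generate_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], AnnotationSet, GroundTruth]:
    """Random genome plus truth-first transcript placement.

    Planted pairs realise their orientation class by span geometry and their
    requested exonic overlap length exactly; decoys are interleaved.
    """
    rng = np.random.default_rng([config.seed, 1])
    layout = _Layout(config, rng)
    ann = AnnotationSet()
    truth = GroundTruth()

    orientations = (
        ["enclosed"] * config.n_enclosed
        + ["convergent"] * config.n_convergent
        + ["divergent"] * config.n_divergent
    )
    n_isoforms_left = config.n_isoform_decoys

    # --- planted one-to-one pairs -------------------------------------------------
    for i, orientation in enumerate(orientations):
        ov = int(rng.integers(config.overlap_range[0], config.overlap_range[1] + 1))
        plus_rel, minus_rel, zone_rel, width = _pair_geometry(
            rng, orientation, ov, config.pad_range
        )
        chrom, offset = layout.place(width)
        plus_span = (plus_rel[0] + offset, plus_rel[1] + offset)
        minus_span = (minus_rel[0] + offset, minus_rel[1] + offset)
        zone = (zone_rel[0] + offset, zone_rel[1] + offset)

        bt_a, bt_b = PARTNER_CLASS_CYCLE[i % len(PARTNER_CLASS_CYCLE)]
        if rng.random() < 0.5:
            bt_plus, bt_minus = bt_a, bt_b
        else:
            bt_plus, bt_minus = bt_b, bt_a
        plus_id, minus_id = f"PT{i:03d}", f"MT{i:03d}"
        plus = TranscriptModel(
            plus_id, f"PL{i:03d}", chrom, "+",
            _exons_for_span(rng, chrom, "+", *plus_span, protect=zone), bt_plus,
        )
        minus = TranscriptModel(
            minus_id, f"ML{i:03d}", chrom, "-",
            _exons_for_span(rng, chrom, "-", *minus_span, protect=zone), bt_minus,
        )
        ann.add(plus)
        ann.add(minus)
        _, realized = exonic_overlap(plus, minus)
        assert realized == ov, "generator must realise the planted overlap exactly"

        if orientation == "convergent" and n_isoforms_left > 0 and ov >= 60:
            # competing isoform of the plus member with a 30 nt shorter overlap
            n_isoforms_left -= 1
            iso_end = plus_span[1] - 30
            ann.add(
                TranscriptModel(
                    f"{plus_id}i", f"PL{i:03d}", chrom, "+",
                    [GenomeInterval(chrom, plus_span[0], iso_end, "+")], bt_plus,
                )
            )

        pt = PairTruth(
            pair_id=f"{plus_id}|{minus_id}",
            plus_id=plus_id,
            minus_id=minus_id,
            chrom=chrom,
            orientation=orientation,
            partner_class=_partner_label(bt_plus, bt_minus),
            overlap_length=ov,
            one_to_one=True,
            bias_class=BIAS_CYCLE[i % len(BIAS_CYCLE)],
            exclusive=(i % config.exclusive_every == 0),
            enriched=(i % config.enriched_every == 4),
            stress_exclusive=(i % config.stress_exclusive_every == config.stress_exclusive_every - 1),
        )
        pt.enriched = pt.enriched or pt.exclusive
        truth.pairs[pt.pair_id] = pt

    # subgroups are planted on co-expressed (non stress-exclusive) pairs
    k = 0
    for pt in truth.one_to_one_pairs():
        if pt.stress_exclusive:
            continue
        pt.subgroup = SUBGROUP_CYCLE[k % len(SUBGROUP_CYCLE)]
        k += 1

    # --- planted network groups ---------------------------------------------------
    bt_cycle = 0

    def next_bt() -> str:
        nonlocal bt_cycle
        bt = PAIRABLE_BIOTYPES[bt_cycle % len(PAIRABLE_BIOTYPES)]
        bt_cycle += 1
        return bt

    def add_single(tid: str, chrom: str, strand: str, span: tuple[int, int], bt: str) -> None:
        ann.add(
            TranscriptModel(
                tid, f"L{tid}", chrom, strand,
                [GenomeInterval(chrom, span[0], span[1], strand)], bt,
            )
        )

    def record_group_pair(
        gkey: str, plus_id: str, minus_id: str, chrom: str, orientation: str, ov: int
    ) -> None:
        pt = PairTruth(
            pair_id=f"{plus_id}|{minus_id}",
            plus_id=plus_id,
            minus_id=minus_id,
            chrom=chrom,
            orientation=orientation,
            partner_class=_partner_label(ann[plus_id].biotype, ann[minus_id].biotype),
            overlap_length=ov,
            one_to_one=False,
            group=gkey,
            bias_class="balanced",
        )
        truth.pairs[pt.pair_id] = pt
        truth.groups[gkey]["pair_ids"].append(pt.pair_id)

    gidx = 0
    for subtype in config.one_to_two_subtypes:
        gidx += 1
        gkey = f"net{gidx:02d}"
        wanted = subtype.split("+")
        hub_len = 2400
        chrom, offset = layout.place(hub_len + 1400)
        hub_start = offset + 500
        hub = (hub_start, hub_start + hub_len)
        hub_id = f"N{gidx:02d}H"
        add_single(hub_id, chrom, "+", hub, next_bt())
        truth.groups[gkey] = {"type": "one-to-two", "subtype": subtype, "pair_ids": []}
        enclosed_slot = 0
        conv_slot = 0
        for p, orientation in enumerate(wanted):
            ov = 150 + 70 * p
            if orientation == "enclosed":
                s = hub_start + 100 + 900 * enclosed_slot
                span = (s, s + ov)
                enclosed_slot += 1
            elif orientation == "convergent":
                s = hub[1] - ov
                span = (s, s + ov + 350 + 150 * conv_slot)
                conv_slot += 1
            else:  # divergent
                span = (hub_start - 400, hub_start + ov)
            partner_id = f"N{gidx:02d}P{p + 1}"
            add_single(partner_id, chrom, "-", span, next_bt())
            record_group_pair(gkey, hub_id, partner_id, chrom, orientation, ov)

    for n_partners, count, label in (
        (3, config.n_one_to_three, "one-to-three"),
        (4, config.n_one_to_four, "one-to-four"),
    ):
        for _ in range(count):
            gidx += 1
            gkey = f"net{gidx:02d}"
            hub_len = 1000 * n_partners + 500
            chrom, offset = layout.place(hub_len + 200)
            hub = (offset, offset + hub_len)
            hub_id = f"N{gidx:02d}H"
            add_single(hub_id, chrom, "+", hub, next_bt())
            truth.groups[gkey] = {"type": label, "subtype": None, "pair_ids": []}
            for p in range(n_partners):
                ov = 200
                s = offset + 100 + 1000 * p
                partner_id = f"N{gidx:02d}P{p + 1}"
                add_single(partner_id, chrom, "-", (s, s + ov), next_bt())
                record_group_pair(gkey, hub_id, partner_id, chrom, "enclosed", ov)

    for _ in range(config.n_two_to_two):
        gidx += 1
        gkey = f"net{gidx:02d}"
        chrom, offset = layout.place(1300)
        ids = {n: f"N{gidx:02d}{n}" for n in ("A", "B", "C", "D")}
        add_single(ids["A"], chrom, "+", (offset, offset + 500), next_bt())
        add_single(ids["B"], chrom, "-", (offset + 100, offset + 300), next_bt())
        add_single(ids["C"], chrom, "-", (offset + 400, offset + 900), next_bt())
        add_single(ids["D"], chrom, "+", (offset + 600, offset + 1200), next_bt())
        truth.groups[gkey] = {"type": "two-to-two", "subtype": None, "pair_ids": []}
        record_group_pair(gkey, ids["A"], ids["B"], chrom, "enclosed", 200)
        record_group_pair(gkey, ids["A"], ids["C"], chrom, "convergent", 100)
        record_group_pair(gkey, ids["D"], ids["C"], chrom, "divergent", 300)

    # --- decoys -------------------------------------------------------------------
    for d in range(config.n_same_strand_decoys):
        chrom, offset = layout.place(800)
        add_single(f"SS{d}a", chrom, "+", (offset, offset + 500), "CDS-p")
        add_single(f"SS{d}b", chrom, "+", (offset + 200, offset + 800), "CDS-p")

    for d in range(config.n_threshold_decoys):
        # exonic overlap of exactly the threshold: excluded by the strict rule
        chrom, offset = layout.place(600)
        add_single(f"TH{d}a", chrom, "+", (offset, offset + 300), "CDS-n")
        add_single(
            f"TH{d}b", chrom, "-",
            (offset + 300 - config.min_overlap, offset + 600), "ncRNA",
        )

    decoy_bts = ("transposon", "miRNA", "rRNA", "transposon")
    for d in range(config.n_excluded_biotype_decoys):
        chrom, offset = layout.place(900)
        add_single(f"XB{d}a", chrom, "+", (offset, offset + 500), "CDS-p")
        add_single(
            f"XB{d}b", chrom, "-", (offset + 300, offset + 900),
            decoy_bts[d % len(decoy_bts)],
        )
        truth.n_decoy_antisense += 1

    structural = ("rRNA", "tRNA", "snRNA", "snoRNA")
    for d in range(config.n_structural_rnas):
        chrom, offset = layout.place(250)
        add_single(f"SR{d}", chrom, "+", (offset, offset + 200), structural[d % 4])

    for d in range(config.n_transposons):
        chrom, offset = layout.place(600)
        add_single(f"TE{d}", chrom, "+", (offset, offset + 500), "transposon")

    # expressed status: FPKM is positive everywhere except the control side of
    # stress-exclusive pairs, and every pair gets >= 1 overlap read per
    # condition, so the expressed call is fixed by construction.
    for pt in truth.pairs.values():
        for cond in config.conditions:
            pt.expressed[cond] = not (
                pt.stress_exclusive and cond == config.control_condition
            )

    # planted DEG labels: transcripts given a >= 2-fold stress effect with a
    # guaranteed healthy baseline (subgroup 2-5 members and stress-exclusive
    # pairs); subgroup-1 members are planted non-DEG.
    for pt in truth.one_to_one_pairs():
        if pt.stress_exclusive:
            truth.deg_transcripts[pt.plus_id] = True
            truth.deg_transcripts[pt.minus_id] = True
        elif pt.subgroup in ("2", "3", "4", "5"):
            truth.deg_transcripts[pt.plus_id] = True
            truth.deg_transcripts[pt.minus_id] = True
        elif pt.subgroup == "1":
            truth.deg_transcripts[pt.plus_id] = False
            truth.deg_transcripts[pt.minus_id] = False

    genome = _random_genome(config)
    return genome, ann, truth


def _random_genome(config: SimulationConfig) -> dict[str, str]:
    rng = np.random.default_rng([config.seed, 9])
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    genome = {}
    for i in range(config.n_chromosomes):
        seq = alphabet[rng.integers(0, 4, size=config.chromosome_length)]
        genome[f"chr{i + 1}"] = seq.tobytes().decode()
    seq = alphabet[rng.integers(0, 4, size=config.organelle_length)]
    genome[config.organelle_chrom] = seq.tobytes().decode()
    return genome


def _pair_regions(
    ann: AnnotationSet, pt: PairTruth
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    plus, minus = ann[pt.plus_id], ann[pt.minus_id]
    overlap, _ = exonic_overlap(plus, minus)
    exons = [(e.start, e.end) for t in (plus, minus) for e in t.exons]
    flanks = _subtract(_merge(exons), overlap)
    return overlap, flanks


def _draw_sequence(rng: np.random.Generator, length: int, first_nt_weights) -> str:
    nts = "ACGT"
    first = nts[int(rng.choice(4, p=np.asarray(first_nt_weights)))]
    rest = "".join(nts[j] for j in rng.integers(0, 4, size=length - 1))
    return first + rest


def _place_read(
    rng: np.random.Generator, blocks: list[tuple[int, int]], length: int
) -> Optional[tuple[int, int]]:
    usable = [(s, e) for s, e in blocks if e - s >= length]
    if not usable:
        return None
    weights = np.array([e - s for s, e in usable], dtype=float)
    idx = int(rng.choice(len(usable), p=weights / weights.sum()))
    s, e = usable[idx]
    start = int(rng.integers(s, e - length + 1))
    return start, start + length


_LENGTHS = np.arange(18, 35)
_LENGTH_P = np.array([_LENGTH_WEIGHTS[n] for n in _LENGTHS])
_LENGTH_P = _LENGTH_P / _LENGTH_P.sum()


def generate_smallrna_reads(
    config: SimulationConfig, ann: AnnotationSet, truth: GroundTruth
) -> dict[str, list[SmallRnaRead]]:
    """Per-condition collapsed small-RNA reads around the planted statistics."""
    out: dict[str, list[SmallRnaRead]] = {}
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    regions = {pid: _pair_regions(ann, pt) for pid, pt in truth.pairs.items()}
    structural = [
        (t.chrom, t.start, t.end) for t in ann.sorted_transcripts()
        if t.biotype in ("rRNA", "tRNA", "snRNA", "snoRNA")
    ]
    copy_p = 1.0 / config.copy_mean

    for ci, cond in enumerate(config.conditions):
        rng = np.random.default_rng([config.seed, 20 + ci])
        reads: list[SmallRnaRead] = []
        serial = 0

        def emit(chrom: str, start: int, end: int, strand: str) -> None:
            nonlocal serial
            serial += 1
            length = end - start
            seq = _draw_sequence(rng, length, config.first_nt_weights)
            copies = int(rng.geometric(copy_p))
            reads.append(
                SmallRnaRead(
                    read_id=f"{cond[:2]}r{serial:06d}_{seq}",
                    interval=GenomeInterval(chrom, start, end, strand),
                    copies=copies,
                )
            )

        for pid in sorted(truth.pairs):
            pt = truth.pairs[pid]
            overlap, flanks = regions[pid]
            ov_len = sum(e - s for s, e in overlap)
            fl_len = sum(e - s for s, e in flanks)
            # ``reads_per_pair`` nat-siRNAs land in the overlap; the flank
            # read count is fixed by the target overlap/flank density ratio,
            # so exclusivity and enrichment labels hold by construction.
            if pt.exclusive or fl_len == 0:
                n_flank = 0
            else:
                ratio = (
                    config.target_ratio_enriched
                    if pt.enriched
                    else config.target_ratio_plain
                )
                r = ratio * ov_len / fl_len
                n_flank = min(300, max(1, round(config.reads_per_pair / r)))
            p_plus = BIAS_PLUS_FRACTION[pt.bias_class or "balanced"]
            for j in range(config.reads_per_pair + n_flank):
                length = int(rng.choice(_LENGTHS, p=_LENGTH_P))
                in_overlap = j < config.reads_per_pair
                placed = _place_read(rng, overlap if in_overlap else flanks, length)
                if placed is None:
                    placed = _place_read(rng, overlap, length)
                if placed is None:
                    continue
                strand = "+" if rng.random() < p_plus else "-"
                emit(pt.chrom, placed[0], placed[1], strand)

        # intergenic background in the reserved tail of each chromosome
        for _ in range(config.n_background_reads):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            zone_lo = config.chromosome_length - config.intergenic_reserve + 2000
            zone_hi = config.chromosome_length - 500
            length = int(rng.choice(_LENGTHS, p=_LENGTH_P))
            start = int(rng.integers(zone_lo, zone_hi - length))
            emit(chrom, start, start + length, "+" if rng.random() < 0.5 else "-")

        # reads inside structural RNAs (dropped by the exclusion filter)
        for _ in range(config.n_excluded_reads):
            chrom, fs, fe = structural[int(rng.integers(0, len(structural)))]
            length = int(rng.choice(_LENGTHS, p=_LENGTH_P))
            start = int(rng.integers(fs, fe - length))
            emit(chrom, start, start + length, "+")

        # out-of-size-range reads (dropped by the length filter)
        for j in range(config.n_out_of_range_reads):
            chrom = chroms[0]
            zone_lo = config.chromosome_length - config.intergenic_reserve + 2000
            length = 16 if j % 2 == 0 else 36
            start = zone_lo + 50 * j
            emit(chrom, start, start + length, "+")

        # organelle reads (dropped by the organelle filter)
        for _ in range(config.n_organelle_reads):
            length = int(rng.choice(_LENGTHS, p=_LENGTH_P))
            start = int(rng.integers(0, config.organelle_length - length))
            emit(config.organelle_chrom, start, start + length, "+")

        out[cond] = reads
    return out


def generate_expression(
    config: SimulationConfig, ann: AnnotationSet, truth: GroundTruth
) -> ExpressionTable:
    """Per-transcript, per-condition FPKM and fragment counts.

    FPKM = planted baseline x stress effect x log-normal noise; fragment
    counts follow Poisson(FPKM x exonic kb x library millions).  The control
    side of stress-exclusive pairs is forced to zero.
    """
    rng = np.random.default_rng([config.seed, 40])
    # role of each transcript within its pair, if any
    sense_effect: dict[str, float] = {}
    zero_in_control: set[str] = set()
    fixed_baseline: set[str] = set()
    for pt in truth.one_to_one_pairs():
        if pt.stress_exclusive:
            zero_in_control.update((pt.plus_id, pt.minus_id))
            fixed_baseline.update((pt.plus_id, pt.minus_id))
            continue
        es, ea = SUBGROUP_EFFECTS[pt.subgroup or "1"]
        sense_effect[pt.plus_id] = es
        sense_effect[pt.minus_id] = ea
        if pt.subgroup in ("2", "3", "4", "5"):
            fixed_baseline.update((pt.plus_id, pt.minus_id))

    records: list[ExpressionRecord] = []
    for t in ann.sorted_transcripts():
        if t.id in fixed_baseline:
            baseline = config.planted_baseline_fpkm
        else:
            baseline = float(
                rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sigma)
            )
        for cond in config.conditions:
            is_control = cond == config.control_condition
            if t.id in zero_in_control and is_control:
                fpkm = 0.0
            else:
                effect = 1.0 if is_control else sense_effect.get(t.id, 1.0)
                noise = float(rng.lognormal(0.0, config.noise_log_sigma))
                fpkm = baseline * effect * noise
            mean_count = fpkm * (t.exonic_length / 1000.0) * (config.library_size / 1e6)
            count = int(rng.poisson(mean_count)) if mean_count > 0 else 0
            records.append(
                ExpressionRecord(
                    transcript_id=t.id,
                    condition=cond,
                    fpkm=round(fpkm, 4),
                    fragment_count=count,
                    library_size=config.library_size,
                )
            )
    return ExpressionTable(records)


def generate_domain_map(
    config: SimulationConfig, ann: AnnotationSet, truth: GroundTruth
) -> dict[str, set[str]]:
    """Transcript-to-domain-term map with one term planted as enriched among
    the sense members of subgroup-1 pairs."""
    rng = np.random.default_rng([config.seed, 41])
    subgroup1_sense = {
        pt.plus_id for pt in truth.one_to_one_pairs() if pt.subgroup == "1"
    }
    mapping: dict[str, set[str]] = {}
    generic = [t for t in DOMAIN_TERMS if t != config.enriched_term]
    for t in ann.sorted_transcripts():
        if t.biotype != "CDS-p":
            continue
        terms = {generic[int(rng.integers(0, len(generic)))]}
        rate = (
            config.enriched_term_rate
            if t.id in subgroup1_sense
            else config.background_term_rate
        )
        if rng.random() < rate:
            terms.add(config.enriched_term)
        mapping[t.id] = terms
    return mapping


def _write_fasta(genome: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_fixture(
    config: SimulationConfig, out_dir: str, overwrite: bool = False
) -> dict[str, str]:
    """Emit the complete fixture bundle into ``out_dir``.

    Re-running with the same seed reproduces every file byte-for-byte.
    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.
    """
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise ValidationError(
            f"output directory {out_dir!r} is not empty (use overwrite)"
        )
    os.makedirs(out_dir, exist_ok=True)
    genome, ann, truth = generate_annotation(config)
    reads = generate_smallrna_reads(config, ann, truth)
    expr = generate_expression(config, ann, truth)
    domains = generate_domain_map(config, ann, truth)

    paths = {"genome": os.path.join(out_dir, "genome.fa")}
    _write_fasta(genome, paths["genome"])
    paths["annotation"] = os.path.join(out_dir, "annotation.gff3")
    cio.write_gff3(ann, paths["annotation"])
    for cond in config.conditions:
        key = f"smallrna_{cond}"
        paths[key] = os.path.join(out_dir, f"smallrna_{cond}.bed")
        cio.write_smallrna_bed(reads[cond], paths[key])
    paths["expression"] = os.path.join(out_dir, "expression.tsv")
    cio.write_expression_table(expr, paths["expression"])
    paths["domains"] = os.path.join(out_dir, "domains.tsv")
    cio.write_domain_map(domains, paths["domains"])
    paths["truth"] = os.path.join(out_dir, "truth.json")
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json() + "\n")
    return paths
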