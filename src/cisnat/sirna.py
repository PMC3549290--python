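"""Small-RNA filtering, nat-siRNA assignment and per-pair siRNA statistics.

A filtered small-RNA read is a putative nat-siRNA of a cis-NAT pair when its
genomic interval lies wholly within a single merged overlap block of that
pair.  Per pair and per condition the module computes strand-resolved unique
and copy-summed counts, read densities inside the overlap versus the
non-overlapping exonic flanks, a strand-bias class at a configurable fold
threshold, and an overlap-exclusivity flag.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Optional

from .core import (
    DEFAULT_ORGANELLE_CHROMS,
    EXCLUDED_READ_BIOTYPES,
    AnnotationSet,
    CisNatPair,
    SiRnaProfile,
    SmallRnaRead,
    ValidationError,
)


def filter_small_rnas(
    reads: Iterable[SmallRnaRead],
    exclusion_ann: Optional[AnnotationSet] = None,
    min_len: int = 18,
    max_len: int = 34,
    excluded_biotypes: frozenset[str] = EXCLUDED_READ_BIOTYPES,
    organelle_chroms: frozenset[str] = DEFAULT_ORGANELLE_CHROMS,
) -> list[SmallRnaRead]:
    """Drop reads outside [min_len, max_len], on organelles, or overlapping
    rRNA/tRNA/sn/snoRNA features.

    Input reads are assumed pre-collapsed, uniquely and perfectly mapped
    (multi-mappers and mismatched reads are removed upstream of this
    pipeline).
    """
    kept = []
    for r in reads:
        if not (min_len <= r.length <= max_len):
            continue
        if r.interval.chrom in organelle_chroms:
            continue
        if exclusion_ann is not None:
            hits = exclusion_ann.query(r.interval.chrom, r.interval.start, r.interval.end)
            if any(t.biotype in excluded_biotypes for t in hits):
                continue
        kept.append(r)
    return kept


def assign_nat_sirnas(
    reads: Iterable[SmallRnaRead], pair: CisNatPair
) -> tuple[list[SmallRnaRead], list[SmallRnaRead]]:
    """Strand-resolved nat-siRNA read sets of a pair.

    A read qualifies iff it is wholly contained in one merged overlap
    interval of the pair; reads straddling a block boundary or bridging two
    blocks do not qualify.  The read's own strand decides which member it is
    attributed to.
    """
    plus, minus = [], []
    for r in reads:
        iv = r.interval
        if iv.chrom != pair.chrom:
            continue
        if pair.contains_interval(iv.start, iv.end):
            (plus if iv.strand == "+" else minus).append(r)
    return plus, minus


def classify_strand_bias(
    plus_unique: int, minus_unique: int, fold: float = 5.0
) -> str:
    """Strand-bias class from unique read counts at a fold threshold.

    ``one-strand-*`` when the other strand produced no reads at all,
    ``*-biased`` when the larger side is at least ``fold`` times the smaller,
    ``balanced`` otherwise (including the all-zero case).
    """
    if fold < 0:
        raise ValidationError(f"fold threshold must be >= 0, got {fold}")
    if plus_unique < 0 or minus_unique < 0:
        raise ValidationError("read counts must be non-negative")
    if plus_unique == 0 and minus_unique == 0:
        return "balanced"
    if minus_unique == 0:
        return "one-strand-plus"
    if plus_unique == 0:
        return "one-strand-minus"
    hi, lo = max(plus_unique, minus_unique), min(plus_unique, minus_unique)
    if hi / lo >= fold:
        return "plus-biased" if plus_unique > minus_unique else "minus-biased"
    return "balanced"


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = out[-1]
        if s <= le:
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def _subtract(
    blocks: list[tuple[int, int]], holes: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for bs, be in blocks:
        cur = bs
        for hs, he in holes:
            if he <= cur or hs >= be:
                continue
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
            if cur >= be:
                break
        if cur < be:
            out.append((cur, be))
    return out


def flank_intervals(pair: CisNatPair, ann: AnnotationSet) -> list[tuple[int, int]]:
    """Union of both members' exons minus the pair's overlap blocks."""
    exons = [
        (e.start, e.end)
        for tid in (pair.plus_transcript, pair.minus_transcript)
        for e in ann[tid].exons
    ]
    return _subtract(_merge(exons), list(pair.overlap_intervals))


def _contained_in_union(
    iv_start: int, iv_end: int, blocks: list[tuple[int, int]]
) -> bool:
    return any(s <= iv_start and iv_end <= e for s, e in blocks)


def sirna_density(
    pair: CisNatPair,
    reads: Iterable[SmallRnaRead],
    ann: AnnotationSet,
    enrichment_threshold: float = 5.0,
) -> tuple[float, float, float, bool]:
    """Unique-read densities (reads/kb) in overlap vs non-overlap exon flanks.

    Returns (density_overlap, density_flank, enrichment_ratio, enriched).
    A zero flank density (no flank reads or no flank region) makes the ratio
    infinite; the pair counts as enriched whenever the ratio exceeds the
    threshold.
    """
    flanks = flank_intervals(pair, ann)
    n_overlap = 0
    n_flank = 0
    for r in reads:
        iv = r.interval
        if iv.chrom != pair.chrom:
            continue
        if pair.contains_interval(iv.start, iv.end):
            n_overlap += 1
        elif _contained_in_union(iv.start, iv.end, flanks):
            n_flank += 1
    density_overlap = n_overlap / (pair.overlap_length / 1000.0)
    flank_len = sum(e - s for s, e in flanks)
    if flank_len == 0:
        density_flank = 0.0
    else:
        density_flank = n_flank / (flank_len / 1000.0)
    if density_flank == 0.0:
        ratio = math.inf if density_overlap > 0 else 0.0
    else:
        ratio = density_overlap / density_flank
    return density_overlap, density_flank, ratio, ratio > enrichment_threshold


def overlap_exclusivity(
    pair: CisNatPair,
    reads: Iterable[SmallRnaRead],
    ann: AnnotationSet,
    min_unique: int = 5,
) -> bool:
    """True iff every read touching either member's exons lies wholly in the
    overlap and the pair has strictly more than ``min_unique`` unique
    nat-siRNAs."""
    exons = _merge(
        [
            (e.start, e.end)
            for tid in (pair.plus_transcript, pair.minus_transcript)
            for e in ann[tid].exons
        ]
    )
    n_inside = 0
    for r in reads:
        iv = r.interval
        if iv.chrom != pair.chrom:
            continue
        touches = any(s < iv.end and iv.start < e for s, e in exons)
        if not touches:
            continue
        if pair.contains_interval(iv.start, iv.end):
            n_inside += 1
        else:
            return False
    return n_inside > min_unique


def build_profile(
    pair: CisNatPair,
    reads: Iterable[SmallRnaRead],
    condition: str,
    ann: AnnotationSet,
    bias_fold: float = 5.0,
    enrichment_threshold: float = 5.0,
    exclusivity_min_unique: int = 5,
) -> SiRnaProfile:
    """All per-pair siRNA statistics for one condition's filtered reads."""
    reads = list(reads)
    plus, minus = assign_nat_sirnas(reads, pair)
    d_ov, d_fl, ratio, enriched = sirna_density(
        pair, reads, ann, enrichment_threshold=enrichment_threshold
    )
    return SiRnaProfile(
        pair_id=pair.pair_id,
        condition=condition,
        plus_unique=len(plus),
        minus_unique=len(minus),
        plus_total=sum(r.copies for r in plus),
        minus_total=sum(r.copies for r in minus),
        density_overlap=d_ov,
        density_flank=d_fl,
        enrichment_ratio=ratio,
        enriched=enriched,
        bias_class=classify_strand_bias(len(plus), len(minus), fold=bias_fold),
        exclusive=overlap_exclusivity(pair, reads, ann, min_unique=exclusivity_min_unique),
    )


def sequence_stats(
    reads: Iterable[SmallRnaRead], min_len: int = 18, max_len: int = 34
) -> tuple[dict[int, int], dict[str, float]]:
    """Length histogram and 5'-first-nucleotide frequencies of unique reads.

    Reads with unknown first nucleotide (``N``) are excluded from the
    frequency denominator; an empty input yields zero frequencies.
    """
    lengths: Counter[int] = Counter()
    first: Counter[str] = Counter()
    for r in reads:
        if min_len <= r.length <= max_len:
            lengths[r.length] += 1
        if r.first_nt != "N":
            first[r.first_nt] += 1
    total = sum(first.values())
    freqs = {
        nt: (first[nt] / total if total else 0.0) for nt in ("A", "C", "G", "T")
    }
    return dict(sorted(lengths.items())), freqs


_CONTEXT_ORDER = ("transposon", "exon", "intron", "upstream", "downstream", "intergenic")


def classify_genomic_context(
    read: SmallRnaRead, ann: AnnotationSet, flank_bp: int = 1000
) -> str:
    """Genomic context of a read with precedence
    transposon > exon > intron > upstream > downstream > intergenic.

    Upstream/downstream are strand-aware windows of ``flank_bp`` from the
    nearest transcript span.
    """
    iv = read.interval
    hits = ann.query(iv.chrom, iv.start - flank_bp, iv.end + flank_bp)
    found = set()
    for t in hits:
        overlaps_span = t.start < iv.end and iv.start < t.end
        if overlaps_span and t.biotype == "transposon":
            return "transposon"
        if overlaps_span:
            in_exon = any(e.start < iv.end and iv.start < e.end for e in t.exons)
            found.add("exon" if in_exon else "intron")
            continue
        if t.strand == "+":
            up = (t.start - flank_bp, t.start)
            down = (t.end, t.end + flank_bp)
        else:
            up = (t.end, t.end + flank_bp)
            down = (t.start - flank_bp, t.start)
        if up[0] < iv.end and iv.start < up[1]:
            found.add("upstream")
        if down[0] < iv.end and iv.start < down[1]:
            found.add("downstream")
    for label in _CONTEXT_ORDER[1:-1]:
        if label in found:
            return label
    return "intergenic"


def profiles_to_table(profiles: Iterable[SiRnaProfile]):
    import pandas as pd

    rows = []
    for p in profiles:
        ratio = "inf" if math.isinf(p.enrichment_ratio) else f"{p.enrichment_ratio:.4f}"
        rows.append(
            {
                "pair_id": p.pair_id,
                "condition": p.condition,
                "plus_unique": p.plus_unique,
                "minus_unique": p.minus_unique,
                "plus_total": p.plus_total,
                "minus_total": p.minus_total,
                "density_overlap": round(p.density_overlap, 4),
                "density_flank": round(p.density_flank, 4),
                "enrichment_ratio": ratio,
                "enriched": p.enriched,
                "bias_class": p.bias_class,
                "exclusive": p.exclusive,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "condition", "plus_unique", "minus_unique",
            "plus_total", "minus_total", "density_overlap", "density_flank",
            "enrichment_ratio", "enriched", "bias_class", "exclusive",
        ],
    )
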