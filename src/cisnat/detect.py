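"""Detection and classification of cis-natural antisense transcript pairs.

Two transcripts form a candidate cis-NAT pair when they sit on opposite
strands of the same chromosome and the non-redundant union of their exon
intersections exceeds a minimum length (default: strictly more than 25 nt).
Orientation is decided on genomic spans: containment is *enclosed*, a partial
overlap with the plus member upstream puts both 3' termini inside the overlap
(*convergent*, 3'-3'), otherwise both 5' termini do (*divergent*, 5'-5').
"""

from __future__ import annotations

from typing import Iterable, Optional

from .core import (
    EXCLUDED_PAIR_BIOTYPES,
    PARTNER_CLASS_RANK,
    AnnotationSet,
    CisNatPair,
    TranscriptModel,
    ValidationError,
)


def exonic_overlap(
    a: TranscriptModel, b: TranscriptModel
) -> tuple[list[tuple[int, int]], int]:
    """Merged union of all pairwise exon intersections of ``a`` and ``b``.

    Returns the sorted, disjoint overlap intervals and their total length
    (each base counted once, however many exon pairs cover it).  Disjoint
    transcripts yield ``([], 0)``.
    """
    if a.chrom != b.chrom:
        return [], 0
    raw: list[tuple[int, int]] = []
    for ea in a.exons:
        for eb in b.exons:
            s, e = max(ea.start, eb.start), min(ea.end, eb.end)
            if s < e:
                raw.append((s, e))
    if not raw:
        return [], 0
    raw.sort()
    merged = [raw[0]]
    for s, e in raw[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged, sum(e - s for s, e in merged)


def classify_orientation(a: TranscriptModel, b: TranscriptModel) -> str:
    """Orientation class of an overlapping opposite-strand transcript pair."""
    if a.strand == b.strand:
        raise ValidationError(
            f"classify_orientation requires opposite strands, got "
            f"{a.id}{a.strand} / {b.id}{b.strand}"
        )
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    p_s, p_e = plus.start, plus.end
    m_s, m_e = minus.start, minus.end
    if (p_s <= m_s and m_e <= p_e) or (m_s <= p_s and p_e <= m_e):
        return "enclosed"
    # Partial overlap: the upstream member contributes its 3' end on the plus
    # strand, the downstream member its 3' end on the minus strand.
    return "convergent" if p_s < m_s else "divergent"


def _make_pair(
    plus: TranscriptModel,
    minus: TranscriptModel,
    intervals: list[tuple[int, int]],
    length: int,
) -> CisNatPair:
    return CisNatPair(
        plus_transcript=plus.id,
        minus_transcript=minus.id,
        chrom=plus.chrom,
        overlap_intervals=tuple(intervals),
        overlap_length=length,
        orientation=classify_orientation(plus, minus),
    )


def enumerate_antisense_pairs(
    ann: AnnotationSet, min_overlap: int = 25
) -> list[CisNatPair]:
    """All opposite-strand pairs with exonic overlap strictly > ``min_overlap``.

    No biotype exclusion is applied here so the pre-exclusion candidate count
    is reportable.  Output is sorted by (chrom, overlap start, plus id).
    """
    pairs: list[CisNatPair] = []
    seen: set[tuple[str, str]] = set()
    for t in ann:
        if t.strand != "+":
            continue
        for other in ann.query(t.chrom, t.start, t.end):
            if other.strand != "-":
                continue
            key = (t.id, other.id)
            if key in seen:
                continue
            seen.add(key)
            intervals, length = exonic_overlap(t, other)
            if length > min_overlap:
                pairs.append(_make_pair(t, other, intervals, length))
    pairs.sort(
        key=lambda p: (p.chrom, p.overlap_intervals[0][0], p.plus_transcript, p.minus_transcript)
    )
    return pairs


def partner_class(pair: CisNatPair, ann: AnnotationSet) -> str:
    """Unordered partner-class label of a pair (e.g. ``CDS-p vs ncRNA``)."""
    biotypes = [
        ann[pair.plus_transcript].biotype,
        ann[pair.minus_transcript].biotype,
    ]
    for bt in biotypes:
        if bt not in PARTNER_CLASS_RANK:
            raise ValidationError(
                f"pair {pair.pair_id}: biotype {bt!r} is not a pairable class"
            )
    biotypes.sort(key=PARTNER_CLASS_RANK.__getitem__)
    return f"{biotypes[0]} vs {biotypes[1]}"


def detect_candidate_pairs(
    ann: AnnotationSet,
    min_overlap: int = 25,
    excluded_biotypes: frozenset[str] = EXCLUDED_PAIR_BIOTYPES,
) -> list[CisNatPair]:
    """Candidate cis-NAT pairs after the biotype exclusion filter.

    Exclusion is applied pair-wise (either member) *after* enumeration; use
    :func:`enumerate_antisense_pairs` for the pre-exclusion candidate list.
    Surviving pairs carry their partner-class label.
    """
    kept: list[CisNatPair] = []
    for pair in enumerate_antisense_pairs(ann, min_overlap=min_overlap):
        if ann[pair.plus_transcript].biotype in excluded_biotypes:
            continue
        if ann[pair.minus_transcript].biotype in excluded_biotypes:
            continue
        kept.append(
            CisNatPair(
                plus_transcript=pair.plus_transcript,
                minus_transcript=pair.minus_transcript,
                chrom=pair.chrom,
                overlap_intervals=pair.overlap_intervals,
                overlap_length=pair.overlap_length,
                orientation=pair.orientation,
                partner_class=partner_class(pair, ann),
            )
        )
    return kept


def select_representatives(
    pairs: Iterable[CisNatPair], ann: AnnotationSet
) -> list[CisNatPair]:
    """One representative pair per unordered locus pair.

    Isoform combinations of the same two gene loci compete; the pair with the
    longest exonic overlap wins, ties broken by the lexicographically smallest
    (plus id, minus id).
    """
    best: dict[frozenset[str], CisNatPair] = {}
    for pair in pairs:
        key = frozenset(
            (
                ann[pair.plus_transcript].locus_id,
                ann[pair.minus_transcript].locus_id,
            )
        )
        cur = best.get(key)
        if cur is None:
            best[key] = pair
            continue
        cand = (-pair.overlap_length, pair.plus_transcript, pair.minus_transcript)
        incumbent = (-cur.overlap_length, cur.plus_transcript, cur.minus_transcript)
        if cand < incumbent:
            best[key] = pair
    out = list(best.values())
    out.sort(
        key=lambda p: (p.chrom, p.overlap_intervals[0][0], p.plus_transcript, p.minus_transcript)
    )
    return out


def pairs_to_table(pairs: Iterable[CisNatPair], ann: AnnotationSet):
    """Pair report rows (overlap locations reported 1-based inclusive)."""
    import pandas as pd

    rows = []
    for p in pairs:
        locs = ";".join(f"{p.chrom}:{s + 1}-{e}" for s, e in p.overlap_intervals)
        rows.append(
            {
                "plus_id": p.plus_transcript,
                "plus_len": ann[p.plus_transcript].exonic_length,
                "minus_id": p.minus_transcript,
                "minus_len": ann[p.minus_transcript].exonic_length,
                "overlap_len": p.overlap_length,
                "overlap_locations": locs,
                "orientation": p.orientation,
                "partner_class": p.partner_class or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "plus_id", "plus_len", "minus_id", "minus_len",
            "overlap_len", "overlap_locations", "orientation", "partner_class",
        ],
    )
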