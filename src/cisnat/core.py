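"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)``.  GFF3 I/O
converts at the boundary; BED coordinates are used as-is.  Using a single
arithmetic convention internally removes an entire class of off-by-one bugs
when intersecting exons, overlap regions and small-RNA reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from intervaltree import IntervalTree

#: Closed vocabulary of transcript biotypes.  ``CDS-p`` is a predicted coding
#: sequence with a protein-domain hit, ``CDS-n`` one without, the remainder
#: are structural/regulatory RNA classes that are excluded from antisense
#: pairing.
BIOTYPES = frozenset(
    {
        "CDS-p",
        "CDS-n",
        "ncRNA",
        "transposon",
        "rRNA",
        "tRNA",
        "snRNA",
        "snoRNA",
        "miRNA",
    }
)

#: Biotypes whose members disqualify an antisense pair (housekeeping RNAs,
#: transposons and miRNA precursors produce small RNAs through unrelated
#: pathways).
EXCLUDED_PAIR_BIOTYPES = frozenset(
    {"transposon", "rRNA", "tRNA", "snRNA", "snoRNA", "miRNA"}
)

#: Biotypes whose footprint disqualifies a small-RNA read (rRNA/tRNA/sn/snoRNA
#: degradation products masquerade as siRNAs).
EXCLUDED_READ_BIOTYPES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA"})

#: Chromosome names treated as organellar; reads mapping there are discarded.
DEFAULT_ORGANELLE_CHROMS = frozenset({"chrM", "chrC", "Mt", "Pt"})


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class ParseError(ValidationError):
    """Raised when a file cannot be parsed; carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class TranscriptModel:
    """A strand-resolved, multi-exon transcript model."""

    id: str
    locus_id: str
    chrom: str
    strand: str
    exons: list[GenomeInterval]
    biotype: str

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"transcript {self.id}: unknown biotype {self.biotype!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = -1
        for exon in self.exons:
            if exon.chrom != self.chrom or exon.strand != self.strand:
                raise ValidationError(
                    f"transcript {self.id}: exon {exon} disagrees with "
                    f"transcript {self.chrom}{self.strand}"
                )
            if exon.start < prev_end:
                raise ValidationError(
                    f"transcript {self.id}: overlapping exons"
                )
            prev_end = exon.end

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


class AnnotationSet:
    """Transcripts indexed by id and, per chromosome, by span interval."""

    def __init__(self, transcripts: Optional[list[TranscriptModel]] = None):
        self._by_id: dict[str, TranscriptModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts or []:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.id in self._by_id:
            raise ValidationError(f"duplicate transcript id {t.id!r}")
        self._by_id[t.id] = t
        self._trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t.id)

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, tid: str) -> bool:
        return tid in self._by_id

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._by_id.values())

    def __getitem__(self, tid: str) -> TranscriptModel:
        try:
            return self._by_id[tid]
        except KeyError:
            raise KeyError(f"unknown transcript id {tid!r}") from None

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def query(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        """Transcripts whose span intersects ``[start, end)`` on ``chrom``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self._by_id[iv.data] for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda t: (t.start, t.id))

    def sorted_transcripts(self) -> list[TranscriptModel]:
        return sorted(
            self._by_id.values(), key=lambda t: (t.chrom, t.start, t.id)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self._by_id == other._by_id


@dataclass(frozen=True)
class SmallRnaRead:
    """One collapsed small-RNA alignment (one record per unique sequence).

    ``copies`` carries the collapsed read count, so "unique small RNAs" in
    statistics counts records while "total reads" sums copies.
    """

    read_id: str
    interval: GenomeInterval
    copies: int
    first_nt: str = "N"

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValidationError(
                f"read {self.read_id}: copies must be >= 1, got {self.copies}"
            )
        if self.first_nt not in ("A", "C", "G", "T", "N"):
            raise ValidationError(
                f"read {self.read_id}: invalid first nucleotide {self.first_nt!r}"
            )

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class CisNatPair:
    """Two opposite-strand transcripts with exonic overlap > threshold."""

    plus_transcript: str
    minus_transcript: str
    chrom: str
    overlap_intervals: tuple[tuple[int, int], ...]
    overlap_length: int
    orientation: str  # enclosed | convergent | divergent
    partner_class: Optional[str] = None

    @property
    def pair_id(self) -> str:
        return f"{self.plus_transcript}|{self.minus_transcript}"

    def contains_interval(self, start: int, end: int) -> bool:
        """True when ``[start, end)`` lies wholly within one overlap block."""
        return any(s <= start and end <= e for s, e in self.overlap_intervals)


ORIENTATIONS = ("enclosed", "convergent", "divergent")

PARTNER_CLASS_RANK = {"CDS-p": 0, "CDS-n": 1, "ncRNA": 2}

PARTNER_CLASSES = (
    "CDS-p vs ncRNA",
    "CDS-p vs CDS-n",
    "CDS-p vs CDS-p",
    "CDS-n vs ncRNA",
    "CDS-n vs CDS-n",
    "ncRNA vs ncRNA",
)


@dataclass
class CisNatGroup:
    """A connected component of cis-NAT pairs (a many-to-many network)."""

    group_id: str
    transcripts: list[str]
    pairs: list[CisNatPair]
    n_plus: int
    n_minus: int
    group_type: str
    subtype: Optional[str] = None


@dataclass
class SiRnaProfile:
    """Per-pair, per-condition nat-siRNA statistics."""

    pair_id: str
    condition: str
    plus_unique: int
    minus_unique: int
    plus_total: int
    minus_total: int
    density_overlap: float
    density_flank: float
    enrichment_ratio: float  # math.inf when the flank density is zero
    enriched: bool
    bias_class: str
    exclusive: bool

    @property
    def n_unique(self) -> int:
        return self.plus_unique + self.minus_unique

    @property
    def n_total(self) -> int:
        return self.plus_total + self.minus_total


@dataclass
class PairExpression:
    """Per-pair, per-condition expression evidence."""

    pair_id: str
    condition: str
    fpkm_plus: float
    fpkm_minus: float
    count_plus: int
    count_minus: int
    n_sirna: int
    expressed: bool
    log_ratio: float


@dataclass
class DegResult:
    """Differential-expression call for one transcript in one comparison."""

    transcript_id: str
    stress_condition: str
    control_condition: str
    fold_change: float
    p_value: float
    is_deg: bool


@dataclass
class ExpressionRecord:
    transcript_id: str
    condition: str
    fpkm: float
    fragment_count: int
    library_size: int

    def __post_init__(self) -> None:
        if self.fpkm < 0 or self.fragment_count < 0:
            raise ValidationError(
                f"{self.transcript_id}/{self.condition}: negative expression value"
            )
        if self.library_size <= 0:
            raise ValidationError(
                f"{self.transcript_id}/{self.condition}: library_size must be > 0"
            )


class ExpressionTable:
    """Expression records keyed by (transcript_id, condition)."""

    def __init__(self, records: list[ExpressionRecord]):
        self._records: dict[tuple[str, str], ExpressionRecord] = {}
        for rec in records:
            key = (rec.transcript_id, rec.condition)
            if key in self._records:
                raise ValidationError(f"duplicate expression record for {key}")
            self._records[key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def get(self, transcript_id: str, condition: str) -> ExpressionRecord:
        try:
            return self._records[(transcript_id, condition)]
        except KeyError:
            raise ValidationError(
                f"missing expression record for transcript {transcript_id!r} "
                f"under condition {condition!r}"
            ) from None

    @property
    def conditions(self) -> list[str]:
        return sorted({cond for _, cond in self._records})

    def records(self) -> list[ExpressionRecord]:
        return list(self._records.values())
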