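"""Readers and writers for the formats the pipeline touches.

GFF3 carries the transcript models (feature types ``transcript`` and
``exon``; attributes ``ID``, ``Parent``, ``locus_id``, ``biotype``), BED6
carries collapsed small-RNA alignments (score column = copy count, the read
name may end in ``_<sequence>``), and plain TSV carries expression values and
the optional transcript-to-domain-term map.
"""

from __future__ import annotations

import os
from typing import Optional

import gffutils
import pandas as pd

from .core import (
    AnnotationSet,
    ExpressionRecord,
    ExpressionTable,
    GenomeInterval,
    ParseError,
    SmallRnaRead,
    TranscriptModel,
    ValidationError,
)


def _validate_gff3_lines(path: str) -> None:
    # Cheap structural pre-check so a malformed line is reported with its
    # line number instead of surfacing as an opaque database error.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if not (fields[3].isdigit() and fields[4].isdigit()):
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates")


def read_gff3(path: str) -> AnnotationSet:
    """Load transcript models from GFF3 into an :class:`AnnotationSet`.

    GFF3 1-based closed coordinates are converted to the internal 0-based
    half-open convention at this boundary.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="error",
    )
    ann = AnnotationSet()
    for feat in db.features_of_type("transcript"):
        tid = feat.attributes["ID"][0]
        locus = feat.attributes.get("locus_id", [tid])[0]
        biotype = feat.attributes.get("biotype", [None])[0]
        if biotype is None:
            raise ValidationError(f"transcript {tid}: missing biotype attribute")
        exons = []
        for exon in db.children(feat, featuretype="exon", order_by="start"):
            if exon.strand != feat.strand:
                raise ValidationError(
                    f"transcript {tid}: exon strand {exon.strand!r} conflicts "
                    f"with transcript strand {feat.strand!r}"
                )
            exons.append(
                GenomeInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
            )
        if not exons:
            # A transcript line without exon children models a single exon.
            exons = [GenomeInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)]
        ann.add(TranscriptModel(tid, locus, feat.seqid, feat.strand, exons, biotype))
    return ann


def write_gff3(ann: AnnotationSet, path: str) -> None:
    """Emit an :class:`AnnotationSet` in the dialect read by :func:`read_gff3`.

    Record order is deterministic: transcripts by (chrom, span start, id),
    each followed by its exons in coordinate order.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in ann.sorted_transcripts():
            fh.write(
                f"{t.chrom}\tcisnat\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\tID={t.id};locus_id={t.locus_id};biotype={t.biotype}\n"
            )
            for i, exon in enumerate(t.exons, start=1):
                fh.write(
                    f"{t.chrom}\tcisnat\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{t.strand}\t.\tID={t.id}.exon{i};Parent={t.id}\n"
                )


_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_smallrna_bed(path: str, condition_label: Optional[str] = None) -> list[SmallRnaRead]:
    """Load collapsed small-RNA reads from BED6.

    The score column carries the copy count of the collapsed read; when the
    name column ends in ``_<sequence>`` the 5' nucleotide is taken from the
    first character of that sequence (the sequence is stored in read
    orientation, so no reverse complementing is needed for minus-strand
    reads), otherwise it is recorded as ``N``.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=_BED_COLUMNS, comment="#",
            dtype={"chrom": str, "name": str, "strand": str},
        )
    except pd.errors.EmptyDataError:
        return []
    reads: list[SmallRnaRead] = []
    for row in df.itertuples(index=False):
        if row.start >= row.end:
            raise ValidationError(
                f"{path}: read {row.name}: start >= end ({row.start} >= {row.end})"
            )
        copies = int(row.score)
        if copies < 1:
            raise ValidationError(
                f"{path}: read {row.name}: copy count {copies} < 1"
            )
        first_nt = "N"
        if "_" in row.name:
            seq = row.name.rsplit("_", 1)[1].upper().replace("U", "T")
            if seq and all(c in "ACGTN" for c in seq):
                first_nt = seq[0]
        reads.append(
            SmallRnaRead(
                read_id=str(row.name),
                interval=GenomeInterval(row.chrom, int(row.start), int(row.end), row.strand),
                copies=copies,
                first_nt=first_nt,
            )
        )
    return reads


def write_smallrna_bed(reads: list[SmallRnaRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in sorted(reads, key=lambda r: (r.interval.chrom, r.interval.start, r.read_id)):
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.read_id}\t{r.copies}\t{iv.strand}\n"
            )


_EXPR_COLUMNS = ["transcript_id", "condition", "fpkm", "fragment_count", "library_size"]


def read_expression_table(path: str) -> ExpressionTable:
    """Load per-transcript, per-condition FPKM/count records from TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EXPR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df["library_size"].isna().any():
        raise ValidationError(f"{path}: missing library_size values")
    records = [
        ExpressionRecord(
            transcript_id=str(row.transcript_id),
            condition=str(row.condition),
            fpkm=float(row.fpkm),
            fragment_count=int(row.fragment_count),
            library_size=int(row.library_size),
        )
        for row in df.itertuples(index=False)
    ]
    return ExpressionTable(records)


def write_expression_table(table: ExpressionTable, path: str) -> None:
    rows = sorted(
        table.records(), key=lambda r: (r.transcript_id, r.condition)
    )
    df = pd.DataFrame(
        [
            (r.transcript_id, r.condition, r.fpkm, r.fragment_count, r.library_size)
            for r in rows
        ],
        columns=_EXPR_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_domain_map(path: str) -> dict[str, set[str]]:
    """Load the optional transcript-to-domain-term map (TSV, two columns)."""
    df = pd.read_csv(path, sep="\t")
    if not {"transcript_id", "domain_term"} <= set(df.columns):
        raise ValidationError(
            f"{path}: expected columns transcript_id, domain_term"
        )
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(str(row.transcript_id), set()).add(str(row.domain_term))
    return mapping


def write_domain_map(mapping: dict[str, set[str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tdomain_term\n")
        for tid in sorted(mapping):
            for term in sorted(mapping[tid]):
                fh.write(f"{tid}\t{term}\n")
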