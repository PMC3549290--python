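"""Report writers shaped like the field's summary tables.

``summarize_pairs`` produces the per-chromosome pair statistics (orientation
and partner-class columns, closing to a total row); ``summarize_expression``
the per-condition expression-evidence counts with co-expressed and total
rows.  ``headline_metrics`` turns any Table-1-shaped counts frame plus
genome-wide totals into the percentages such surveys quote.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .core import CisNatPair, AnnotationSet, PARTNER_CLASSES, ORIENTATIONS

PAIR_SUMMARY_COLUMNS = (
    ["chrom", "transcripts", "pairs"] + list(ORIENTATIONS) + list(PARTNER_CLASSES)
)


def summarize_pairs(pairs: Iterable[CisNatPair], ann: AnnotationSet) -> pd.DataFrame:
    """Per-chromosome pair statistics plus a closing total row."""
    pairs = list(pairs)
    per_chrom_tx: dict[str, int] = {}
    for t in ann:
        per_chrom_tx[t.chrom] = per_chrom_tx.get(t.chrom, 0) + 1
    rows = []
    for chrom in sorted(per_chrom_tx):
        chrom_pairs = [p for p in pairs if p.chrom == chrom]
        row = {"chrom": chrom, "transcripts": per_chrom_tx[chrom], "pairs": len(chrom_pairs)}
        for o in ORIENTATIONS:
            row[o] = sum(1 for p in chrom_pairs if p.orientation == o)
        for pc in PARTNER_CLASSES:
            row[pc] = sum(1 for p in chrom_pairs if p.partner_class == pc)
        rows.append(row)
    df = pd.DataFrame(rows, columns=PAIR_SUMMARY_COLUMNS)
    total = {"chrom": "Total"}
    for col in PAIR_SUMMARY_COLUMNS[1:]:
        total[col] = int(df[col].sum()) if len(df) else 0
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def check_pair_table_closure(df: pd.DataFrame) -> bool:
    """Orientation and partner-class columns must sum to the pair column in
    every row, and every numeric column must sum to the total row."""
    body = df[df["chrom"] != "Total"]
    total = df[df["chrom"] == "Total"]
    for _, row in body.iterrows():
        if sum(row[o] for o in ORIENTATIONS) != row["pairs"]:
            return False
        if sum(row[pc] for pc in PARTNER_CLASSES) != row["pairs"]:
            return False
    if len(total) != 1:
        return False
    for col in PAIR_SUMMARY_COLUMNS[1:]:
        if int(body[col].sum()) != int(total.iloc[0][col]):
            return False
    return True


def summarize_expression(
    expressed: Mapping[str, set[str]],
    exclusive: Mapping[str, set[str]],
    enriched: Mapping[str, set[str]],
    conditions: Iterable[str],
) -> pd.DataFrame:
    """Per-condition expression-evidence counts plus co-expressed/total rows.

    ``expressed``/``exclusive``/``enriched`` map each condition to the pair-id
    sets satisfying that screen; the co-expressed row intersects and the total
    row unions across conditions.
    """
    conditions = list(conditions)
    rows = []
    for cond in conditions:
        rows.append(
            {
                "condition": cond,
                "expressed": len(expressed.get(cond, set())),
                "exclusive": len(exclusive.get(cond, set())),
                "enriched": len(enriched.get(cond, set())),
            }
        )

    def across(sets: Mapping[str, set[str]], op) -> int:
        values = [set(sets.get(c, set())) for c in conditions]
        if not values:
            return 0
        return len(op(*values))

    rows.append(
        {
            "condition": "Co-expressed",
            "expressed": across(expressed, set.intersection),
            "exclusive": across(exclusive, set.intersection),
            "enriched": across(enriched, set.intersection),
        }
    )
    rows.append(
        {
            "condition": "Total",
            "expressed": across(expressed, set.union),
            "exclusive": across(exclusive, set.union),
            "enriched": across(enriched, set.union),
        }
    )
    return pd.DataFrame(rows, columns=["condition", "expressed", "exclusive", "enriched"])


def check_expression_table_closure(df: pd.DataFrame) -> bool:
    """Every per-condition and co-expressed count must not exceed the total."""
    total = df[df["condition"] == "Total"]
    if len(total) != 1:
        return False
    for col in ("expressed", "exclusive", "enriched"):
        if (df[col] > int(total.iloc[0][col])).any():
            return False
    return True


def headline_metrics(
    pair_counts: pd.DataFrame, cohort: Mapping[str, int]
) -> dict[str, float]:
    """Headline percentages from a pair-counts frame and genome-wide totals.

    All values are on the percent scale.  The frame must carry the
    orientation and partner-class columns of :func:`summarize_pairs` (a total
    row, if present, is ignored).
    """
    body = pair_counts[pair_counts["chrom"] != "Total"]
    n_pairs = int(body["pairs"].sum())
    pct = lambda num, den: 100.0 * num / den
    metrics = {
        "pct_enclosed": pct(int(body["enclosed"].sum()), n_pairs),
        "pct_convergent": pct(int(body["convergent"].sum()), n_pairs),
        "pct_divergent": pct(int(body["divergent"].sum()), n_pairs),
        "pct_coding_vs_noncoding": pct(int(body["CDS-p vs ncRNA"].sum()), n_pairs),
        "pct_coding_vs_undomained": pct(int(body["CDS-p vs CDS-n"].sum()), n_pairs),
    }
    if "one_to_one_pairs" in cohort:
        metrics["pct_one_to_one"] = pct(cohort["one_to_one_pairs"], cohort["total_pairs"])
    if "network_transcripts" in cohort and "total_transcripts" in cohort:
        involved = 2 * cohort["one_to_one_pairs"] + cohort["network_transcripts"]
        metrics["pct_transcripts_in_cisnat"] = pct(involved, cohort["total_transcripts"])
    if "coexpressed_pairs" in cohort:
        metrics["pct_coexpressed"] = pct(
            cohort["coexpressed_pairs"], cohort["expressed_pairs"]
        )
    if "stress_preferential_pairs" in cohort:
        metrics["pct_stress_preferential"] = pct(
            cohort["stress_preferential_pairs"], cohort["expressed_pairs"]
        )
    if "epidermal_pairs" in cohort:
        metrics["pct_epidermal"] = pct(cohort["epidermal_pairs"], cohort["expressed_pairs"])
        metrics["pct_epidermal_coexpressed"] = pct(
            cohort["epidermal_coexpressed"], cohort["epidermal_pairs"]
        )
    return metrics
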