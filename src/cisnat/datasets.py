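"""Bundled reference tables.

``rice_pair_counts.tsv`` holds the per-chromosome cis-NAT pair statistics of
a published genome-wide ssRNA-seq survey of rice (counts per orientation
class and partner class), and ``rice_cohort_counts.tsv`` the survey's
genome-wide totals (candidate pairs before/after biotype exclusion, network
bookkeeping, expression-evidence counts per condition).  They serve as a
worked example for the report arithmetic: every percentage the survey quotes
is a one-line computation over these counts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _path(name: str):
    return resources.files("cisnat").joinpath("datasets", name)


def load_reference_pair_counts() -> pd.DataFrame:
    """Per-chromosome pair counts (orientation and partner-class columns)."""
    with resources.as_file(_path("rice_pair_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def load_reference_cohort_counts() -> dict[str, int]:
    """Genome-wide totals of the reference survey, keyed by quantity name."""
    with resources.as_file(_path("rice_cohort_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["key"], df["value"].astype(int)))
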