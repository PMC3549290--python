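"""Condition-wise expression analysis of cis-NAT pairs.

A pair counts as expressed in a condition when both strands have FPKM > 0 and
at least one nat-siRNA falls in the overlap region of that condition's
small-RNA library.  Co-expression Venn sets, sense/antisense ratio
subgrouping, Fisher-exact differential-expression calls on fragment counts,
stress-preferential flags and domain-term enrichment follow from those calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import special, stats

from .core import (
    CisNatPair,
    DegResult,
    ExpressionTable,
    PairExpression,
    SiRnaProfile,
    ValidationError,
)

SUBGROUP_LABELS = ("1", "2", "3", "4", "5", "outlier")


def call_expressed(fpkm_plus: float, fpkm_minus: float, n_sirna: int) -> bool:
    """Expression evidence: FPKM > 0 on both strands and >= 1 nat-siRNA."""
    return fpkm_plus > 0 and fpkm_minus > 0 and n_sirna >= 1


def pair_expression(
    pair: CisNatPair,
    expr: ExpressionTable,
    profile: SiRnaProfile,
    condition: str,
    epsilon: float = 0.1,
) -> PairExpression:
    """Assemble the per-condition expression record for one pair."""
    rec_p = expr.get(pair.plus_transcript, condition)
    rec_m = expr.get(pair.minus_transcript, condition)
    n_sirna = profile.plus_unique + profile.minus_unique
    return PairExpression(
        pair_id=pair.pair_id,
        condition=condition,
        fpkm_plus=rec_p.fpkm,
        fpkm_minus=rec_m.fpkm,
        count_plus=rec_p.fragment_count,
        count_minus=rec_m.fragment_count,
        n_sirna=n_sirna,
        expressed=call_expressed(rec_p.fpkm, rec_m.fpkm, n_sirna),
        log_ratio=math.log2((rec_p.fpkm + epsilon) / (rec_m.fpkm + epsilon)),
    )


@dataclass
class CoexpressionSets:
    per_condition: dict[str, set[str]]
    intersection: set[str]
    union: set[str]


def coexpression_sets(
    expressed: Mapping[str, set[str]],
) -> CoexpressionSets:
    """Per-condition expressed pair sets plus their intersection and union."""
    sets = {c: set(s) for c, s in expressed.items()}
    values = list(sets.values())
    inter = set.intersection(*values) if values else set()
    union = set.union(*values) if values else set()
    return CoexpressionSets(per_condition=sets, intersection=inter, union=union)


def classify_subgroup(
    fpkm_plus_control: float,
    fpkm_minus_control: float,
    fpkm_plus_stress: float,
    fpkm_minus_stress: float,
    fc_threshold: float = 2.0,
    epsilon: float = 0.1,
) -> str:
    """Subgroup of a co-expressed pair from its stress/control log ratios.

    With ``ds`` the sense (plus strand) log2 stress/control ratio and ``da``
    the antisense one, and ``t = log2(fc_threshold)``:

    - ``1``: both ratios within +/- t (expression similar to control)
    - ``2``: sense up, antisense down; ``3``: sense down, antisense up
    - ``4``: both up; ``5``: both down
    - ``outlier``: any remaining mixed pattern
    """
    t = math.log2(fc_threshold)
    ds = math.log2((fpkm_plus_stress + epsilon) / (fpkm_plus_control + epsilon))
    da = math.log2((fpkm_minus_stress + epsilon) / (fpkm_minus_control + epsilon))
    if abs(ds) < t and abs(da) < t:
        return "1"
    if ds >= t and da <= -t:
        return "2"
    if ds <= -t and da >= t:
        return "3"
    if ds >= t and da >= t:
        return "4"
    if ds <= -t and da <= -t:
        return "5"
    return "outlier"


def pearson_r2(x: Iterable[float], y: Iterable[float]) -> float:
    """Square of the Pearson product-moment correlation coefficient."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("pearson_r2 requires two equal-length vectors, n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson_r2 undefined for zero-variance input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def _fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    # Exact hypergeometric enumeration with integer arithmetic: sum the
    # probabilities of all tables (same margins) no more probable than the
    # observed one.  Probabilities share the denominator C(N, r1), so the
    # comparison is done on integer numerators.
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    numers = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)
    }
    obs = numers[a]
    total = sum(v for v in numers.values() if v <= obs)
    return float(Fraction(total, math.comb(n, c1)))


def _fisher_two_sided_float(a: int, b: int, c: int, d: int) -> float:
    # Log-space enumeration for large margins; ties use a tiny relative slack.
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    ks = np.arange(lo, hi + 1)
    logp = (
        special.gammaln(r1 + 1)
        - special.gammaln(ks + 1)
        - special.gammaln(r1 - ks + 1)
        + special.gammaln(r2 + 1)
        - special.gammaln(c1 - ks + 1)
        - special.gammaln(r2 - (c1 - ks) + 1)
        - (special.gammaln(n + 1) - special.gammaln(c1 + 1) - special.gammaln(n - c1 + 1))
    )
    p = np.exp(logp)
    obs = p[a - lo]
    return float(min(1.0, p[p <= obs * (1 + 1e-10)].sum()))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact probability of the 2x2 table [[a, b], [c, d]].

    Computed by hypergeometric enumeration: the sum of the probabilities of
    every table with the observed margins whose probability does not exceed
    the observed table's.  Small tables use exact integer arithmetic; large
    ones a numerically stable log-space path.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("Fisher table entries must be non-negative")
    if a + b + c + d == 0:
        return 1.0
    if a + b + c + d <= 10_000:
        return _fisher_two_sided_exact(a, b, c, d)
    return _fisher_two_sided_float(a, b, c, d)


def fisher_exact_deg(
    count_stress: int,
    lib_stress: int,
    count_control: int,
    lib_control: int,
    fpkm_stress: float,
    fpkm_control: float,
    transcript_id: str = "",
    stress_condition: str = "stress",
    control_condition: str = "control",
    epsilon: float = 0.1,
    fc_threshold: float = 2.0,
    p_threshold: float = 1e-3,
) -> DegResult:
    """Differential-expression call for one transcript between two libraries.

    Significance comes from a two-sided Fisher exact test on fragment counts
    against the remaining library mass; the fold change is computed on FPKM
    with a pseudocount guard.  A transcript is a DEG when
    ``|log2(fold_change)| >= log2(fc_threshold)`` and ``p < p_threshold``.
    """
    if min(count_stress, count_control) < 0 or lib_stress <= count_stress or lib_control <= count_control:
        raise ValidationError("counts must be non-negative and below library sizes")
    p = fisher_exact_two_sided(
        count_stress, lib_stress - count_stress, count_control, lib_control - count_control
    )
    fold = (fpkm_stress + epsilon) / (fpkm_control + epsilon)
    is_deg = abs(math.log2(fold)) >= math.log2(fc_threshold) and p < p_threshold
    return DegResult(
        transcript_id=transcript_id,
        stress_condition=stress_condition,
        control_condition=control_condition,
        fold_change=fold,
        p_value=p,
        is_deg=is_deg,
    )


def stress_preferential(
    expressed_by_condition: Mapping[str, bool], control_condition: str
) -> dict[str, bool]:
    """Per-stress preferential-expression flags for one pair.

    A pair is preferential for a stress when it is expressed under that
    stress but not under the control; ``any`` combines across stresses.
    """
    if control_condition not in expressed_by_condition:
        raise ValidationError(f"missing control condition {control_condition!r}")
    in_control = expressed_by_condition[control_condition]
    flags = {
        cond: (not in_control) and flag
        for cond, flag in expressed_by_condition.items()
        if cond != control_condition
    }
    flags["any"] = any(flags.values())
    return flags


def domain_enrichment(
    target_transcripts: Iterable[str],
    background_transcripts: Iterable[str],
    domain_map: Mapping[str, set[str]],
    p_threshold: float = 1e-3,
):
    """Per-term two-sided Fisher enrichment of a target set vs background.

    The 2x2 table contrasts term membership inside the target against the
    background-only remainder; direction is read off the odds ratio.
    """
    import pandas as pd

    target = set(target_transcripts)
    background = set(background_transcripts)
    if not background:
        raise ValidationError("background transcript set is empty")
    if not target <= background:
        raise ValidationError("target transcripts must be a subset of the background")
    rest = background - target
    terms = sorted({t for tid in background for t in domain_map.get(tid, ())})
    rows = []
    for term in terms:
        a = sum(1 for tid in target if term in domain_map.get(tid, ()))
        b = len(target) - a
        c = sum(1 for tid in rest if term in domain_map.get(tid, ()))
        d = len(rest) - c
        p = fisher_exact_two_sided(a, b, c, d)
        # odds ratio direction; ties count as depleted only when strictly so
        lhs, rhs = a * d, b * c
        direction = "enriched" if lhs >= rhs else "depleted"
        rows.append(
            {
                "term": term,
                "count_target": a,
                "count_background": c,
                "p_value": p,
                "direction": direction,
                "significant": p < p_threshold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["term", "count_target", "count_background", "p_value", "direction", "significant"],
    )
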