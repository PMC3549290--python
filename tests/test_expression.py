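"""expression_analysis: expressed calls, subgroups, Fisher tests, enrichment."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from cisnat import (
    ValidationError,
    call_expressed,
    classify_subgroup,
    coexpression_sets,
    domain_enrichment,
    fisher_exact_deg,
    fisher_exact_two_sided,
    pearson_r2,
    stress_preferential,
)
from cisnat.expression import SUBGROUP_LABELS


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Independent brute-force two-sided Fisher oracle in exact rationals.

    Enumerates every 2x2 table with the observed margins, computes each
    hypergeometric probability from factorials, and sums those not exceeding
    the observed table's probability.
    """
    f = math.factorial
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2

    def prob(k: int) -> Fraction:
        # P(k in cell a) = r1! r2! c1! c2! / (n! k! (r1-k)! (c1-k)! (r2-c1+k)!)
        return Fraction(
            f(r1) * f(r2) * f(c1) * f(c2),
            f(n) * f(k) * f(r1 - k) * f(c1 - k) * f(r2 - (c1 - k)),
        )

    observed = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        p = prob(k)
        if p <= observed:
            total += p
    return total


class TestCallExpressed:
    def test_both_strands_and_sirna_present(self):
        assert call_expressed(3.2, 0.8, 2)

    def test_zero_fpkm_on_one_strand_fails(self):
        assert not call_expressed(3.2, 0.0, 9)

    def test_zero_sirna_fails(self):
        assert not call_expressed(3.2, 0.8, 0)


class TestCoexpression:
    def test_planted_membership_matrix(self):
        expressed = {
            "control": {"a", "b", "c"},
            "salt": {"a", "b"},
            "cold": {"a", "d"},
        }
        sets = coexpression_sets(expressed)
        assert sets.intersection == {"a"}
        assert sets.union == {"a", "b", "c", "d"}
        assert sets.per_condition["salt"] == {"a", "b"}

    def test_pair_expressed_everywhere_is_coexpressed(self):
        sets = coexpression_sets({c: {"p"} for c in "wxyz"})
        assert sets.intersection == {"p"}

    def test_single_condition_membership_reaches_union_only(self):
        sets = coexpression_sets({"control": set(), "cold": {"p"}})
        assert "p" in sets.union and "p" not in sets.intersection


def fpkm_for_delta(ctrl: float, delta: float, eps: float = 0.1) -> float:
    """Stress FPKM realizing exactly log2((s+eps)/(ctrl+eps)) = delta."""
    return (ctrl + eps) * 2.0 ** delta - eps


class TestSubgroups:
    def _classify(self, ds, da):
        ctrl = 10.0
        return classify_subgroup(
            ctrl, ctrl, fpkm_for_delta(ctrl, ds), fpkm_for_delta(ctrl, da)
        )

    def test_sense_up_antisense_down_is_subgroup_2(self):
        assert self._classify(+2.0, -1.5) == "2"

    def test_sense_down_antisense_up_is_subgroup_3(self):
        assert self._classify(-2.0, +1.5) == "3"

    def test_both_up_is_subgroup_4(self):
        assert self._classify(+1.5, +2.5) == "4"

    def test_both_down_is_subgroup_5(self):
        assert self._classify(-1.2, -3.0) == "5"

    def test_both_small_is_subgroup_1(self):
        assert self._classify(0.2, -0.3) == "1"

    def test_mixed_pattern_is_outlier(self):
        assert self._classify(+2.0, -0.2) == "outlier"

    def test_changes_just_past_the_threshold_classify_as_changed(self):
        assert self._classify(+1.01, +1.01) == "4"
        assert self._classify(+1.01, -1.01) == "2"
        assert self._classify(+0.99, -0.99) == "1"

    def test_every_input_gets_exactly_one_known_label(self):
        rng = np.random.default_rng(20240903)
        for _ in range(500):
            label = classify_subgroup(*rng.uniform(0.0, 50.0, size=4))
            assert label in SUBGROUP_LABELS

    def test_planted_subgroups_recover_on_default_fixture(self, run_result, bundle):
        truth = bundle["truth"]["pairs"]
        n = ok = 0
        for (pid, _cond), label in run_result.subgroups.items():
            planted = truth.get(pid, {}).get("subgroup")
            if planted is None:
                continue
            n += 1
            ok += label == planted
        assert n >= 100
        assert ok / n >= 0.95


class TestPearson:
    def test_identity_gives_one(self):
        assert pearson_r2([1, 2, 3, 5], [1, 2, 3, 5]) == pytest.approx(1.0)

    def test_sign_invariance(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_r2(x, [-2 * v for v in x]) == pytest.approx(1.0)

    def test_hand_derived_value(self):
        # x=(1,2,3), y=(1,2,4): cov=1, var_x=2/3, var_y=14/9, r^2 = 27/28
        assert pearson_r2([1, 2, 3], [1, 2, 4]) == pytest.approx(27 / 28, abs=1e-12)

    def test_zero_variance_is_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r2([1, 1, 1], [1, 2, 3])

    def test_concordant_low_noise_ratio_vectors_correlate(self):
        # subgroup-1-like regime: stress ratios track control ratios closely
        rng = np.random.default_rng(20240904)
        control = rng.normal(0.0, 1.0, size=200)
        stress = control + rng.normal(0.0, 0.15, size=200)
        assert pearson_r2(control, stress) > 0.85


class TestFisher:
    def test_empty_effect_table_gives_one(self):
        assert fisher_exact_two_sided(0, 1000, 0, 1000) == 1.0

    def test_all_zero_table_gives_one(self):
        assert fisher_exact_two_sided(0, 0, 0, 0) == 1.0

    def test_derived_enumeration_example(self):
        p = fisher_exact_two_sided(3, 997, 30, 970)
        oracle = float(fisher_oracle(3, 997, 30, 970))
        assert p == pytest.approx(oracle, abs=1e-12)
        assert p < 0.001

    def test_matches_oracle_on_random_small_tables(self):
        rng = np.random.default_rng(20240905)
        for _ in range(150):
            a, b, c, d = (int(v) for v in rng.integers(0, 60, size=4))
            p = fisher_exact_two_sided(a, b, c, d)
            assert p == pytest.approx(float(fisher_oracle(a, b, c, d)), abs=1e-12)
            assert 0.0 <= p <= 1.0

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(20240906)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 40, size=4))
            ours = fisher_exact_two_sided(a, b, c, d)
            ref = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_row_and_column_symmetry(self):
        assert fisher_exact_two_sided(3, 10, 12, 5) == pytest.approx(
            fisher_exact_two_sided(12, 5, 3, 10), abs=1e-15
        )
        assert fisher_exact_two_sided(3, 10, 12, 5) == pytest.approx(
            fisher_exact_two_sided(10, 3, 5, 12), abs=1e-15
        )

    def test_large_table_path_is_consistent_with_exact_path(self):
        # same table through both code paths (scaled past the integer cutoff)
        small = fisher_exact_two_sided(20, 4980, 60, 4940)  # N = 10,000: exact
        large = fisher_exact_two_sided(40, 9960, 120, 9880)  # N = 20,000: float
        assert 0 <= small <= 1 and 0 <= large <= 1
        ref = stats.fisher_exact([[40, 9960], [120, 9880]])[1]
        assert large == pytest.approx(ref, rel=1e-6)

    def test_negative_entries_are_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_two_sided(-1, 2, 3, 4)


class TestFisherDeg:
    def test_fold_change_arithmetic(self):
        res = fisher_exact_deg(300, 10000, 60, 10000, 8.0, 2.0)
        assert res.fold_change == pytest.approx(8.1 / 2.1)
        assert abs(math.log2(res.fold_change)) >= 1.0
        assert res.p_value < 0.001
        assert res.is_deg

    def test_no_change_is_not_deg(self):
        res = fisher_exact_deg(10, 10000, 10, 10000, 5.0, 5.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.is_deg

    def test_significant_but_small_fold_is_not_deg(self):
        # counts differ strongly, FPKM fold below 2: fails the fold criterion
        res = fisher_exact_deg(300, 10000, 60, 10000, 3.0, 2.0)
        assert res.p_value < 0.001
        assert not res.is_deg

    def test_count_exceeding_library_is_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_deg(11, 10, 1, 100, 1.0, 1.0)

    def test_planted_deg_labels_recover_on_default_fixture(self, run_result, bundle):
        truth = bundle["truth"]["deg_transcripts"]
        n = ok = 0
        for d in run_result.degs:
            planted = truth.get(d.transcript_id)
            if planted is None:
                continue
            n += 1
            ok += d.is_deg == planted
        assert n >= 100
        assert ok / n >= 0.95


class TestStressPreferential:
    def test_single_stress_exclusive(self):
        flags = stress_preferential(
            {"control": False, "cold": True, "salt": False}, "control"
        )
        assert flags == {"cold": True, "salt": False, "any": True}

    def test_expressed_in_control_disables_all_flags(self):
        flags = stress_preferential(
            {"control": True, "cold": True, "salt": True}, "control"
        )
        assert flags == {"cold": False, "salt": False, "any": False}

    def test_two_stresses_flagged(self):
        flags = stress_preferential(
            {"control": False, "salt": True, "drought": True, "cold": False},
            "control",
        )
        assert flags["salt"] and flags["drought"] and not flags["cold"]
        assert flags["any"]

    def test_missing_control_is_rejected(self):
        with pytest.raises(ValidationError):
            stress_preferential({"cold": True}, "control")


class TestDomainEnrichment:
    def test_strong_enrichment_is_significant(self):
        target = [f"t{i}" for i in range(10)]
        background = target + [f"b{i}" for i in range(1000)]
        domain_map = {t: {"PPR"} for t in target}
        domain_map.update({f"b{i}": {"PPR"} for i in range(10)})
        df = domain_enrichment(target, background, domain_map)
        row = df[df["term"] == "PPR"].iloc[0]
        assert row["direction"] == "enriched"
        assert row["count_target"] == 10 and row["count_background"] == 10
        assert row["p_value"] == pytest.approx(
            float(fisher_oracle(10, 0, 10, 990)), abs=1e-12
        )
        assert row["significant"]

    def test_identical_frequency_is_not_significant(self):
        target = [f"t{i}" for i in range(20)]
        rest = [f"b{i}" for i in range(20)]
        domain_map = {t: {"X"} for t in (target[:10] + rest[:10])}
        df = domain_enrichment(target, target + rest, domain_map)
        row = df.iloc[0]
        assert row["p_value"] > 0.5
        assert not row["significant"]

    def test_absence_from_target_is_depleted(self):
        target = ["t0", "t1"]
        background = target + ["b0", "b1", "b2"]
        domain_map = {"b0": {"X"}, "b1": {"X"}}
        row = domain_enrichment(target, background, domain_map).iloc[0]
        assert row["direction"] == "depleted"

    def test_target_outside_background_is_rejected(self):
        with pytest.raises(ValidationError):
            domain_enrichment(["a"], ["b"], {})

    def test_empty_background_is_rejected(self):
        with pytest.raises(ValidationError):
            domain_enrichment([], [], {})

    def test_planted_term_emerges_in_the_pipeline(self, run_result, bundle):
        # the generator plants one term among subgroup-1 sense members
        enr = run_result.enrichment
        term = bundle["config"].enriched_term
        hits = enr[(enr["term"] == term) & enr["significant"]]
        assert set(hits["subgroup"]) == {"1"}
        assert (hits["direction"] == "enriched").all()
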