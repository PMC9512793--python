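"""Conditional matrix, weighted proportions, Poisson-bootstrap CI, accumulated rate."""

import numpy as np
import pandas as pd
import pytest

from oncoprev.epidemiology import WeightVector
from oncoprev.exceptions import AlignmentError, NumericError
from oncoprev.filtering import GeneSampleTable
from oncoprev.prevalence import (
    ConditionalMatrix,
    accumulated_rate,
    conditional_matrix,
    poisson_ci,
    weighted_proportions,
)


def wv(d):
    return WeightVector(weights=pd.Series(d, dtype=float), kind="final", q=0.0)


def table(cohort_id, n, mutated, record_counts=None):
    return GeneSampleTable(
        cohort_id=cohort_id, n_samples=n,
        mutated_samples={g: set(s) for g, s in mutated.items()},
        record_counts=record_counts
        or {g: len(s) for g, s in mutated.items()},
    )


class TestConditionalMatrix:
    def test_two_of_four_samples_gives_half(self):
        tables = {"A": table("A", 4, {"TP53": {"s1", "s2"}})}
        m = conditional_matrix(tables, ["TP53"], site_order=["A"])
        assert m.prob[0, 0] == pytest.approx(0.5)

    def test_unobserved_gene_gets_zero_row(self):
        tables = {"A": table("A", 4, {"TP53": {"s1"}})}
        m = conditional_matrix(tables, ["TP53", "EGFR"], site_order=["A"])
        assert m.prob[1].tolist() == [0.0]

    def test_matches_brute_force_recount(self, small_study):
        from oncoprev.epidemiology import aggregate_profiles
        from oncoprev.filtering import tabulate, tier1_filter, tier2_filter
        from oncoprev.mutation_io import CohortProfile, resolve_synonyms

        truth = small_study["truth"]
        panel = truth.panel()
        filtered = []
        for c in small_study["cohorts"]:
            recs, _ = resolve_synonyms(c.records, panel)
            recs = tier2_filter(tier1_filter(recs, panel))
            filtered.append(
                CohortProfile(c.cohort_id, c.subtype_code, c.samples, recs,
                              icd10_site=c.icd10_site)
            )
        merged = aggregate_profiles(
            filtered, {c.subtype_code: c.icd10_site for c in filtered}
        )
        tables = {c.icd10_site: tabulate(c) for c in merged}
        m = conditional_matrix(tables, truth.gene_ids,
                               site_order=truth.site_ids)
        for j, site in enumerate(truth.site_ids):
            cohort = next(c for c in merged if c.icd10_site == site)
            for i, gene in enumerate(truth.gene_ids):
                mutated = {r.sample_id for r in cohort.records if r.gene == gene}
                assert m.counts[i, j] == len(mutated)

    def test_count_exceeding_n_rejected(self):
        with pytest.raises(NumericError):
            ConditionalMatrix(genes=["g"], sites=["s"],
                              counts=np.array([[5]]), n_samples=np.array([4]))

    def test_empty_cohort_site_rejected(self):
        with pytest.raises(NumericError):
            ConditionalMatrix(genes=["g"], sites=["s"],
                              counts=np.array([[0]]), n_samples=np.array([0]))


class TestWeightedProportions:
    def test_forced_arithmetic(self):
        m = ConditionalMatrix(genes=["g"], sites=["A", "B"],
                              counts=np.array([[5, 2]]),
                              n_samples=np.array([10, 10]))
        est = weighted_proportions(m, wv({"A": 0.6, "B": 0.4}))
        assert est["g"] == pytest.approx(0.38)

    def test_single_site_identity(self):
        m = ConditionalMatrix(genes=["g"], sites=["A"],
                              counts=np.array([[3]]), n_samples=np.array([4]))
        est = weighted_proportions(m, wv({"A": 1.0}))
        assert est["g"] == pytest.approx(0.75)

    def test_site_mismatch_raises_listing_difference(self):
        m = ConditionalMatrix(genes=["g"], sites=["A"],
                              counts=np.array([[1]]), n_samples=np.array([4]))
        with pytest.raises(AlignmentError, match="B"):
            weighted_proportions(m, wv({"B": 1.0}))

    def test_monotone_in_each_probability(self, rng):
        counts = rng.integers(0, 20, size=(5, 3))
        n = np.full(3, 20)
        v = wv({"A": 0.5, "B": 0.3, "C": 0.2})
        m = ConditionalMatrix(genes=list("abcde"), sites=["A", "B", "C"],
                              counts=counts, n_samples=n)
        base = weighted_proportions(m, v)
        bumped = counts.copy()
        bumped[2, 1] = min(20, bumped[2, 1] + 1)
        m2 = ConditionalMatrix(genes=list("abcde"), sites=["A", "B", "C"],
                               counts=bumped, n_samples=n)
        est2 = weighted_proportions(m2, v)
        assert (est2 >= base - 1e-15).all()

    def test_invariant_to_site_permutation(self, rng):
        counts = rng.integers(0, 15, size=(4, 3))
        m = ConditionalMatrix(genes=list("abcd"), sites=["A", "B", "C"],
                              counts=counts, n_samples=np.full(3, 15))
        v = wv({"A": 0.2, "B": 0.5, "C": 0.3})
        perm = ConditionalMatrix(genes=list("abcd"), sites=["C", "A", "B"],
                                 counts=counts[:, [2, 0, 1]],
                                 n_samples=np.full(3, 15))
        assert np.allclose(weighted_proportions(m, v),
                           weighted_proportions(perm, v))


class TestPoissonCI:
    def test_all_zero_counts_give_degenerate_ci(self):
        m = ConditionalMatrix(genes=["g"], sites=["A"],
                              counts=np.array([[0]]), n_samples=np.array([50]))
        ci = poisson_ci(m, wv({"A": 1.0}), n_reps=100, seed=1)
        assert ci.loc["g", "ci_low"] == 0.0 and ci.loc["g", "ci_high"] == 0.0

    def test_saturated_count_clamped_at_one(self):
        m = ConditionalMatrix(genes=["g"], sites=["A"],
                              counts=np.array([[30]]), n_samples=np.array([30]))
        ci = poisson_ci(m, wv({"A": 1.0}), n_reps=500, seed=1)
        assert ci.loc["g", "ci_high"] == pytest.approx(1.0)
        assert ci.loc["g", "ci_low"] <= 1.0

    def test_bit_identical_under_fixed_seed(self, rng):
        counts = rng.integers(0, 40, size=(6, 3))
        m = ConditionalMatrix(genes=list("abcdef"), sites=["A", "B", "C"],
                              counts=counts, n_samples=np.full(3, 60))
        v = wv({"A": 0.3, "B": 0.3, "C": 0.4})
        a = poisson_ci(m, v, n_reps=2000, seed=99)
        b = poisson_ci(m, v, n_reps=2000, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_chunking_does_not_change_the_stream(self, rng):
        counts = rng.integers(0, 40, size=(4, 2))
        m = ConditionalMatrix(genes=list("abcd"), sites=["A", "B"],
                              counts=counts, n_samples=np.full(2, 60))
        v = wv({"A": 0.5, "B": 0.5})
        a = poisson_ci(m, v, n_reps=400, seed=5, chunk=400)
        b = poisson_ci(m, v, n_reps=400, seed=5, chunk=37)
        pd.testing.assert_frame_equal(a, b)

    def test_ci_width_shrinks_with_counts_at_fixed_proportion(self):
        v = wv({"A": 1.0})
        widths = []
        for scale in (1, 10, 100):
            m = ConditionalMatrix(genes=["g"], sites=["A"],
                                  counts=np.array([[3 * scale]]),
                                  n_samples=np.array([20 * scale]))
            ci = poisson_ci(m, v, n_reps=2000, seed=7)
            widths.append(ci.loc["g", "ci_high"] - ci.loc["g", "ci_low"])
        assert widths[0] > widths[1] > widths[2]

    def test_ci_bounds_ordered_and_in_unit_interval(self, rng):
        counts = rng.integers(0, 30, size=(8, 4))
        m = ConditionalMatrix(genes=[f"g{i}" for i in range(8)],
                              sites=list("ABCD"), counts=counts,
                              n_samples=np.full(4, 30))
        v = wv({"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25})
        ci = poisson_ci(m, v, n_reps=500, seed=3)
        assert (ci["ci_low"] <= ci["ci_high"]).all()
        assert (ci["ci_low"] >= 0).all() and (ci["ci_high"] <= 1).all()

    def test_too_few_replicates_rejected(self):
        m = ConditionalMatrix(genes=["g"], sites=["A"],
                              counts=np.array([[1]]), n_samples=np.array([4]))
        with pytest.raises(NumericError):
            poisson_ci(m, wv({"A": 1.0}), n_reps=1, seed=0)


class TestAccumulatedRate:
    def test_two_mutations_one_patient_is_200_percent(self):
        t = table("c", 1, {"EGFR": {"s1"}}, record_counts={"EGFR": 2})
        assert accumulated_rate(t, "EGFR") == pytest.approx(2.0)

    def test_equals_prevalence_when_one_record_each(self):
        t = table("c", 4, {"KRAS": {"s1", "s2"}}, record_counts={"KRAS": 2})
        assert accumulated_rate(t, "KRAS") == pytest.approx(t.proportion("KRAS"))

    def test_matches_brute_force_record_count(self, small_study):
        from oncoprev.filtering import tabulate, tier1_filter, tier2_filter
        from oncoprev.mutation_io import CohortProfile, resolve_synonyms

        truth = small_study["truth"]
        panel = truth.panel()
        c = small_study["cohorts"][0]
        recs, _ = resolve_synonyms(c.records, panel)
        recs = tier2_filter(tier1_filter(recs, panel))
        cohort = CohortProfile(c.cohort_id, c.subtype_code, c.samples, recs)
        t = tabulate(cohort)
        for gene in {r.gene for r in recs}:
            expected = sum(1 for r in recs if r.gene == gene) / cohort.n_samples
            assert accumulated_rate(t, gene) == pytest.approx(expected)
            assert accumulated_rate(t, gene) >= t.proportion(gene) - 1e-12

    def test_absent_gene_is_zero_and_empty_cohort_rejected(self):
        t = table("c", 5, {})
        assert accumulated_rate(t, "TP53") == 0.0
        empty = GeneSampleTable(cohort_id="c", n_samples=0)
        with pytest.raises(NumericError):
            accumulated_rate(empty, "TP53")
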