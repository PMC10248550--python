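import math

import numpy as np
import pytest

from dnvscreen.enrichment import (
    ContingencyTable,
    bh_adjust,
    enrichment_screen,
    fet_one_sided,
    relative_risk,
    score_threshold_membership,
    wilcoxon_greater,
)
from dnvscreen.simulate import (
    CategorySimConfig,
    CohortSimConfig,
    ScoreSimConfig,
    plant_category,
    simulate_cohort,
    simulate_scores,
)
from oracles import bh_stepup_reference, hyper_upper_tail_exact, hyper_upper_tail_lgamma, ranksum_greater_exact


class TestFisherOneSided:
    def test_tiny_table_enumeration(self):
        # C(2,2)C(2,0)/C(4,2) = 1/6
        p, _ = fet_one_sided(ContingencyTable(2, 0, 2, 2))
        assert p == pytest.approx(1 / 6, abs=1e-15)

    def test_zero_proband_count_gives_p_one(self):
        p, _ = fet_one_sided(ContingencyTable(0, 5, 10, 10))
        assert p == 1.0

    def test_empty_category_convention(self):
        p, odds = fet_one_sided(ContingencyTable(0, 0, 10, 10))
        assert p == 1.0 and math.isnan(odds)

    def test_cohort_scale_stopgain_counts_match_tail_oracle(self):
        # stop-gain burden: 120 proband vs 62 sibling dnSNVs
        t = ContingencyTable(120, 62, 134_969, 131_896)
        p, _ = fet_one_sided(t)
        oracle = hyper_upper_tail_lgamma(120, 134_969 + 131_896, 182, 134_969)
        assert p == pytest.approx(oracle, abs=1e-12)
        assert p < 0.001  # strongly enriched before any adjustment

    def test_random_small_tables_match_exact_enumeration(self, rng):
        for _ in range(200):
            n_p = int(rng.integers(1, 30))
            n_s = int(rng.integers(1, 30))
            k_p = int(rng.integers(0, n_p + 1))
            k_s = int(rng.integers(0, n_s + 1))
            p, _ = fet_one_sided(ContingencyTable(k_p, k_s, n_p, n_s))
            expect = 1.0 if k_p == 0 else hyper_upper_tail_exact(
                k_p, n_p + n_s, k_p + k_s, n_p
            )
            assert p == pytest.approx(expect, rel=1e-12, abs=1e-300)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(5, 0, 4, 10)


class TestRelativeRisk:
    def test_equal_proportions_give_unity(self):
        assert relative_risk(ContingencyTable(10, 20, 100, 200)) == pytest.approx(1.0)

    def test_lof_coding_burden_counts(self):
        # 604 proband vs 467 sibling predicted LoF coding mutations
        rr = relative_risk(ContingencyTable(604, 467, 134_969, 131_896))
        assert rr == pytest.approx((604 / 134_969) / (467 / 131_896), rel=1e-12)
        assert rr == pytest.approx(1.264, abs=5e-3)

    def test_linearity_in_proband_count(self):
        base = relative_risk(ContingencyTable(10, 20, 100, 200))
        assert relative_risk(ContingencyTable(20, 20, 100, 200)) == pytest.approx(2 * base)

    def test_zero_sibling_count_reported_missing(self):
        assert math.isnan(relative_risk(ContingencyTable(3, 0, 10, 10)))


class TestScoreThreshold:
    def test_integer_scores_top_five_percent(self):
        sp = np.arange(1.0, 51.0)
        ss = np.arange(51.0, 101.0)
        t, thr = score_threshold_membership(sp, ss, 0.05)
        assert thr == 96.0
        assert (t.k_p, t.k_s) == (0, 5)
        assert (t.n_p, t.n_s) == (50, 50)

    def test_constant_scores_all_tied_at_threshold(self):
        t, _ = score_threshold_membership(np.ones(10), np.ones(20), 0.05)
        assert (t.k_p, t.k_s) == (10, 20)  # inclusive tie policy

    def test_all_missing_scores_error(self):
        with pytest.raises(ValueError):
            score_threshold_membership(np.array([np.nan]), np.ones(3))

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            score_threshold_membership(np.ones(3), np.ones(3), fraction=1.0)


class TestWilcoxonGreater:
    def test_fully_separated_small_samples(self):
        # all 20 rank assignments: only one puts {4,5,6} on top
        assert wilcoxon_greater([4, 5, 6], [1, 2, 3]) == pytest.approx(0.05)

    def test_swapped_samples_exceed_half(self):
        assert wilcoxon_greater([1, 2, 3], [4, 5, 6]) >= 0.5

    def test_matches_enumeration_oracle_at_small_n(self, rng):
        for n1, n2 in [(3, 3), (5, 4), (6, 6)]:
            x = rng.random(n1)
            y = rng.random(n2)
            assert wilcoxon_greater(x, y) == pytest.approx(
                ranksum_greater_exact(x, y), rel=1e-12
            )

    def test_identical_constant_samples_carry_no_evidence(self):
        assert wilcoxon_greater(np.ones(5), np.ones(7)) == 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_greater(np.array([]), np.ones(3))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.034])[0] == pytest.approx(0.034)

    def test_closed_form_triple(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_stepup_reference_and_bounds(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            adj = bh_adjust(p)
            assert adj == pytest.approx(bh_stepup_reference(list(p)), rel=1e-12)
            assert np.all(adj >= p) and np.all(adj <= 1.0)
            # monotone non-decreasing in the sorted-p domain
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnrichmentScreen:
    def test_planted_strong_effect_among_nulls(self):
        # one coding-like strong category among 64 null categories: the
        # planted effect must top the screen and survive BH; FDR control at
        # 0.05 still tolerates an occasional false discovery among nulls
        cohort = simulate_cohort(CohortSimConfig(n_families=150, seed=21))
        strong, _ = plant_category(
            cohort, CategorySimConfig(baseline_prop=0.01, relative_excess=1.0, seed=1)
        )
        strong.name = "planted_strong"
        nulls = []
        for i in range(64):
            cat, _ = plant_category(
                cohort, CategorySimConfig(baseline_prop=0.03, relative_excess=0.0, seed=100 + i)
            )
            cat.name = f"null_{i:02d}"
            nulls.append(cat)
        res = enrichment_screen(cohort, [strong] + nulls)
        sig = res[res.significant]
        assert sig.category.iloc[0] == "planted_strong"
        assert (sig.category != "planted_strong").sum() <= 1

    def test_score_columns_get_fet_and_ranksum_rows(self, small_cohort):
        t = small_cohort.__class__(small_cohort.df.copy())
        simulate_scores(t, ScoreSimConfig(proband_shift=0.3, seed=2), column="turf")
        res = enrichment_screen(t, [], ["turf"])
        assert set(res.test) == {"fet_top5", "ranksum"}
        assert (res[res.test == "ranksum"]["p_raw"]
                == res[res.test == "ranksum"]["p_adjusted"]).all()

    def test_empty_screen_returns_empty_frame(self, small_cohort):
        res = enrichment_screen(small_cohort, [], [])
        assert len(res) == 0

    def test_screen_deterministic(self, small_cohort):
        cat, _ = plant_category(small_cohort, CategorySimConfig(0.05, 0.2, seed=4))
        a = enrichment_screen(small_cohort, [cat])
        b = enrichment_screen(small_cohort, [cat])
        assert a.equals(b)

    def test_adjusted_never_below_raw(self, small_cohort):
        cats = []
        for i in range(5):
            c, _ = plant_category(small_cohort, CategorySimConfig(0.05, 0.0, seed=i))
            c.name = f"c{i}"
            cats.append(c)
        res = enrichment_screen(small_cohort, cats)
        assert (res.p_adjusted >= res.p_raw - 1e-15).all()
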