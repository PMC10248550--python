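import math

import numpy as np
import pytest

from dnvscreen.callsets import CallSet, callset_ops, upset_counts
from dnvscreen.simulate import (
    CategorySimConfig,
    CohortSimConfig,
    ScoreSimConfig,
    StudySimConfig,
    plant_category,
    sample_overlap_counts,
    simulate_cohort,
    simulate_multistudy_callsets,
    simulate_scores,
    simulate_trio_genotypes,
)


class TestSimulateCohort:
    def test_fullscale_cohort_matches_reference_structure(self, fullscale_cohort):
        t = fullscale_cohort
        # total proband dnSNVs within 3 SD of the reference total
        expected = 134_969
        assert abs(t.n_proband - expected) < 3 * math.sqrt(expected)
        # median per-child count near 70 / 68
        per_child = t.df.groupby(["cohort", "child_id"], observed=True).size()
        assert abs(per_child["proband"].median() - 70) <= 1
        assert abs(per_child["sibling"].median() - 68) <= 1
        # ~98% of dnSNVs land in intronic/intergenic compartments
        noncoding = t.df["compartment"].isin(["intronic", "intergenic"]).mean()
        assert 0.97 < noncoding < 0.99

    def test_positions_unique_and_autosomal(self, small_cohort):
        df = small_cohort.df
        assert not df.duplicated(["chrom", "pos"]).any()
        assert set(df["chrom"]) <= {str(i) for i in range(1, 23)}

    def test_deterministic_under_seed(self):
        cfg = CohortSimConfig(n_families=20, seed=9)
        assert simulate_cohort(cfg).df.equals(simulate_cohort(cfg).df)
        other = simulate_cohort(CohortSimConfig(n_families=20, seed=10))
        assert not simulate_cohort(cfg).df.equals(other.df)

    def test_near_empty_rates_do_not_crash(self):
        t = simulate_cohort(CohortSimConfig(n_families=10, rate_proband=1e-4,
                                            rate_sibling=1e-4, seed=0))
        assert len(t) <= 2

    def test_compartment_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSimConfig(compartment_probs={"intronic": 0.5})


class TestPlantCategory:
    def test_null_effect_gives_equal_overlap_fractions(self, small_cohort):
        cfg = CategorySimConfig(baseline_prop=0.05, relative_excess=0.0, seed=1)
        _, member = plant_category(small_cohort, cfg)
        f_p = member[small_cohort.is_proband].mean()
        f_s = member[~small_cohort.is_proband].mean()
        # both binomial around 0.05; 4 SD of the difference
        se = math.sqrt(2 * 0.05 * 0.95 / small_cohort.n_proband)
        assert abs(f_p - f_s) < 4 * se

    def test_planted_excess_hits_binomial_expectation(self, fullscale_cohort):
        # effect-size structure of the best-performing published category
        cfg = CategorySimConfig(baseline_prop=0.0496, relative_excess=0.0219, seed=2)
        _, member = plant_category(fullscale_cohort, cfg)
        n_p = fullscale_cohort.n_proband
        k_p = member[fullscale_cohort.is_proband].sum()
        expect = cfg.proband_prop * n_p
        assert abs(k_p - expect) < 4 * math.sqrt(expect)

    def test_zero_baseline_gives_no_overlaps(self, small_cohort):
        _, member = plant_category(
            small_cohort, CategorySimConfig(baseline_prop=0.0, seed=3)
        )
        assert member.sum() == 0

    def test_invalid_proband_probability_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            CategorySimConfig(baseline_prop=0.6, relative_excess=0.8)

    def test_counts_fast_path_matches_distribution(self, rng):
        cfg = CategorySimConfig(baseline_prop=0.05, relative_excess=0.5, seed=0)
        k_p, k_s = sample_overlap_counts(10_000, 10_000, cfg, rng)
        assert abs(k_p - 750) < 4 * math.sqrt(750)
        assert abs(k_s - 500) < 4 * math.sqrt(500)


class TestSimulateScores:
    def test_extreme_shift_puts_probands_on_top(self, small_cohort):
        from dnvscreen.enrichment import wilcoxon_greater

        t = small_cohort.__class__(small_cohort.df.copy())
        simulate_scores(t, ScoreSimConfig(proband_shift=1.0, seed=4), column="s")
        sp, ss = t.cohort_scores("s")
        assert sp.min() == 1.0
        assert wilcoxon_greater(sp, ss) < 1e-100

    def test_top_fraction_membership_matches_quantile_oracle(self, small_cohort):
        from dnvscreen.enrichment import score_threshold_membership

        t = small_cohort.__class__(small_cohort.df.copy())
        simulate_scores(t, ScoreSimConfig(proband_shift=0.0, seed=5), column="s")
        sp, ss = t.cohort_scores("s")
        table, thr = score_threshold_membership(sp, ss, 0.05)
        # sort-based oracle for the "higher" empirical quantile
        pooled = np.sort(np.concatenate([sp, ss]))
        cut = pooled[math.ceil(0.95 * (len(pooled) - 1))]
        assert thr == cut
        assert table.k_p + table.k_s == int((pooled >= cut).sum())
        assert table.k_p == int((sp >= cut).sum())

    def test_deterministic_under_seed(self, small_cohort):
        a = small_cohort.__class__(small_cohort.df.copy())
        b = small_cohort.__class__(small_cohort.df.copy())
        simulate_scores(a, ScoreSimConfig(seed=6))
        simulate_scores(b, ScoreSimConfig(seed=6))
        assert np.array_equal(a.df["score"], b.df["score"])


class TestQuadFixtures:
    def test_all_inherited_yields_zero_candidates(self):
        from dnvscreen.filtering import filter_denovo
        from dnvscreen.vcfio import parse_ped, parse_vcf_minimal

        res = simulate_trio_genotypes({"inherited": 30}, seed=3)
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as d:
            paths = res.write(d)
            sites, _ = parse_vcf_minimal(paths["vcf"], parse_ped(paths["ped"]))
        table, report = filter_denovo(sites)
        assert len(table) == 0 and report.n_candidates == 0

    def test_truth_table_covers_every_planted_site(self, quad_fixture):
        result, _ = quad_fixture
        spec_counts = result.truth.site_class.value_counts()
        assert spec_counts["true_denovo"] == 20
        assert spec_counts["recurrent"] == 6  # 3 pairs, two carriers each

    def test_unknown_site_class_rejected(self):
        with pytest.raises(ValueError, match="unknown site classes"):
            simulate_trio_genotypes({"bogus": 1})


class TestMultistudyCallsets:
    def _truth(self, n=400):
        t = simulate_cohort(CohortSimConfig(n_families=3, seed=8))
        return CallSet.from_table(t, "truth")

    def test_perfect_studies_all_equal_truth(self):
        truth = self._truth()
        studies = simulate_multistudy_callsets(
            truth, StudySimConfig(n_studies=3, false_negative_rate=0.0,
                                  false_positive_rate=0.0, seed=1)
        )
        for s in studies:
            assert s.keys == truth.keys

    def test_independent_false_positives_never_shared(self):
        truth = self._truth()
        studies = simulate_multistudy_callsets(
            truth, StudySimConfig(n_studies=2, false_negative_rate=0.0,
                                  false_positive_rate=0.1, seed=2)
        )
        fps = [s.keys - truth.keys for s in studies]
        assert fps[0] and fps[1]
        assert not (fps[0] & fps[1])
        inter = callset_ops(*studies)["intersection"]
        assert not (inter.keys - truth.keys)  # intersection purges FPs

    def test_upset_totals_match_study_sizes(self):
        truth = self._truth()
        studies = simulate_multistudy_callsets(
            truth, StudySimConfig(n_studies=4, seed=3)
        )
        counts = upset_counts(studies)
        for s in studies:
            assert sum(v for pat, v in counts.items() if s.study_name in pat) == len(s)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_multistudy_callsets(CallSet("t", frozenset()), StudySimConfig())
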