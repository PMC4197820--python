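"""Statistical operations: seed classification, BH, exact tests, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirededit.quantify import EditingQuant
from mirededit.stats import (
    CONSERVED_SITE_CATALOG,
    age_correlation,
    analyze_cancer_pairs,
    bh_adjust,
    binomial_direction_test,
    chisq_pair_test,
    cluster_profiles,
    cut_clusters,
    seed_classify,
    seed_fraction,
    species_comparison,
    target_expression_comparison,
    tissue_comparison,
)


class TestSeedClassification:
    def test_catalog_fraction_is_11_of_15(self):
        positions = [p for _m, p in CONSERVED_SITE_CATALOG]
        assert len(positions) == 15
        frac = seed_fraction(positions)
        assert frac == pytest.approx(11 / 15)
        assert round(frac * 100) == 73

    def test_position_one_outside_seed(self):
        assert seed_classify(1) is False

    def test_position_eight_inside_default_span(self):
        assert seed_classify(8) is True
        assert seed_classify(8, seed_span=(2, 7)) is False

    def test_catalog_fraction_identical_under_2_7_span(self):
        # no catalog site sits at position 8, so both conventions agree
        positions = [p for _m, p in CONSERVED_SITE_CATALOG]
        assert seed_fraction(positions, (2, 7)) == seed_fraction(positions, (2, 8))

    def test_invalid_position_rejected(self):
        with pytest.raises(ValueError):
            seed_classify(0)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_q_at_least_p_and_in_unit_interval(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all((q >= 0) & (q <= 1))
        # monotone in rank: sorting by p sorts q
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestBinomialDirectionTest:
    def test_observed_tallies_match_printed_precision(self):
        assert binomial_direction_test(21, 26) == pytest.approx(0.0025, abs=5e-5)
        assert binomial_direction_test(136, 213) == pytest.approx(6.4e-5, rel=0.01)

    def test_symmetric_center_is_one(self):
        assert binomial_direction_test(5, 10) == pytest.approx(1.0)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            binomial_direction_test(0, 0)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=1, max_value=200), st.data())
    def test_symmetry_at_half(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        assert binomial_direction_test(k, n) == pytest.approx(
            binomial_direction_test(n - k, n)
        )


class TestChisqPairTest:
    def test_identical_proportions_tied_p_one(self):
        c = EditingQuant("n", "m", edited=200, unedited=800)
        t = EditingQuant("t", "m", edited=200, unedited=800)
        cmp = chisq_pair_test(c, t)
        assert cmp.direction == "tied" and cmp.p_value == pytest.approx(1.0)

    def test_closed_form_value_and_direction(self):
        c = EditingQuant("n", "m", edited=200, unedited=800)
        t = EditingQuant("t", "m", edited=100, unedited=900)
        cmp = chisq_pair_test(c, t)
        assert cmp.direction == "down"
        n, a, b, cc, d = 2000, 200, 800, 100, 900
        chi2 = n * (a * d - b * cc) ** 2 / (1000 * 1000 * 300 * 1700)
        assert cmp.chi2 == pytest.approx(chi2)

    def test_chi2_equals_squared_two_proportion_z(self):
        from scipy.stats import norm

        c = EditingQuant("n", "m", edited=150, unedited=850)
        t = EditingQuant("t", "m", edited=120, unedited=880)
        cmp = chisq_pair_test(c, t)
        # 1-df identity: chi2 p equals the two-sided tail of z = sqrt(chi2)
        assert 2 * norm.sf(np.sqrt(cmp.chi2)) == pytest.approx(cmp.p_value)

    def test_coverage_rule_excludes_pairs(self):
        good = (EditingQuant("n", "m", 60, 60), EditingQuant("t", "m", 30, 90))
        thin = (EditingQuant("n2", "m", 10, 20), EditingQuant("t2", "m", 5, 25))
        analysis = analyze_cancer_pairs([good, thin])
        assert analysis.n_excluded_coverage == 1
        assert len(analysis.comparisons) == 1

    def test_majority_down_direction_recovered(self):
        rng = np.random.default_rng(2)
        pairs = []
        for i in range(30):
            f = rng.uniform(0.3, 0.6)
            ec = rng.binomial(1000, f)
            et = rng.binomial(1000, max(f - 0.15, 0.0))
            pairs.append((EditingQuant(f"n{i}", "m", ec, 1000 - ec),
                          EditingQuant(f"t{i}", "m", et, 1000 - et)))
        analysis = analyze_cancer_pairs(pairs)
        assert analysis.n_down > analysis.n_tested / 2
        assert analysis.binomial_p_all < 0.05
        assert analysis.n_significant_down > analysis.n_significant_up


class TestAgeCorrelation:
    AGES = [1, 2, 4, 8, 16, 32, 50, 60]

    def test_strictly_increasing_rho_one(self):
        freq = pd.DataFrame([np.linspace(0.1, 0.5, 8)], index=["m1"])
        out = age_correlation(freq, self.AGES)
        assert out.rho.iloc[0] == pytest.approx(1.0)

    def test_low_edited_count_excluded(self):
        freq = pd.DataFrame([np.linspace(0.1, 0.5, 8)] * 2, index=["m1", "m2"])
        # nine edited reads in total across the series: below the minimum of 10
        counts = pd.DataFrame([[2, 2, 2, 3, 0, 0, 0, 0], [10] * 8],
                              index=["m1", "m2"])
        out = age_correlation(freq, self.AGES, edited_counts=counts).set_index("entity_id")
        assert out.loc["m1", "flag"] == "low-coverage"
        assert np.isnan(out.loc["m1", "rho"])
        assert out.loc["m2", "flag"] == ""

    def test_constant_series_flagged_not_tested(self):
        freq = pd.DataFrame([[0.3] * 8], index=["m1"])
        out = age_correlation(freq, self.AGES)
        assert out.flag.iloc[0] == "constant" and np.isnan(out.rho.iloc[0])

    def test_rho_invariant_under_monotone_age_transform(self):
        rng = np.random.default_rng(5)
        freq = pd.DataFrame([rng.uniform(0, 1, 8)], index=["m1"])
        a = age_correlation(freq, self.AGES).rho.iloc[0]
        b = age_correlation(freq, [np.log(x) for x in self.AGES]).rho.iloc[0]
        assert a == pytest.approx(b)

    def test_fewer_than_three_ages_rejected(self):
        with pytest.raises(ValueError):
            age_correlation(pd.DataFrame([[0.1, 0.2]], index=["m"]), [1, 2])


class TestTargetComparison:
    AGES = list(range(10))

    def _expr(self, rows):
        return pd.DataFrame(rows)

    def test_identical_distributions_p_near_one(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(0, 1, (8, 10)),
                            index=[f"g{i}" for i in range(8)])
        r_ed, r_un, p = target_expression_comparison(
            ["g0", "g1", "g2", "g3"], ["g4", "g5", "g6", "g7"], expr, self.AGES
        )
        assert p > 0.2

    def test_shared_gene_excluded(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(0, 1, (5, 10)),
                            index=[f"g{i}" for i in range(5)])
        r_ed, r_un, _p = target_expression_comparison(
            ["g0", "g1", "g2"], ["g2", "g3", "g4"], expr, self.AGES
        )
        assert len(r_ed) == 2 and len(r_un) == 2  # g2 dropped from both

    def test_empty_set_after_exclusion_errors(self):
        expr = pd.DataFrame(np.zeros((2, 10)), index=["g0", "g1"])
        with pytest.raises(ValueError, match="edited"):
            target_expression_comparison(["g0"], ["g0", "g1"], expr, self.AGES)

    def test_declining_edited_targets_detected(self):
        rng = np.random.default_rng(7)
        tau = np.linspace(0, 1, 10)
        rows, names = [], []
        for i in range(10):
            names.append(f"ed{i}")
            rows.append(8 - tau + rng.normal(0, 0.2, 10))
        for i in range(10):
            names.append(f"un{i}")
            rows.append(8 + rng.normal(0, 0.2, 10))
        expr = pd.DataFrame(rows, index=names)
        r_ed, r_un, p = target_expression_comparison(
            [f"ed{i}" for i in range(10)], [f"un{i}" for i in range(10)],
            expr, self.AGES,
        )
        assert np.median(r_ed) < np.median(r_un)
        assert p < 0.01


class TestGroupComparisons:
    def test_equal_frequencies_p_one(self):
        freq = {t: [0.3, 0.3, 0.3] for t in
                ("brain", "cerebellum", "heart", "kidney", "testis")}
        assert tissue_comparison(freq) == pytest.approx(1.0)

    def test_neural_enrichment_detected(self):
        freq = {"brain": [0.5, 0.6, 0.55, 0.62], "cerebellum": [0.5, 0.58, 0.52, 0.6],
                "heart": [0.1, 0.12, 0.15, 0.09], "kidney": [0.2, 0.18, 0.21, 0.17],
                "testis": [0.05, 0.04, 0.06, 0.08]}
        assert tissue_comparison(freq) < 0.01

    def test_species_comparison_identical_pairs(self):
        assert species_comparison([(0.2, 0.2), (0.5, 0.5), (0.7, 0.7)]) == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            tissue_comparison({"brain": [0.5], "heart": [0.1, 0.2]})


class TestClustering:
    def test_identical_vectors_merge_first_at_height_zero(self):
        profiles = pd.DataFrame(
            [[0.4, 0.3, 0.1], [0.4, 0.3, 0.1], [0.9, 0.8, 0.7]],
            index=["a", "b", "c"],
        )
        link = cluster_profiles(profiles)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
        assert link[0, 2] == pytest.approx(0.0)

    def test_clusters_group_by_mirna_identity_not_species(self):
        """Conserved per-miRNA profiles with small noise cluster by miRNA."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(11)
        n_mirnas, n_species = 5, 3
        base = rng.uniform(0, 0.8, (n_mirnas, 5))
        rows, labels = [], []
        for s in range(n_species):
            for m in range(n_mirnas):
                rows.append(base[m] + rng.normal(0, 0.03, 5))
                labels.append(m)
        link = cluster_profiles(pd.DataFrame(rows))
        found = cut_clusters(link, n_mirnas)
        assert adjusted_rand_score(labels, found) == pytest.approx(1.0)

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(pd.DataFrame([[0.1, 0.2]]))
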