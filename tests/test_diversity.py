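"""Unit tests for the diversity estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from provdiv import diversity
from provdiv.diversity import DiversityError, QuorumUnattainableError

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Fisher's alpha
# ---------------------------------------------------------------------------

class TestFisherAlpha:
    def test_reference_value(self):
        # S=10 species in n=150 records
        assert diversity.fisher_alpha(10, 150) == pytest.approx(2.4119, abs=1e-3)

    def test_round_trip(self):
        for S, n in [(10, 150), (50, 2000), (300, 5000), (2, 10)]:
            a = diversity.fisher_alpha(S, n)
            assert a * np.log1p(n / a) == pytest.approx(S, rel=1e-9)

    def test_near_saturated_sample(self):
        # S close to n pushes the root far above 1e6
        a = diversity.fisher_alpha(99998, 99999)
        assert a * np.log1p(99999 / a) == pytest.approx(99998, rel=1e-9)

    def test_monotone_in_S(self):
        alphas = [diversity.fisher_alpha(S, 1000) for S in (10, 50, 100, 500)]
        assert alphas == sorted(alphas)

    def test_invalid_inputs(self):
        with pytest.raises(DiversityError):
            diversity.fisher_alpha(0, 100)
        with pytest.raises(DiversityError):
            diversity.fisher_alpha(100, 100)

    @given(st.integers(min_value=2, max_value=5000))
    def test_round_trip_property(self, n):
        S = max(1, n // 3)
        a = diversity.fisher_alpha(S, n)
        assert a > 0
        assert a * np.log1p(n / a) == pytest.approx(S, rel=1e-9)


# ---------------------------------------------------------------------------
# Simpson, Chao1, jackknives, coverage
# ---------------------------------------------------------------------------

class TestSimpson:
    def test_inverse_form(self):
        # concentration = 3*2 / (6*5) = 0.2 -> inverse 5
        assert diversity.simpson_D([2, 2, 2]) == pytest.approx(5.0)

    def test_complement_form(self):
        assert diversity.simpson_D([2, 2, 2], form="complement") == pytest.approx(0.8)

    def test_monospecific(self):
        assert diversity.simpson_D([5]) == pytest.approx(1.0)

    def test_unknown_form(self):
        with pytest.raises(DiversityError):
            diversity.simpson_D([2, 2], form="gini")


class TestRichnessExtrapolators:
    def test_chao1_with_doubletons(self):
        assert diversity.chao1(10, 4, 2) == pytest.approx(14.0)

    def test_chao1_no_doubletons(self):
        assert diversity.chao1(10, 4, 0) == pytest.approx(16.0)

    def test_first_order_jackknife(self):
        assert diversity.first_order_jackknife(10, 4, 100) == pytest.approx(13.96)

    def test_corrected_jackknife_definition(self):
        S, s1, s2, n = 10, 4, 2, 100
        expect = S + (n - 1) / n * (s1 + s1 * (s1 - 1) / (2 * (s2 + 1)))
        assert diversity.corrected_jackknife(S, s1, s2, n) == pytest.approx(expect)

    @given(
        st.lists(st.integers(min_value=1, max_value=30), min_size=2, max_size=60)
    )
    def test_extrapolators_at_least_raw_richness(self, counts):
        x = np.asarray(counts)
        S, n = x.size, int(x.sum())
        s1, s2 = int((x == 1).sum()), int((x == 2).sum())
        assert diversity.chao1(S, s1, s2) >= S
        assert diversity.first_order_jackknife(S, s1, n) >= S
        assert diversity.corrected_jackknife(S, s1, s2, n) >= S


class TestCoverage:
    def test_all_singletons_zero_coverage(self):
        assert diversity.good_turing_coverage([1, 1, 1]) == pytest.approx(0.0)

    def test_no_singletons_full_coverage(self):
        assert diversity.good_turing_coverage([5, 5]) == pytest.approx(1.0)

    def test_rarefied_richness_full_sample(self):
        x = [5, 3, 2, 1, 1]
        assert diversity.rarefied_richness(x, 12) == pytest.approx(5.0)

    def test_rarefied_coverage_monotone(self, logseries_counts):
        n = int(logseries_counts.sum())
        ms = [10, 100, 500, 1000, n]
        covs = [diversity.rarefied_coverage(logseries_counts, m) for m in ms]
        assert covs == sorted(covs)
        assert 0.0 <= covs[0] and covs[-1] <= 1.0


# ---------------------------------------------------------------------------
# SQS
# ---------------------------------------------------------------------------

class TestSQS:
    def test_monotone_in_quorum(self, logseries_counts):
        vals = [
            diversity.sqs_analytical(logseries_counts, q)
            for q in (0.2, 0.4, 0.6, 0.8)
        ]
        assert vals == sorted(vals)

    def test_interpolation_bounded_by_raw_richness(self, logseries_counts):
        s = diversity.sqs_analytical(logseries_counts, 0.5)
        assert 1.0 <= s <= logseries_counts.size

    def test_unattainable_quorum_raises(self):
        # all singletons: estimated coverage 0
        with pytest.raises(QuorumUnattainableError):
            diversity.sqs_analytical([1, 1, 1, 1], 0.5)

    def test_invalid_quorum(self):
        with pytest.raises(DiversityError):
            diversity.sqs_analytical([3, 2, 1], 1.5)

    def test_montecarlo_matches_analytic(self, logseries_counts):
        rng = np.random.default_rng(5)
        a = diversity.sqs_analytical(logseries_counts, 0.5)
        reps = diversity.sqs_montecarlo(logseries_counts, 0.5, reps=500, rng=rng)
        se = reps.std(ddof=1) / np.sqrt(reps.size)
        assert abs(a - reps.mean()) < 4 * se

    def test_montecarlo_deterministic_given_seed(self, logseries_counts):
        r1 = diversity.sqs_montecarlo(
            logseries_counts, 0.5, reps=50, rng=np.random.default_rng(3)
        )
        r2 = diversity.sqs_montecarlo(
            logseries_counts, 0.5, reps=50, rng=np.random.default_rng(3)
        )
        np.testing.assert_array_equal(r1, r2)


# ---------------------------------------------------------------------------
# size_profile and diversity_table
# ---------------------------------------------------------------------------

class TestSizeProfile:
    def test_raw_richness_increases_with_size(self, logseries_counts):
        prof = diversity.size_profile(
            logseries_counts, [100, 500, 1500], reps=30,
            rng=np.random.default_rng(0),
        )
        raw = prof[prof["estimator"] == "raw_S"].sort_values("size")["mean"]
        assert raw.is_monotonic_increasing

    def test_simpson_stable_under_subsampling(self, logseries_counts):
        prof = diversity.size_profile(
            logseries_counts, [150, 1500], reps=50,
            rng=np.random.default_rng(0),
        )
        sub = prof[prof["estimator"] == "simpson_D"].set_index("size")
        assert abs(sub.loc[150, "mean"] - sub.loc[1500, "mean"]) < 2 * sub["sd"].max()


class TestDiversityTable:
    def test_columns_and_invariants(self, small_matrix):
        matrix, _ = small_matrix
        table = diversity.diversity_table(matrix)
        assert list(table.columns) == [
            "n", "raw_S", "fisher_alpha", "simpson_D", "chao1", "cJ1", "sqs",
        ]
        assert (table.index == matrix.index).all()
        ok = table.dropna()
        assert (ok["chao1"] >= ok["raw_S"] - 1e-9).all()
        assert (ok["cJ1"] >= ok["raw_S"] - 1e-9).all()
        assert (ok["sqs"] <= ok["raw_S"] + 1e-9).all()

    def test_row_totals_match_matrix(self, small_matrix):
        matrix, _ = small_matrix
        table = diversity.diversity_table(matrix)
        np.testing.assert_array_equal(
            table["n"].to_numpy(), matrix.sum(axis=1).to_numpy()
        )
        np.testing.assert_array_equal(
            table["raw_S"].to_numpy(), (matrix > 0).sum(axis=1).to_numpy()
        )
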