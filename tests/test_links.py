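"""CdF evaluation, the three ratio families and category-order reversal."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

import longirt as L
from conftest import random_etas

CDF_NAMES = ("logistic", "gaussian", "gumbel_min", "gumbel_max")
FAMILIES = ("adjacent", "cumulative", "sequential")


class TestCdf:
    @pytest.mark.parametrize(
        "name,eta,expected",
        [
            ("logistic", 0.0, 0.5),
            ("gumbel_max", 0.0, np.exp(-1.0)),
            ("logistic", 2.1, 1.0 / (1.0 + np.exp(-2.1))),
        ],
    )
    def test_known_values(self, name, eta, expected):
        assert L.cdf_eval(L.CdfSpec(name), eta) == pytest.approx(expected, abs=1e-12)

    def test_unknown_name_rejected(self):
        with pytest.raises(L.ConfigurationError):
            L.CdfSpec("cauchy")

    @pytest.mark.parametrize("name", CDF_NAMES)
    def test_in_unit_interval_and_increasing(self, name):
        F = L.CdfSpec(name)
        x = np.linspace(-30, 30, 500)
        v = F.cdf(x)
        assert np.all((v >= 0) & (v <= 1))
        assert np.all(np.diff(v) >= 0)
        inner = F.cdf(np.linspace(-3, 3, 100))
        assert np.all((inner > 0) & (inner < 1))

    @pytest.mark.parametrize("name", ("logistic", "gaussian"))
    def test_symmetry(self, name):
        F = L.CdfSpec(name)
        assert F.symmetric
        x = np.linspace(-8, 8, 101)
        assert np.allclose(F.cdf(x) + F.cdf(-x), 1.0, atol=1e-12)

    @pytest.mark.parametrize("name", ("gumbel_min", "gumbel_max"))
    def test_gumbels_asymmetric(self, name):
        F = L.CdfSpec(name)
        assert not F.symmetric
        assert abs(F.cdf(1.0) + F.cdf(-1.0) - 1.0) > 1e-3

    @pytest.mark.parametrize("name", CDF_NAMES)
    def test_matches_scipy_reference(self, name):
        """The direct formulas agree with the scipy distributions."""
        ref = {
            "logistic": stats.logistic,
            "gaussian": stats.norm,
            "gumbel_max": stats.gumbel_r,
            "gumbel_min": stats.gumbel_l,
        }[name]
        F = L.CdfSpec(name)
        x = np.linspace(-20, 20, 201)
        assert np.allclose(F.cdf(x), ref.cdf(x), atol=1e-12)
        assert np.allclose(F.pdf(x), ref.pdf(x), atol=1e-12)
        p = np.linspace(0.001, 0.999, 51)
        assert np.allclose(F.ppf(p), ref.ppf(p), rtol=1e-9)


class TestCumulative:
    def test_item9_baseline_published_rounding(self, logistic):
        probs = L.probs_cumulative([2.1, -1.0, -2.75], logistic)
        assert np.allclose(probs, (0.10, 0.62, 0.22, 0.06), atol=0.02)

    def test_item9_baseline_exact(self, logistic):
        # frozen hand evaluation of the logistic differences at theta = 0
        e = lambda x: 1.0 / (1.0 + np.exp(-x))
        expected = (1 - e(2.1), e(2.1) - e(-1.0), e(-1.0) - e(-2.75), e(-2.75))
        probs = L.probs_cumulative([2.1, -1.0, -2.75], logistic)
        assert np.allclose(probs, expected, atol=1e-12)

    def test_single_threshold_symmetry(self, logistic):
        assert np.allclose(L.probs_cumulative([0.0], logistic), (0.5, 0.5))

    def test_unordered_etas_rejected(self, logistic):
        with pytest.raises(L.DomainError, match="thresholds"):
            L.probs_cumulative([-1.0, 1.0], logistic)

    @pytest.mark.parametrize("name", CDF_NAMES)
    def test_merging_invariance(self, name):
        """Summing two adjacent categories equals the model built without
        the threshold that separates them."""
        rng = np.random.default_rng(5)
        F = L.CdfSpec(name)
        for _ in range(20):
            etas = random_etas(rng, 4)
            full = L.probs_cumulative(etas, F)
            for drop in (1, 2, 3):
                # deleting threshold eta_{drop+1} merges categories
                # drop and drop + 1
                sub = np.delete(etas, drop)
                merged = L.probs_cumulative(sub, F)
                gathered = np.concatenate(
                    [full[:drop], [full[drop] + full[drop + 1]], full[drop + 2:]]
                )
                assert np.allclose(merged, gathered, atol=1e-12)

    def test_tail_probabilities_non_increasing(self, all_cdfs):
        rng = np.random.default_rng(9)
        for F in all_cdfs:
            etas = random_etas(rng, 5)
            probs = L.probs_cumulative(etas, F)
            tails = np.cumsum(probs[::-1])[::-1]
            assert np.all(np.diff(tails) <= 1e-12)


class TestAdjacent:
    def test_single_threshold_symmetry(self, logistic):
        assert np.allclose(L.probs_adjacent([0.0], logistic), (0.5, 0.5))

    def test_partial_credit_identity(self, logistic):
        """With the logistic CdF the adjacent family is exactly the
        exponential partial-credit form pi_m propto exp(sum_{k<=m} eta_k)."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            etas = rng.normal(0, 4, size=rng.integers(1, 6))
            a = np.concatenate([[0.0], np.cumsum(etas)])
            expected = np.exp(a - a.max())
            expected /= expected.sum()
            assert np.allclose(L.probs_adjacent(etas, logistic), expected, atol=1e-12)

    def test_extreme_etas_no_overflow(self, logistic):
        probs = L.probs_adjacent([10.0, 10.0, 10.0], logistic)
        assert probs[-1] > 0.999
        probs = L.probs_adjacent([200.0, 200.0], logistic)
        assert np.isfinite(probs).all() and probs[-1] == pytest.approx(1.0)


class TestSequential:
    def test_single_threshold_symmetry(self, logistic):
        assert np.allclose(L.probs_sequential([0.0], logistic), (0.5, 0.5))

    def test_equal_half_ratios(self, logistic):
        # F(eta_1) = F(eta_2) = 1/2  =>  (1/2, 1/4, 1/4)
        assert np.allclose(
            L.probs_sequential([0.0, 0.0], logistic), (0.5, 0.25, 0.25), atol=1e-12
        )

    @pytest.mark.parametrize("name", CDF_NAMES)
    def test_brute_force_ratio_equations(self, name):
        """Independent oracle: solve the continuation-ratio equations
        r_m = pi_m / (pi_m + ... + pi_M) = F(eta_{m+1}) numerically."""
        rng = np.random.default_rng(3)
        F = L.CdfSpec(name)
        for _ in range(10):
            etas = rng.normal(0, 2, size=3)
            r = F.cdf(etas)

            def equations(p):
                tails = np.cumsum(p[::-1])[::-1]
                return np.concatenate([p[:-1] / tails[:-1] - r, [p.sum() - 1.0]])

            sol = optimize.least_squares(
                equations, np.full(4, 0.25), bounds=(1e-12, 1.0),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
            assert sol.cost < 1e-13
            assert np.allclose(L.probs_sequential(etas, F), sol.x, atol=1e-7)

    def test_not_reversible_flag(self):
        assert not L.RatioFamily("sequential").reversible
        assert L.RatioFamily("adjacent").reversible
        assert L.RatioFamily("cumulative").reversible


class TestReversal:
    def test_permutation_and_involution(self):
        probs = np.array([0.1, 0.2, 0.7])
        assert np.allclose(L.reverse_coding(probs), [0.7, 0.2, 0.1])
        assert np.allclose(L.reverse_coding(L.reverse_coding(probs)), probs)

    @pytest.mark.parametrize("family", ("cumulative", "adjacent"))
    @pytest.mark.parametrize("name", ("logistic", "gaussian"))
    def test_reversibility_symmetric_cdfs(self, family, name):
        """Reversing categories equals the same model with negated,
        order-reversed predictors, for symmetric CdFs."""
        rng = np.random.default_rng(11)
        F = L.CdfSpec(name)
        fam = L.RatioFamily(family)
        for _ in range(25):
            etas = random_etas(rng, 3)
            direct = L.reverse_coding(L.category_probs(fam, etas, F))
            mirrored = L.category_probs(fam, -etas[::-1], F)
            assert np.allclose(direct, mirrored, atol=1e-12)

    @pytest.mark.parametrize("name", ("gumbel_min", "gumbel_max"))
    def test_reversibility_fails_for_gumbel(self, name):
        F = L.CdfSpec(name)
        etas = np.array([1.5, 0.0, -1.5])
        direct = L.reverse_coding(L.probs_cumulative(etas, F))
        mirrored = L.probs_cumulative(-etas[::-1], F)
        assert np.max(np.abs(direct - mirrored)) > 1e-3


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    family=st.sampled_from(FAMILIES),
    name=st.sampled_from(CDF_NAMES),
    seed=st.integers(0, 10_000),
    M=st.integers(1, 6),
)
def test_normalization_property(family, name, seed, M):
    """Every family/CdF pair yields probabilities in [0, 1] summing to 1."""
    rng = np.random.default_rng(seed)
    etas = random_etas(rng, M)
    probs = L.category_probs(L.RatioFamily(family), etas, L.CdfSpec(name))
    assert probs.shape == (M + 1,)
    assert np.all(probs >= 0)
    assert abs(probs.sum() - 1.0) < 1e-10
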