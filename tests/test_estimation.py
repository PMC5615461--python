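"""Marginal likelihood, fitting, Wald tests and BIC selection."""

import numpy as np
import pandas as pd
import pytest

import longirt as L
from longirt.estimation import IrtParameters, QuadratureConfig, marginal_loglik


def _params(beta1=0.3, sigma0_sq=1.5, sigma1_sq=0.2, thresholds=(-1.6, 1.0, 1.45)):
    return IrtParameters(
        beta=L.FixedEffects((beta1,)),
        thresholds={"i1": tuple(thresholds)},
        random=L.RandomEffectsSpec(sigma0_sq=sigma0_sq, sigma1_sq=sigma1_sq),
    )


class TestMarginalLoglik:
    def test_degenerate_variance_equals_fixed_effect_loglik(self, tiny_dataset):
        """As sigma -> 0 the marginal likelihood collapses onto the
        conditional multinomial likelihood at xi = 0."""
        spec = L.ModelSpec("adjacent", "logistic", random_structure=1)
        params = _params(sigma0_sq=1e-10, sigma1_sq=0.0)
        ll = marginal_loglik(tiny_dataset, spec, params)
        item = tiny_dataset.items.items[0]
        expected = 0.0
        for _, row in tiny_dataset.records.iterrows():
            theta = row["time"] * 0.3
            probs = L.category_probability(theta, item, spec)
            expected += np.log(probs[int(row["response"])])
        assert ll == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("ratio", ("adjacent", "cumulative", "sequential"))
    def test_matches_monte_carlo_oracle(self, tiny_dataset, ratio):
        """Brute-force integration oracle with 10^6 Gaussian draws."""
        spec = L.ModelSpec(ratio, "logistic", random_structure=2)
        params = _params()
        ll = marginal_loglik(tiny_dataset, spec, params)
        rng = np.random.default_rng(123)
        R = 1_000_000
        xi0 = rng.normal(0, np.sqrt(1.5), R)
        xi1 = rng.normal(0, np.sqrt(0.2), R)
        item = tiny_dataset.items.items[0]
        total, rel_ses = 0.0, []
        for _, grp in tiny_dataset.records.groupby("subject_id"):
            like = np.ones(R)
            for _, row in grp.iterrows():
                theta = row["time"] * 0.3 + xi0 + row["time"] * xi1
                probs = L.category_probability(theta, item, spec)
                like *= probs[:, int(row["response"])]
            m = like.mean()
            total += np.log(m)
            rel_ses.append(like.std() / np.sqrt(R) / m)
        assert abs(ll - total) < 3.0 * np.hypot(*rel_ses)

    def test_quadrature_convergence(self, tiny_dataset):
        spec = L.ModelSpec("adjacent", "logistic", random_structure=2)
        params = _params()
        lls = [
            marginal_loglik(tiny_dataset, spec, params, QuadratureConfig(k))
            for k in (5, 9, 15)
        ]
        assert abs(lls[0] - lls[2]) < 1e-4
        assert abs(lls[1] - lls[2]) < 1e-5

    def test_deterministic(self, small_sim):
        spec = L.ModelSpec("adjacent", "logistic", random_structure=2)
        params = IrtParameters(
            beta=L.FixedEffects((0.3,)),
            thresholds={"item1": L.DELTA_NEAR[0], "item2": L.DELTA_NEAR[1]},
            random=L.RandomEffectsSpec(1.5, 0.2),
        )
        a = marginal_loglik(small_sim, spec, params)
        b = marginal_loglik(small_sim, spec, params)
        assert a == b

    def test_unordered_cumulative_thresholds_rejected(self, tiny_dataset):
        spec = L.ModelSpec("cumulative", "logistic", random_structure=1)
        params = _params(thresholds=(1.0, -1.0, 2.0), sigma1_sq=0.0)
        with pytest.raises(L.DomainError):
            marginal_loglik(tiny_dataset, spec, params)


class TestFit:
    def test_parameter_recovery_within_3se(self):
        """Self-simulated adjacent data at the study's sample size."""
        preset = L.ScenarioPreset(
            ratio="adjacent", beta1=0.3, sigma0_sq=1.5, sigma1_sq=0.2, seed=314
        )
        data = L.simulate_dataset(preset)
        fit = L.fit_irt(data, L.ModelSpec("adjacent", "logistic", random_structure=2))
        assert fit.converged
        assert abs(fit.beta_hat.beta[0] - 0.3) < 3 * fit.se["time"]
        assert abs(fit.random_hat.sigma1_sq - 0.2) < 3 * fit.se["sigma1_sq"]
        assert abs(fit.random_hat.sigma0_sq - 1.5) < 3 * fit.se["sigma0_sq"]
        # thresholds recovered roughly
        for est, true in zip(fit.thresholds_hat["item1"], L.DELTA_NEAR[0]):
            assert est == pytest.approx(true, abs=0.5)

    def test_bic_formula_and_threshold_ordering(self, small_sim):
        fit = L.fit_irt(
            small_sim,
            L.ModelSpec("cumulative", "logistic", random_structure=1),
            compute_se=False,
        )
        p = fit.n_params
        assert fit.bic == pytest.approx(-2 * fit.loglik + p * np.log(fit.n_used))
        for deltas in fit.thresholds_hat.values():
            assert np.all(np.diff(deltas) > 0)

    def test_reverse_coding_invariance_of_loglik(self, small_sim):
        """For a symmetric CdF, the likelihood of reversed data at the
        mirrored parameters equals the original optimum, and a warm-started
        refit reproduces it."""
        spec = L.ModelSpec("adjacent", "logistic", random_structure=2)
        fit = L.fit_irt(small_sim, spec, compute_se=False)
        rev = L.reverse_functional_scale(small_sim)
        mirrored = IrtParameters(
            beta=L.FixedEffects((-fit.beta_hat.beta[0],)),
            thresholds={
                k: tuple(-np.asarray(v)[::-1]) for k, v in fit.thresholds_hat.items()
            },
            random=fit.random_hat,
        )
        ll_rev = marginal_loglik(rev, spec, mirrored)
        assert ll_rev == pytest.approx(fit.loglik, abs=1e-6)
        refit = L.fit_irt(rev, spec, start=mirrored, compute_se=False)
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-4)

    def test_sigma1_boundary_under_m1_truth(self):
        preset = L.ScenarioPreset(
            ratio="adjacent", beta1=0.3, sigma1_sq=0.0, n_subjects=120, seed=88
        )
        data = L.simulate_dataset(preset)
        f1, f2 = L.fit_random_structures(data, L.ModelSpec("adjacent", "logistic"))
        assert f2.random_hat.sigma1_sq < 0.01
        assert L.bic_select(f1, f2) == "M1"

    def test_single_observed_category_rejected(self):
        bank = L.ItemBank((L.Item("i1", 3, (0.0, 1.0)),))
        df = pd.DataFrame(
            {
                "subject_id": [1, 2, 3],
                "group": 0,
                "time": 0.0,
                "item_id": "i1",
                "response": 1,
            }
        )
        data = L.ResponseDataset(df, bank)
        with pytest.raises(L.DomainError, match="fewer than 2"):
            L.fit_irt(data, L.ModelSpec("adjacent", "logistic"))

    def test_cumulative_collapses_unobserved_top_category(self, caplog):
        """Unobserved top category: merged away (cumulative gathering)."""
        rng = np.random.default_rng(4)
        n, times = 60, (0.0, 1.0, 2.0)
        df = pd.DataFrame(
            {
                "subject_id": np.repeat(np.arange(n), len(times)),
                "group": 0,
                "time": np.tile(times, n),
                "item_id": "i1",
                "response": rng.integers(0, 3, size=n * len(times)),  # never 3
            }
        )
        bank = L.ItemBank((L.Item("i1", 4, (-1.0, 0.0, 1.0)),))
        data = L.ResponseDataset(df, bank)
        fit = L.fit_irt(
            data,
            L.ModelSpec("cumulative", "logistic", random_structure=1),
            compute_se=False,
        )
        assert len(fit.thresholds_hat["i1"]) == 2


class TestWaldAndBic:
    @pytest.mark.parametrize(
        "est,se,expected,tol",
        [
            (0.0, 1.0, 1.0, 1e-12),
            (1.96, 1.0, 0.05, 1e-3),
            (-0.188, 0.092, 0.041, 1e-3),   # published pain interaction row
        ],
    )
    def test_wald_p_values(self, est, se, expected, tol):
        assert L.wald_p(est, se) == pytest.approx(expected, abs=tol)

    def test_wald_missing_se(self):
        assert np.isnan(L.wald_p(1.0, np.nan))

    def test_bic_select_parsimony_and_dominance(self):
        def fake(loglik, n_params, a):
            return L.FitResult(
                spec=L.ModelSpec("adjacent", "logistic", random_structure=a),
                beta_hat=L.FixedEffects((0.0,)),
                thresholds_hat={},
                random_hat=L.RandomEffectsSpec(1.0),
                loglik=loglik,
                bic=-2 * loglik + n_params * np.log(300),
                se={},
                wald_p={},
                converged=True,
                n_used=300,
                n_params=n_params,
            )

        assert L.bic_select(fake(-100, 8, 1), fake(-100, 10, 2)) == "M1"
        assert L.bic_select(fake(-150, 8, 1), fake(-100, 10, 2)) == "M2"
        bad = fake(-100, 10, 2)
        bad.converged = False
        with pytest.raises(L.DomainError):
            L.bic_select(fake(-100, 8, 1), bad)


class TestProbabilityCurves:
    def test_pain_item_trial_curves(self, item9):
        spec = L.ModelSpec(
            "cumulative", "logistic", random_structure=2,
            fixed_design="group_time_interaction", random_cov="unstructured_2x2",
        )
        params = IrtParameters(
            beta=L.FixedEffects((0.0, -0.330, -0.188), "group_time_interaction"),
            thresholds={"item9": item9.thresholds},
            random=L.RandomEffectsSpec(1.0, 0.1),
        )
        curves = L.probability_curves(params, item9, times=[0.0, 4.0], spec=spec)
        base = curves[(curves.time == 0.0)]
        # baseline bands identical across groups
        for m in range(4):
            vals = base[base.category == m]["prob"].to_numpy()
            assert np.allclose(vals, vals[0])
        ctl4 = curves[(curves.time == 4.0) & (curves.group == 0)]
        exp4 = curves[(curves.time == 4.0) & (curves.group == 1)]
        assert ctl4[ctl4.category == 3]["prob"].iloc[0] == pytest.approx(0.02, abs=0.01)
        assert exp4[exp4.category == 3]["prob"].iloc[0] == pytest.approx(0.01, abs=0.01)
        # bands sum to one at every (time, group)
        sums = curves.groupby(["time", "group"])["prob"].sum()
        assert np.allclose(sums, 1.0)
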