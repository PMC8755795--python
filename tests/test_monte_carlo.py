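import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gojirisk.data_model import RiskConfig
from gojirisk.distribution_fitting import fit_family
from gojirisk.errors import ConfigurationError, EmptyDataError
from gojirisk.monte_carlo import (
    CensoredMixtureInput,
    EmpiricalInput,
    FixedInput,
    concentration_inputs_from_dataset,
    exceedance_probability,
    run_probabilistic_risk,
    sample_inputs,
    summarize_percentiles,
)

SEED = 1234
FIXED_FACTORS = {"DI": 1.37, "EF": 145.7, "ED": 5.93, "BW": 64.81}


class TestSampleInputs:
    def test_fixed_scalars_give_identical_rows(self):
        m = sample_inputs({"DI": FixedInput(1.37), "EF": 145.7}, 1000, SEED)
        assert (m.nunique() == 1).all()
        assert list(m.columns) == ["DI", "EF"]  # deterministic name order

    def test_same_seed_bitwise_identical(self, rng):
        fit = fit_family(rng.lognormal(0, 1, 200), "lognormal")
        a = sample_inputs({"C:As": fit, "DI": 1.0}, 2000, 42)
        b = sample_inputs({"C:As": fit, "DI": 1.0}, 2000, 42)
        pd.testing.assert_frame_equal(a, b)

    def test_fitted_beta_moment_check(self, rng):
        data = stats.beta(5, 3, loc=40, scale=60).rvs(size=2000, random_state=rng)
        fit = fit_family(data, "beta")
        draws = sample_inputs({"BW": fit}, 10_000, SEED)["BW"]
        se = draws.std() / np.sqrt(len(draws))
        assert draws.mean() == pytest.approx(fit.mean(), abs=3 * se)

    def test_ef_clipped_to_physical_year(self):
        wide = fit_family(np.linspace(-100, 900, 100), "normal")
        draws = sample_inputs({"EF": wide}, 5000, SEED)["EF"]
        assert draws.min() >= 1.0 and draws.max() <= 365.0

    def test_negative_concentration_truncated_to_zero(self):
        wide = fit_family(np.linspace(-10, 10, 100), "normal")
        draws = sample_inputs({"C:Pb": wide}, 5000, SEED)["C:Pb"]
        assert draws.min() >= 0.0

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_inputs({"DI": 1.0}, 10, SEED)


class TestPercentiles:
    def test_known_median_of_1_to_100(self):
        pct = summarize_percentiles(np.arange(1.0, 101.0), [0.1, 0.5, 0.9])
        assert pct[0.5] == pytest.approx(50.5)

    def test_standard_normal_p90(self, rng):
        pct = summarize_percentiles(rng.standard_normal(1_000_000), [0.9])
        assert pct[0.9] == pytest.approx(1.2816, abs=0.01)

    def test_permutation_invariance(self, rng):
        x = rng.lognormal(0, 1, 5000)
        shuffled = rng.permutation(x)
        assert summarize_percentiles(x, [0.1, 0.5, 0.9]) == summarize_percentiles(
            shuffled, [0.1, 0.5, 0.9]
        )

    def test_empty_trials_error(self):
        with pytest.raises(EmptyDataError):
            summarize_percentiles(np.array([]), [0.5])


class TestRunProbabilisticRisk:
    def test_degenerate_inputs_collapse_to_deterministic(self, registry, factors):
        """All-scalar inputs reproduce the deterministic HI in every trial."""
        from gojirisk.deterministic_risk import compute_deterministic_risk

        means = {"As": 0.20, "Cu": 8.70, "fenvalerate": 0.88}
        cfg = RiskConfig(mc_iterations=1000, seed=SEED, fit_outputs=False)
        run = run_probabilistic_risk(
            {k: FixedInput(v) for k, v in means.items()},
            FIXED_FACTORS, registry, cfg,
        )
        det = compute_deterministic_risk(means, factors, registry)
        hi = run.results["HI_total"].trials
        np.testing.assert_allclose(hi, det.hi_total, rtol=1e-12)
        for p, q in run.results["HI_total"].percentiles.items():
            assert q == pytest.approx(det.hi_total, rel=1e-12)
        np.testing.assert_allclose(run.results["R_As"].trials, det.r["As"], rtol=1e-12)

    def test_missing_factor_is_configuration_error(self, registry):
        cfg = RiskConfig(mc_iterations=1000, seed=SEED)
        with pytest.raises(ConfigurationError):
            run_probabilistic_risk({"As": FixedInput(0.2)}, {"DI": 1.0}, registry, cfg)

    def test_lognormal_product_matches_closed_form(self, registry):
        """Two lognormal inputs through the multiplicative exposure chain give
        a lognormal output with known quantiles."""
        from gojirisk.distribution_fitting import FittedDistribution

        mu_c, s_c = -1.6, 0.5
        mu_d, s_d = 0.3, 0.4

        def lognormal_input(mu, s):
            return FittedDistribution(
                family="lognormal",
                params={"meanlog": mu, "sdlog": s, "location": 0.0},
                dist=stats.lognorm(s, 0.0, np.exp(mu)),
                support=(0.0, np.inf), n=0,
            )

        cfg = RiskConfig(mc_iterations=20_000, seed=SEED, fit_outputs=False)
        run = run_probabilistic_risk(
            {"As": lognormal_input(mu_c, s_c)},
            {"DI": lognormal_input(mu_d, s_d), "EF": 145.7, "ED": 5.93, "BW": 64.81},
            registry, cfg,
        )
        # closed form: log HI = log C + log DI + log(k), k = EF/(365·BW·ADI)
        k = 145.7 / (365.0 * 64.81 * registry["As"].adi)
        mu = mu_c + mu_d + np.log(k)
        s = np.hypot(s_c, s_d)
        for p in (0.1, 0.5, 0.9):
            expected = np.exp(mu + s * stats.norm.ppf(p))
            assert run.results["HI_total"].percentiles[p] == pytest.approx(
                expected, rel=0.05
            )

    def test_median_stability_under_doubling(self, registry, plantation_dataset, factors):
        cfg = RiskConfig(mc_iterations=10_000, seed=SEED, fit_outputs=False)
        inputs = concentration_inputs_from_dataset(plantation_dataset, registry, cfg)
        medians = []
        for n in (50_000, 100_000):
            c = RiskConfig(mc_iterations=n, seed=SEED, fit_outputs=False)
            run = run_probabilistic_risk(inputs, FIXED_FACTORS, registry, c)
            medians.append(run.results["HI_total"].percentiles[0.5])
        assert medians[1] == pytest.approx(medians[0], rel=0.02)

    def test_deterministic_mean_lies_within_percentile_band(
        self, registry, plantation_dataset
    ):
        cfg = RiskConfig(mc_iterations=5000, seed=SEED, fit_outputs=False)
        inputs = concentration_inputs_from_dataset(plantation_dataset, registry, cfg)
        run = run_probabilistic_risk(inputs, FIXED_FACTORS, registry, cfg)
        assert run.results["HI_total"].within_band

    def test_all_censored_chemical_becomes_fixed_zero(
        self, registry, plantation_dataset
    ):
        cfg = RiskConfig(mc_iterations=1000, seed=SEED)
        inputs = concentration_inputs_from_dataset(plantation_dataset, registry, cfg)
        assert isinstance(inputs["deltamethrin"], FixedInput)
        assert inputs["deltamethrin"].value == 0.0

    def test_sparse_detection_falls_back_to_empirical(self, registry, supermarket_dataset):
        cfg = RiskConfig(mc_iterations=1000, seed=SEED)
        inputs = concentration_inputs_from_dataset(supermarket_dataset, registry, cfg)
        assert isinstance(inputs["dichlorvos"], EmpiricalInput)  # 8 detects of 80
        assert isinstance(inputs["As"], CensoredMixtureInput)


def test_exceedance_probability_counts_strict_exceedances():
    assert exceedance_probability(np.array([0.5, 1.0, 2.0, 3.0]), 1.0) == 0.5
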