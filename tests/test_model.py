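"""Hierarchical Dirichlet regression: likelihood, link, MAP fits, predictions."""

import numpy as np
import pytest
from scipy import stats

from reefnutro import model, simulate
from reefnutro.model import (
    DegenerateCovariateError,
    ModelSpec,
    Priors,
    dirichlet_loglik,
    linear_predictor,
    softmax_mean,
    standardize,
)


class TestStandardize:
    def test_unit_example(self):
        z, mean, sd = standardize([1.0, 2.0, 3.0])
        assert np.allclose(z, [-1.0, 0.0, 1.0])
        assert (mean, sd) == (2.0, 1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateCovariateError):
            standardize([4.0, 4.0, 4.0])

    def test_lognormal_sample_moments(self, rng):
        x = rng.lognormal(1.0, 0.8, 300)
        z, mean, sd = standardize(x)
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(z * sd + mean, x)


class TestDirichletLoglik:
    def test_uniform_alpha_density_is_two(self, rng):
        """Dirichlet(1,1,1) is flat with density Gamma(3) = 2 everywhere."""
        for _ in range(10):
            y = rng.dirichlet([2.0, 2.0, 2.0])
            assert dirichlet_loglik(y, np.ones(3)) == pytest.approx(np.log(2.0))

    def test_matches_scipy_closed_form(self, rng):
        y = np.array([0.5, 0.3, 0.2])
        a = np.array([2.0, 3.0, 4.0])
        assert dirichlet_loglik(y, a) == pytest.approx(
            stats.dirichlet.logpdf(y, a), rel=1e-12
        )
        for _ in range(20):
            y = rng.dirichlet([1.5, 1.5, 1.5])
            a = rng.uniform(0.2, 8.0, 3)
            assert dirichlet_loglik(y, a) == pytest.approx(
                stats.dirichlet.logpdf(y, a), rel=1e-10
            )

    def test_boundary_point_rejected(self):
        with pytest.raises(ValueError):
            dirichlet_loglik(np.array([1.0, 0.0, 0.0]), np.ones(3))

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            dirichlet_loglik(np.array([0.4, 0.3, 0.3]), np.array([1.0, -1.0, 1.0]))


class TestLinearPredictor:
    @staticmethod
    def _zero_params(n_cov=7, C=2, M=3):
        return {
            "intercept": np.zeros(2), "beta": np.zeros((n_cov, 2)),
            "z_slope": np.zeros((C, 2)), "log_sd_slope": np.zeros(2),
            "z_mgmt": np.zeros((M, 2)), "log_sd_mgmt": np.zeros(2),
            "log_phi": np.log(10.0),
        }

    def test_all_zero_parameters_give_uniform_mean(self):
        p = self._zero_params()
        X = np.zeros((4, 7))
        mu, alpha = linear_predictor(p, X, np.zeros(4), np.zeros(4, int),
                                     np.zeros(4, int), reference_index=1)
        assert np.allclose(mu, 1.0 / 3.0)
        assert np.allclose(alpha, 10.0 / 3.0)

    def test_large_intercept_saturates(self):
        p = self._zero_params()
        p["intercept"] = np.array([30.0, 0.0])  # herbivore (free cat 0)
        mu, _ = linear_predictor(p, np.zeros((1, 7)), np.zeros(1),
                                 np.zeros(1, int), np.zeros(1, int), 1)
        assert mu[0, 0] > 0.999999

    def test_hand_computed_softmax(self):
        p = self._zero_params(n_cov=1)
        p["intercept"] = np.array([0.5, -0.2])
        p["beta"] = np.array([[0.3, 0.1]])
        X = np.array([[2.0]])
        mu, alpha = linear_predictor(p, X, np.array([2.0]), np.zeros(1, int),
                                     np.zeros(1, int), reference_index=1)
        eta = np.array([0.5 + 0.3 * 2.0, 0.0, -0.2 + 0.1 * 2.0])
        expect = np.exp(eta) / np.exp(eta).sum()
        assert np.allclose(mu[0], expect)
        assert np.allclose(alpha[0], expect * 10.0)

    def test_softmax_rows_always_sum_to_one(self, rng):
        eta = rng.normal(0, 5, (50, 2))
        mu = softmax_mean(eta, 1)
        assert np.allclose(mu.sum(axis=1), 1.0)
        assert (mu > 0).all()


@pytest.fixture(scope="module")
def replicate_fits():
    """Ten replicate simulation + MAP fits at the recovery-study settings."""
    out = []
    for rep in range(10):
        recs, truth = simulate.simulate_composition_records(
            simulate.recovery_truth(), n_sites=300, n_countries=3, seed=500 + rep
        )
        fit = model.fit(recs, method="map", seed=rep)
        out.append((fit, truth))
    return out


class TestMapFit:
    def test_fixed_effects_recovered(self, replicate_fits):
        """MAP point estimates track the generating coefficients."""
        worst = max(
            abs(fit.coef(n) - truth[n])
            for fit, truth in replicate_fits
            for n in fit.fixed_effect_names()
        )
        assert worst < 0.2

    def test_laplace_intervals_calibrated(self, replicate_fits):
        """90% Laplace intervals cover the generating fixed effects at
        roughly the nominal rate (pooled over replicates)."""
        hits = total = 0
        for fit, truth in replicate_fits:
            for n in fit.fixed_effect_names():
                lo, hi = fit.credible_interval(n, 0.9)
                hits += lo <= truth[n] <= hi
                total += 1
        assert 0.78 <= hits / total <= 0.98

    def test_precision_recovered(self, replicate_fits):
        phis = [np.exp(fit.map_params["log_phi"]) for fit, _ in replicate_fits]
        assert np.median(phis) == pytest.approx(80.0, rel=0.15)

    def test_zero_signal_intervals_contain_zero(self):
        """With no true effects, credible intervals rarely exclude zero."""
        truth0 = simulate.DirichletTruth(
            intercept=(0.0, 0.0), beta=tuple((0.0, 0.0) for _ in range(7)),
            sd_slope=0.1, sd_mgmt=0.1, phi=80.0,
        )
        hits = total = 0
        for rep in range(10):
            recs, _ = simulate.simulate_composition_records(
                truth0, n_sites=300, n_countries=3, seed=900 + rep
            )
            fit = model.fit(recs, method="map", seed=rep)
            for n in fit.fixed_effect_names():
                lo, hi = fit.credible_interval(n, 0.9)
                hits += lo <= 0.0 <= hi
                total += 1
        assert hits / total >= 0.85

    def test_single_country_collapses_gracefully(self):
        """One country: varying terms drop to one level, fixed effects are
        still recovered."""
        recs, truth = simulate.simulate_composition_records(
            simulate.recovery_truth(), n_sites=250, n_countries=1, seed=77
        )
        fit = model.fit(recs, method="map", seed=0)
        assert fit.converged
        errs = [abs(fit.coef(n) - truth[n]) for n in fit.fixed_effect_names()
                if n.startswith("beta[") and "biomass" not in n]
        assert max(errs) < 0.25

    def test_reference_relabeling_leaves_fitted_mean_unchanged(self):
        """With flat coefficient priors and group effects pinned off, the
        fitted mean composition is invariant to the reference category."""
        recs, _ = simulate.simulate_composition_records(
            simulate.recovery_truth(), n_sites=120, n_countries=1, seed=21
        )
        priors = Priors(sd_coef=1e6, scale_group_sd=1e-6)
        mus = []
        for ref in ("mobile_invertivore", "herbivore"):
            spec = ModelSpec(reference=ref, priors=priors)
            fit = model.fit(recs, spec=spec, method="map", seed=0)
            data = model._prepare(recs, spec)
            mu, _ = linear_predictor(
                fit.map_params, data.X, data.biomass, data.country_idx,
                data.cm_idx, spec.reference_index,
            )
            mus.append(mu)
        assert np.max(np.abs(mus[0] - mus[1])) < 1e-5

    def test_covariate_rescaling_absorbed_by_standardization(self):
        """Multiplying a raw covariate by a constant leaves the fit on the
        standardized scale unchanged."""
        recs, _ = simulate.simulate_composition_records(
            simulate.recovery_truth(), n_sites=150, n_countries=2, seed=5
        )
        scaled = recs.copy()
        scaled["depth_m"] = scaled["depth_m"] * 12.5
        a = model.fit(recs, method="map", seed=0)
        b = model.fit(scaled, method="map", seed=0)
        # intercepts ride a nearly flat prior ridge against the management
        # effects, so agreement there is limited by optimizer resolution
        for n in a.fixed_effect_names():
            tol = 1e-3 if n.startswith("intercept") else 2e-4
            assert a.coef(n) == pytest.approx(b.coef(n), abs=tol)


@pytest.fixture(scope="module")
def fit300():
    recs, truth = simulate.simulate_composition_records(
        simulate.recovery_truth(), n_sites=300, n_countries=3, seed=31
    )
    return model.fit(recs, method="map", seed=1), truth


class TestPredictAlongBiomass:

    def test_predictions_are_simplexes(self, fit300):
        fit, _ = fit300
        grid = np.geomspace(20, 5000, 8)
        pred = model.predict_along_biomass(fit, fit.countries[0], grid)
        wide = pred.pivot(index="fishable_biomass_kg_ha", columns="group",
                          values="median")
        # each draw's mean is a simplex; medians close only approximately
        assert np.allclose(wide.sum(axis=1), 1.0, atol=0.05)
        assert ((pred["lower"] <= pred["median"]) & (pred["median"] <= pred["upper"])).all()

    def test_positive_true_slope_yields_increasing_piscivore_share(self, fit300):
        fit, truth = fit300
        assert truth["beta[fishable_biomass_kg_ha,piscivore]"] > 0
        grid = np.geomspace(20, 5000, 12)
        pred = model.predict_along_biomass(fit, fit.countries[0], grid)
        pisc = pred[pred["group"] == "piscivore"].sort_values("fishable_biomass_kg_ha")
        assert pisc["median"].is_monotonic_increasing

    def test_extrapolation_guard(self, fit300):
        fit, _ = fit300
        with pytest.raises(ValueError, match="extrapolation"):
            model.predict_along_biomass(fit, fit.countries[0], [1e6])

    def test_unknown_country_rejected(self, fit300):
        fit, _ = fit300
        with pytest.raises(ValueError, match="unknown country"):
            model.predict_along_biomass(fit, "Atlantis", [100.0])


class TestMcmcSmoke:
    def test_short_chain_runs_and_reports_diagnostics(self):
        """A short HMC run produces draws, Rhat/ESS diagnostics, and medians
        consistent with the MAP point."""
        recs, _ = simulate.simulate_composition_records(
            simulate.recovery_truth(), n_sites=80, n_countries=2, seed=13
        )
        fit = model.fit(recs, method="mcmc", seed=0, chains=2, iterations=400)
        assert fit.method == "mcmc"
        assert fit.draws.shape[0] == 2 * 200
        assert fit.max_rhat is not None and fit.min_ess is not None
        assert fit.divergences is not None
        j = fit.param_names.index("beta[depth_m,herbivore]")
        med = np.median(fit.draws[:, j])
        assert med == pytest.approx(fit.map_theta[j], abs=0.3)
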