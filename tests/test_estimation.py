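"""FOCE inner/outer estimation, the OFV, and stepwise covariate selection."""

import math

import numpy as np
import pytest
from scipy import integrate

import siropk as sp
from siropk.dataset import DoseRecord, ObservationRecord, PKDataset, SubjectData
from siropk.estimation import (
    BACKWARD_DELTA_OFV,
    FORWARD_DELTA_OFV,
    FOCESettings,
    conditional_eta,
    evaluate_at,
    fit_model,
    foce_objective,
    lrt_threshold,
    stepwise_covariates,
)
from siropk.population import CovariateRelation, predict_individual
from siropk.synthetic import CohortSpec, generate_cohort, generate_recovery_suite


def _subject_with_obs(spec, weight, obs_times, y):
    doses = [DoseRecord(12.0 * k, 0.05 * weight / 2) for k in range(29)]
    s = SubjectData("s", weight, doses, [])
    s.observations = [
        ObservationRecord(float(t), float(c)) for t, c in zip(obs_times, y)
    ]
    return s


class TestConditionalEta:
    def test_zero_when_observations_match_population(self, published):
        t = np.array([96.0, 216.0])
        s = SubjectData(
            "s", 20.0, [DoseRecord(12.0 * k, 0.5) for k in range(29)], []
        )
        f = predict_individual(published, s, 0.0, t)
        s.observations = [ObservationRecord(float(a), float(b)) for a, b in zip(t, f)]
        eta, curv = conditional_eta(published, s)
        assert eta == pytest.approx(0.0, abs=1e-6)
        assert curv > 0

    def test_large_omega_limit_is_unpenalized_least_squares(self, published):
        t = np.array([96.0, 216.0])
        s = SubjectData("s", 20.0, [DoseRecord(12.0 * k, 0.5) for k in range(29)], [])
        f = predict_individual(published, s, 0.4, t)
        s.observations = [ObservationRecord(float(a), float(b)) for a, b in zip(t, f)]
        big = published.with_values(omega=50.0)
        eta, _ = conditional_eta(big, s)
        # data generated noiselessly at eta=0.4: the unpenalized optimum is 0.4
        assert eta == pytest.approx(0.4, abs=1e-3)

    def test_single_observation_matches_grid_search(self, published):
        s = _subject_with_obs(published, 15.0, [216.0], [12.0])
        eta_hat, _ = conditional_eta(published, s)
        grid = np.arange(-3.0, 3.0, 1e-4)
        t = np.array([216.0])
        sig2 = published.residual.sigma_add**2
        om2 = published.iiv_cl.omega**2
        q = np.array(
            [
                (12.0 - predict_individual(published, s, float(e), t)[0]) ** 2 / sig2
                + e**2 / om2
                for e in grid
            ]
        )
        eta_grid = grid[int(np.argmin(q))]
        assert eta_hat == pytest.approx(eta_grid, abs=2e-4)


class TestObjective:
    def test_omega_zero_reduces_to_weighted_least_squares(self, published, toy_dataset):
        # exact omega=0 short-circuits the inner solve: fixed-effects WLS
        spec0 = published.with_values(omega=0.0)
        ofv = foce_objective(spec0, toy_dataset)
        sig = published.residual.sigma_add
        expected = 0.0
        n = 0
        for s in toy_dataset:
            t = np.array([o.time for o in s.observations])
            y = np.array([o.concentration for o in s.observations])
            f = np.atleast_1d(predict_individual(published, s, 0.0, t))
            expected += float(np.sum((y - f) ** 2)) / sig**2
            n += len(y)
        expected += n * math.log(sig**2)
        assert ofv == pytest.approx(expected, abs=1e-8)

    def test_invariant_under_subject_permutation(self, published, toy_dataset):
        reversed_ds = PKDataset(list(reversed(toy_dataset.subjects)))
        assert foce_objective(published, toy_dataset) == pytest.approx(
            foce_objective(published, reversed_ds), abs=1e-8
        )

    def test_matches_adaptive_quadrature_on_small_instances(self, published):
        """FOCE OFV within 0.5 units of the numerically integrated
        −2 log marginal likelihood (minus the 2π constant) on tiny toys."""
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(20):
            spec = published.with_values(
                cl_std=rng.uniform(6, 16),
                v_std=rng.uniform(200, 500),
                omega=rng.uniform(0.1, 0.4),
                sigma=rng.uniform(1.5, 4.0),
            )
            om, sg = spec.iiv_cl.omega, spec.residual.sigma_add
            subs = []
            for i in range(int(rng.integers(2, 4))):
                w = rng.uniform(5, 50)
                ts = np.sort(rng.uniform(24, 336, size=2))
                doses = [DoseRecord(12.0 * k, 0.05 * w / 2) for k in range(29)]
                s = SubjectData(f"s{i}", w, doses, [])
                f = predict_individual(spec, s, rng.normal(0, om), ts)
                y = np.maximum(np.atleast_1d(f) + rng.normal(0, sg, 2), 0.1)
                s.observations = [
                    ObservationRecord(float(a), float(b)) for a, b in zip(ts, y)
                ]
                subs.append(s)
            ds = PKDataset(subs)
            ofv = foce_objective(spec, ds)
            total, n_obs = 0.0, 0
            for s in ds:
                ts = np.array([o.time for o in s.observations])
                y = np.array([o.concentration for o in s.observations])
                m = len(y)
                n_obs += m

                def integrand(eta):
                    f = np.atleast_1d(predict_individual(spec, s, eta, ts))
                    return math.exp(
                        -0.5 * float(np.sum((y - f) ** 2)) / sg**2
                        - 0.5 * eta**2 / om**2
                    )

                val, _ = integrate.quad(integrand, -8 * om, 8 * om, limit=200)
                total += (
                    -2.0 * math.log(val)
                    + 2 * m * math.log(sg)
                    + 2 * math.log(om)
                    + (m + 1) * math.log(2 * math.pi)
                )
            oracle = total - n_obs * math.log(2 * math.pi)
            worst = max(worst, abs(ofv - oracle))
        assert worst < 0.5


class TestFit:
    def test_noiseless_recovery_within_two_percent(self, published):
        gen = published.with_values(omega=0.0, sigma=0.05)
        ds = generate_cohort(
            CohortSpec(
                n_subjects=10,
                dose_rate_range=(0.08, 0.08),
                sampling_design="rich",
                seed=2,
                generating_model=gen,
            )
        )
        start = published.with_values(cl_std=6.0, v_std=250.0, omega=0.1, sigma=0.5)
        fit = fit_model(start, ds, compute_se=False)
        e = fit.estimates
        assert e.cl_allometry.standard_value == pytest.approx(11.3, rel=0.02)
        assert e.v_allometry.standard_value == pytest.approx(388.0, rel=0.02)

    def test_recovery_bias_small_under_rich_low_censoring_design(
        self, published, neutral_start
    ):
        """Median relative bias of TVCL < 5% and of ω < 15% over replicate
        cohorts dosed inside the assay's linear range (so quantitation-limit
        censoring does not confound the estimator's own bias)."""
        suites = generate_recovery_suite(
            published, n_subjects=100, design="rich", n_replicates=5, seed=123,
            dose_rate=0.08,
        )
        cls, oms = [], []
        for ds in suites:
            e = fit_model(neutral_start, ds, compute_se=False).estimates
            cls.append(e.cl_allometry.standard_value)
            oms.append(e.iiv_cl.omega)
        assert abs(np.median(cls) / 11.3 - 1) < 0.05
        assert abs(np.median(oms) / 0.303 - 1) < 0.15

    def test_optimum_ofv_not_worse_than_generating_parameters(
        self, published, neutral_start, rich_cohort
    ):
        fit = fit_model(neutral_start, rich_cohort, compute_se=False)
        assert fit.converged
        assert fit.ofv <= foce_objective(published, rich_cohort) + 1e-6
        # standard errors from a separate fit with the Hessian enabled
        se_fit = fit_model(fit.estimates, rich_cohort, compute_se=True)
        if se_fit.standard_errors:
            assert all(v > 0 for v in se_fit.standard_errors.values())
            assert "cl_std" in se_fit.standard_errors

    def test_report_mirrors_parameter_layout(self, published, toy_dataset):
        fit = evaluate_at(published, toy_dataset)
        rep = fit.report()
        assert rep["parameters"]["Ka (1/h)"]["fixed"] is True
        assert rep["parameters"]["CL/F (L/h/70 kg)"]["estimate"] == pytest.approx(11.3)


class TestStepwise:
    def test_thresholds_are_chi2_quantiles(self):
        assert round(lrt_threshold(0.05), 2) == 3.84
        assert round(lrt_threshold(0.01), 2) == 6.63
        assert FORWARD_DELTA_OFV == lrt_threshold(0.05)
        assert BACKWARD_DELTA_OFV == lrt_threshold(0.01)

    def test_inclusion_and_backward_decisions(self, monkeypatch, published, toy_dataset):
        """ΔOFV of 4.0 includes (>3.84); 3.0 does not; a retained covariate
        whose removal costs only 5.0 (≤6.63) is removed backward."""
        import siropk.estimation as est

        cand_a = CovariateRelation("power", "age_years", theta=0.0, covariate_median=7.0)
        cand_b = CovariateRelation("power", "albumin_g_per_l", theta=0.0, covariate_median=38.0)
        ofvs = {(): 100.0, ("age_years",): 96.0, ("albumin_g_per_l",): 97.0,
                ("age_years", "albumin_g_per_l"): 95.5, ("albumin_g_per_l", "age_years"): 95.5}

        def fake_fit(spec, dataset, settings=None, compute_se=True):
            key = tuple(r.covariate_name for r in spec.included_covariates)
            return est.FitResult(
                estimates=spec, ofv=ofvs[key], eta_hat=np.zeros(2),
                subject_ids=["T1", "T2"], converged=True,
            )

        monkeypatch.setattr(est, "fit_model", fake_fit)
        final, log = est.stepwise_covariates(published, [cand_a, cand_b], toy_dataset)
        # forward: age drops 4.0 -> included; albumin then adds only 0.5 -> stop
        # backward: removing age raises OFV by 4.0 <= 6.63 -> removed
        actions = {(s.phase, s.covariate): s.action for s in log}
        assert actions[("forward", "age_years")] == "included"
        assert actions[("forward", "albumin_g_per_l")] == "rejected"
        assert actions[("backward", "age_years")] == "removed"
        assert final.included_covariates == ()

    def test_detects_true_covariate_effect(self, published, neutral_start):
        """A strong power effect of albumin on CL is found and retained."""
        gen = published.with_values(
            included_covariates=(
                CovariateRelation("power", "albumin_g_per_l", theta=1.0, covariate_median=38.0),
            )
        )
        ds = generate_cohort(
            CohortSpec(
                n_subjects=40, dose_rate_range=(0.08, 0.08), sampling_design="rich",
                seed=21, generating_model=gen,
            )
        )
        cands = [
            CovariateRelation("power", "albumin_g_per_l", theta=0.0, covariate_median=38.0),
            CovariateRelation("power", "age_years", theta=0.0, covariate_median=7.0),
        ]
        final, log = stepwise_covariates(neutral_start, cands, ds)
        names = [r.covariate_name for r in final.included_covariates]
        assert names == ["albumin_g_per_l"]
        assert any(s.action == "retained" for s in log)

    def test_null_covariate_rarely_included(self, published, neutral_start):
        """Approximate type-I control: with no true effect the candidate is
        included in well under 20% of replicate cohorts (scaled-down run)."""
        cand = CovariateRelation("power", "age_years", theta=0.0, covariate_median=7.0)
        included = 0
        n_rep = 6
        for seed in range(n_rep):
            ds = generate_cohort(
                CohortSpec(
                    n_subjects=25, dose_rate_range=(0.08, 0.08),
                    sampling_design="rich", seed=900 + seed,
                    generating_model=published,
                )
            )
            final, _ = stepwise_covariates(neutral_start, [cand], ds)
            included += bool(final.included_covariates)
        assert included / n_rep < 0.2
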