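"""CWRES, goodness-of-fit tables, bootstrap and prediction-corrected VPC."""

import numpy as np
import pytest

from siropk.dataset import DoseRecord, ObservationRecord, PKDataset, SubjectData
from siropk.diagnostics import (
    bootstrap_model,
    compute_cwres,
    goodness_of_fit_table,
    pc_vpc,
)
from siropk.estimation import evaluate_at
from siropk.population import predict_individual
from siropk.synthetic import CohortSpec, generate_cohort


def _scale_doses(ds: PKDataset, factor: float) -> PKDataset:
    subs = []
    for s in ds:
        subs.append(
            SubjectData(
                s.subject_id,
                s.weight,
                [DoseRecord(d.time, d.amount * factor, d.interval, d.steady_state) for d in s.doses],
                list(s.observations),
                dict(s.covariates),
            )
        )
    return PKDataset(subs)


class TestCWRES:
    def test_near_zero_when_data_match_population_predictions(self, published):
        spec = published.with_values(sigma=0.01)
        subs = []
        t = np.array([96.0, 216.0, 336.0])
        for i, w in enumerate((8.0, 20.0, 40.0)):
            s = SubjectData(f"c{i}", w, [DoseRecord(12.0 * k, 0.05 * w / 2) for k in range(29)], [])
            f = predict_individual(spec, s, 0.0, t)
            s.observations = [ObservationRecord(float(a), float(b)) for a, b in zip(t, f)]
            subs.append(s)
        ds = PKDataset(subs)
        tab = compute_cwres(evaluate_at(spec, ds), ds)
        assert np.all(np.abs(tab["cwres"]) < 1e-4)

    def test_omega_zero_reduces_to_plain_weighted_residual(self, published, toy_dataset):
        spec = published.with_values(omega=0.0)
        tab = compute_cwres(evaluate_at(spec, toy_dataset), toy_dataset)
        expected = (tab["observed"] - tab["population_prediction"]) / spec.residual.sigma_add
        np.testing.assert_allclose(tab["cwres"], expected, rtol=1e-9)

    def test_standard_normal_calibration_under_self_simulation(self, published):
        """Data simulated under the evaluated model: CWRES mean ≈ 0 and
        variance ≈ 1 at ≥500 observations."""
        ds = generate_cohort(
            CohortSpec(
                n_subjects=60, dose_rate_range=(0.08, 0.08), sampling_design="rich",
                seed=11, generating_model=published,
            )
        )
        tab = compute_cwres(evaluate_at(published, ds), ds)
        assert len(tab) >= 500
        assert abs(tab["cwres"].mean()) < 0.1
        assert abs(tab["cwres"].var() - 1.0) < 0.2


class TestGOF:
    def test_row_count_and_quantile_monotonicity(self, published, rich_cohort):
        fit = evaluate_at(published, rich_cohort)
        tab = goodness_of_fit_table(fit, rich_cohort)
        n_quantifiable = sum(
            1 for s in rich_cohort for o in s.observations if not o.bql
        )
        assert len(tab) == n_quantifiable
        order = np.argsort(tab["cwres"].to_numpy())
        assert np.all(np.diff(tab["cwres_normal_quantile"].to_numpy()[order]) > 0)

    def test_population_equals_individual_prediction_at_zero_eta(self, published, toy_dataset):
        spec = published.with_values(omega=0.0)  # forces every eta-hat to 0
        tab = goodness_of_fit_table(evaluate_at(spec, toy_dataset), toy_dataset)
        np.testing.assert_allclose(
            tab["population_prediction"], tab["individual_prediction"], rtol=1e-12
        )


class TestBootstrap:
    def test_default_replicate_count_is_one_thousand(self):
        import inspect

        assert inspect.signature(bootstrap_model).parameters["n_replicates"].default == 1000

    def test_cloned_noiseless_subjects_give_degenerate_intervals(self, published):
        # near-noiseless: a little real noise keeps the likelihood bounded
        spec = published.with_values(omega=0.01, sigma=0.05)
        rng = np.random.default_rng(0)
        t = np.array([96.0, 216.0, 312.5, 315.0, 320.0])
        subs = []
        for i in range(6):
            s = SubjectData(f"k{i}", 20.0, [DoseRecord(12.0 * k, 0.5) for k in range(29)], [])
            f = np.atleast_1d(predict_individual(spec, s, 0.0, t))
            y = f + rng.normal(0.0, 0.05, size=len(t))
            s.observations = [ObservationRecord(float(a), float(b)) for a, b in zip(t, y)]
            subs.append(s)
        ds = PKDataset(subs)
        start = spec.with_values(cl_std=8.0, v_std=300.0)
        res = bootstrap_model(start, ds, n_replicates=5, seed=0)
        width = res.ci_upper["cl_std"] - res.ci_lower["cl_std"]
        assert width / res.point_estimates["cl_std"] < 0.01

    def test_bootstrap_median_consistent_with_full_data_estimate(
        self, published, neutral_start
    ):
        ds = generate_cohort(
            CohortSpec(
                n_subjects=30, dose_rate_range=(0.08, 0.08), sampling_design="rich",
                seed=5, generating_model=published,
            )
        )
        res = bootstrap_model(neutral_start, ds, n_replicates=8, seed=1)
        med = float(np.median(res.samples["cl_std"]))
        assert med == pytest.approx(res.point_estimates["cl_std"], rel=0.10)
        assert res.n_failed <= 2
        assert all(
            res.ci_lower[k] <= res.ci_upper[k] for k in res.point_estimates
        )


class TestPcVPC:
    def test_identical_subjects_have_unit_correction_factor(self, published):
        rng = np.random.default_rng(4)
        t = np.array([96.0, 216.0, 336.0])
        subs = []
        for i in range(12):
            s = SubjectData(f"u{i}", 20.0, [DoseRecord(12.0 * k, 0.5) for k in range(29)], [])
            f = np.atleast_1d(predict_individual(published, s, rng.normal(0, 0.3), t))
            y = np.maximum(f + rng.normal(0, 2.0, len(t)), 4.0)
            s.observations = [ObservationRecord(float(a), float(b)) for a, b in zip(t, y)]
            subs.append(s)
        ds = PKDataset(subs)
        res = pc_vpc(evaluate_at(published, ds), ds, n_simulations=100, bins=3, seed=0)
        np.testing.assert_allclose(res.observations["correction_factor"], 1.0, rtol=1e-12)

    def test_correction_factor_invariant_to_dose_rescaling(self, published, rich_cohort):
        fit = evaluate_at(published, rich_cohort)
        a = pc_vpc(fit, rich_cohort, n_simulations=100, bins=4, seed=0)
        scaled = _scale_doses(rich_cohort, 3.0)
        b = pc_vpc(evaluate_at(published, scaled), scaled, n_simulations=100, bins=4, seed=0)
        np.testing.assert_allclose(
            a.observations["correction_factor"],
            b.observations["correction_factor"],
            rtol=1e-9,
        )

    def test_self_simulation_band_coverage(self, published):
        """Observed bin percentiles fall inside the simulated 95% bands
        ≈95% of the time, and the observed median sits inside the
        predicted interquartile band, under self-simulation (20 seeds)."""
        coverages, med_ok = [], []
        for seed in range(20):
            ds = generate_cohort(
                CohortSpec(
                    n_subjects=20, dose_rate_range=(0.08, 0.08),
                    sampling_design="rich", seed=100 + seed,
                    generating_model=published,
                )
            )
            res = pc_vpc(evaluate_at(published, ds), ds, n_simulations=200, bins=5, seed=seed)
            inside = total = 0
            ok = True
            for _, row in res.bins.iterrows():
                for q in ("p2.5", "p50", "p97.5"):
                    total += 1
                    inside += row[f"sim_{q}_lo"] <= row[f"obs_{q}"] <= row[f"sim_{q}_hi"]
                ok &= row["sim_iqr_lo"] <= row["obs_p50"] <= row["sim_iqr_hi"]
            coverages.append(inside / total)
            med_ok.append(ok)
        assert np.mean(coverages) >= 0.90
        assert np.mean(med_ok) >= 0.90

    def test_sparse_bins_are_merged(self, published):
        # one isolated early sample plus a late cluster: the lone-obs bin
        # cannot stand on its own and must be merged with a neighbour
        rng = np.random.default_rng(1)
        late = np.array([300.0, 308.0, 316.0, 324.0, 332.0, 336.0])
        subs = []
        for i in range(2):
            # only the first subject has the isolated early sample
            t = np.concatenate(([24.0], late)) if i == 0 else late
            s = SubjectData(f"m{i}", 20.0, [DoseRecord(12.0 * k, 0.5) for k in range(29)], [])
            f = np.atleast_1d(predict_individual(published, s, 0.0, t))
            y = np.maximum(f + rng.normal(0, 2.0, len(t)), 4.0)
            s.observations = [ObservationRecord(float(a), float(b)) for a, b in zip(t, y)]
            subs.append(s)
        ds = PKDataset(subs)
        res = pc_vpc(evaluate_at(published, ds), ds, n_simulations=100, bins=6, seed=0)
        assert res.n_merged_bins >= 1
        assert (res.bins["n_obs"] >= 2).all()
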