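"""Model-evaluation machinery: CWRES, GOF tables, bootstrap, pc-VPC.

Everything here is numeric-table based: the tested surface is the data
behind the standard goodness-of-fit and VPC figures, not rendered
plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PKDataset, SubjectData
from .estimation import FitResult, FOCESettings, _inner_etas, _Prepared, fit_model
from .population import ModelSpec

__all__ = [
    "BootstrapResult",
    "VPCResult",
    "compute_cwres",
    "goodness_of_fit_table",
    "bootstrap_model",
    "pc_vpc",
]


@dataclass
class BootstrapResult:
    """Percentile confidence intervals from a subject-resampling bootstrap."""

    n_replicates: int
    n_failed: int
    point_estimates: dict[str, float]
    ci_lower: dict[str, float]  # 2.5th percentile
    ci_upper: dict[str, float]  # 97.5th percentile
    samples: pd.DataFrame

    def report(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
            "parameters": {
                k: {
                    "estimate": self.point_estimates[k],
                    "ci95": [self.ci_lower[k], self.ci_upper[k]],
                }
                for k in self.point_estimates
            },
        }


@dataclass
class VPCResult:
    """Prediction-corrected VPC summary.

    ``bins`` has, per time bin, the observed prediction-corrected
    percentiles (2.5/50/97.5) and, for each, the 95% band of the same
    statistic across simulated replicates (plus the interquartile band
    of the simulated median).  ``observations`` carries the per-point
    correction bookkeeping.
    """

    bins: pd.DataFrame
    observations: pd.DataFrame
    n_simulations: int
    n_merged_bins: int


def _etas_for(fit: FitResult, prep: _Prepared, settings: FOCESettings) -> np.ndarray:
    if fit.subject_ids == prep.ids and len(fit.eta_hat) == prep.n:
        return np.asarray(fit.eta_hat, dtype=float)
    e = fit.estimates
    tvcl = prep.tv_clearance(e.cl_allometry.standard_value, e.included_covariates)
    v_i = e.v_allometry.standard_value * prep.allo_v
    return _inner_etas(prep, tvcl, v_i, e.residual.sigma_add, e.iiv_cl.omega, settings)


def _predictions(prep: _Prepared, spec: ModelSpec, eta: np.ndarray):
    tvcl = prep.tv_clearance(spec.cl_allometry.standard_value, spec.included_covariates)
    v_i = spec.v_allometry.standard_value * prep.allo_v
    f_ind = prep.predict(tvcl * np.exp(eta), v_i)
    f_pop = prep.predict(tvcl, v_i)
    h = 1e-5
    fp = prep.predict(tvcl * np.exp(eta + h), v_i)
    fm = prep.predict(tvcl * np.exp(eta - h), v_i)
    g = (fp - fm) / (2 * h)
    return f_pop, f_ind, g


def compute_cwres(
    fit: FitResult, dataset: PKDataset, settings: FOCESettings | None = None
) -> pd.DataFrame:
    """Conditional weighted residuals, one row per non-BQL observation.

    CWRES = C⁻¹ᐟ² (y − E) with E = f(η̂) − G η̂ and C = G ω² Gᵀ + σ² I —
    the FOCE linearisation at the conditional mode, so CWRES is
    approximately standard normal when the model is correct.
    """
    if not fit.converged:
        raise ValueError("CWRES requires a converged fit")
    settings = settings or FOCESettings()
    spec = fit.estimates
    prep = _Prepared(dataset, spec)
    eta = _etas_for(fit, prep, settings)
    f_pop, f_ind, g = _predictions(prep, spec, eta)
    sigma = spec.residual.sigma_add
    omega2 = spec.iiv_cl.omega**2

    rows = []
    for i in range(prep.n):
        m = int(prep.m_i[i])
        if m == 0:
            continue
        y = prep.y[i, :m]
        gi = g[i, :m]
        e_vec = f_ind[i, :m] - gi * eta[i]
        res = y - e_vec
        gg = float(gi @ gi)
        c_scale = omega2 * gg / sigma**2
        if 1.0 + c_scale <= 0:
            raise ValueError(
                f"non-positive-definite residual covariance for subject {prep.ids[i]!r}"
            )
        if gg > 0:
            u = gi / math.sqrt(gg)
            cw = (res + ((1.0 + c_scale) ** -0.5 - 1.0) * u * (u @ res)) / sigma
        else:
            cw = res / sigma
        for j in range(m):
            rows.append(
                {
                    "subject_id": prep.ids[i],
                    "time": prep.t_obs[i, j],
                    "observed": y[j],
                    "population_prediction": f_pop[i, j],
                    "individual_prediction": f_ind[i, j],
                    "cwres": cw[j],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "time",
            "observed",
            "population_prediction",
            "individual_prediction",
            "cwres",
        ],
    )


def goodness_of_fit_table(
    fit: FitResult, dataset: PKDataset, settings: FOCESettings | None = None
) -> pd.DataFrame:
    """Residual table plus Blom normal quantiles of the CWRES ranks.

    These are the paired columns behind the usual GOF panels:
    observed vs population/individual predictions, CWRES vs time and
    predictions, and the CWRES normal QQ plot.
    """
    tab = compute_cwres(fit, dataset, settings)
    n = len(tab)
    if n:
        ranks = stats.rankdata(tab["cwres"].to_numpy(), method="ordinal")
        tab["cwres_normal_quantile"] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    else:
        tab["cwres_normal_quantile"] = []
    return tab


def bootstrap_model(
    spec: ModelSpec,
    dataset: PKDataset,
    n_replicates: int = 1000,
    seed: int | None = None,
    settings: FOCESettings | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects, refit, percentile CIs.

    Each replicate resamples subjects with replacement to the original
    cohort size and refits starting from the full-data estimates;
    non-converged replicates are counted and excluded.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    settings = settings or FOCESettings()
    original = fit_model(spec, dataset, settings, compute_se=False)
    start = original.estimates
    rng = np.random.default_rng(seed)
    n = len(dataset.subjects)
    rows = []
    n_failed = 0
    for r in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        resampled = []
        for k, i in enumerate(idx):
            s = dataset.subjects[i]
            resampled.append(
                SubjectData(
                    subject_id=f"B{r}_{k}_{s.subject_id}",
                    weight=s.weight,
                    doses=list(s.doses),
                    observations=list(s.observations),
                    covariates=dict(s.covariates),
                )
            )
        try:
            fit = fit_model(start, PKDataset(resampled), settings, compute_se=False)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        e = fit.estimates
        row = {
            "cl_std": e.cl_allometry.standard_value,
            "v_std": e.v_allometry.standard_value,
            "omega": e.iiv_cl.omega,
            "sigma": e.residual.sigma_add,
        }
        for rel in e.included_covariates:
            row[f"theta_{rel.covariate_name}"] = rel.theta
        rows.append(row)
    if not rows:
        raise RuntimeError("all bootstrap replicates failed")
    samples = pd.DataFrame(rows)
    e = original.estimates
    points = {
        "cl_std": e.cl_allometry.standard_value,
        "v_std": e.v_allometry.standard_value,
        "omega": e.iiv_cl.omega,
        "sigma": e.residual.sigma_add,
    }
    for rel in e.included_covariates:
        points[f"theta_{rel.covariate_name}"] = rel.theta
    lo = {k: float(np.percentile(samples[k], 2.5)) for k in samples.columns}
    hi = {k: float(np.percentile(samples[k], 97.5)) for k in samples.columns}
    return BootstrapResult(
        n_replicates=n_replicates,
        n_failed=n_failed,
        point_estimates=points,
        ci_lower=lo,
        ci_upper=hi,
        samples=samples,
    )


def pc_vpc(
    fit: FitResult,
    dataset: PKDataset,
    n_simulations: int = 1000,
    bins: int = 6,
    seed: int | None = None,
    settings: FOCESettings | None = None,
) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Observed and simulated concentrations are each multiplied by
    (bin median population prediction)/(own population prediction), so
    the correction factor is invariant to dose scale.  Per time bin the
    observed 2.5/50/97.5 percentiles are compared with the 95% band of
    the same percentile across simulated replicates.  Time bins default
    to equal-count quantile bins; bins with fewer than two observations
    are merged with a neighbour.
    """
    if not fit.converged:
        raise ValueError("pc-VPC requires a converged fit")
    if n_simulations < 100:
        raise ValueError("n_simulations must be >= 100")
    settings = settings or FOCESettings()
    spec = fit.estimates
    prep = _Prepared(dataset, spec)
    tvcl = prep.tv_clearance(spec.cl_allometry.standard_value, spec.included_covariates)
    v_i = spec.v_allometry.standard_value * prep.allo_v
    f_pop = prep.predict(tvcl, v_i)

    t = prep.t_obs[prep.mask]
    y = prep.y[prep.mask]
    pred = f_pop[prep.mask]
    n_obs = len(y)
    if n_obs == 0:
        raise ValueError("dataset has no quantifiable observations")

    # quantile bin edges on observation times, then merge sparse bins
    nbins = min(bins, max(1, n_obs // 2))
    edges = np.unique(np.quantile(t, np.linspace(0, 1, nbins + 1)))
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
    n_merged = 0
    counts = np.bincount(idx, minlength=len(edges) - 1)
    while len(edges) > 2 and counts.min() < 2:
        k = int(counts.argmin())
        drop = k if k > 0 else 1  # merge with left neighbour (or right at edge 0)
        edges = np.delete(edges, drop)
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        n_merged += 1
    n_final = len(edges) - 1

    bin_median_pred = np.array([np.median(pred[idx == b]) for b in range(n_final)])
    factor = bin_median_pred[idx] / pred
    pc_obs = y * factor

    band_qs = (2.5, 50.0, 97.5)  # compared observed-vs-simulated statistics
    all_qs = (2.5, 25.0, 50.0, 75.0, 97.5)
    obs_pct = np.array(
        [[np.percentile(pc_obs[idx == b], q) for q in band_qs] for b in range(n_final)]
    )

    rng = np.random.default_rng(seed)
    omega = spec.iiv_cl.omega
    sigma = spec.residual.sigma_add
    sim_pct = np.empty((n_simulations, n_final, len(all_qs)))
    for r in range(n_simulations):
        eta = rng.normal(0.0, omega, size=prep.n) if omega > 0 else np.zeros(prep.n)
        f_ind = prep.predict(tvcl * np.exp(eta), v_i)
        y_sim = f_ind[prep.mask] + rng.normal(0.0, sigma, size=n_obs)
        pc_sim = y_sim * factor
        for b in range(n_final):
            sim_pct[r, b, :] = np.percentile(pc_sim[idx == b], all_qs)

    rows = []
    for b in range(n_final):
        row = {
            "bin_lower": edges[b],
            "bin_upper": edges[b + 1],
            "n_obs": int(counts[b]),
            "median_time": float(np.median(t[idx == b])),
        }
        for qi, q in zip((0, 2, 4), band_qs):
            key = f"p{q:g}"
            row[f"obs_{key}"] = obs_pct[b, band_qs.index(q)]
            row[f"sim_{key}_lo"] = float(np.percentile(sim_pct[:, b, qi], 2.5))
            row[f"sim_{key}_hi"] = float(np.percentile(sim_pct[:, b, qi], 97.5))
        # typical predicted interquartile band of pc concentrations
        row["sim_iqr_lo"] = float(np.median(sim_pct[:, b, 1]))
        row["sim_iqr_hi"] = float(np.median(sim_pct[:, b, 3]))
        rows.append(row)
    obs_table = pd.DataFrame(
        {
            "time": t,
            "observed": y,
            "population_prediction": pred,
            "bin": idx,
            "correction_factor": factor,
            "pc_observed": pc_obs,
        }
    )
    return VPCResult(
        bins=pd.DataFrame(rows),
        observations=obs_table,
        n_simulations=n_simulations,
        n_merged_bins=n_merged,
    )
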