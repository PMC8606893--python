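"""FOCE-I estimation of the nonlinear mixed-effects model.

The marginal likelihood of each subject's concentration vector is
approximated by linearising the model in the subject-level random effect
η at its conditional mode η̂ (empirical Bayes estimate).  With

    G_i = ∂f_i/∂η at η̂_i,
    C_i = G_i ω² G_iᵀ + σ² I,
    r_i = y_i − f_i(η̂_i) + G_i η̂_i,

the objective function value is

    OFV = Σ_i [ log det C_i + r_iᵀ C_i⁻¹ r_i ]

excluding the N·log 2π constant by default (the usual NONMEM
convention; the constant cancels from every ΔOFV comparison).  Because
the residual model is purely additive, the η-interaction term of FOCE-I
is identically zero here, so FOCE-I and FOCE coincide; the machinery is
written against the general linearisation.

The inner η optimisation is a safeguarded (backtracking) Gauss–Newton
iteration started at 0 and vectorised across subjects; the outer
optimisation over (TVCL, TVV, covariate θs, ω, σ) uses Nelder–Mead on a
log-transformed parameter vector, with Ka held fixed.  Standard errors
come from a finite-difference Hessian of the OFV at the optimum.

Below-quantitation-limit observations are excluded from the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .dataset import PKDataset, SubjectData
from .population import CovariateRelation, ModelSpec

__all__ = [
    "FOCESettings",
    "FitResult",
    "SelectionStep",
    "lrt_threshold",
    "FORWARD_DELTA_OFV",
    "BACKWARD_DELTA_OFV",
    "conditional_eta",
    "foce_objective",
    "evaluate_at",
    "fit_model",
    "stepwise_covariates",
]

#: ΔOFV thresholds for stepwise covariate selection: χ²(1 df) quantiles
#: at p = 0.05 (forward inclusion) and p = 0.01 (backward retention).
def lrt_threshold(p: float, df: int = 1) -> float:
    """χ² quantile used as a likelihood-ratio ΔOFV threshold."""
    return float(stats.chi2.ppf(1.0 - p, df))


FORWARD_DELTA_OFV = lrt_threshold(0.05)  # ≈ 3.84
BACKWARD_DELTA_OFV = lrt_threshold(0.01)  # ≈ 6.63

_ETA_BOUND = 8.0  # |η| clamp for the inner search
_ETA_FD_STEP = 1e-5  # central-difference step for ∂f/∂η


@dataclass(frozen=True)
class FOCESettings:
    """Numerical settings for the FOCE estimator."""

    inner_tolerance: float = 1e-8
    outer_tolerance: float = 1e-4
    max_inner_iterations: int = 40
    max_function_evals: int = 2000
    include_log2pi: bool = False
    se_step: float = 1e-4  # relative finite-difference step for the Hessian

    def __post_init__(self) -> None:
        if self.inner_tolerance <= 0 or self.outer_tolerance <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FitResult:
    """Estimates, uncertainty and per-subject empirical Bayes η̂."""

    estimates: ModelSpec
    ofv: float
    eta_hat: np.ndarray
    subject_ids: list[str]
    converged: bool
    standard_errors: dict[str, float] = field(default_factory=dict)  # RSE %
    n_function_evals: int = 0

    def report(self) -> dict:
        """Structured fit report (estimate / RSE% / fixed), JSON-ready."""
        e = self.estimates
        rows = {
            "CL/F (L/h/70 kg)": {
                "estimate": e.cl_allometry.standard_value,
                "rse_percent": self.standard_errors.get("cl_std"),
                "fixed": False,
            },
            "V/F (L/70 kg)": {
                "estimate": e.v_allometry.standard_value,
                "rse_percent": self.standard_errors.get("v_std"),
                "fixed": False,
            },
            "Ka (1/h)": {"estimate": e.ka_fixed, "rse_percent": None, "fixed": True},
            "omega_CL/F": {
                "estimate": e.iiv_cl.omega,
                "rse_percent": self.standard_errors.get("omega"),
                "fixed": False,
            },
            "sigma_add (ng/ml)": {
                "estimate": e.residual.sigma_add,
                "rse_percent": self.standard_errors.get("sigma"),
                "fixed": False,
            },
        }
        for rel in e.included_covariates:
            rows[f"theta_{rel.covariate_name}"] = {
                "estimate": rel.theta,
                "rse_percent": self.standard_errors.get(f"theta_{rel.covariate_name}"),
                "fixed": False,
            }
        return {"ofv": self.ofv, "converged": self.converged, "parameters": rows}


# ---------------------------------------------------------------------------
# prepared cohort: padded arrays for vectorised prediction across subjects
# ---------------------------------------------------------------------------


class _Prepared:
    """Cohort flattened to padded numpy arrays (non-BQL observations only)."""

    def __init__(self, dataset: PKDataset, spec: ModelSpec):
        subs = dataset.subjects
        self.ids = [s.subject_id for s in subs]
        self.n = len(subs)
        self.weights = np.array([s.weight for s in subs])

        obs = [[o for o in s.observations if not o.bql] for s in subs]
        self.m_i = np.array([len(o) for o in obs])
        m = max(1, int(self.m_i.max()) if self.n else 1)
        self.y = np.zeros((self.n, m))
        self.t_obs = np.zeros((self.n, m))
        self.mask = np.zeros((self.n, m), dtype=bool)
        for i, oo in enumerate(obs):
            for j, o in enumerate(oo):
                self.y[i, j] = o.concentration
                self.t_obs[i, j] = o.time
                self.mask[i, j] = True
        self.n_obs_total = int(self.mask.sum())

        dose_lists = [_explicit_doses(s) for s in subs]
        d = max(1, max(len(dt) for dt, _ in dose_lists) if self.n else 1)
        self.dose_t = np.zeros((self.n, d))
        self.dose_a = np.zeros((self.n, d))
        for i, (dt, da) in enumerate(dose_lists):
            self.dose_t[i, : len(dt)] = dt
            self.dose_a[i, : len(da)] = da

        self.allo_cl = (self.weights / spec.cl_allometry.standard_weight) ** spec.cl_allometry.exponent
        self.allo_v = (self.weights / spec.v_allometry.standard_weight) ** spec.v_allometry.exponent
        self.ka = spec.ka_fixed
        # subject covariate values for every candidate/included relation
        self.cov_values: dict[str, np.ndarray] = {}
        for rel in tuple(spec.candidate_covariates) + tuple(spec.included_covariates):
            self.cov_values[rel.covariate_name] = np.array(
                [_covariate_value(s, rel.covariate_name) for s in subs]
            )

    def tv_clearance(self, cl_std: float, relations: tuple[CovariateRelation, ...]) -> np.ndarray:
        cl = cl_std * self.allo_cl
        for rel in relations:
            x = self.cov_values[rel.covariate_name]
            if rel.kind == "power":
                cl = cl * (x / rel.covariate_median) ** rel.theta
            else:
                cl = cl * rel.theta**x
        return cl

    def predict(self, cl_i: np.ndarray, v_i: np.ndarray) -> np.ndarray:
        """Concentrations (n, m), ng/ml, by superposition; vectorised."""
        ke = (cl_i / v_i)[:, None, None]
        dt = self.t_obs[:, :, None] - self.dose_t[:, None, :]
        active = dt >= 0
        dt = np.where(active, dt, 0.0)
        diff = self.ka - ke
        degen = np.abs(diff) <= 1e-10 * self.ka
        safe = np.where(degen, 1.0, diff)
        unit = np.where(
            degen,
            dt * np.exp(-self.ka * dt),
            (np.exp(-ke * dt) - np.exp(-self.ka * dt)) / safe,
        )
        c = (self.dose_a[:, None, :] * self.ka / v_i[:, None, None]) * unit * active
        return 1000.0 * c.sum(axis=-1)


def _explicit_doses(subject: SubjectData) -> tuple[list[float], list[float]]:
    times: list[float] = []
    amounts: list[float] = []
    for rec in subject.doses:
        if rec.steady_state:
            # cover ≈ 45 days of history; ample for pediatric sirolimus ke
            n_back = int(math.ceil(45 * 24 / rec.interval))
            for k in range(n_back + 1):
                times.append(rec.time - k * rec.interval)
                amounts.append(rec.amount)
        else:
            times.append(rec.time)
            amounts.append(rec.amount)
    return times, amounts


def _covariate_value(subject: SubjectData, name: str) -> float:
    if name == "weight":
        return subject.weight
    if name not in subject.covariates:
        raise KeyError(
            f"subject {subject.subject_id!r} lacks covariate {name!r}"
        )
    return subject.covariates[name]


# ---------------------------------------------------------------------------
# inner problem: conditional (empirical Bayes) eta
# ---------------------------------------------------------------------------


def _penalized_obj(prep: _Prepared, tvcl, v_i, eta, sigma2, omega2) -> np.ndarray:
    f = prep.predict(tvcl * np.exp(eta), v_i)
    res2 = np.where(prep.mask, (prep.y - f) ** 2, 0.0).sum(axis=1)
    pen = eta**2 / omega2 if omega2 > 0 else np.zeros_like(eta)
    return res2 / sigma2 + pen


def _inner_etas(
    prep: _Prepared,
    tvcl: np.ndarray,
    v_i: np.ndarray,
    sigma: float,
    omega: float,
    settings: FOCESettings,
    eta0: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised safeguarded Gauss–Newton for all subjects' η̂."""
    if omega == 0.0 or prep.n == 0:
        return np.zeros(prep.n)
    sigma2, omega2 = sigma**2, omega**2
    eta = np.zeros(prep.n) if eta0 is None else np.clip(eta0, -_ETA_BOUND, _ETA_BOUND).copy()
    h = _ETA_FD_STEP
    q = _penalized_obj(prep, tvcl, v_i, eta, sigma2, omega2)
    for _ in range(settings.max_inner_iterations):
        f0 = prep.predict(tvcl * np.exp(eta), v_i)
        fp = prep.predict(tvcl * np.exp(eta + h), v_i)
        fm = prep.predict(tvcl * np.exp(eta - h), v_i)
        g_obs = (fp - fm) / (2 * h)
        resid = np.where(prep.mask, prep.y - f0, 0.0)
        grad = -2.0 * (resid * g_obs).sum(axis=1) / sigma2 + 2.0 * eta / omega2
        hess = 2.0 * np.where(prep.mask, g_obs**2, 0.0).sum(axis=1) / sigma2 + 2.0 / omega2
        step = -grad / hess
        step = np.clip(step, -1.0, 1.0)
        alpha = np.ones(prep.n)
        # subjects whose Newton step is already below tolerance are done
        accepted = np.abs(step) < settings.inner_tolerance
        new_eta = eta.copy()
        new_q = q.copy()
        for _ in range(8):
            if accepted.all():
                break
            trial = np.clip(eta + alpha * step, -_ETA_BOUND, _ETA_BOUND)
            qt = _penalized_obj(prep, tvcl, v_i, trial, sigma2, omega2)
            improve = (qt < q) & ~accepted
            new_eta[improve] = trial[improve]
            new_q[improve] = qt[improve]
            accepted |= improve
            alpha = np.where(accepted, alpha, alpha / 2.0)
        moved = np.abs(new_eta - eta)
        eta, q = new_eta, new_q
        if moved.max(initial=0.0) < settings.inner_tolerance:
            break
    return eta


def conditional_eta(
    spec: ModelSpec, subject: SubjectData, settings: FOCESettings | None = None
) -> tuple[float, float]:
    """Empirical Bayes η̂ and the curvature d²Q/dη² at the mode.

    Minimises Σ_j (y_j − f_j(η))²/σ² + η²/ω² (the joint −2 log density up
    to constants).
    """
    settings = settings or FOCESettings()
    if spec.iiv_cl.omega <= 0:
        raise ValueError("conditional_eta requires omega > 0")
    if not any(not o.bql for o in subject.observations):
        raise ValueError("subject has no quantifiable observations")
    prep = _Prepared(PKDataset([subject]), spec)
    tvcl = prep.tv_clearance(spec.cl_allometry.standard_value, spec.included_covariates)
    v_i = spec.v_allometry.standard_value * prep.allo_v
    eta = _inner_etas(prep, tvcl, v_i, spec.residual.sigma_add, spec.iiv_cl.omega, settings)
    s2, w2 = spec.residual.sigma_add**2, spec.iiv_cl.omega**2
    h = 1e-4
    qp = _penalized_obj(prep, tvcl, v_i, eta + h, s2, w2)[0]
    q0 = _penalized_obj(prep, tvcl, v_i, eta, s2, w2)[0]
    qm = _penalized_obj(prep, tvcl, v_i, eta - h, s2, w2)[0]
    curvature = (qp - 2 * q0 + qm) / h**2
    return float(eta[0]), float(curvature)


# ---------------------------------------------------------------------------
# FOCE objective and fitting
# ---------------------------------------------------------------------------


def _ofv_from_prepared(
    prep: _Prepared,
    cl_std: float,
    v_std: float,
    relations: tuple[CovariateRelation, ...],
    omega: float,
    sigma: float,
    settings: FOCESettings,
    eta0: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    if sigma <= 0:
        raise ValueError("estimation requires a positive residual sigma")
    tvcl = prep.tv_clearance(cl_std, relations)
    v_i = v_std * prep.allo_v
    eta = _inner_etas(prep, tvcl, v_i, sigma, omega, settings, eta0=eta0)
    sigma2, omega2 = sigma**2, omega**2
    h = _ETA_FD_STEP
    f0 = prep.predict(tvcl * np.exp(eta), v_i)
    fp = prep.predict(tvcl * np.exp(eta + h), v_i)
    fm = prep.predict(tvcl * np.exp(eta - h), v_i)
    g = np.where(prep.mask, (fp - fm) / (2 * h), 0.0)
    r = np.where(prep.mask, prep.y - f0 + g * eta[:, None], 0.0)
    gg = (g**2).sum(axis=1)
    gr = (g * r).sum(axis=1)
    rr = (r**2).sum(axis=1)
    # rank-1 C = sigma² I + omega² g gᵀ: Sherman–Morrison / determinant lemma
    quad = rr / sigma2 - omega2 * gr**2 / (sigma2 * (sigma2 + omega2 * gg))
    logdet = prep.m_i * math.log(sigma2) + np.log1p(omega2 * gg / sigma2)
    ofv = float((quad + logdet).sum())
    if settings.include_log2pi:
        ofv += prep.n_obs_total * math.log(2 * math.pi)
    return ofv, eta


def foce_objective(
    spec: ModelSpec, dataset: PKDataset, settings: FOCESettings | None = None
) -> float:
    """FOCE OFV of ``dataset`` under ``spec`` (η̂ re-estimated internally)."""
    settings = settings or FOCESettings()
    prep = _Prepared(dataset, spec)
    ofv, _ = _ofv_from_prepared(
        prep,
        spec.cl_allometry.standard_value,
        spec.v_allometry.standard_value,
        spec.included_covariates,
        spec.iiv_cl.omega,
        spec.residual.sigma_add,
        settings,
    )
    return ofv


def evaluate_at(
    spec: ModelSpec, dataset: PKDataset, settings: FOCESettings | None = None
) -> FitResult:
    """A :class:`FitResult` at fixed parameters (no optimisation).

    Useful for diagnostics of a known/published model and as a warm
    start for refits.
    """
    settings = settings or FOCESettings()
    prep = _Prepared(dataset, spec)
    ofv, eta = _ofv_from_prepared(
        prep,
        spec.cl_allometry.standard_value,
        spec.v_allometry.standard_value,
        spec.included_covariates,
        spec.iiv_cl.omega,
        spec.residual.sigma_add,
        settings,
    )
    return FitResult(
        estimates=spec, ofv=ofv, eta_hat=eta, subject_ids=prep.ids, converged=True
    )


def _pack(spec: ModelSpec) -> tuple[np.ndarray, tuple[CovariateRelation, ...]]:
    rels = tuple(spec.included_covariates)
    x = [
        math.log(spec.cl_allometry.standard_value),
        math.log(spec.v_allometry.standard_value),
    ]
    for rel in rels:
        x.append(math.log(rel.theta) if rel.kind == "categorical" else rel.theta)
    x.append(math.log(max(spec.iiv_cl.omega, 1e-6)))
    x.append(math.log(spec.residual.sigma_add))
    return np.array(x), rels


def _unpack(
    x: np.ndarray, rels: tuple[CovariateRelation, ...]
) -> tuple[float, float, tuple[CovariateRelation, ...], float, float]:
    cl_std = math.exp(x[0])
    v_std = math.exp(x[1])
    out_rels = []
    for k, rel in enumerate(rels):
        th = math.exp(x[2 + k]) if rel.kind == "categorical" else float(x[2 + k])
        out_rels.append(replace(rel, theta=th))
    omega = math.exp(x[2 + len(rels)])
    sigma = math.exp(x[3 + len(rels)])
    return cl_std, v_std, tuple(out_rels), omega, sigma


def _param_names(rels: tuple[CovariateRelation, ...]) -> list[str]:
    return (
        ["cl_std", "v_std"]
        + [f"theta_{r.covariate_name}" for r in rels]
        + ["omega", "sigma"]
    )


def fit_model(
    spec: ModelSpec,
    dataset: PKDataset,
    settings: FOCESettings | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Fit (TVCL, TVV, covariate θs, ω, σ) by minimising the FOCE OFV.

    ``spec`` supplies both the model structure and the initial estimates.
    Ka stays fixed.  Standard errors are reported as RSE% from the
    inverse finite-difference Hessian of the OFV (2·H⁻¹ on the −2LL
    scale); they are omitted when the Hessian is not positive definite.
    """
    settings = settings or FOCESettings()
    n_with_obs = sum(1 for s in dataset.subjects if any(not o.bql for o in s.observations))
    if n_with_obs < 2:
        raise ValueError("fitting requires at least two subjects with observations")
    prep = _Prepared(dataset, spec)
    x0, rels = _pack(spec)
    state = {"eta": None, "evals": 0}

    def objective(x: np.ndarray) -> float:
        cl_std, v_std, rr, omega, sigma = _unpack(x, rels)
        ofv, eta = _ofv_from_prepared(
            prep, cl_std, v_std, rr, omega, sigma, settings, eta0=state["eta"]
        )
        state["eta"] = eta
        state["evals"] += 1
        return ofv

    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": settings.outer_tolerance,
            "fatol": settings.outer_tolerance,
            "maxfev": settings.max_function_evals,
            "adaptive": True,
        },
    )
    cl_std, v_std, fitted_rels, omega, sigma = _unpack(res.x, rels)
    fitted = spec.with_values(
        cl_std=cl_std, v_std=v_std, omega=omega, sigma=sigma,
        included_covariates=fitted_rels,
    )
    state["eta"] = None  # cold restart for the final, definitive evaluation
    ofv, eta = _ofv_from_prepared(
        prep, cl_std, v_std, fitted_rels, omega, sigma, settings
    )
    ses: dict[str, float] = {}
    if compute_se and res.success:
        ses = _relative_standard_errors(
            prep, res.x, rels, settings, state
        )
    return FitResult(
        estimates=fitted,
        ofv=ofv,
        eta_hat=eta,
        subject_ids=prep.ids,
        converged=bool(res.success) and math.isfinite(ofv),
        standard_errors=ses,
        n_function_evals=state["evals"],
    )


def _relative_standard_errors(prep, x_opt, rels, settings, state) -> dict[str, float]:
    """RSE% via central finite-difference Hessian of the OFV at the optimum.

    The Hessian is taken in the natural parameter space (not log) so the
    RSEs refer directly to the reported estimates.
    """
    names = _param_names(rels)
    cl, v, rr, om, sg = _unpack(x_opt, rels)
    p = np.array([cl, v] + [r.theta for r in rr] + [om, sg])

    def ofv_at(pvec: np.ndarray) -> float:
        rloc = tuple(replace(r, theta=float(pvec[2 + k])) for k, r in enumerate(rr))
        out, _ = _ofv_from_prepared(
            prep, pvec[0], pvec[1], rloc, pvec[-2], pvec[-1], settings,
            eta0=state["eta"],
        )
        return out

    k = len(p)
    steps = np.maximum(np.abs(p) * settings.se_step, 1e-8)
    hess = np.zeros((k, k))
    f0 = ofv_at(p)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        fpp = ofv_at(p + ei)
        fmm = ofv_at(p - ei)
        hess[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            fij = ofv_at(p + ei + ej)
            fi = ofv_at(p + ei - ej)
            fj = ofv_at(p - ei + ej)
            f2 = ofv_at(p - ei - ej)
            hess[i, j] = hess[j, i] = (fij - fi - fj + f2) / (4 * steps[i] * steps[j])
    try:
        cov = 2.0 * np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return {}
    d = np.diag(cov)
    if np.any(d <= 0):
        return {}
    return {n: float(100.0 * math.sqrt(di) / abs(pi)) for n, di, pi in zip(names, d, p)}


# ---------------------------------------------------------------------------
# stepwise covariate selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionStep:
    """One stepwise-selection event with its ΔOFV."""

    phase: str  # "forward" | "backward"
    covariate: str
    delta_ofv: float
    action: str  # "included" | "rejected" | "removed" | "retained"


def stepwise_covariates(
    base_spec: ModelSpec,
    candidates: list[CovariateRelation],
    dataset: PKDataset,
    settings: FOCESettings | None = None,
) -> tuple[ModelSpec, list[SelectionStep]]:
    """Forward-inclusion / backward-elimination covariate selection.

    Forward: iteratively add the candidate with the largest OFV decrease
    while that decrease exceeds the χ²(1) p=0.05 threshold (≈3.84); ties
    break deterministically on declared candidate order.  Backward: a
    retained covariate is removed unless dropping it raises the OFV by
    more than the p=0.01 threshold (≈6.63).  Every ΔOFV is logged.
    """
    settings = settings or FOCESettings()
    log: list[SelectionStep] = []
    current = fit_model(base_spec, dataset, settings, compute_se=False)
    remaining = list(candidates)
    included: list[CovariateRelation] = list(base_spec.included_covariates)

    while remaining:
        trials = []
        for cand in remaining:
            trial_spec = current.estimates.with_values(
                included_covariates=tuple(included) + (cand,)
            )
            fit = fit_model(trial_spec, dataset, settings, compute_se=False)
            trials.append((cand, fit, current.ofv - fit.ofv))
        best_cand, best_fit, best_drop = max(trials, key=lambda t: t[2])
        # deterministic tie-break: first declared candidate within 1e-9
        for cand, fit, drop in trials:
            if drop > best_drop - 1e-9:
                best_cand, best_fit, best_drop = cand, fit, drop
                break
        if best_drop > FORWARD_DELTA_OFV:
            log.append(SelectionStep("forward", best_cand.covariate_name, best_drop, "included"))
            included = list(best_fit.estimates.included_covariates)
            current = best_fit
            remaining = [c for c in remaining if c.covariate_name != best_cand.covariate_name]
            for cand, _, drop in trials:
                if cand.covariate_name != best_cand.covariate_name:
                    log.append(SelectionStep("forward", cand.covariate_name, drop, "rejected"))
        else:
            for cand, _, drop in trials:
                log.append(SelectionStep("forward", cand.covariate_name, drop, "rejected"))
            break

    for rel in list(included):
        reduced = [r for r in included if r.covariate_name != rel.covariate_name]
        red_spec = current.estimates.with_values(included_covariates=tuple(reduced))
        red_fit = fit_model(red_spec, dataset, settings, compute_se=False)
        increase = red_fit.ofv - current.ofv
        if increase <= BACKWARD_DELTA_OFV:
            log.append(SelectionStep("backward", rel.covariate_name, increase, "removed"))
            included = reduced
            current = red_fit
        else:
            log.append(SelectionStep("backward", rel.covariate_name, increase, "retained"))

    final = fit_model(
        current.estimates.with_values(included_covariates=tuple(included)),
        dataset,
        settings,
        compute_se=False,
    )
    return final.estimates, log
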