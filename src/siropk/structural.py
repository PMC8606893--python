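"""Analytic one-compartment oral (first-order absorption/elimination) model.

All concentrations returned by this module are in ng/ml; internal doses
are mg and volumes L, so the mg/L Bateman solution is scaled by 1000.
Bioavailability is folded into the apparent parameters CL/F and V/F, so
no separate F appears anywhere.

The flip-flop degenerate case ka == ke is handled by the analytic limit
``(D/V)·ka·t·exp(-ka·t)``, never by division by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MG_L_TO_NG_ML",
    "StructuralParams",
    "DoseRegimen",
    "concentration_single_dose",
    "concentration_from_doses",
    "concentration_profile",
    "steady_state_trough",
]

MG_L_TO_NG_ML = 1000.0

# relative ka-ke gap below which the degenerate limit branch is used
_DEGENERATE_RTOL = 1e-10


@dataclass(frozen=True)
class StructuralParams:
    """Apparent oral one-compartment parameters.

    cl : CL/F, L/h.  v : V/F, L.  ka : absorption rate constant, h⁻¹.
    """

    cl: float
    v: float
    ka: float

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.v <= 0 or self.ka <= 0:
            raise ValueError(
                f"cl, v and ka must all be positive, got ({self.cl}, {self.v}, {self.ka})"
            )

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/V, h⁻¹."""
        return self.cl / self.v


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated oral dosing: ``n_doses`` doses every ``interval`` hours.

    ``n_doses=None`` marks a steady-state (infinite-history) regimen.
    """

    dose_per_administration: float
    interval: float
    n_doses: int | None = None

    def __post_init__(self) -> None:
        if self.dose_per_administration < 0:
            raise ValueError("dose_per_administration must be nonnegative")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.n_doses is not None and self.n_doses < 1:
            raise ValueError("n_doses must be >= 1 when given")


def _bateman_unit(ka, ke, t):
    """(exp(-ke t) - exp(-ka t))/(ka - ke) with the ka→ke limit, vectorised."""
    ka = np.asarray(ka, dtype=float)
    ke = np.asarray(ke, dtype=float)
    t = np.asarray(t, dtype=float)
    diff = ka - ke
    degenerate = np.abs(diff) <= _DEGENERATE_RTOL * ka
    safe = np.where(degenerate, 1.0, diff)
    general = (np.exp(-ke * t) - np.exp(-ka * t)) / safe
    limit = t * np.exp(-ka * t)
    return np.where(degenerate, limit, general)


def concentration_single_dose(p: StructuralParams, dose: float, t):
    """Concentration (ng/ml) at time(s) ``t`` hours after one oral dose (mg).

    Standard Bateman solution ``D·ka/(V·(ka−ke))·(e^(−ke·t) − e^(−ka·t))``;
    exactly 0 at t=0 and for t<0 (dose not yet given).
    """
    t = np.asarray(t, dtype=float)
    active = t >= 0
    c = (dose * p.ka / p.v) * _bateman_unit(p.ka, p.ke, np.where(active, t, 0.0))
    out = MG_L_TO_NG_ML * np.where(active, c, 0.0)
    return float(out) if out.ndim == 0 else out


def concentration_from_doses(p: StructuralParams, dose_times, dose_amounts, times):
    """Superposition of single-dose solutions over an explicit dose list."""
    dose_times = np.asarray(dose_times, dtype=float)
    dose_amounts = np.asarray(dose_amounts, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = times[..., None] - dose_times
    active = dt >= 0
    unit = _bateman_unit(p.ka, p.ke, np.where(active, dt, 0.0))
    c = (dose_amounts * p.ka / p.v) * unit * active
    out = MG_L_TO_NG_ML * c.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def concentration_profile(p: StructuralParams, regimen: DoseRegimen, times):
    """Concentration (ng/ml) at ``times`` under a repeated-dose regimen.

    Doses are administered at 0, τ, 2τ, ... ; a steady-state regimen
    (``n_doses=None``) uses the closed-form accumulation instead of an
    explicit (infinite) superposition.
    """
    times = np.asarray(times, dtype=float)
    if regimen.n_doses is None:
        return _steady_state_concentration(p, regimen, times)
    dose_times = regimen.interval * np.arange(regimen.n_doses)
    amounts = np.full(regimen.n_doses, regimen.dose_per_administration)
    return concentration_from_doses(p, dose_times, amounts, times)


def _accumulation(rate: float, tau: float) -> float:
    """Geometric accumulation factor e^(−k·τ)/(1 − e^(−k·τ))."""
    x = np.exp(-rate * tau)
    return x / (1.0 - x)


def _steady_state_concentration(p: StructuralParams, regimen: DoseRegimen, t_in_interval):
    """Steady-state concentration at time t (0 ≤ t < τ) after a dose."""
    t = np.asarray(t_in_interval, dtype=float)
    tau = regimen.interval
    d = regimen.dose_per_administration
    ka, ke = p.ka, p.ke
    if abs(ka - ke) <= _DEGENERATE_RTOL * ka:
        # limit of the accumulated Bateman sum at ka == ke == k:
        # (D k / V) Σ_{j≥0} (t + jτ) e^{-k(t+jτ)}
        x = np.exp(-ka * tau)
        s = np.exp(-ka * t) * (t / (1.0 - x) + tau * x / (1.0 - x) ** 2)
        c = (d * ka / p.v) * s
    else:
        c = (d * ka / (p.v * (ka - ke))) * (
            np.exp(-ke * t) / (1.0 - np.exp(-ke * tau))
            - np.exp(-ka * t) / (1.0 - np.exp(-ka * tau))
        )
    out = MG_L_TO_NG_ML * c
    return float(out) if np.ndim(out) == 0 else out


def steady_state_trough(p: StructuralParams, regimen: DoseRegimen) -> float:
    """Steady-state pre-dose (trough) concentration, ng/ml.

    Closed-form accumulation
    ``D·ka/(V·(ka−ke)) · [e^(−ke·τ)/(1−e^(−ke·τ)) − e^(−ka·τ)/(1−e^(−ka·τ))]``,
    i.e. the τ⁻ limit of the repeated-dose superposition.
    """
    tau = regimen.interval
    d = regimen.dose_per_administration
    if d == 0:
        return 0.0
    ka, ke = p.ka, p.ke
    if abs(ka - ke) <= _DEGENERATE_RTOL * ka:
        x = np.exp(-ka * tau)
        c = (d * ka / p.v) * tau * x / (1.0 - x) ** 2
    else:
        c = (d * ka / (p.v * (ka - ke))) * (
            _accumulation(ke, tau) - _accumulation(ka, tau)
        )
    return float(MG_L_TO_NG_ML * c)
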