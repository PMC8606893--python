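"""Virtual TDM cohorts with the statistical structure the analysis assumes.

The generator emulates a small pediatric lymphangioma cohort on oral
sirolimus: 15 subjects by default, body weights spanning 4–54 kg,
twice-daily dosing, and sparse trough-dominated sampling as collected in
routine therapeutic drug monitoring.  Concentrations are simulated from
the population model (lognormal inter-individual variability on
clearance, additive residual error) and censored at the assay's lower
limit of linearity (3.5 ng/ml): censored observations are flagged BQL
and carry the limit itself.  Negative simulated observations (possible
under the additive error) are likewise flagged BQL.

Two sampling designs are provided:

``trough-sparse``
    n pre-dose troughs spread over four weeks of therapy — the realistic
    TDM design.  Apparent volume is weakly identifiable from troughs
    alone.
``rich``
    six samples across one dosing interval at two weeks plus three
    troughs — the design parameter-recovery experiments need.

Extra covariates (age, albumin, ...) are drawn from plausible pediatric
distributions purely as distractors for covariate-selection tests; by
construction they do not influence concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import (
    ASSAY_LOWER_LIMIT,
    DoseRecord,
    ObservationRecord,
    PKDataset,
    SubjectData,
)
from .population import ModelSpec, predict_individual, published_model

__all__ = ["CohortSpec", "generate_cohort", "generate_recovery_suite"]

_DOSE_INTERVAL_H = 12.0  # twice-daily dosing

#: Distractor covariates: (mean, SD, lower truncation), pediatric ranges.
_DISTRACTOR_COVARIATES = {
    "age_years": (7.29, 3.11, 0.1),
    "albumin_g_per_l": (37.8, 7.5, 15.0),
    "creatinine_umol_per_l": (32.4, 16.2, 8.0),
    "hematocrit_percent": (33.2, 5.3, 15.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated TDM cohort."""

    n_subjects: int = 15
    weight_range: tuple[float, float] = (4.0, 54.0)
    dose_rate_range: tuple[float, float] = (0.03, 0.08)  # mg/kg/day
    sampling_design: str = "trough-sparse"
    n_samples_per_subject: int = 4
    seed: int = 0
    generating_model: ModelSpec | None = None
    weight_distribution: str = "uniform"  # or "truncnorm" (22.27 ± 9.87 kg)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.weight_range
        if lo <= 0 or hi < lo:
            raise ValueError("weight_range must be positive and ordered")
        if self.sampling_design not in ("trough-sparse", "rich"):
            raise ValueError(f"unknown sampling design {self.sampling_design!r}")
        if self.sampling_design == "trough-sparse" and not (
            1 <= self.n_samples_per_subject <= 28
        ):
            raise ValueError(
                "trough-sparse design supports 1..28 samples per subject, "
                f"got {self.n_samples_per_subject}"
            )


def _trough_times(n: int) -> np.ndarray:
    """n pre-dose sampling times (h) spread over four weeks of therapy."""
    days = np.unique(np.rint(np.geomspace(3, 28, n)).astype(int))
    while len(days) < n:  # rounding collisions at small n
        extra = max(days) + 2
        days = np.append(days, extra)
    return days[:n].astype(float) * 24.0


def _rich_times() -> np.ndarray:
    """Interval-profile times at two weeks plus three troughs (h)."""
    profile = 312.0 + np.array([0.5, 1.5, 3.0, 5.0, 8.0, 11.0])
    troughs = np.array([96.0, 216.0, 336.0])
    return np.sort(np.concatenate([troughs, profile]))


def _sample_weights(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.weight_range
    if spec.weight_distribution == "uniform":
        return rng.uniform(lo, hi, size=spec.n_subjects)
    if spec.weight_distribution == "truncnorm":
        out = np.empty(spec.n_subjects)
        for i in range(spec.n_subjects):
            w = rng.normal(22.27, 9.87)
            while not (lo <= w <= hi):
                w = rng.normal(22.27, 9.87)
            out[i] = w
        return out
    raise ValueError(f"unknown weight distribution {spec.weight_distribution!r}")


def generate_cohort(spec: CohortSpec) -> PKDataset:
    """Simulate a cohort under the generating model; deterministic per seed."""
    model = spec.generating_model or published_model()
    rng = np.random.default_rng(spec.seed)
    weights = _sample_weights(spec, rng)
    dose_rates = rng.uniform(*spec.dose_rate_range, size=spec.n_subjects)
    etas = rng.normal(0.0, model.iiv_cl.omega, size=spec.n_subjects) if model.iiv_cl.omega > 0 else np.zeros(spec.n_subjects)

    if spec.sampling_design == "rich":
        obs_times = _rich_times()
    else:
        obs_times = _trough_times(spec.n_samples_per_subject)
    horizon = float(obs_times.max())
    n_doses = int(math.floor(horizon / _DOSE_INTERVAL_H)) + 1

    subjects: list[SubjectData] = []
    for i in range(spec.n_subjects):
        amount = dose_rates[i] * weights[i] / 2.0  # mg per administration, BID
        doses = [
            DoseRecord(time=k * _DOSE_INTERVAL_H, amount=amount)
            for k in range(n_doses)
        ]
        covs = {
            name: float(max(lo_trunc, rng.normal(mu, sd)))
            for name, (mu, sd, lo_trunc) in _DISTRACTOR_COVARIATES.items()
        }
        subject = SubjectData(
            subject_id=f"S{i + 1:03d}",
            weight=float(weights[i]),
            doses=doses,
            covariates=covs,
        )
        truth = np.atleast_1d(
            predict_individual(model, subject, float(etas[i]), obs_times)
        )
        eps = (
            rng.normal(0.0, model.residual.sigma_add, size=len(obs_times))
            if model.residual.sigma_add > 0
            else np.zeros(len(obs_times))
        )
        observed = truth + eps
        records = []
        for t, c in zip(obs_times, observed):
            if c < ASSAY_LOWER_LIMIT:
                records.append(
                    ObservationRecord(time=float(t), concentration=ASSAY_LOWER_LIMIT, bql=True)
                )
            else:
                records.append(ObservationRecord(time=float(t), concentration=float(c)))
        subject.observations = sorted(records, key=lambda o: o.time)
        subjects.append(subject)
    return PKDataset(subjects=subjects)


def generate_recovery_suite(
    generating_model: ModelSpec,
    n_subjects: int,
    design: str = "rich",
    n_replicates: int = 5,
    seed: int = 0,
    dose_rate: float = 0.05,
    weight_range: tuple[float, float] = (4.0, 54.0),
) -> list[PKDataset]:
    """Replicate cohorts with seeds derived deterministically from ``seed``.

    Every replicate uses the same design and a fixed dose rate
    (mg/kg/day) so recovery experiments differ only in their random
    draws.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    out = []
    for s in child_seeds:
        out.append(
            generate_cohort(
                CohortSpec(
                    n_subjects=n_subjects,
                    weight_range=weight_range,
                    dose_rate_range=(dose_rate, dose_rate),
                    sampling_design=design,
                    seed=int(s),
                    generating_model=generating_model,
                )
            )
        )
    return out
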