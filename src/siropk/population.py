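"""Population model: allometric/covariate fixed effects and random effects.

The structural parameters of each subject are built from typical values
at a 70 kg standard weight via allometric scaling — exponent 0.75 on
apparent clearance (flow-like) and 1 on apparent volume (size-like) —
optionally modified by power or categorical covariate relations, and a
lognormal inter-individual deviation on clearance:

    CL/F_i = TVCL · (WT_i/70)^0.75 · Π_c effect_c(cov_i) · exp(η_i)
    V/F_i  = TVV  · (WT_i/70)
    Ka     fixed

with η_i ~ Normal(0, ω²) and an additive residual ε ~ Normal(0, σ²) on
the observed concentration (ng/ml).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from .dataset import SubjectData
from .structural import StructuralParams, concentration_from_doses

__all__ = [
    "STANDARD_WEIGHT",
    "AllometricRelation",
    "CovariateRelation",
    "RandomEffectSpec",
    "ResidualSpec",
    "ModelSpec",
    "typical_clearance",
    "typical_volume",
    "individual_parameter",
    "apply_covariate",
    "clearance_for_subject",
    "structural_params_for_subject",
    "predict_individual",
    "load_model",
    "published_model",
]

#: Standard (reference) body weight for allometric scaling, kg.
STANDARD_WEIGHT = 70.0


@dataclass(frozen=True)
class AllometricRelation:
    """Power-law weight scaling X_i = X_std · (WT_i / WT_std)^exponent."""

    standard_value: float
    exponent: float
    standard_weight: float = STANDARD_WEIGHT

    def __post_init__(self) -> None:
        if self.standard_value <= 0:
            raise ValueError("standard_value must be positive")
        if self.standard_weight <= 0:
            raise ValueError("standard_weight must be positive")

    def __call__(self, weight: float) -> float:
        if weight <= 0:
            raise ValueError(f"weight must be positive, got {weight}")
        return self.standard_value * (weight / self.standard_weight) ** self.exponent


@dataclass(frozen=True)
class CovariateRelation:
    """A single-θ covariate relation on a parameter.

    kind "power":       Z_i = TV(Z) · (cov_i / median)^θ
    kind "categorical": Z_i = TV(Z) · θ^cov_i  with cov_i ∈ {0, 1}
    """

    kind: str
    covariate_name: str
    theta: float = 0.0
    covariate_median: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("power", "categorical"):
            raise ValueError(f"unknown covariate relation kind {self.kind!r}")
        if self.kind == "power":
            if self.covariate_median is None or self.covariate_median <= 0:
                raise ValueError("power relation requires a positive covariate_median")
        if not math.isfinite(self.theta):
            raise ValueError("theta must be finite")


@dataclass(frozen=True)
class RandomEffectSpec:
    """Lognormal inter-individual variability; omega is the SD of η."""

    omega: float

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be nonnegative")


@dataclass(frozen=True)
class ResidualSpec:
    """Additive residual error; sigma_add in ng/ml.

    Zero is allowed only as the noiseless degenerate case used by the
    synthetic-data generator; estimation requires a positive value.
    """

    sigma_add: float

    def __post_init__(self) -> None:
        if self.sigma_add < 0:
            raise ValueError("sigma_add must be nonnegative")


@dataclass(frozen=True)
class ModelSpec:
    """Complete model definition: structure, covariates, random effects."""

    cl_allometry: AllometricRelation
    v_allometry: AllometricRelation
    ka_fixed: float
    iiv_cl: RandomEffectSpec
    residual: ResidualSpec
    candidate_covariates: tuple[CovariateRelation, ...] = ()
    included_covariates: tuple[CovariateRelation, ...] = ()

    def __post_init__(self) -> None:
        if self.ka_fixed <= 0:
            raise ValueError("ka_fixed must be positive")

    def with_values(
        self,
        cl_std: float | None = None,
        v_std: float | None = None,
        omega: float | None = None,
        sigma: float | None = None,
        included_covariates: tuple[CovariateRelation, ...] | None = None,
    ) -> "ModelSpec":
        """A copy with selected values replaced (used by the estimator)."""
        out = self
        if cl_std is not None:
            out = replace(out, cl_allometry=replace(out.cl_allometry, standard_value=cl_std))
        if v_std is not None:
            out = replace(out, v_allometry=replace(out.v_allometry, standard_value=v_std))
        if omega is not None:
            out = replace(out, iiv_cl=RandomEffectSpec(omega))
        if sigma is not None:
            out = replace(out, residual=ResidualSpec(sigma))
        if included_covariates is not None:
            out = replace(out, included_covariates=tuple(included_covariates))
        return out


def typical_clearance(spec: ModelSpec, weight: float) -> float:
    """Typical CL/F (L/h) at ``weight`` kg from the allometric relation."""
    return spec.cl_allometry(weight)


def typical_volume(spec: ModelSpec, weight: float) -> float:
    """Typical V/F (L) at ``weight`` kg from the allometric relation."""
    return spec.v_allometry(weight)


def individual_parameter(typical: float, eta: float) -> float:
    """Lognormal individualisation: typical · e^η."""
    if typical <= 0:
        raise ValueError("typical value must be positive")
    return typical * math.exp(eta)


def apply_covariate(base: float, rel: CovariateRelation, cov_value: float) -> float:
    """Apply one covariate relation to a base parameter value."""
    if rel.kind == "power":
        if cov_value <= 0:
            raise ValueError(
                f"power covariate {rel.covariate_name!r} requires a positive "
                f"value, got {cov_value}"
            )
        return base * (cov_value / rel.covariate_median) ** rel.theta
    return base * rel.theta**cov_value


def clearance_for_subject(
    spec: ModelSpec, weight: float, covariates: dict[str, float] | None = None
) -> float:
    """Typical CL/F for a subject: allometry plus included covariate effects."""
    cl = typical_clearance(spec, weight)
    for rel in spec.included_covariates:
        if covariates is None or rel.covariate_name not in covariates:
            raise KeyError(
                f"subject lacks covariate {rel.covariate_name!r} required by the model"
            )
        cl = apply_covariate(cl, rel, covariates[rel.covariate_name])
    return cl


def structural_params_for_subject(
    spec: ModelSpec, subject: SubjectData, eta: float = 0.0
) -> StructuralParams:
    """Individual structural parameters for a subject at a given η."""
    cl = individual_parameter(
        clearance_for_subject(spec, subject.weight, subject.covariates), eta
    )
    v = typical_volume(spec, subject.weight)
    return StructuralParams(cl=cl, v=v, ka=spec.ka_fixed)


def _expand_doses(subject: SubjectData, ke: float) -> tuple[list[float], list[float]]:
    """Explicit (time, amount) dose lists; steady-state records are expanded
    far enough back that the omitted tail is numerically negligible."""
    times: list[float] = []
    amounts: list[float] = []
    for rec in subject.doses:
        if rec.steady_state:
            # back-fill until ~30 elimination half-lives are covered
            n_back = max(3, int(math.ceil(30.0 * math.log(2) / max(ke, 1e-6) / rec.interval)))
            for k in range(n_back + 1):
                times.append(rec.time - k * rec.interval)
                amounts.append(rec.amount)
        else:
            times.append(rec.time)
            amounts.append(rec.amount)
    return times, amounts


def predict_individual(spec: ModelSpec, subject: SubjectData, eta: float, times):
    """Individual predicted concentrations (ng/ml) at ``times`` hours."""
    if not subject.doses:
        raise ValueError(f"subject {subject.subject_id!r} has no dosing history")
    p = structural_params_for_subject(spec, subject, eta)
    dt, da = _expand_doses(subject, p.ke)
    return concentration_from_doses(p, dt, da, times)


def _spec_from_mapping(doc: dict, omega_is_variance: bool = False) -> ModelSpec:
    omega = float(doc["omega_cl"])
    if omega_is_variance:
        omega = math.sqrt(omega)
    return ModelSpec(
        cl_allometry=AllometricRelation(
            standard_value=float(doc["cl_f_std"]),
            exponent=float(doc.get("cl_exponent", 0.75)),
            standard_weight=float(doc.get("standard_weight", STANDARD_WEIGHT)),
        ),
        v_allometry=AllometricRelation(
            standard_value=float(doc["v_f_std"]),
            exponent=float(doc.get("v_exponent", 1.0)),
            standard_weight=float(doc.get("standard_weight", STANDARD_WEIGHT)),
        ),
        ka_fixed=float(doc["ka"]),
        iiv_cl=RandomEffectSpec(omega),
        residual=ResidualSpec(float(doc["sigma_add"])),
    )


def load_model(name: str = "pediatric-lymphangioma-sirolimus", *, omega_is_variance: bool = False) -> ModelSpec:
    """Load a named model definition shipped with the package.

    ``omega_is_variance`` reinterprets the stored ω value as a variance
    (the default treats it as the SD of η, ≈30% CV on clearance).
    """
    fname = name.replace("-", "_") + ".yaml"
    ref = resources.files(__package__) / "models" / fname
    with ref.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _spec_from_mapping(doc, omega_is_variance=omega_is_variance)


def published_model(*, omega_is_variance: bool = False) -> ModelSpec:
    """The final pediatric-lymphangioma sirolimus model (versioned config)."""
    return load_model(omega_is_variance=omega_is_variance)
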