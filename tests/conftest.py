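import numpy as np
import pytest

import siropk as sp
from siropk.dataset import DoseRecord, ObservationRecord, PKDataset, SubjectData
from siropk.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def published():
    return sp.published_model()


@pytest.fixture(scope="session")
def neutral_start(published):
    """Initial estimates deliberately away from the generating values."""
    return published.with_values(cl_std=5.0, v_std=150.0, omega=0.5, sigma=2.0)


@pytest.fixture(scope="session")
def rich_cohort(published):
    """40 subjects, rich design, dosed high enough to avoid BQL censoring."""
    return generate_cohort(
        CohortSpec(
            n_subjects=40,
            dose_rate_range=(0.08, 0.08),
            sampling_design="rich",
            seed=11,
            generating_model=published,
        )
    )


@pytest.fixture()
def toy_subject():
    """One subject: 28 BID doses of 0.5 mg, two trough observations."""
    doses = [DoseRecord(time=12.0 * k, amount=0.5) for k in range(28)]
    obs = [
        ObservationRecord(time=168.0, concentration=9.0),
        ObservationRecord(time=336.0, concentration=11.0),
    ]
    return SubjectData(subject_id="T1", weight=20.0, doses=doses, observations=obs)


@pytest.fixture()
def toy_dataset(toy_subject):
    other = SubjectData(
        subject_id="T2",
        weight=35.0,
        doses=[DoseRecord(time=12.0 * k, amount=0.9) for k in range(28)],
        observations=[
            ObservationRecord(time=168.0, concentration=7.5),
            ObservationRecord(time=336.0, concentration=8.5),
        ],
    )
    return PKDataset([toy_subject, other])


def random_cohort(rng: np.random.Generator, n_subjects: int = 3) -> PKDataset:
    """Small random but valid cohort for round-trip style properties."""
    subs = []
    for i in range(n_subjects):
        n_d = int(rng.integers(1, 5))
        n_o = int(rng.integers(1, 5))
        dose_times = np.sort(rng.uniform(0, 100, n_d))
        dose_times[0] = 0.0
        doses = [
            DoseRecord(time=float(t), amount=float(rng.uniform(0.1, 5)))
            for t in dose_times
        ]
        obs = [
            ObservationRecord(
                time=float(t),
                concentration=float(rng.uniform(3.5, 30)),
                bql=bool(rng.random() < 0.2),
            )
            for t in np.sort(rng.uniform(0.5, 200, n_o))
        ]
        subs.append(
            SubjectData(
                subject_id=f"R{i}",
                weight=float(rng.uniform(4, 54)),
                doses=doses,
                observations=obs,
                covariates={"age_years": float(rng.uniform(0.5, 16))},
            )
        )
    return PKDataset(subs)
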