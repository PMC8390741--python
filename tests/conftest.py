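import numpy as np
import pytest

import prrtdose as pr


@pytest.fixture(scope="session")
def dft():
    return pr.load_packaged_dose_factors("adult_male")


@pytest.fixture(scope="session")
def sphere():
    return pr.load_packaged_sphere_theta()


@pytest.fixture(scope="session")
def dfts():
    return {p: pr.load_packaged_dose_factors(p)
            for p in ("adult_male", "adult_female")}


@pytest.fixture(scope="session")
def packaged_coefficients():
    return pr.load_packaged_coefficients()


@pytest.fixture(scope="session")
def matched_cohort(dfts, sphere):
    """Small noiseless cohort on which the log-log models are exact."""
    spec = pr.model_matched(pr.CohortSpec(seed=11, n_patients=12))
    return pr.generate_cohort(spec, dfts, sphere)


@pytest.fixture(scope="session")
def noisy_cohort(dfts, sphere):
    """Default study conditions: 5% noise, populations with spread."""
    spec = pr.CohortSpec(seed=7, n_patients=24)
    return pr.generate_cohort(spec, dfts, sphere)


def make_study(measurements=None, blood=None, patient_id="P001", cycle=1,
               injected=7300.0, phantom="adult_male"):
    ms = tuple(pr.VOIMeasurement(*m) for m in (measurements or []))
    bs = tuple(pr.BloodSample(*b) for b in (blood or []))
    return pr.CycleStudy(patient_id=patient_id, cycle_index=cycle,
                         injected_activity_MBq=injected, phantom=phantom,
                         measurements=ms, blood_samples=bs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
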