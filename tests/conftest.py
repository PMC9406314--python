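import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adchist as A

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def scheme():
    return A.BinningScheme()


@pytest.fixture
def small_cohort():
    """Six patients, two per class, with well-separated voxel distributions
    (WT ~ 800 < MT ~ 1300 < PA ~ 2000)."""
    rng = np.random.default_rng(7)
    centers = {"WT": 800.0, "MT": 1300.0, "PA": 2000.0}
    samples = []
    for cls in A.CLASSES:
        for j in range(2):
            voxels = rng.normal(centers[cls], 60.0, size=200)
            samples.append(A.PatientSample(patient_id=f"{cls}{j}",
                                           true_class=cls,
                                           voxels=np.abs(voxels)))
    return A.Cohort(samples=tuple(samples))


@pytest.fixture(scope="session")
def default_cohort():
    """The default 73-patient synthetic cohort (30 PA / 22 WT / 21 MT)."""
    return A.generate_cohort(A.CohortGeneratorConfig(seed=42))
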