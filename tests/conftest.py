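import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hodvh.cohort import CohortConfig, calibrate
from hodvh.dvh import DVHCurve, DifferentialDVH

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def two_step_curve() -> DVHCurve:
    """Half the volume drops between 0 and 7 Gy, the rest by 8 Gy."""
    return DVHCurve("CTV", [0.0, 7.0, 8.0], [1.0, 0.5, 0.0])


@pytest.fixture
def box_curve() -> DVHCurve:
    """Near-uniform 7 Gy irradiation."""
    return DVHCurve("CTV", [0.0, 7.0, 7.01], [1.0, 1.0, 0.0])


def random_diff(rng: np.random.Generator, max_bins: int = 12, dose_lo: float = 1.0,
                dose_hi: float = 10.0) -> DifferentialDVH:
    """Random differential DVH with positive doses and normalized volumes."""
    k = int(rng.integers(1, max_bins + 1))
    doses = np.sort(rng.uniform(dose_lo, dose_hi, size=k))
    v = rng.uniform(0.05, 1.0, size=k)
    return DifferentialDVH(doses, v / v.sum())


def random_cumulative(rng: np.random.Generator, max_points: int = 15) -> DVHCurve:
    """Random valid cumulative curve starting at (0 Gy, 1.0)."""
    k = int(rng.integers(2, max_points + 1))
    doses = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 10.0, size=k - 1))])
    drops = rng.uniform(0.0, 1.0, size=k - 1)
    cum = np.concatenate([[1.0], 1.0 - np.cumsum(drops) / drops.sum() * rng.uniform(0.5, 1.0)])
    cum = np.clip(cum, 0.0, 1.0)
    return DVHCurve("rand", doses, cum)


@pytest.fixture(scope="session")
def calibration() -> tuple[CohortConfig, dict]:
    """Generator hyperparameters tuned to the reference cohort targets
    (run once per session; the audit carries the residuals)."""
    return calibrate(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def calibrated_config(calibration) -> CohortConfig:
    return calibration[0]
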