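import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cephrr.simulate import CantSpec, SimulationTruth, paperlike_scenario, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_truth(**kwargs) -> SimulationTruth:
    """A quiet, fully controlled truth: no pose, no cant, no outliers."""
    defaults = dict(
        sigma_r_default=0.0,
        sigma_L_default=0.0,
        subject_sd=0.0,
        pose_rot_deg=0.0,
        pose_trans_mm=0.0,
        cant=CantSpec("none"),
        seed=0,
    )
    defaults.update(kwargs)
    return SimulationTruth(**defaults)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """2 subjects x 3 operators x 2 sessions with zero noise: all six
    repetitions of every landmark coincide."""
    dataset, _ = simulate(make_truth(), n_subjects=2, n_operators=3, n_sessions=2)
    return dataset


@pytest.fixture(scope="session")
def quiet_dataset():
    """Small low-noise dataset with realistic pose/anatomy variation."""
    truth = make_truth(
        sigma_r_default=0.15, sigma_L_default=0.10, subject_sd=3.0,
        pose_rot_deg=10.0, pose_trans_mm=20.0, seed=7,
    )
    dataset, _ = simulate(truth, n_subjects=4, n_operators=3, n_sessions=2)
    return dataset


@pytest.fixture(scope="session")
def paperlike_sim():
    """The packaged study-like scenario at full design (20 x 3 x 2)."""
    truth = paperlike_scenario(seed=11)
    return simulate(truth, n_subjects=20, n_operators=3, n_sessions=2)


@pytest.fixture(scope="session")
def paperlike_results(paperlike_sim):
    from cephrr.model import LandmarkRRModel

    dataset, _ = paperlike_sim
    return LandmarkRRModel(dataset).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
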