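import dataclasses

import numpy as np
import pytest

from scpflow.formulas import MODEL_FORMULAS
from scpflow.models import BayesianMixedModel
from scpflow.simulate import simulate_features, simulate_srs
from scpflow.study import StudyDesign, default_ground_truth


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """Reduced factorial layout used where full study scale is unnecessary."""
    return StudyDesign(n_experimental=6, n_control=6, n_sessions=6,
                       phase_break_session=3, trials_per_session=24)


@pytest.fixture(scope="session")
def small_truth(small_design):
    return default_ground_truth(small_design, seed=0)


@pytest.fixture(scope="session")
def noise_free_truth(small_design):
    truth = default_ground_truth(small_design, seed=0)
    return dataclasses.replace(
        truth, residual_sd=0.0, varying_sd=np.zeros(6),
        srs_varying_sd=np.zeros(3), srs_residual_sd=np.zeros(5),
        pink_noise_sd=0.0, alpha_osc_amplitude=0.0, artifact_rate=0.0)


@pytest.fixture(scope="session")
def scp_frame(small_design, small_truth):
    return simulate_features(small_design, small_truth, seed=11)


@pytest.fixture(scope="session")
def srs_frame(small_design, small_truth):
    return simulate_srs(small_design, small_truth, seed=12)


@pytest.fixture(scope="session")
def srs_fit(srs_frame):
    """Quadratic SRS-total fit reused across inference tests."""
    frame = srs_frame.rename(columns={"Total": "Score"})
    return BayesianMixedModel(MODEL_FORMULAS["M2SRS"], draws=500, warmup=300,
                              seed=21).fit(frame)


@pytest.fixture(scope="session")
def scp_fit(scp_frame):
    """Quadratic SCP fit at reduced scale reused across inference tests."""
    return BayesianMixedModel(MODEL_FORMULAS["M2SCP"], draws=500, warmup=300,
                              seed=22).fit(scp_frame)


class PointPredictor:
    """Deterministic stand-in for a fitted model: closed-form predictions.

    ``surface(row) -> value`` defines the population expectation; every
    posterior draw is identical, so derived posteriors are point masses
    and closed-form identities can be asserted exactly.
    """

    def __init__(self, surface, n_draws: int = 4,
                 groups=("control", "experimental")):
        self.surface = surface
        self.n_draws = n_draws
        self._groups_cache = set(groups)

    def predict_draws(self, newdata):
        vals = np.array([self.surface(row) for _, row in newdata.iterrows()],
                        dtype=float)
        return np.tile(vals, (self.n_draws, 1))


@pytest.fixture
def point_predictor():
    return PointPredictor
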