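import numpy as np
import pytest

from afferent_csd.locomotion import segment_locomotion
from afferent_csd.signals import standardize_session_traces
from afferent_csd.synth import SimConfig, generate_session


class AnalyzedSession:
    """A generated session with the locomotion/signal stages precomputed."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.session, self.truth = generate_session(cfg)
        fs = self.session.frame_rate_hz
        self.locomotion = segment_locomotion(
            self.session.wheel_position, self.session.wheel_rate_hz,
            fs, self.session.n_frames, seed=0,
        )
        self.traces = standardize_session_traces(
            self.session.roi_traces, self.session.neuropil_traces,
            self.locomotion.stillness_mask, fs,
        )

    def fiber_z(self, fiber: int) -> np.ndarray:
        m = np.flatnonzero(self.truth.fiber_of_roi == fiber)
        return np.mean([self.traces[i].z for i in m], axis=0)

    def fiber_dff(self, fiber: int) -> np.ndarray:
        m = np.flatnonzero(self.truth.fiber_of_roi == fiber)
        return np.mean([self.traces[i].dff for i in m], axis=0)


@pytest.fixture(scope="session")
def csd_session():
    """Mid-sized session with a CSD wave and all post-CSD effects."""
    return AnalyzedSession(SimConfig(seed=1234, pre_min=25, post_min=70,
                                     n_fibers=8))


@pytest.fixture(scope="session")
def baseline_session():
    """CSD-free session used for clustering and encoding-model tests."""
    return AnalyzedSession(SimConfig(
        seed=4321, pre_min=30, post_min=5, csd=False, n_fibers=12,
        frac_sensitized=0.0, frac_coupled_stable=0.5, frac_unmasked=0.0,
        frac_lost=0.0,
    ))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240301)
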