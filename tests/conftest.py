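import numpy as np
import pytest

from hvgh.gp import GPClassModel, KernelParams
from hvgh.hdp import StickWeights, TransitionCounts


@pytest.fixture
def kp():
    """Kernel coefficients used throughout the motion experiments."""
    return KernelParams(theta0=1.0, theta1=1.0, theta2=0.0, theta3=16.0, omega=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gp_model(segments, kp, latent_dim=1, **kwargs):
    """GPClassModel pre-loaded with the given (T, d) segments, uncapped."""
    m = GPClassModel(0, latent_dim, kp, max_points=None, **kwargs)
    for seg in segments:
        m.add_segment(np.atleast_2d(np.asarray(seg, dtype=float)))
    return m


def make_counts(n_class=None, n_trans=None):
    return TransitionCounts(n_class=dict(n_class or {}), n_trans=dict(n_trans or {}))


@pytest.fixture
def tiny_instance(kp):
    """A fixed 2-class instance small enough for exhaustive enumeration:
    T=5 latent frames (1-dim), fixed class training data, fixed
    linear-domain transition/start probabilities."""
    rng = np.random.default_rng(7)
    latent = rng.normal(0.0, 1.0, (5, 1))
    class_data = {
        0: ([1, 2, 3], rng.normal(0.0, 1.0, (3, 1))),
        1: ([1, 2], rng.normal(0.0, 1.0, (2, 1))),
    }
    trans = np.array([[0.7, 0.3], [0.4, 0.6]])
    start = np.array([0.5, 0.5])
    return latent, class_data, trans, start
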