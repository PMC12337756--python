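import warnings

import numpy as np
import pytest
from hypothesis import settings

from flutterpath.trajectory import Sex, Species, StopEvent, Trajectory

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_traj(t, x, y, **kw):
    """Trajectory builder that silences the unknown-sex advisory."""
    kw.setdefault("individual_id", "tst")
    kw.setdefault("species", Species.CP)
    kw.setdefault("sex", Sex.FEMALE)
    kw.setdefault("site_id", "S01")
    return Trajectory(t=np.asarray(t), x=np.asarray(x, float), y=np.asarray(y, float), **kw)


@pytest.fixture
def straight_track():
    """60 fixes due east at 1 m/s, 1-s sampling."""
    t = np.arange(60)
    return make_traj(t, t.astype(float), np.zeros(60))


@pytest.fixture
def track_with_stop():
    """Flight, a jittered interior stop at (20, 0) over [20, 30], flight."""
    rng = np.random.default_rng(5)
    t = np.arange(51)
    x = np.where(t <= 20, t.astype(float), np.where(t <= 30, 20.0, t - 10.0))
    y = np.zeros(51)
    jitter = rng.normal(0, 0.2, size=(51, 2))
    stop = (t >= 20) & (t <= 30)
    x = x + np.where(stop, jitter[:, 0], 0.0)
    y = y + np.where(stop, jitter[:, 1], 0.0)
    events = [StopEvent(20, 30, activity="nectaring")]
    return make_traj(t, x, y), events


@pytest.fixture(autouse=True)
def _no_warning_noise():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
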