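import numpy as np
import pytest

from cardiopore.synth_cardiomyocyte import APParams, CultureModel
from cardiopore.synth_interface import ElectrodeState, PorationEvent


@pytest.fixture
def default_params():
    return APParams(amplitude_mv=100.0, t_dep_ms=10.0, apd90_ms=300.0, rep_width_ms=20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_state():
    return ElectrodeState(electrode_id=0, noise_sd_uv=0.0)


@pytest.fixture
def quiet_culture(default_params):
    return CultureModel(ap=default_params, cell_sd=0.0, cv=0.0, seed=7)


def make_event(eid=0, t_end=1.0, g0=0.2, offset_mv=0.0):
    return PorationEvent(
        electrode_id=eid, t_end_s=t_end, success=True, g0_realized=g0, offset_mv=offset_mv
    )


def gaussian_snippet(amp_uv, fwhm_ms, fs_hz=20000.0, pre_ms=25.0, post_ms=600.0, center_ms=None):
    """Bump with an exact analytic full width at half maximum."""
    n = int(round((pre_ms + post_ms) * fs_hz / 1000.0))
    t = np.arange(n) * 1000.0 / fs_hz
    c = pre_ms if center_ms is None else center_ms
    sigma = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amp_uv * np.exp(-0.5 * ((t - c) / sigma) ** 2)
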