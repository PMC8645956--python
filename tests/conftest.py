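import numpy as np
import pytest

from vilipower import (
    LungModelParams,
    VentSettings,
    WaveformRecording,
    simulate_ventilation,
)


@pytest.fixture(scope="session")
def linear_lung():
    """Noiseless linear one-compartment lung, Table-1-like parameters."""
    return LungModelParams(E1=57.3, E2=0.0, R=12.4, PEEP=5.0, noise_sigma=0.0)


@pytest.fixture(scope="session")
def vcv_settings():
    """VT 0.3 L at a grid-exact inspiratory flow (0.5 s flow time, 100 Hz)."""
    return VentSettings(vt_ml_kg=6.0, body_mass_kg=50.0, rr=20.0,
                        insp_flow_lpm=36.0, ie_ratio=1.0, sample_rate=100.0)


@pytest.fixture(scope="session")
def clean_recording(vcv_settings, linear_lung):
    """10 noiseless VCV breaths from the linear lung."""
    return simulate_ventilation(vcv_settings, linear_lung, n_breaths=10)


@pytest.fixture()
def square_breath_recording():
    """Hand-built square-flow breath: 0.5 L/s for 0.6 s, then zero flow.

    Constant paw of 5 cmH2O throughout (pressures decoupled from flow), so
    pressure summaries are trivial while volumes are exact rectangles.
    """
    fs = 100.0
    n = 300
    flow = np.zeros(n)
    flow[10:70] = 0.5  # 0.6 s inspiration
    flow[70] = 0.25    # half-sample so the trapezoid hits 0.300 L
    flow[110:150] = -0.3
    paw = np.full(n, 5.0)
    return WaveformRecording(time=np.arange(n) / fs, paw=paw, flow=flow,
                             sample_rate=fs)
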