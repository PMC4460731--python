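import numpy as np
import pytest

from coilassay import coil_model as cm
from coilassay import drive_circuit as dc


@pytest.fixture(scope="session")
def ref_spec():
    return cm.reference_coil()


@pytest.fixture(scope="session")
def ref_stack(ref_spec):
    return cm.build_loop_stack(ref_spec)


@pytest.fixture(scope="session")
def ref_inductance(ref_spec, ref_stack):
    """Uncalibrated geometric inductance of the reference winding
    (computed once; the pairwise mutual sum is the slow part)."""
    return cm.estimate_inductance(ref_stack, ref_spec.wire_diameter_bare / 2.0)


@pytest.fixture(scope="session")
def ref_sawtooth_trace():
    """Reference drive through the series-RL model of the reference coil."""
    w = dc.Waveform(kind="sawtooth", peak_to_peak=20.0, period=1e-5,
                    fall_time=50e-9)
    c = dc.CircuitModel(source_impedance=50.0, coil_resistance=50.45,
                        coil_inductance=14.25e-3)
    t, v = dc.sample_waveform(w, 8192)
    return dc.steady_state_current(c, t, v)


@pytest.fixture(scope="session")
def sine_trace():
    w = dc.Waveform(kind="sine", peak_to_peak=2.0, period=1e-5)
    c = dc.CircuitModel(source_impedance=50.0, coil_resistance=50.45,
                        coil_inductance=14.25e-3)
    t, v = dc.sample_waveform(w, 4096)
    return dc.steady_state_current(c, t, v)


def segment_A_unit(a, rho, z, n_seg=100_000):
    """Brute-force Biot–Savart line integral for the loop vector potential:
    discretise the loop into straight segments and sum μ0/(4π)·dl·cosφ/r
    at the field point (rho, 0, z)."""
    phi = (np.arange(n_seg) + 0.5) * (2 * np.pi / n_seg)
    dl = a * (2 * np.pi / n_seg)
    r = np.sqrt(a**2 + rho**2 + z**2 - 2 * a * rho * np.cos(phi))
    mu0 = 4e-7 * np.pi
    return mu0 / (4 * np.pi) * np.sum(dl * np.cos(phi) / r)
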