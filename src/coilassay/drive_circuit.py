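"""Function-generator drive and periodic steady-state coil current.

The drive is a periodic voltage source (sawtooth by default: a slow linear
ramp followed by a sharp drop lasting ``fall_time``) behind a resistive
output impedance, feeding the coil's series R–L branch, with an optional
parasitic self-capacitance ``C_p`` in parallel with that branch.  The
periodic steady state is solved exactly in the frequency domain: each
Fourier harmonic of the source voltage is divided by the drive-point
transfer to the inductor branch, and ``di/dt`` is obtained by spectral
differentiation, so the returned trace is periodic and zero-net-change to
machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "CircuitModel",
    "CurrentTrace",
    "sample_waveform",
    "steady_state_current",
    "didt_extrema",
]


@dataclass(frozen=True)
class Waveform:
    """Periodic drive waveform.

    ``kind='sawtooth'`` rises linearly from ``offset − Vpp/2`` to
    ``offset + Vpp/2`` over ``period − fall_time`` and falls back linearly
    over ``fall_time``.  ``kind='sampled'`` interpolates user samples
    ``(t, V)`` over one period.
    """

    kind: str
    peak_to_peak: float = 0.0
    dc_offset: float = 0.0
    period: float = 1.0
    fall_time: float = 0.0
    samples: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("sawtooth", "triangle", "sine", "sampled"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.peak_to_peak < 0:
            raise ValueError("peak_to_peak must be >= 0")
        if self.kind == "sawtooth" and not (0 < self.fall_time < self.period):
            raise ValueError("sawtooth requires 0 < fall_time < period")
        if self.kind == "sampled" and self.samples is None:
            raise ValueError("sampled waveform requires samples")


def sample_waveform(w: Waveform, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample one period of ``w`` on a uniform grid of ``n_samples`` points
    (endpoint excluded; the waveform is periodic).

    For a sawtooth the grid must place at least 4 samples inside the fall.
    """
    if n_samples < 8:
        raise ValueError("n_samples too small")
    T = w.period
    t = np.arange(n_samples) * (T / n_samples)
    if w.kind == "sawtooth":
        if n_samples * w.fall_time / T < 4:
            raise ValueError(
                "n_samples too small to resolve the sawtooth fall "
                f"(need >= {int(np.ceil(4 * T / w.fall_time))})"
            )
        rise = T - w.fall_time
        lo = w.dc_offset - w.peak_to_peak / 2.0
        hi = w.dc_offset + w.peak_to_peak / 2.0
        v = np.where(
            t < rise,
            lo + (hi - lo) * t / rise,
            hi - (hi - lo) * (t - rise) / w.fall_time,
        )
    elif w.kind == "triangle":
        half = T / 2.0
        lo = w.dc_offset - w.peak_to_peak / 2.0
        hi = w.dc_offset + w.peak_to_peak / 2.0
        v = np.where(
            t < half,
            lo + (hi - lo) * t / half,
            hi - (hi - lo) * (t - half) / half,
        )
    elif w.kind == "sine":
        v = w.dc_offset + (w.peak_to_peak / 2.0) * np.sin(2.0 * np.pi * t / T)
    else:  # sampled
        ts, vs = w.samples
        ts = np.asarray(ts, dtype=float)
        vs = np.asarray(vs, dtype=float)
        # periodic interpolation: wrap the first sample around
        v = np.interp(t, np.r_[ts, ts[0] + T], np.r_[vs, vs[0]])
    return t, v


@dataclass(frozen=True)
class CircuitModel:
    """Source output impedance in series with the coil's R–L branch; an
    optional parasitic capacitance ``C_p`` sits in parallel with R–L."""

    source_impedance: float = 50.0
    coil_resistance: float = 0.0
    coil_inductance: float = 1.0
    coil_capacitance: float = 0.0

    def __post_init__(self) -> None:
        if min(self.source_impedance, self.coil_resistance, self.coil_capacitance) < 0:
            raise ValueError("impedances must be >= 0")
        if self.coil_inductance <= 0:
            raise ValueError("coil_inductance must be positive")


@dataclass(frozen=True)
class CurrentTrace:
    """Periodic steady-state inductor-branch current over one period."""

    t: np.ndarray
    v_source: np.ndarray
    i: np.ndarray
    di_dt: np.ndarray
    period: float

    def __post_init__(self) -> None:
        n = self.t.size
        if not (self.v_source.size == self.i.size == self.di_dt.size == n):
            raise ValueError("trace arrays must share one grid")
        scale = np.max(np.abs(self.i))
        if scale > 0:
            # periodicity: frequency-domain construction guarantees it
            dscale = np.max(np.abs(self.di_dt))
            if dscale > 0 and abs(np.mean(self.di_dt)) > 1e-9 * dscale:
                raise ValueError("di/dt does not average to zero over the period")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "V_source": self.v_source, "i_A": self.i,
             "di_dt_A_per_s": self.di_dt}
        )


def steady_state_current(
    c: CircuitModel, t: np.ndarray, v: np.ndarray
) -> CurrentTrace:
    """Periodic steady-state inductor-branch current for source samples
    ``v`` on the uniform grid ``t`` (one period, endpoint excluded).

    Harmonic k of the source sees load ``Z_RL ∥ 1/(jωC_p)`` behind the
    source impedance; the inductor-branch current is the load voltage over
    ``Z_RL``.  All grid-representable harmonics are retained; the Nyquist
    bin's derivative is dropped (its phase is undefined on the grid).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    n = t.size
    if n < 2 or v.size != n:
        raise ValueError("need matching t and v arrays with >= 2 samples")
    period = n * (t[1] - t[0])
    vh = np.fft.rfft(v)
    omega = 2.0 * np.pi * np.arange(vh.size) / period
    z_rl = c.coil_resistance + 1j * omega * c.coil_inductance
    if c.coil_capacitance > 0:
        z_load = z_rl / (1.0 + 1j * omega * c.coil_capacitance * z_rl)
    else:
        z_load = z_rl
    with np.errstate(invalid="ignore", divide="ignore"):
        v_load = vh * z_load / (c.source_impedance + z_load)
        ih = v_load / z_rl
    # DC bin: capacitor open, inductor short -> i0 = V0 / (Zs + R).  A pure
    # zero-resistance loop has no DC steady state; the conventional
    # zero-mean current is returned (the DC drive component is dropped).
    r_total = c.source_impedance + c.coil_resistance
    ih[0] = vh[0] / r_total if r_total > 0 else 0.0
    dih = ih * (1j * omega)
    if n % 2 == 0:
        dih[-1] = 0.0
    i = np.fft.irfft(ih, n)
    di_dt = np.fft.irfft(dih, n)
    return CurrentTrace(t=t, v_source=v, i=i, di_dt=di_dt, period=period)


def didt_extrema(trace: CurrentTrace) -> tuple[float, float, float]:
    """(max positive di/dt, max negative di/dt, fraction of the period with
    di/dt > 0), evaluated on the trace's uniform grid.  The negative
    extremum is returned signed (≤ 0)."""
    d = trace.di_dt
    pos = float(max(d.max(), 0.0))
    neg = float(min(d.min(), 0.0))
    frac = float(np.mean(d > 0))
    return pos, neg, frac
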