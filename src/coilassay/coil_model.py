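"""Multilayer coil geometry expanded into a stack of circular filament loops.

The coil that drives the non-contact electrotaxis assay is a multilayer
solenoid wound on a thin rod.  For field and inductance work it is idealised
as ``n_layers × turns_per_layer`` coaxial circular loops sharing one current.
Layer radii are spaced uniformly between the inner and outer winding radii
(the printed envelope), because stacking 35 layers at one insulated-wire
diameter each would overflow the printed outer diameter; the envelope is the
only self-consistent constraint.  Within each layer, turn centres are spaced
uniformly along the coil length.

Printed winding counts and measured electricals are not mutually consistent
for the reference coil, so an ``effective_turn_scale`` is carried on the
stack: it multiplies the per-loop current weight (equivalently the effective
turn count), so estimated resistance scales linearly and estimated
inductance quadratically with it.  :func:`calibrate_effective_turns` sets it
to reconcile the geometric estimate with a measured R or L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import ellipe, ellipk

from .constants import COPPER_RESISTIVITY, MU0

__all__ = [
    "CoilSpec",
    "WindingStack",
    "reference_coil",
    "build_loop_stack",
    "estimate_resistance",
    "loop_self_inductance",
    "mutual_inductance",
    "estimate_inductance",
    "calibrate_effective_turns",
]


@dataclass(frozen=True)
class CoilSpec:
    """Physical description of a wound multilayer coil (SI units).

    ``measured_resistance`` / ``measured_inductance`` are optional LCR-meter
    values used only for calibration.
    """

    inner_diameter: float
    outer_diameter: float
    coil_length: float
    n_layers: int
    turns_per_layer: int
    wire_diameter_bare: float
    wire_diameter_insulated: float
    measured_resistance: float | None = None
    measured_inductance: float | None = None

    def __post_init__(self) -> None:
        if not (self.wire_diameter_insulated >= self.wire_diameter_bare > 0):
            raise ValueError("need wire_diameter_insulated >= wire_diameter_bare > 0")
        if not (self.outer_diameter > self.inner_diameter > 0):
            raise ValueError("need outer_diameter > inner_diameter > 0")
        if self.coil_length <= 0:
            raise ValueError("coil_length must be positive")
        if self.n_layers < 1 or self.turns_per_layer < 1:
            raise ValueError("need n_layers >= 1 and turns_per_layer >= 1")

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        return self.outer_diameter / 2.0

    @property
    def n_turns(self) -> int:
        return self.n_layers * self.turns_per_layer


def reference_coil() -> CoilSpec:
    """The coil used in the transmembrane electrotaxis experiments this
    package models: 35 layers × 159 turns of AWG32 wire (0.202 mm bare /
    0.268 mm insulated), 3 mm ID, 1.4 cm OD, 10.5 cm long; measured
    50.45 Ω and 14.25 mH at 1 kHz."""
    return CoilSpec(
        inner_diameter=3.0e-3,
        outer_diameter=1.4e-2,
        coil_length=0.105,
        n_layers=35,
        turns_per_layer=159,
        wire_diameter_bare=0.202e-3,
        wire_diameter_insulated=0.268e-3,
        measured_resistance=50.45,
        measured_inductance=14.25e-3,
    )


@dataclass(frozen=True)
class WindingStack:
    """Coaxial circular filament loops sharing one current.

    ``radii[k]`` and ``z[k]`` give loop k's radius and axial centre
    (z measured from the coil midplane).  ``effective_turn_scale`` weights
    the per-loop current; ``filament_clearance`` is the minimum approach
    distance to any filament below which field evaluation is rejected
    (one bare-wire radius for built stacks).
    """

    radii: np.ndarray
    z: np.ndarray
    effective_turn_scale: float = 1.0
    filament_clearance: float = 0.0

    def __post_init__(self) -> None:
        radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if radii.shape != z.shape:
            raise ValueError("radii and z must have the same length")
        if radii.size and np.any(radii <= 0):
            raise ValueError("loop radii must be positive")
        if self.effective_turn_scale < 0:
            raise ValueError("effective_turn_scale must be >= 0")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "z", z)

    @property
    def n_loops(self) -> int:
        return int(self.radii.size)

    @property
    def loops(self) -> list[tuple[float, float]]:
        return list(zip(self.radii.tolist(), self.z.tolist()))

    def to_frame(self) -> pd.DataFrame:
        """Loop table (a_k, z_k, weight) for CSV export."""
        return pd.DataFrame(
            {
                "a_m": self.radii,
                "z_m": self.z,
                "weight": np.full(self.n_loops, self.effective_turn_scale),
            }
        )


def build_loop_stack(spec: CoilSpec) -> WindingStack:
    """Expand a :class:`CoilSpec` into its filament-loop stack.

    Layer radii: uniformly spaced between ``inner_radius + wire_ins/2`` and
    ``outer_radius − wire_ins/2`` (single layer: midway between inner and
    outer radius).  Turn centres within a layer: uniform bins across the
    coil length, symmetric about the midplane.
    """
    r_lo = spec.inner_radius + spec.wire_diameter_insulated / 2.0
    r_hi = spec.outer_radius - spec.wire_diameter_insulated / 2.0
    if spec.n_layers == 1:
        layer_radii = np.array([(spec.inner_radius + spec.outer_radius) / 2.0])
    else:
        layer_radii = np.linspace(r_lo, r_hi, spec.n_layers)
    n = spec.turns_per_layer
    pitch = spec.coil_length / n
    turn_z = -spec.coil_length / 2.0 + (np.arange(n) + 0.5) * pitch
    radii = np.repeat(layer_radii, n)
    z = np.tile(turn_z, spec.n_layers)
    return WindingStack(
        radii=radii,
        z=z,
        effective_turn_scale=1.0,
        filament_clearance=spec.wire_diameter_bare / 2.0,
    )


def estimate_resistance(
    stack: WindingStack,
    wire_diameter_bare: float,
    resistivity: float = COPPER_RESISTIVITY,
) -> float:
    """DC resistance of the stack: ρ × (total wire length) / (bare cross
    section), scaled linearly by ``effective_turn_scale``."""
    if wire_diameter_bare <= 0:
        raise ValueError("wire_diameter_bare must be positive")
    if stack.n_loops == 0:
        return 0.0
    area = np.pi * (wire_diameter_bare / 2.0) ** 2
    length = float(np.sum(2.0 * np.pi * stack.radii))
    return stack.effective_turn_scale * resistivity * length / area


def loop_self_inductance(a, wire_radius):
    """Self-inductance of a circular loop of round wire,
    ``μ0·a·(ln(8a/r_w) − 2)`` (thin-wire, surface-current form)."""
    a = np.asarray(a, dtype=float)
    if np.any(wire_radius <= 0):
        raise ValueError("wire_radius must be positive")
    return MU0 * a * (np.log(8.0 * a / wire_radius) - 2.0)


def mutual_inductance(a, b, d):
    """Mutual inductance of two coaxial circular loops (radii ``a``, ``b``,
    axial separation ``d``), Maxwell's elliptic-integral formula.

    Uses the elliptic-integral *parameter* ``m = k² = 4ab/((a+b)² + d²)``
    (scipy's convention); a small-``m`` series avoids cancellation for
    well-separated loops.  Symmetric in ``a`` and ``b``.
    """
    scalar = np.isscalar(a) and np.isscalar(b) and np.isscalar(d)
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    m = 4.0 * a * b / ((a + b) ** 2 + d**2)
    a, b, m = np.broadcast_arrays(a, b, m)
    out = np.empty(m.shape, dtype=float)
    if np.any(m >= 1.0):
        raise ValueError("coincident filaments: mutual inductance is singular")
    small = m < 1e-4
    large = ~small
    if np.any(large):
        ml = m[large]
        k = np.sqrt(ml)
        out[large] = (
            MU0
            * np.sqrt(a[large] * b[large])
            * ((2.0 / k - k) * ellipk(ml) - (2.0 / k) * ellipe(ml))
        )
    if np.any(small):
        ms = m[small]
        out[small] = (
            MU0 * np.sqrt(a[small] * b[small]) * np.pi * ms**1.5 * (1.0 + 0.75 * ms) / 16.0
        )
    return float(out[0]) if scalar else out


def estimate_inductance(
    stack: WindingStack, wire_radius: float, chunk: int = 512
) -> float:
    """Total inductance: per-loop self terms plus all pairwise mutual terms,
    scaled by ``effective_turn_scale²`` (the scale acts on effective turns).

    Coincident loops (identical radius and position) contribute the self
    term in place of the singular mutual term.
    """
    n = stack.n_loops
    if n == 0:
        return 0.0
    a = stack.radii
    z = stack.z
    self_terms = loop_self_inductance(a, wire_radius)
    total = float(np.sum(self_terms))
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        ai = a[i0:i1, None]
        zi = z[i0:i1, None]
        # upper-triangle mask: pair (i, j) with j > i, counted twice below
        cols = np.arange(n)[None, :]
        rows = np.arange(i0, i1)[:, None]
        upper = cols > rows
        d = np.abs(zi - z[None, :])
        coincident = upper & (d == 0.0) & (ai == a[None, :])
        pair = upper & ~coincident
        if np.any(pair):
            aj = np.broadcast_to(a[None, :], pair.shape)[pair]
            ap = np.broadcast_to(ai, pair.shape)[pair]
            dp = d[pair]
            total += 2.0 * float(np.sum(mutual_inductance(ap, aj, dp)))
        if np.any(coincident):
            ap = np.broadcast_to(ai, coincident.shape)[coincident]
            total += 2.0 * float(np.sum(loop_self_inductance(ap, wire_radius)))
    return stack.effective_turn_scale**2 * total


CalibrationMode = Literal["none", "match_R", "match_L"]


def calibrate_effective_turns(
    spec: CoilSpec,
    mode: CalibrationMode = "none",
    resistivity: float = COPPER_RESISTIVITY,
) -> WindingStack:
    """Build the loop stack and set ``effective_turn_scale`` so the chosen
    estimator reproduces the measured value (geometry untouched).

    ``match_R`` scales linearly against the measured DC resistance;
    ``match_L`` scales as a square root against the measured inductance.
    """
    stack = build_loop_stack(spec)
    if mode == "none":
        return stack
    if mode == "match_R":
        if spec.measured_resistance is None:
            raise ValueError("match_R requires measured_resistance")
        r0 = estimate_resistance(stack, spec.wire_diameter_bare, resistivity)
        return replace(stack, effective_turn_scale=spec.measured_resistance / r0)
    if mode == "match_L":
        if spec.measured_inductance is None:
            raise ValueError("match_L requires measured_inductance")
        l0 = estimate_inductance(stack, spec.wire_diameter_bare / 2.0)
        return replace(stack, effective_turn_scale=float(np.sqrt(spec.measured_inductance / l0)))
    raise ValueError(f"unknown calibration mode: {mode!r}")
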