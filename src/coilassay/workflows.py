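"""End-to-end field reconstructions wiring the coil, circuit, and assay
geometry together with the reference-apparatus defaults."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from . import assay_geometry as ag
from . import coil_model as cm
from . import drive_circuit as dc
from . import field_solver as fs

__all__ = ["TranswellExposure", "reference_drive", "transwell_exposure"]


@lru_cache(maxsize=4)
def _calibrated_reference_stack(mode: str) -> cm.WindingStack:
    return cm.calibrate_effective_turns(cm.reference_coil(), mode)


def reference_drive() -> dc.Waveform:
    """The reference drive: 20 Vpp zero-offset sawtooth at 100 kHz with a
    50 ns fall."""
    return dc.Waveform(
        kind="sawtooth", peak_to_peak=20.0, dc_offset=0.0, period=1e-5,
        fall_time=50e-9,
    )


@dataclass(frozen=True)
class TranswellExposure:
    """Everything a Transwell field reconstruction produces."""

    stack: cm.WindingStack
    trace: dc.CurrentTrace
    plan: ag.SamplePlan
    fmap: fs.FieldMap
    metrics: ag.ExposureMetrics


def transwell_exposure(
    side: str = "north",
    calibration: str = "match_L",
    coil_capacitance: float = 0.0,
    n_radial: int = 5,
    n_samples: int = 8192,
    waveform: dc.Waveform | None = None,
    transwell: ag.TranswellConfig | None = None,
) -> TranswellExposure:
    """Reconstruct the membrane exposure of the reference apparatus.

    Defaults: the reference coil calibrated against its measured
    inductance, a series-RL circuit using the measured R and L behind a
    50 Ω source (optional parallel ``coil_capacitance``), the reference
    sawtooth drive, and the default three-well membrane placement.
    """
    spec = cm.reference_coil()
    stack = (
        cm.build_loop_stack(spec)
        if calibration == "none"
        else _calibrated_reference_stack(calibration)
    )
    circuit = dc.CircuitModel(
        source_impedance=50.0,
        coil_resistance=spec.measured_resistance,
        coil_inductance=spec.measured_inductance,
        coil_capacitance=coil_capacitance,
    )
    w = waveform or reference_drive()
    t, v = dc.sample_waveform(w, n_samples)
    trace = dc.steady_state_current(circuit, t, v)
    cfg = transwell or ag.default_transwell_config(spec.outer_radius, side=side)
    plan = ag.transwell_sample_points(cfg, n_radial, spec.outer_radius)
    fmap = fs.induced_E(stack, plan.points, trace)
    metrics = ag.exposure_metrics(fmap, plan)
    return TranswellExposure(stack=stack, trace=trace, plan=plan, fmap=fmap,
                             metrics=metrics)
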