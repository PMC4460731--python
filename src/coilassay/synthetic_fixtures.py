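"""Synthetic inputs with known ground truth.

Everything downstream of the field solver consumes lab data (count tables,
fluorescence images, digitised waveforms) that no public archive provides
for this kind of experiment, so these generators emulate them:

* per-field migration counts — independent Poisson draws with a
  multiplicative condition effect on the control rate (5 fields per well,
  wells grouped into experiments);
* fluorescence images — elliptical cells filled with line-segment
  "filaments" whose axial orientations follow a doubled-angle von Mises law
  of known mean and concentration κ, plus Gaussian background noise;
* sampled drive waveforms — analytic waveforms with optional amplitude
  jitter, exercising the sampled-waveform path of the circuit solver.

All generators are pure functions of (model, seed); no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line_aa

from .drive_circuit import Waveform, sample_waveform
from .migration_stats import MigrationRecord

__all__ = [
    "CountModel",
    "FiberImageModel",
    "gen_migration_counts",
    "gen_fiber_image",
    "gen_sampled_waveform",
]


@dataclass(frozen=True)
class CountModel:
    """Poisson count model for per-field migration counts."""

    control_rate: float
    condition_effects: dict[str, float]
    n_wells: int = 9
    n_fields: int = 5
    wells_per_experiment: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_rate <= 0:
            raise ValueError("control_rate must be positive")
        if any(f <= 0 for f in self.condition_effects.values()):
            raise ValueError("condition effects must be positive")
        if self.n_wells < 1 or self.n_fields < 1 or self.wells_per_experiment < 1:
            raise ValueError("counts must be >= 1")


def gen_migration_counts(model: CountModel) -> list[MigrationRecord]:
    """Draw per-field counts for every condition in the model.

    Field counts are iid Poisson with rate ``control_rate × effect``; wells
    are labelled W1.. within experiments E1.. of ``wells_per_experiment``
    wells each.  Identical seeds give identical tables."""
    rng = np.random.default_rng(model.seed)
    records: list[MigrationRecord] = []
    for cond in model.condition_effects:  # insertion order: deterministic
        rate = model.control_rate * model.condition_effects[cond]
        counts = rng.poisson(rate, size=(model.n_wells, model.n_fields))
        for w in range(model.n_wells):
            exp = w // model.wells_per_experiment + 1
            well = w % model.wells_per_experiment + 1
            records.append(
                MigrationRecord(
                    condition=cond,
                    experiment_id=f"E{exp}",
                    well_id=f"W{well}",
                    field_counts=tuple(int(x) for x in counts[w]),
                )
            )
    return records


@dataclass(frozen=True)
class FiberImageModel:
    """Synthetic fluorescence image of fibrous cells.

    ``kappa`` is the doubled-angle von Mises concentration of filament
    orientations around ``mean_orientation`` (radians, from the column axis
    toward the row axis); κ = 0 is isotropic."""

    shape: tuple[int, int] = (448, 448)
    n_cells: int = 3
    cell_axes: tuple[float, float] = (60.0, 42.0)
    fibers_per_cell: int = 600
    fiber_length: float = 12.0
    kappa: float = 0.0
    mean_orientation: float = 0.0
    background_noise: float = 0.02
    fiber_intensity: float = 0.3
    body_intensity: float = 0.6
    saturation: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if max(self.cell_axes) * 2 >= min(self.shape):
            raise ValueError("cells do not fit within the image")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


def _axial_vonmises(rng: np.random.Generator, mu: float, kappa: float, size: int):
    """Axial orientations in [0, π): half of a von Mises draw on the
    doubled angle (uniform when κ = 0)."""
    if kappa < 1e-12:
        return rng.uniform(0.0, np.pi, size)
    doubled = rng.vonmises(2.0 * mu, kappa, size)
    return np.mod(doubled / 2.0, np.pi)


def gen_fiber_image(
    model: FiberImageModel, max_tries: int = 2000
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the image and return it with a per-cell ground-truth table
    (centroid, circular-mean orientation of the drawn fibers, κ).

    Cells are placed by rejection sampling with a no-overlap margin;
    overfull packings fail after ``max_tries`` attempts."""
    rng = np.random.default_rng(model.seed)
    h, w = model.shape
    a, b = model.cell_axes
    margin = a + 2
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < model.n_cells:
        if tries >= max_tries:
            raise ValueError("could not place all cells: packing too dense")
        tries += 1
        r0 = rng.uniform(margin, h - margin)
        c0 = rng.uniform(margin, w - margin)
        if all(np.hypot(r0 - r, c0 - c) > 2 * margin for r, c in centers):
            centers.append((r0, c0))
    img = np.zeros((h, w), dtype=float)
    truth_rows = []
    for idx, (r0, c0) in enumerate(centers):
        body_angle = rng.uniform(0.0, np.pi)
        rr, cc = draw_ellipse(r0, c0, a, b, shape=(h, w), rotation=body_angle)
        img[rr, cc] += model.body_intensity
        mask = np.zeros((h, w), dtype=bool)
        mask[rr, cc] = True
        phis = _axial_vonmises(rng, model.mean_orientation, model.kappa,
                               model.fibers_per_cell)
        for phi in phis:
            # short segment centred on a random interior point along
            # (cosφ, sinφ); short fibers keep boundary clipping rare so the
            # cell-body aspect ratio does not bias the orientation content
            j = rng.integers(0, rr.size)
            pr, pc = float(rr[j]), float(cc[j])
            dr, dc = np.sin(phi), np.cos(phi)
            half = model.fiber_length / 2.0
            r1, c1 = pr - half * dr, pc - half * dc
            r2, c2 = pr + half * dr, pc + half * dc
            lr, lc, val = line_aa(
                int(round(np.clip(r1, 0, h - 1))), int(round(np.clip(c1, 0, w - 1))),
                int(round(np.clip(r2, 0, h - 1))), int(round(np.clip(c2, 0, w - 1))),
            )
            keep = mask[lr, lc]
            img[lr[keep], lc[keep]] += model.fiber_intensity * val[keep]
        two = np.exp(2j * phis)
        mean_phi = float(np.mod(0.5 * np.angle(two.sum()), np.pi)) if phis.size else np.nan
        truth_rows.append(
            {"cell": idx, "row": r0, "col": c0, "orientation": mean_phi,
             "kappa": model.kappa, "n_fibers": int(phis.size)}
        )
    if model.background_noise > 0:
        img += rng.normal(0.0, model.background_noise, size=img.shape)
    # detector saturation: filament crossings clip like a real camera
    np.clip(img, 0.0, model.saturation, out=img)
    truth = pd.DataFrame(
        truth_rows, columns=["cell", "row", "col", "orientation", "kappa", "n_fibers"]
    )
    return img, truth


def gen_sampled_waveform(
    kind: str,
    peak_to_peak: float,
    period: float,
    n_samples: int,
    dc_offset: float = 0.0,
    fall_time: float = 0.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> Waveform:
    """Analytic waveform sampled onto a grid, with optional additive
    Gaussian amplitude jitter (volts), returned as a ``kind='sampled'``
    waveform.  Zero jitter reproduces the analytic samples exactly."""
    base = Waveform(
        kind=kind,
        peak_to_peak=peak_to_peak,
        dc_offset=dc_offset,
        period=period,
        fall_time=fall_time,
    )
    t, v = sample_waveform(base, n_samples)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, jitter, size=v.shape)
    return Waveform(
        kind="sampled",
        peak_to_peak=peak_to_peak,
        dc_offset=dc_offset,
        period=period,
        samples=(t, v),
    )
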