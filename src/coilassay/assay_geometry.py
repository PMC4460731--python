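"""Assay sample placement in the coil frame and exposure-metric reduction.

Two layouts are covered.  In the transmembrane (Transwell) layout a
horizontal coil lies between two rows of wells; each porous membrane is a
horizontal annular patch level with the coil centreline, so the azimuthal
induced field there is vertical — either along the migration direction
(downward, top chamber → bottom chamber) or against it.  In the plate
layout a culture plate sits on top of a horizontal coil and the field at
the plate bottom is horizontal.

Sign bookkeeping: the solver returns the azimuthal field for one arbitrary
current orientation.  ``winding_handedness`` fixes the physical sense of
the winding (unobservable from the geometry alone); with the default −1 the
longer duty lobe of the reference sawtooth drive maps to *downward on the
North side*, which is how the modelled apparatus labels itself.  North and
South sides see opposite vertical signs at equal magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .field_solver import FieldMap, FieldPoint

__all__ = [
    "TranswellConfig",
    "PlateConfig",
    "SamplePlan",
    "ExposureMetrics",
    "default_transwell_config",
    "transwell_sample_points",
    "plate_sample_points",
    "exposure_metrics",
    "radial_profile",
    "lobe_balance_residual",
]


@dataclass(frozen=True)
class TranswellConfig:
    """Transwell membranes beside the coil, level with its centreline."""

    well_axial_centers: tuple[float, ...]
    membrane_radial_span: tuple[float, float]
    side: str = "north"
    winding_handedness: int = -1

    def __post_init__(self) -> None:
        if self.side not in ("north", "south"):
            raise ValueError("side must be 'north' or 'south'")
        if self.winding_handedness not in (-1, 1):
            raise ValueError("winding_handedness must be +1 or -1")
        lo, hi = self.membrane_radial_span
        if not (0 < lo < hi):
            raise ValueError("membrane_radial_span must satisfy 0 < rho_min < rho_max")
        if len(self.well_axial_centers) < 1:
            raise ValueError("need at least one well")

    @property
    def wells_per_side(self) -> int:
        return len(self.well_axial_centers)

    @property
    def migration_sign(self) -> int:
        """Factor mapping computed E_θ to the migration (downward)
        direction on this config's side."""
        return self.winding_handedness * (1 if self.side == "north" else -1)


def default_transwell_config(
    coil_outer_radius: float,
    side: str = "north",
    standoff: float = 2.0e-3,
    insert_diameter: float = 6.5e-3,
) -> TranswellConfig:
    """Three wells spread along the coil (±30 mm and midplane), membranes
    starting ``standoff`` beyond the winding and spanning one Transwell
    insert diameter.  The true membrane distances of the modelled apparatus
    are unpublished; these defaults are explicit stand-ins and the radial
    profile reports the sensitivity."""
    lo = coil_outer_radius + standoff
    return TranswellConfig(
        well_axial_centers=(-0.03, 0.0, 0.03),
        membrane_radial_span=(lo, lo + insert_diameter),
        side=side,
    )


@dataclass(frozen=True)
class PlateConfig:
    """Culture plate above a horizontal coil: ``plate_bottom_offset`` is the
    vertical gap from the coil surface to the plate bottom, ``region`` the
    sampled rectangle (along-axis × across-axis) on the plate bottom."""

    plate_bottom_offset: float
    region: tuple[float, float] = (1.0e-2, 1.0e-2)

    def __post_init__(self) -> None:
        if self.plate_bottom_offset <= 0:
            raise ValueError("plate_bottom_offset must be positive")
        if min(self.region) <= 0:
            raise ValueError("region dimensions must be positive")


@dataclass(frozen=True)
class SamplePlan:
    """Field points plus the bookkeeping exposure reduction needs."""

    points: tuple[FieldPoint, ...]
    sign: int
    groups: np.ndarray
    ref_index: int
    plot_coords: tuple[np.ndarray, np.ndarray] | None = None


def transwell_sample_points(
    cfg: TranswellConfig,
    n_radial: int = 5,
    coil_outer_radius: float | None = None,
) -> SamplePlan:
    """Membrane sample points: ``n_radial`` radii across the span at each
    well's axial centre.  The duty-fraction reference point is the innermost
    radius of the central well (the one nearest the median axial centre)."""
    if n_radial < 1:
        raise ValueError("n_radial must be >= 1")
    lo, hi = cfg.membrane_radial_span
    if coil_outer_radius is not None and lo <= coil_outer_radius:
        raise ValueError("membrane radial span intersects the coil winding")
    radii = np.array([lo]) if n_radial == 1 else np.linspace(lo, hi, n_radial)
    pts: list[FieldPoint] = []
    groups: list[int] = []
    for w, zc in enumerate(cfg.well_axial_centers):
        for r in radii:
            pts.append(FieldPoint(rho=float(r), z=float(zc)))
            groups.append(w)
    centers = np.asarray(cfg.well_axial_centers)
    ref_well = int(np.argmin(np.abs(centers - np.median(centers))))
    ref_index = ref_well * n_radial  # innermost radius of that well
    return SamplePlan(
        points=tuple(pts),
        sign=cfg.migration_sign,
        groups=np.asarray(groups),
        ref_index=ref_index,
    )


def plate_sample_points(
    cfg: PlateConfig, nx: int, ny: int, coil_outer_radius: float
) -> SamplePlan:
    """Grid on the plate bottom mapped into coil cylindrical coordinates.

    The coil axis is horizontal; a plate point at along-axis position x and
    across-axis position y sits at height ``h = outer_radius + offset``
    above the axis, i.e. at (ρ, z) = (√(y² + h²), x).  The field there is
    horizontal, perpendicular to the coil axis."""
    if nx < 1 or ny < 1:
        raise ValueError("grid must be at least 1×1")
    h = coil_outer_radius + cfg.plate_bottom_offset
    wx, wy = cfg.region
    xs = np.array([0.0]) if nx == 1 else np.linspace(-wx / 2, wx / 2, nx)
    ys = np.array([0.0]) if ny == 1 else np.linspace(-wy / 2, wy / 2, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = tuple(
        FieldPoint(rho=float(np.hypot(y, h)), z=float(x))
        for x, y in zip(gx.ravel(), gy.ravel())
    )
    return SamplePlan(
        points=pts,
        sign=1,
        groups=np.zeros(len(pts), dtype=int),
        ref_index=0,
        plot_coords=(gx, gy),
    )


@dataclass(frozen=True)
class ExposureMetrics:
    """Reduction of a field map to the quantities an exposure is described
    by: peak fields along/against the migration direction, the duty
    fraction of each at the reference point, across-well uniformity, and
    the radial decay profile."""

    max_field_migration_dir: float
    max_field_opposing_dir: float
    duty_fraction_migration_dir: float
    duty_fraction_opposing_dir: float
    uniformity: float
    radial_profile: tuple[tuple[float, float], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "max_field_migration_dir_V_per_m",
                    "max_field_opposing_dir_V_per_m",
                    "duty_fraction_migration_dir",
                    "duty_fraction_opposing_dir",
                    "uniformity",
                ],
                "value": [
                    self.max_field_migration_dir,
                    self.max_field_opposing_dir,
                    self.duty_fraction_migration_dir,
                    self.duty_fraction_opposing_dir,
                    self.uniformity,
                ],
            }
        )


def exposure_metrics(fmap: FieldMap, plan: SamplePlan) -> ExposureMetrics:
    """Reduce a field map over one period to :class:`ExposureMetrics`.

    The duty fraction is evaluated at the plan's reference point; the
    uniformity is the max relative spread of per-well peak |E|; the radial
    profile follows the reference well's points."""
    if len(fmap.points) == 0 or len(fmap.points) != len(plan.points):
        raise ValueError("field map and sample plan do not match")
    E = fmap.E_theta
    s = plan.sign * E
    max_mig = float(max(s.max(), 0.0))
    max_opp = float(max((-s).max(), 0.0))
    ref = s[plan.ref_index]
    duty_mig = float(np.mean(ref > 0))
    duty_opp = float(np.mean(ref < 0))
    peaks = fmap.max_abs_E()
    labels = np.unique(plan.groups)
    if labels.size >= 2:
        group_peak = np.array([peaks[plan.groups == g].max() for g in labels])
        uniformity = float((group_peak.max() - group_peak.min()) / group_peak.mean())
    else:
        uniformity = 0.0
    ref_group = plan.groups[plan.ref_index]
    sel = plan.groups == ref_group
    rho = np.array([p.rho for p in fmap.points])[sel]
    order = np.argsort(rho)
    prof = tuple(zip(rho[order].tolist(), peaks[sel][order].tolist()))
    return ExposureMetrics(
        max_field_migration_dir=max_mig,
        max_field_opposing_dir=max_opp,
        duty_fraction_migration_dir=duty_mig,
        duty_fraction_opposing_dir=duty_opp,
        uniformity=uniformity,
        radial_profile=prof,
    )


def radial_profile(fmap: FieldMap) -> tuple[tuple[float, float], ...]:
    """(ρ, max_t |E|) for every point of the map, sorted by ρ."""
    rho = np.array([p.rho for p in fmap.points])
    peaks = fmap.max_abs_E()
    order = np.argsort(rho)
    return tuple(zip(rho[order].tolist(), peaks[order].tolist()))


def lobe_balance_residual(m: ExposureMetrics) -> float:
    """Relative mismatch of duty×E_down,max against (1−duty)×E_up,max.

    For a two-lobed zero-mean field the products agree approximately; the
    residual is |p·d − q·u| / mean(p·d, q·u) with p the migration-direction
    duty and q the opposing duty."""
    pd_ = m.duty_fraction_migration_dir * m.max_field_migration_dir
    qu = m.duty_fraction_opposing_dir * m.max_field_opposing_dir
    denom = 0.5 * (pd_ + qu)
    if denom == 0:
        return 0.0
    return abs(pd_ - qu) / denom
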