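"""Drive-signal parameter maps over sample mechanical properties.

Each cell of a map answers: "if the surface under the tip had these
mechanical parameters, what drive amplitude would the FM controller need
while imaging?". Cells are evaluated at the piezo elongation that holds a
common frequency-shift setpoint (imaging-like constant-shift tracking), so
a map is the in-silico analogue of recording the drive channel while
scanning a sample whose properties vary laterally.

Two canonical sweeps are provided: drive versus (elastic modulus, adhesion)
and drive versus (elastic modulus, viscosity), together with the
monotonicity/invariance reports that quantify how the drive channel encodes
conservative sample properties in liquid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .control import (OperatingSetpoint, ResonanceTracker, z_feedback_solve,
                      UnreachableSetpointError, TrackingFailureError)
from .dynamics import CantileverConfig, energy_budget
from .forces import ContactMaterial, ForceModel

# Default grids. The modulus axis spans compliant biomaterial to hard
# substrate; its lower end is set by reachability of the common setpoint at
# the default amplitude (softer cells cannot develop the required contact
# stiffness within a safe indentation). Ranges are config-exposed.
DEFAULT_E_GRID = np.logspace(8, 10, 12)                    # 100 MPa .. 10 GPa
DEFAULT_FADH_GRID = np.linspace(0.0, 200.0, 9)             # pN
DEFAULT_ETA_GRID = np.logspace(-2, 3, 9)                   # Pa*s

# Imaging-like operating point for maps and scans: amplitude 1 nm; the
# frequency-shift setpoint is chosen so the mean imaging force across the
# default modulus grid falls inside the 40-80 pN window used experimentally.
DEFAULT_MAP_SETPOINT_SHIFT = 2000.0  # Hz


@dataclass
class DriveMap2D:
    """Normalized drive amplitude over a 2-D grid of material parameters."""

    axis1_name: str
    axis1_grid: np.ndarray
    axis2_name: str
    axis2_grid: np.ndarray
    values: np.ndarray           # shape (len(axis1), len(axis2)); NaN = missing
    tipsample_fraction: np.ndarray  # per-cycle tip-sample loss / drive input
    z_solved: np.ndarray
    setpoint: OperatingSetpoint = None
    meta: dict = field(default_factory=dict)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


def _sweep(cantilever: CantileverConfig, base_model: ForceModel,
           axis1_name: str, grid1: np.ndarray, axis2_name: str,
           grid2: np.ndarray, material_for, setpoint: OperatingSetpoint,
           tracker_kwargs: dict) -> DriveMap2D:
    n1, n2 = len(grid1), len(grid2)
    if n1 == 0 or n2 == 0:
        raise ValueError("parameter grids must be non-empty")
    values = np.full((n1, n2), np.nan)
    ts_frac = np.full((n1, n2), np.nan)
    z_solved = np.full((n1, n2), np.nan)
    tracker = ResonanceTracker(cantilever, setpoint, **tracker_kwargs)
    for i, p1 in enumerate(grid1):
        for j, p2 in enumerate(grid2):
            model = base_model.with_material(material_for(p1, p2))
            try:
                z, state = z_feedback_solve(cantilever, model, setpoint,
                                            tracker=tracker)
            except (UnreachableSetpointError, TrackingFailureError):
                continue
            values[i, j] = state.drive_amplitude
            z_solved[i, j] = z
            budget = energy_budget(state.response)
            ts_frac[i, j] = budget.fraction_tipsample
    return DriveMap2D(
        axis1_name=axis1_name, axis1_grid=np.asarray(grid1, dtype=float),
        axis2_name=axis2_name, axis2_grid=np.asarray(grid2, dtype=float),
        values=values, tipsample_fraction=ts_frac, z_solved=z_solved,
        setpoint=setpoint,
        meta={"f_free": tracker.f_free,
              "drive_force_free": tracker.f_drive_free},
    )


def sweep_drive_vs_modulus_adhesion(cantilever: CantileverConfig,
                                    base_model: ForceModel,
                                    e_grid=None, fadh_grid=None,
                                    setpoint: Optional[OperatingSetpoint] = None,
                                    **tracker_kwargs) -> DriveMap2D:
    """Normalized drive versus (elastic modulus Pa, adhesion pN)."""
    e_grid = DEFAULT_E_GRID if e_grid is None else np.asarray(e_grid)
    fadh_grid = DEFAULT_FADH_GRID if fadh_grid is None else np.asarray(fadh_grid)
    if setpoint is None:
        setpoint = OperatingSetpoint(1.0, DEFAULT_MAP_SETPOINT_SHIFT)
    base = base_model.material

    def material_for(e, fadh):
        return ContactMaterial(elastic_modulus=e, adhesion_force=fadh,
                               viscosity=base.viscosity)

    return _sweep(cantilever, base_model, "elastic_modulus_Pa", e_grid,
                  "adhesion_pN", fadh_grid, material_for, setpoint,
                  tracker_kwargs)


def sweep_drive_vs_modulus_viscosity(cantilever: CantileverConfig,
                                     base_model: ForceModel,
                                     e_grid=None, eta_grid=None,
                                     setpoint: Optional[OperatingSetpoint] = None,
                                     **tracker_kwargs) -> DriveMap2D:
    """Normalized drive versus (elastic modulus Pa, viscosity Pa*s)."""
    e_grid = DEFAULT_E_GRID if e_grid is None else np.asarray(e_grid)
    eta_grid = DEFAULT_ETA_GRID if eta_grid is None else np.asarray(eta_grid)
    if setpoint is None:
        setpoint = OperatingSetpoint(1.0, DEFAULT_MAP_SETPOINT_SHIFT)
    base = base_model.material

    def material_for(e, eta):
        return ContactMaterial(elastic_modulus=e,
                               adhesion_force=base.adhesion_force,
                               viscosity=eta)

    return _sweep(cantilever, base_model, "elastic_modulus_Pa", e_grid,
                  "viscosity_Pa_s", eta_grid, material_for, setpoint,
                  tracker_kwargs)


@dataclass(frozen=True)
class MonotonicityReport:
    """Per-line monotonicity of a drive map along one axis."""

    axis: int
    monotone_fraction: float        # fraction of non-decreasing adjacent pairs
    strict_fraction: float
    largest_violation: float        # largest decrease (positive number)
    violation_index: Optional[tuple]
    passed: bool


def monotonicity_report(map2d: DriveMap2D, axis: int = 0,
                        tolerance: float = 0.0) -> MonotonicityReport:
    """Check that drive values are non-decreasing along ``axis``.

    Missing cells break the lines they sit on; only finite adjacent pairs
    are compared. ``tolerance`` permits decreases up to that size.
    """
    v = map2d.values if axis == 0 else map2d.values.T
    diffs = np.diff(v, axis=0)
    ok = np.isfinite(diffs)
    if not ok.any():
        raise ValueError("no comparable pairs along the requested axis")
    d = diffs[ok]
    mono = float(np.mean(d >= -tolerance))
    strict = float(np.mean(d > tolerance))
    worst = float(max(0.0, -d.min()))
    vio = None
    if worst > 0:
        flat = np.where(ok & (diffs == d.min()))
        if len(flat[0]):
            vio = (int(flat[0][0]), int(flat[1][0]))
            if axis == 1:
                vio = (vio[1], vio[0])
    return MonotonicityReport(axis=axis, monotone_fraction=mono,
                              strict_fraction=strict, largest_violation=worst,
                              violation_index=vio,
                              passed=bool(worst <= tolerance))


@dataclass(frozen=True)
class ContrastReport:
    """Conservative drive contrast along a modulus line."""

    drive_ratio: float              # max/min normalized drive
    max_tipsample_fraction: float   # worst per-cell dissipation fraction
    values: np.ndarray
    e_grid: np.ndarray


def conservative_contrast(cantilever: CantileverConfig,
                          base_model: ForceModel,
                          e_grid=None,
                          setpoint: Optional[OperatingSetpoint] = None,
                          **tracker_kwargs) -> ContrastReport:
    """Drive contrast across a purely conservative modulus line.

    Runs the (modulus, adhesion) sweep with zero adhesion and zero
    viscosity: any drive variation across the line is contrast carried by
    conservative interactions alone, with the per-cell tip-sample
    dissipation fraction reported alongside as the control.
    """
    e_grid = DEFAULT_E_GRID if e_grid is None else np.asarray(e_grid)
    m = sweep_drive_vs_modulus_adhesion(cantilever, base_model,
                                        e_grid=e_grid, fadh_grid=[0.0],
                                        setpoint=setpoint, **tracker_kwargs)
    vals = m.values[:, 0]
    if not np.isfinite(vals).all():
        raise UnreachableSetpointError(
            "conservative contrast line has unreachable cells")
    return ContrastReport(
        drive_ratio=float(np.max(vals) / np.min(vals)),
        max_tipsample_fraction=float(np.nanmax(np.abs(m.tipsample_fraction))),
        values=vals, e_grid=np.asarray(e_grid, dtype=float),
    )
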