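"""Approach-curve pipeline: simultaneous mean force, frequency shift and
drive amplitude versus piezo elongation, plus calibration diagnostics.

An approach curve is the FM-AFM analogue of a force curve: at every piezo
elongation z the resonance tracker holds the oscillation amplitude and the
pi/2 phase condition, and the co-registered observables are

* the cycle-averaged tip-sample force (mean cantilever deflection times the
  static stiffness),
* the frequency shift of the tracked resonance,
* the drive amplitude normalized to its free value.

Diagnostics reproduce the usual calibration landmarks: the pre-contact
solvation elbow, the hard-contact origin of the z scale (two-line
intersection of the elbow plateau with the linear contact rise), and the
mean force while imaging at a given frequency-shift setpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .control import (OperatingSetpoint, ResonanceTracker,
                      TrackingFailureError, default_z_start)
from .dynamics import CantileverConfig
from .forces import ForceModel


class ContactOriginError(RuntimeError):
    """No linear hard-contact rise detectable in the curve."""


class SetpointError(RuntimeError):
    """Requested frequency-shift setpoint is not attained by the curve."""


@dataclass
class ApproachCurve:
    """Co-registered approach channels on a common (descending) z grid."""

    z: np.ndarray                 # nm, descending toward contact
    mean_force: np.ndarray        # pN
    frequency_shift: np.ndarray   # Hz
    drive_amplitude: np.ndarray   # normalized
    z_origin: Optional[float] = None  # detected hard-contact origin (raw z)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.z)
        if not (len(self.mean_force) == len(self.frequency_shift)
                == len(self.drive_amplitude) == n):
            raise ValueError("all channels must share the z grid")

    def rereference(self, z_origin: float) -> "ApproachCurve":
        """Shift the z scale so ``z_origin`` becomes 0."""
        return ApproachCurve(
            z=self.z - z_origin,
            mean_force=self.mean_force,
            frequency_shift=self.frequency_shift,
            drive_amplitude=self.drive_amplitude,
            z_origin=0.0,
            meta=dict(self.meta, raw_z_origin=z_origin),
        )


def simulate_approach(cantilever: CantileverConfig, model: Optional[ForceModel],
                      setpoint: OperatingSetpoint,
                      z_range: Optional[tuple] = None,
                      n_points: int = 200,
                      tracker: Optional[ResonanceTracker] = None,
                      **tracker_kwargs) -> ApproachCurve:
    """Sweep z from far field toward contact with warm-started tracking.

    ``z_range = (z_far, z_near)``; the default spans the far field down to
    light indentation for the given amplitude. Tracking failures deep in
    contact truncate the curve with a warning instead of aborting.
    """
    a = setpoint.target_amplitude
    if z_range is None:
        z_range = (default_z_start(model, a) + 2.0, a - 0.35)
    z_far, z_near = max(z_range), min(z_range)
    z_grid = np.linspace(z_far, z_near, n_points)
    if tracker is None:
        tracker = ResonanceTracker(cantilever, setpoint, **tracker_kwargs)

    forces, shifts, drives = [], [], []
    warm = None
    kept = 0
    for z in z_grid:
        try:
            state = tracker.track(model, float(z), warm=warm)
        except TrackingFailureError as err:
            warnings.warn(f"approach truncated at z={z:.3f} nm: {err}",
                          RuntimeWarning, stacklevel=2)
            break
        warm = state.tracker_vector
        forces.append(state.response.mean_force)
        shifts.append(state.frequency_shift)
        drives.append(state.drive_amplitude)
        kept += 1
    if kept == 0:
        raise TrackingFailureError("no z point could be tracked")
    return ApproachCurve(
        z=z_grid[:kept],
        mean_force=np.array(forces),
        frequency_shift=np.array(shifts),
        drive_amplitude=np.array(drives),
        meta={"amplitude": a, "f_free": tracker.f_free,
              "drive_force_free": tracker.f_drive_free},
    )


def detect_contact_origin(curve: ApproachCurve,
                          contact_fraction: float = 0.6,
                          plateau_force: float = 5.0) -> float:
    """z of the hard-contact onset: intersection of the elbow-end plateau
    with the least-squares line through the steep contact rise.

    The contact line is fitted over the deepest points whose mean force
    exceeds ``contact_fraction`` of the curve maximum; the plateau level is
    the force just outside the rise. Returns the raw z origin (use
    ``curve.rereference`` to move the scale).
    """
    z, f = curve.z, curve.mean_force
    fmax = float(np.max(f))
    if fmax <= plateau_force:
        raise ContactOriginError("curve never develops a repulsive rise")
    mask = f >= contact_fraction * fmax
    # restrict to the innermost contiguous run (the contact rise)
    idx = np.where(mask)[0]
    runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    rise = runs[-1]
    if len(rise) < 2:
        raise ContactOriginError("contact rise not resolved by the z grid")
    slope, icept = np.polyfit(z[rise], f[rise], 1)
    if slope >= 0:
        raise ContactOriginError("contact rise has non-negative slope in z")
    # plateau level: the flat outer half of the pre-rise region (the far
    # side of the elbow), robust to ripples riding on the baseline
    pre = np.arange(rise[0])
    if len(pre) == 0:
        plateau = 0.0
    else:
        outer = pre[: max(1, len(pre) // 2)]
        plateau = float(np.median(f[outer]))
    z0 = (plateau - icept) / slope
    return float(z0)


def force_at_setpoint(curve: ApproachCurve, frequency_shift: float) -> float:
    """Mean force (pN) interpolated at the outermost z where the frequency
    shift crosses ``frequency_shift`` (Hz)."""
    df = curve.frequency_shift - frequency_shift
    if frequency_shift == 0.0:
        return float(curve.mean_force[0])
    crossings = np.where(df[:-1] * df[1:] <= 0)[0]
    crossings = crossings[df[crossings] != df[crossings + 1]]
    if len(crossings) == 0:
        raise SetpointError(
            f"frequency shift {frequency_shift} Hz never attained "
            f"(range {curve.frequency_shift.min():.2f}.."
            f"{curve.frequency_shift.max():.2f} Hz)")
    i = crossings[0]  # outermost: the grid descends from far field
    t = -df[i] / (df[i + 1] - df[i])
    return float(curve.mean_force[i] + t * (curve.mean_force[i + 1]
                                            - curve.mean_force[i]))


def first_precontact_maximum(curve: ApproachCurve,
                             z_origin: Optional[float] = None) -> tuple:
    """(z, force) of the solvation-elbow maximum of the mean force.

    The elbow top is the dominant local maximum of the mean-force channel
    at positive gap (z before the hard-contact origin): with a decaying
    layered interaction the ring maxima grow monotonically on approach, so
    the dominant one is the last and largest crest before the hard rise.
    """
    if z_origin is None:
        z_origin = curve.z_origin
        if z_origin is None:
            z_origin = detect_contact_origin(curve)
    z, f = curve.z, curve.mean_force
    pre = z > z_origin
    zp, fp = z[pre], f[pre]
    if len(fp) < 3:
        raise ContactOriginError("no pre-contact region in the curve")
    interior = (fp[1:-1] >= fp[:-2]) & (fp[1:-1] > fp[2:])
    idx = np.where(interior)[0] + 1
    if len(idx) == 0:
        raise ContactOriginError("no pre-contact mean-force maximum found")
    best = idx[np.argmax(fp[idx])]
    return float(zp[best]), float(fp[best])
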