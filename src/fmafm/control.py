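"""FM-AFM feedback stack as steady-state fixed points.

Three nested loops of a frequency-modulation AFM are emulated:

* resonance tracking -- the drive frequency follows the frequency at which
  the fundamental tip response lags the drive by pi/2;
* amplitude-gain control -- the drive force is adjusted so the fundamental
  oscillation amplitude stays at the setpoint;
* z feedback -- the piezo elongation is adjusted until the frequency shift
  matches the imaging setpoint.

The controllers are resolved as quasi-static fixed points of the periodic
steady state rather than as time-domain PLL/AGC transients: images and
parameter maps are steady-state observables, so the fixed point is the
quantity of interest. Both feedback conditions are appended to the
harmonic-balance system and solved jointly: the unknown vector is
(modal Fourier coefficients, drive frequency, drive force) and the extra
residuals pin the complex fundamental amplitude to ``-i * A_set``
(amplitude A_set at a pi/2 lag). Warm starts across a z sweep make
approach curves and per-pixel feedback solves cheap.

Drive amplitude is reported normalized to the free-oscillation drive, so 1
means "no extra energy demand from the interaction".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .dynamics import (
    CantileverConfig, HarmonicBalance, SteadyStateResponse,
    free_resonance, free_response_amplitude, ConvergenceError,
    ContactOverloadError,
)
from .forces import ForceModel


class TrackingFailureError(RuntimeError):
    """Resonance tracking found no acceptable fixed point."""


class UnreachableSetpointError(RuntimeError):
    """The frequency-shift setpoint is never reached on the approach."""


@dataclass(frozen=True)
class OperatingSetpoint:
    """Imaging operating point: amplitude (nm) and frequency shift (Hz)."""

    target_amplitude: float
    frequency_shift_setpoint: float = 0.0

    def __post_init__(self):
        if not self.target_amplitude > 0:
            raise ValueError("target amplitude must be > 0")


@dataclass
class FMState:
    """Resolved state of the FM feedback at one piezo elongation."""

    z: float
    drive_frequency: float
    frequency_shift: float
    drive_amplitude: float  # normalized; free oscillation == 1
    response: SteadyStateResponse
    tracker_vector: np.ndarray  # packed warm-start vector


class ResonanceTracker:
    """Tracks resonance and constant amplitude for one cantilever/setpoint.

    Reusable across z values and materials; carrying the previous solution
    as a warm start makes sweeps fast and continuation robust.
    """

    def __init__(self, cantilever: CantileverConfig, setpoint: OperatingSetpoint,
                 n_harmonics: int = 12, n_samples: int = 512,
                 residual_tol: float = 1e-7, overload_indentation: float = 5.0,
                 phase_tol: float = 1e-3, amplitude_rtol: float = 1e-3):
        self.cant = cantilever
        self.setpoint = setpoint
        self.n_h = n_harmonics
        self.n_t = n_samples
        self.residual_tol = residual_tol
        self.overload = overload_indentation
        self.phase_tol = phase_tol
        self.amplitude_rtol = amplitude_rtol
        self.f_free = free_resonance(cantilever)
        h = free_response_amplitude(cantilever, self.f_free, 1.0)
        self.f_drive_free = setpoint.target_amplitude / abs(h)
        # frequency unknown measured in resonance half-widths: keeps the
        # joint Jacobian well conditioned at high Q
        self.freq_scale = 2.0 * cantilever.modes[0].quality_factor

    # --- augmented system ----------------------------------------------------
    def _free_vector(self, hb: HarmonicBalance) -> np.ndarray:
        x0 = hb.linear_guess(2.0 * np.pi * self.f_free, self.f_drive_free)
        return np.concatenate([x0, [0.0, 1.0]])  # rel. freq shift, rel. drive

    def _residual(self, v: np.ndarray, hb: HarmonicBalance) -> np.ndarray:
        x, df_scaled, fd_rel = v[:-2], v[-2], v[-1]
        freq = self.f_free * (1.0 + df_scaled / self.freq_scale)
        f_d = self.f_drive_free * fd_rel
        omega = 2.0 * np.pi * freq
        res = hb.residual(x, omega, f_d)
        d = hb.unpack(x)
        d1 = d[:, 1].sum()
        a = self.setpoint.target_amplitude
        return np.concatenate([res, [d1.real / a, (d1.imag + a) / a]])

    def track(self, model: Optional[ForceModel], z: float,
              warm: Optional[np.ndarray] = None) -> FMState:
        """Solve the two-condition fixed point at piezo elongation ``z``."""
        hb = HarmonicBalance(self.cant, model, z, n_harmonics=self.n_h,
                             n_samples=self.n_t, residual_tol=self.residual_tol,
                             overload_indentation=self.overload)
        starts = []
        if warm is not None:
            starts.append(np.asarray(warm, dtype=float))
        starts.append(self._free_vector(hb))
        last_err: Optional[Exception] = None
        for v0 in starts:
            for attempt in range(3):
                if attempt == 0:
                    guess = v0
                elif attempt == 1:
                    # polish the modal coefficients at the frozen operating
                    # point before re-entering the joint solve (helps stiff
                    # contact at high Q, where the coupled Jacobian is harsh)
                    guess = self._polish_coefficients(v0, hb)
                    if guess is None:
                        continue
                else:
                    guess = v0
                method = "lm" if attempt == 2 else "hybr"
                opts = {"xtol": 1e-12} if method == "hybr" else {
                    "xtol": 1e-14, "ftol": 1e-14}
                sol = optimize.root(self._residual, guess, args=(hb,),
                                    method=method, options=opts)
                v = sol.x
                rnorm = float(np.max(np.abs(self._residual(v, hb))))
                if rnorm <= self.residual_tol:
                    try:
                        return self._state_from(v, hb)
                    except (TrackingFailureError, ContactOverloadError) as err:
                        last_err = err
                        continue
                last_err = ConvergenceError("tracker residual "
                                            f"{rnorm:.3e}", residual=rnorm)
        raise TrackingFailureError(
            f"resonance tracking failed at z={z:.4f} nm: {last_err}")

    def _polish_coefficients(self, v0: np.ndarray, hb: HarmonicBalance):
        """Re-solve the modal balance at the (f, F_drive) carried by ``v0``."""
        x, df_scaled, fd_rel = v0[:-2], v0[-2], v0[-1]
        omega = 2.0 * np.pi * self.f_free * (1.0 + df_scaled / self.freq_scale)
        f_d = self.f_drive_free * fd_rel
        sol = optimize.root(hb.residual, x, args=(omega, f_d), method="hybr",
                            options={"xtol": 1e-12})
        if not np.all(np.isfinite(sol.x)):
            return None
        return np.concatenate([sol.x, [df_scaled, fd_rel]])

    def _state_from(self, v: np.ndarray, hb: HarmonicBalance) -> FMState:
        x, df_scaled, fd_rel = v[:-2], v[-2], v[-1]
        freq = self.f_free * (1.0 + df_scaled / self.freq_scale)
        f_d = self.f_drive_free * fd_rel
        if f_d <= 0:
            raise TrackingFailureError("negative drive at fixed point")
        resp = hb.response_from(x, freq, f_d)
        a = self.setpoint.target_amplitude
        if abs(resp.phase_lag - np.pi / 2.0) > self.phase_tol:
            raise TrackingFailureError(
                f"phase residual {resp.phase_lag - np.pi / 2.0:.2e} rad")
        if abs(resp.fundamental_amplitude - a) / a > self.amplitude_rtol:
            raise TrackingFailureError("amplitude residual too large")
        return FMState(
            z=hb.z,
            drive_frequency=freq,
            frequency_shift=freq - self.f_free,
            drive_amplitude=f_d / self.f_drive_free,
            response=resp,
            tracker_vector=v.copy(),
        )


def track_resonance(cantilever: CantileverConfig, model: Optional[ForceModel],
                    z: float, setpoint: OperatingSetpoint,
                    **kwargs) -> FMState:
    """One-shot resonance tracking at fixed ``z`` (see ResonanceTracker)."""
    return ResonanceTracker(cantilever, setpoint, **kwargs).track(model, z)


def default_z_start(model: Optional[ForceModel], amplitude: float) -> float:
    """A piezo elongation safely in the far field for ``model``."""
    reach = 1.5
    if model is not None and model.solvation is not None:
        reach = max(reach, 8.0 * model.solvation.decay_length)
    if model is not None and model.long_range is not None:
        reach = max(reach, 10.0 * model.long_range.offset)
    return amplitude + reach


def z_feedback_solve(cantilever: CantileverConfig, model: ForceModel,
                     setpoint: OperatingSetpoint,
                     z_start: Optional[float] = None,
                     z_min: Optional[float] = None,
                     coarse_step: float = 0.05,
                     z_tol: float = 1e-4,
                     tracker: Optional[ResonanceTracker] = None) -> tuple:
    """Largest z at which the frequency shift equals the setpoint.

    Walks inward from the far field (mirroring a physical approach) with
    warm-started resonance tracking, brackets the outermost crossing of the
    setpoint, and refines it by bisection. Returns ``(z, FMState)``.

    Raises UnreachableSetpointError when the setpoint is never crossed
    before ``z_min``.
    """
    df_set = setpoint.frequency_shift_setpoint
    a = setpoint.target_amplitude
    if z_start is None:
        z_start = default_z_start(model, a)
    if z_min is None:
        z_min = a - 3.0
    if tracker is None:
        tracker = ResonanceTracker(cantilever, setpoint)

    z = z_start
    state = tracker.track(model, z)
    # degenerate setpoint already met at the far field: the outermost
    # solution is the bracket start itself
    if abs(state.frequency_shift - df_set) < 0.5:
        return z, state
    warm = state.tracker_vector
    prev_z, prev_df, prev_warm = z, state.frequency_shift, warm.copy()
    while True:
        z = z - coarse_step
        if z < z_min:
            raise UnreachableSetpointError(
                f"frequency shift setpoint {df_set} Hz not reached above "
                f"z={z_min:.3f} nm (last df={prev_df:.3f} Hz)")
        try:
            state = tracker.track(model, z, warm=warm)
        except TrackingFailureError as err:
            raise UnreachableSetpointError(
                f"tracking lost before reaching setpoint: {err}") from err
        warm = state.tracker_vector
        df = state.frequency_shift
        if (prev_df - df_set) * (df - df_set) <= 0 and df != prev_df:
            break
        prev_z, prev_df, prev_warm = z, df, warm.copy()

    # bisection refinement inside [z, prev_z]
    lo_z, hi_z = z, prev_z
    lo_state = state
    warm_ref = warm.copy()
    while hi_z - lo_z > z_tol:
        mid = 0.5 * (lo_z + hi_z)
        mid_state = tracker.track(model, mid, warm=warm_ref)
        warm_ref = mid_state.tracker_vector
        if (mid_state.frequency_shift - df_set) * (lo_state.frequency_shift - df_set) > 0:
            lo_z, lo_state = mid, mid_state
        else:
            hi_z = mid
    return lo_z, lo_state
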