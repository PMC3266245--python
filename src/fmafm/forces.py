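"""Tip-sample force laws for dynamic AFM in liquid.

All public quantities use the field's customary units: lengths in nm, forces
in pN, elastic moduli in Pa, viscosities in Pa*s, spring constants in N/m.
Internally everything is converted to a consistent (nm, pN, s) system:

* 1 Pa      = 1e-6 pN/nm^2
* 1 Pa*s    = 1e-6 pN*s/nm^2
* 1 N/m     = 1e3  pN/nm

The composite model is the sum of four terms, each optional except contact:

* a repulsive elastic contact (Hertz sphere-on-flat, or a linear spring for
  thin-shell particles whose stiffness is quoted in N/m),
* a DMT adhesion offset: constant pull-off inside contact, reached
  continuously through a short-range attractive tail just outside,
* a Kelvin-Voigt sample viscosity scaled by the instantaneous contact radius,
* a decaying-oscillatory solvation-layer force above the surface, standing in
  for the ordered liquid layers a sharp tip feels before mechanical contact,
* an optional long-range van der Waals tail (off by default).

Sign convention: positive force pushes the tip away from the surface
(repulsive). ``gap`` is the instantaneous tip-surface separation; negative
gap means indentation ``delta = -gap``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# unit conversions into the internal (nm, pN, s) system
PA_TO_INTERNAL = 1e-6        # Pa -> pN/nm^2
PAS_TO_INTERNAL = 1e-6       # Pa*s -> pN*s/nm^2
NPM_TO_INTERNAL = 1e3        # N/m -> pN/nm

HERTZ = "hertz_sphere"
LINEAR = "linear_spring"


class InvalidParameterError(ValueError):
    """Raised when a force-model parameter violates its physical domain."""


@dataclass(frozen=True)
class TipGeometry:
    """Spherical tip apex. ``radius`` in nm."""

    radius: float = 10.0

    def __post_init__(self):
        if not self.radius > 0:
            raise InvalidParameterError(f"tip radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class ContactMaterial:
    """Local mechanical identity of the surface under the tip.

    ``elastic_modulus`` is the effective (reduced) modulus E* in Pa, used by
    the Hertz law. ``spring_constant`` (N/m) is used instead when
    ``contact_law == "linear_spring"`` -- the natural description for virus
    capsids, whose nanoindentation response is linear at small indentation.
    ``adhesion_force`` (pN) is a DMT-style offset: the constant pull-off
    force inside contact, approached continuously from outside through a
    short-range attractive tail of reach ``adhesion_range`` (nm) -- the
    classical DMT picture, where the surface attraction is already fully
    developed at touch. ``viscosity`` (Pa*s) feeds the Kelvin-Voigt
    damping term.
    """

    elastic_modulus: float = 1e9
    adhesion_force: float = 0.0
    viscosity: float = 0.0
    contact_law: str = HERTZ
    spring_constant: float = 0.0
    adhesion_range: float = 0.2

    def __post_init__(self):
        if self.elastic_modulus < 0:
            raise InvalidParameterError("elastic_modulus must be >= 0")
        if self.adhesion_force < 0:
            raise InvalidParameterError("adhesion_force must be >= 0")
        if self.viscosity < 0:
            raise InvalidParameterError("viscosity must be >= 0")
        if self.contact_law not in (HERTZ, LINEAR):
            raise InvalidParameterError(f"unknown contact law {self.contact_law!r}")
        if self.contact_law == LINEAR and not self.spring_constant > 0:
            raise InvalidParameterError("spring_constant must be > 0 for linear_spring")
        if not self.adhesion_range > 0:
            raise InvalidParameterError("adhesion_range must be > 0")


@dataclass(frozen=True)
class SolvationParams:
    """Decaying oscillatory solvation-layer force.

    F(gap) = amplitude * exp(-gap/decay_length) * cos(2*pi*gap/period + phase)

    ``amplitude`` pN, ``decay_length`` and ``period`` nm, ``phase`` rad.
    """

    amplitude: float
    decay_length: float
    period: float
    phase: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise InvalidParameterError("solvation amplitude must be >= 0")
        if not self.decay_length > 0:
            raise InvalidParameterError("decay_length must be > 0")
        if not self.period > 0:
            raise InvalidParameterError("period must be > 0")


@dataclass(frozen=True)
class VdwTail:
    """Hamaker-style attractive tail -H*R/(6*(gap+offset)^2), clamped inside
    contact at its gap=0 value so the total stays integrable and continuous.

    ``hamaker`` in zJ (1e-21 J = pN*nm); ``offset`` nm regularizes gap -> 0.
    """

    hamaker: float = 3.0
    offset: float = 0.3

    def __post_init__(self):
        if self.hamaker < 0:
            raise InvalidParameterError("hamaker must be >= 0")
        if not self.offset > 0:
            raise InvalidParameterError("vdW offset must be > 0")


@dataclass(frozen=True)
class GapState:
    """Instantaneous tip-surface separation (nm) and its rate (nm/s)."""

    gap: float
    gap_rate: float = 0.0


# Default solvation calibration. The parameters were fixed once so that the
# default approach simulation (0.6 N/m lever, 1.2 nm amplitude, two-mode
# liquid preset) shows a pre-contact solvation elbow whose dominant
# mean-force maximum is ~20 pN, with hard contact reached below 100 pN.
# The cycle averaging of the oscillating tip attenuates the layered force
# heavily (~30x here), so the static force amplitude is much larger than
# the 20 pN cycle-averaged elbow it produces. Period and decay are on the
# scale of structured liquid layering at a solid interface.
DEFAULT_SOLVATION = SolvationParams(
    amplitude=635.0, decay_length=0.40, period=0.55, phase=0.0
)


@dataclass(frozen=True)
class ForceModel:
    """Composite tip-sample interaction."""

    tip: TipGeometry = field(default_factory=TipGeometry)
    material: ContactMaterial = field(default_factory=ContactMaterial)
    solvation: Optional[SolvationParams] = None
    long_range: Optional[VdwTail] = None

    def total(self, gap, gap_rate=0.0):
        """Total force (pN) at ``gap`` (nm) moving at ``gap_rate`` (nm/s).

        Vectorized over ``gap``/``gap_rate``.
        """
        f = contact_force(gap, self.material, self.tip)
        if self.solvation is not None:
            f = f + solvation_force(np.maximum(gap, 0.0), self.solvation)
        if self.material.viscosity > 0:
            f = f + viscous_force(gap, gap_rate, self.material, self.tip)
        if self.long_range is not None:
            f = f + vdw_force(gap, self.long_range, self.tip)
        return f

    def conservative(self, gap):
        """Position-only (conservative) part of the force (pN)."""
        f = contact_force(gap, self.material, self.tip)
        if self.solvation is not None:
            f = f + solvation_force(np.maximum(gap, 0.0), self.solvation)
        if self.long_range is not None:
            f = f + vdw_force(gap, self.long_range, self.tip)
        return f

    def with_material(self, material: ContactMaterial) -> "ForceModel":
        return ForceModel(tip=self.tip, material=material,
                          solvation=self.solvation, long_range=self.long_range)


def contact_force(gap, material: ContactMaterial, tip: TipGeometry):
    """Elastic contact force plus DMT adhesion (pN).

    Out of contact (gap > 0) the elastic part is exactly zero. In contact,
    Hertz gives (4/3) E* sqrt(R) delta^(3/2); the linear law gives
    k_v * delta. Adhesion is the DMT constant -F_adh inside contact,
    approached continuously from outside by the inverse-square tail
    -F_adh / (1 + gap/range)^2, so the total is continuous at touch.
    """
    gap = np.asarray(gap, dtype=float)
    delta = np.maximum(-gap, 0.0)
    if material.contact_law == HERTZ:
        e_star = material.elastic_modulus * PA_TO_INTERNAL
        f_el = (4.0 / 3.0) * e_star * np.sqrt(tip.radius) * delta ** 1.5
    else:
        k_v = material.spring_constant * NPM_TO_INTERNAL
        f_el = k_v * delta
    f = np.where(gap <= 0, f_el - material.adhesion_force, 0.0)
    if material.adhesion_force > 0:
        tail = -material.adhesion_force / (
            1.0 + np.maximum(gap, 0.0) / material.adhesion_range) ** 2
        f = np.where(gap > 0, tail, f)
    return f if f.ndim else float(f)


def solvation_force(gap, params: SolvationParams):
    """Solvation-layer force (pN) for gap >= 0 (nm); decaying cosine."""
    gap = np.asarray(gap, dtype=float)
    f = params.amplitude * np.exp(-gap / params.decay_length) * np.cos(
        2.0 * np.pi * gap / params.period + params.phase
    )
    return f if f.ndim else float(f)


def viscous_force(gap, gap_rate, material: ContactMaterial, tip: TipGeometry):
    """Kelvin-Voigt damping -eta * sqrt(R*delta) * d(delta...)/dt (pN).

    Active only in contact; the damping coefficient scales with the Hertzian
    contact radius sqrt(R*delta) so it vanishes continuously at touch.
    Opposes the gap rate (closing gap -> positive, repulsive force).
    """
    gap = np.asarray(gap, dtype=float)
    gap_rate = np.asarray(gap_rate, dtype=float)
    delta = np.maximum(-gap, 0.0)
    eta = material.viscosity * PAS_TO_INTERNAL
    f = np.where(gap < 0, -eta * np.sqrt(tip.radius * delta) * gap_rate, 0.0)
    return f if f.ndim else float(f)


def vdw_force(gap, tail: VdwTail, tip: TipGeometry):
    """Long-range attractive tail (pN), clamped inside contact."""
    gap = np.asarray(gap, dtype=float)
    g = np.maximum(gap, 0.0)
    f = -tail.hamaker * tip.radius / (6.0 * (g + tail.offset) ** 2)
    return f if f.ndim else float(f)


def total_force(state: GapState, model: ForceModel) -> float:
    """Convenience scalar evaluation of the composite model (pN)."""
    return float(model.total(state.gap, state.gap_rate))


def default_substrate_material(adhesion_force: float = 0.0,
                               viscosity: float = 0.0) -> ContactMaterial:
    """Rigid substrate preset (E* = 10 GPa), cf. graphite/mica supports."""
    return ContactMaterial(elastic_modulus=1e10, adhesion_force=adhesion_force,
                           viscosity=viscosity, contact_law=HERTZ)


def default_approach_model() -> ForceModel:
    """Shipped calibration for the approach-curve stage: stiff substrate
    plus the default solvation layering; purely conservative."""
    return ForceModel(
        tip=TipGeometry(radius=10.0),
        material=default_substrate_material(),
        solvation=DEFAULT_SOLVATION,
    )
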