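"""Run configuration: schema, validation, provenance.

A run is described by a plain YAML mapping with nested sections. Unknown
keys are rejected (typos must fail loudly, not silently fall back to
defaults), every section is optional, and the resolved configuration plus
its hash are recorded alongside every output file so any artifact can be
traced to the exact parameters that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from typing import Optional

import yaml

from .control import OperatingSetpoint
from .dynamics import CantileverConfig, Eigenmode, liquid_preset
from .forces import (ContactMaterial, ForceModel, SolvationParams, TipGeometry,
                     VdwTail, DEFAULT_SOLVATION)
from .morphology import TipSurface

SCHEMA = {
    "cantilever": {"f1", "k1", "q1", "q2", "n_modes", "tip_radius", "modes"},
    "force_model": {"elastic_modulus", "adhesion_force", "viscosity",
                    "contact_law", "spring_constant", "adhesion_range",
                    "solvation", "vdw"},
    "controller": {"amplitude", "frequency_shift", "n_harmonics", "n_samples",
                   "residual_tol", "overload_indentation", "z_start", "z_min",
                   "coarse_step", "z_tol"},
    "sample": {"size", "pixel_size", "adhesion_patches", "roughness",
               "particles"},
    "sweep": {"e_grid", "fadh_grid", "eta_grid", "e_points", "fadh_points",
              "eta_points"},
    "scan": {},
    "morphology": {"tip_kind", "tip_radius", "support_radius", "boundary"},
    "approach": {"n_points", "z_far", "z_near"},
    "output": {"precision"},
}
SOLVATION_KEYS = {"amplitude", "decay_length", "period", "phase", "enabled"}
VDW_KEYS = {"hamaker", "offset"}


class ConfigError(ValueError):
    """Invalid or unknown configuration content; names the offending key."""


@dataclass
class RunConfig:
    """Validated run configuration (raw sections plus seed and version)."""

    sections: dict = dc_field(default_factory=dict)
    seed: int = 0
    version: str = "1"

    @classmethod
    def from_mapping(cls, raw: Optional[dict]) -> "RunConfig":
        raw = dict(raw or {})
        seed = raw.pop("seed", 0)
        version = str(raw.pop("version", "1"))
        for section, content in raw.items():
            if section not in SCHEMA:
                raise ConfigError(f"unknown config section {section!r}")
            if content is None:
                continue
            if not isinstance(content, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            extra = set(content) - SCHEMA[section]
            if extra:
                raise ConfigError(
                    f"unknown key(s) {sorted(extra)} in section {section!r}")
            if section == "force_model":
                solv = content.get("solvation")
                if isinstance(solv, dict):
                    bad = set(solv) - SOLVATION_KEYS
                    if bad:
                        raise ConfigError(
                            f"unknown solvation key(s) {sorted(bad)}")
                vdw = content.get("vdw")
                if isinstance(vdw, dict) and set(vdw) - VDW_KEYS:
                    raise ConfigError("unknown vdw key(s)")
        return cls(sections=raw, seed=int(seed), version=version)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_mapping(raw)

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name) or {})

    def resolved(self) -> dict:
        return {"version": self.version, "seed": self.seed,
                **{k: self.sections[k] for k in sorted(self.sections)}}

    def hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # --- object factories ---------------------------------------------------
    def cantilever(self) -> CantileverConfig:
        c = self.section("cantilever")
        if "modes" in c:
            modes = tuple(Eigenmode(frequency=m["frequency"],
                                    stiffness=m["stiffness"],
                                    quality_factor=m["quality_factor"])
                          for m in c["modes"])
            return CantileverConfig(
                modes=modes, tip=TipGeometry(radius=c.get("tip_radius", 10.0)))
        return liquid_preset(f1=c.get("f1", 19e3), k1=c.get("k1", 0.6),
                             q1=c.get("q1", 2.0), q2=c.get("q2", 5.0),
                             n_modes=c.get("n_modes", 2),
                             tip_radius=c.get("tip_radius", 10.0))

    def force_model(self, with_default_solvation: bool = False) -> ForceModel:
        f = self.section("force_model")
        material = ContactMaterial(
            elastic_modulus=f.get("elastic_modulus", 1e10),
            adhesion_force=f.get("adhesion_force", 0.0),
            viscosity=f.get("viscosity", 0.0),
            contact_law=f.get("contact_law", "hertz_sphere"),
            spring_constant=f.get("spring_constant", 0.0),
            adhesion_range=f.get("adhesion_range", 0.2),
        )
        solv_cfg = f.get("solvation", "default" if with_default_solvation
                         else None)
        solvation = None
        if solv_cfg == "default" or solv_cfg is True:
            solvation = DEFAULT_SOLVATION
        elif isinstance(solv_cfg, dict):
            if solv_cfg.get("enabled", True):
                solvation = SolvationParams(
                    amplitude=solv_cfg.get("amplitude",
                                           DEFAULT_SOLVATION.amplitude),
                    decay_length=solv_cfg.get("decay_length",
                                              DEFAULT_SOLVATION.decay_length),
                    period=solv_cfg.get("period", DEFAULT_SOLVATION.period),
                    phase=solv_cfg.get("phase", DEFAULT_SOLVATION.phase))
        vdw_cfg = f.get("vdw")
        long_range = None
        if isinstance(vdw_cfg, dict):
            long_range = VdwTail(hamaker=vdw_cfg.get("hamaker", 3.0),
                                 offset=vdw_cfg.get("offset", 0.3))
        cant = self.section("cantilever")
        tip = TipGeometry(radius=cant.get("tip_radius", 10.0))
        return ForceModel(tip=tip, material=material, solvation=solvation,
                          long_range=long_range)

    def setpoint(self, default_amplitude: float = 1.0,
                 default_shift: float = 0.0) -> OperatingSetpoint:
        c = self.section("controller")
        return OperatingSetpoint(
            target_amplitude=c.get("amplitude", default_amplitude),
            frequency_shift_setpoint=c.get("frequency_shift", default_shift))

    def tracker_options(self) -> dict:
        c = self.section("controller")
        out = {}
        for key in ("n_harmonics", "n_samples", "residual_tol",
                    "overload_indentation"):
            if key in c:
                out[key] = c[key]
        return out

    def morphology_tip(self) -> TipSurface:
        m = self.section("morphology")
        return TipSurface(kind=m.get("tip_kind", "sphere"),
                          radius=m.get("tip_radius", 0.2),
                          support_radius=m.get("support_radius", 0.0))


def provenance_header(config: RunConfig, extra: str = "") -> str:
    """Comment line recording the config hash and seed for output files."""
    line = f"# fmafm v{__import__('fmafm').__version__} config={config.hash()} seed={config.seed}"
    if extra:
        line += f" {extra}"
    return line
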