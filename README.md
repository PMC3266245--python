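# fmafm

Simulation of frequency-modulation atomic force microscopy (FM-AFM) in
liquid, built around the question of what the drive-amplitude
("dissipation") channel actually measures there. In vacuum that channel
tracks nonconservative tip–sample losses. In liquid, where cantilever
quality factors are of order unity, nonlinear tip–sample forces distort
the oscillation and feed energy into higher harmonics and higher
eigenmodes of the probe; the surrounding liquid dissipates that energy and
the amplitude-gain loop must resupply it. The drive map therefore shows
contrast from purely **conservative** sample properties — stiffness,
adhesion — while the topography (constant frequency-shift) channel stays
uncontaminated. That is what makes gentle, quantitative imaging of single
virus particles in buffer possible, and it is the behaviour this package
reproduces end to end.

For whom: AFM practitioners and biophysicists who want to understand or
predict FM-AFM contrast in liquid, and anyone needing a tested, scriptable
virtual FM-AFM (multi-eigenmode dynamics + feedback stack + virtual
scanner) for method development.

## Model

Point-mass eigenmodes sharing the tip force (default two-mode liquid
preset, f₁ = 19 kHz, k₁ = 0.6 N/m, Q₁ = 2, Q₂ = 5, Euler–Bernoulli
ratios):

    m_i q̈_i + (k_i/ω_iQ_i) q̇_i + k_i q_i = F_drive(t) + F_ts(u, u̇),
    u = z + Σ q_i

with a composite tip–sample force: Hertz or linear-spring contact, DMT
adhesion, contact-radius-scaled Kelvin–Voigt sample viscosity, a
decaying-oscillatory solvation-layer term, and an optional van der Waals
tail. The periodic steady state is solved by harmonic balance (12
harmonics, Newton on the spectral residual; a time-domain integrator
serves as independent cross-check), and the FM feedback stack — resonance
tracking (phase lag π/2), constant amplitude, and z feedback on a
frequency-shift setpoint Δf_set — is resolved as a quasi-static fixed
point. Per-cycle energy bookkeeping (drive input, medium loss per
harmonic/mode, tip–sample loss) closes to solver precision; the
small-amplitude limit Δf = f₀k_ts/2k and the virial integral are used as
oracles. Details and all defaults: `docs/methods.md`.

## Worked example

Simulate the default approach experiment (stiff substrate with solvation
layers, A = 1.2 nm) and read off the calibration landmarks:

```python
from fmafm import (liquid_preset, default_approach_model, OperatingSetpoint,
                   simulate_approach, detect_contact_origin)
from fmafm.approach import first_precontact_maximum, force_at_setpoint

cant = liquid_preset()                    # 19 kHz, 0.6 N/m, two modes
model = default_approach_model()          # 10 GPa substrate + solvation
curve = simulate_approach(cant, model, OperatingSetpoint(1.2), n_points=200)
z0 = detect_contact_origin(curve)         # hard-contact origin of the z scale
z_e, f_e = first_precontact_maximum(curve, z0)
print(f"solvation elbow: {f_e:.1f} pN at z = {z_e - z0:.2f} nm above contact")
print(f"frequency shift spans {curve.frequency_shift.min():.0f} .. "
      f"{curve.frequency_shift.max():.0f} Hz")
```

prints

```
solvation elbow: 20.0 pN at z = 0.40 nm above contact
frequency shift spans -1197 .. 4331 Hz
```

i.e. the tip feels the ordered liquid layers at ~20 pN just before
mechanical contact — the gentle force scale at which virus imaging
operates. A two-virus scene shows the channel separation:

```python
import numpy as np
from fmafm import make_substrate, place_virus, raster_scan, ForceModel
from fmafm.samples import mvm_particle
from fmafm.scan import crosstalk_check

field = make_substrate((64, 64), 1.0)
field = place_virus(field, mvm_particle("fivefold", (32, 18)))   # 0.6 N/m
field = place_virus(field, mvm_particle("threefold", (32, 46)))  # 0.8 N/m
img = raster_scan(field, cant, ForceModel(), OperatingSetpoint(1.0, 2000.0))
rep = crosstalk_check(img, field.material_index == 1, field.material_index == 2)
print(f"heights {rep.height_1:.1f} / {rep.height_2:.1f} nm, "
      f"drive {rep.drive_1:.3f} / {rep.drive_2:.3f}")
```

```
heights 24.5 / 24.6 nm, drive 1.126 / 1.128
```

Both 25 nm particles image at the same height (no cross-talk into
topography) while the stiffer threefold-oriented particle needs more
drive; the substrate (1.213) needs more than either.

## Command line

`fmafm` exposes the stages as subcommands — `force-curve`, `steady-state`,
`track`, `approach`, `map-ea`, `map-ev`, `make-sample`, `scan`, `dilate` —
plus `reproduce-paper`, which chains the canonical pipeline (approach
curve, both drive-signal parameter maps, the adhesion-patch and two-virus
scenes) and writes a summary report with pass/fail checks; its exit status
reflects the checks. All outputs are plain CSV/ASCII grids stamped with
the configuration hash; `--config` takes a strict-schema YAML file.

```sh
fmafm reproduce-paper --outdir out/
```

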