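# Methods

## The physical question

In frequency-modulation AFM the cantilever is kept oscillating at its
resonance; the tip–sample force gradient shifts that resonance
(frequency-shift channel, used for topography), and a second loop adjusts
the excitation so the oscillation amplitude stays constant. In vacuum the
required drive tracks only nonconservative tip–sample losses, which is why
the drive channel is traditionally called the "dissipation" channel. In
liquid, where cantilever quality factors are of order unity, the drive
channel also responds to purely *conservative* sample properties: the
nonlinear tip–sample force distorts the oscillation, pumping energy into
higher harmonics and higher eigenmodes, and the surrounding liquid
dissipates that energy. The drive loop must supply it, so stiffness and
adhesion contrast appear in the drive map even with zero tip–sample
dissipation. This package simulates that mechanism end to end, down to
virtual scans of virus particles whose stiffness depends on which symmetry
axis faces the tip.

## Cantilever model

The probe is reduced to point-mass eigenmodes sharing the tip:

    m_i q_i'' + c_i q_i' + k_i q_i = F_drive(t) + F_ts(gap, gap_rate),
    d = Σ q_i,  gap = z + d,

with m_i = k_i/ω_i², c_i = k_i/(ω_i Q_i). The default liquid preset has two
modes with the Euler–Bernoulli rectangular-lever ratios f₂/f₁ = 6.27,
k₂/k₁ = 39.4, and f₁ = 19 kHz, k₁ = 0.6 N/m, Q₁ = 2, Q₂ = 5 — matching the
soft probes used for imaging small viruses in buffer. Two modes are the
minimum that exhibits inter-mode energy transfer; a third mode is available
in the preset. Thermal noise is excluded: every simulated observable is a
deterministic steady state.

### Steady-state solver

The periodic steady state is computed by **harmonic balance** (spectral
collocation with alternating frequency/time evaluation of the nonlinear
force): each modal coordinate is expanded in N_h = 12 harmonics of the
drive (DC included), the force is evaluated on 512 uniform samples per
cycle, and the modal balance residual is driven below 10⁻⁷ (in units of
nm, i.e. scaled by k₁) with a damped-Newton root finder. This gives exact
periodicity — Fourier analysis without leakage, per-harmonic energy
bookkeeping that closes to solver precision, and bit-identical results for
identical inputs — at ~10–20 ms per solve, which is what makes per-pixel
feedback solves and dense approach sweeps affordable. A brute-force
time-domain integrator (LSODA, rtol 10⁻⁸, cycle-by-cycle convergence test
at 10⁻⁴ relative, 20–2000 cycles) implements the same equations
independently and is used as the oracle in the linear-regime tests; on the
configurations where both run, amplitude and phase agree to ~10⁻³.

Energy accounting per cycle: drive input E_in = πF_d A sin φ (a pure-tone
drive works only against the fundamental), medium loss per mode and
harmonic c_i (nω)² |q_i,n|² T/2, and tip–sample loss from the truncated
force spectrum, so E_in = E_medium + E_ts identically at a converged
solution. For any conservative force law the tip–sample term vanishes
(state function on a closed cycle), which is the mechanistic premise the
package exists to demonstrate.

### FM feedback

The three instrument loops (resonance tracking, amplitude-gain control, z
feedback) are resolved as **quasi-static fixed points**, not time-domain
PLL/AGC transients: images and parameter maps are steady-state
observables. Tracking appends two conditions to the harmonic-balance
system — the complex fundamental amplitude must equal −i·A_set (amplitude
A_set at a π/2 lag) — and solves coefficients, drive frequency and drive
force jointly; the frequency unknown is scaled by the resonance half-width
so the Jacobian stays conditioned at high Q. Frequency shifts are measured
from the *tracked free resonance* of the full multimode system (the π/2
crossing of the summed free response), which sits slightly above f₁
because of the higher mode's off-resonant tail. The drive amplitude is
reported normalized to its free value.

z feedback walks inward from the far field with warm-started tracking,
brackets the outermost crossing of the frequency-shift setpoint (the
physical approach direction resolves non-monotonic Δf(z) from solvation
ringing), and refines it by bisection to 10⁻⁴ nm.

## Tip–sample force model

Composite, in pN/nm units internally:

- **Contact**: Hertz sphere-on-flat (4/3)E*√R δ^{3/2} for
  modulus-parameterized surfaces, or a linear spring k_v·δ for virus
  capsids — thin-shell nanoindentation is linear at small indentation and
  capsid stiffness is quoted in N/m (0.6 / 0.8 N/m for the fivefold /
  threefold orientation of the 25 nm parvovirus particle).
- **Adhesion**: classical DMT — constant −F_adh inside contact, approached
  continuously from outside through a short inverse-square tail (default
  reach 0.2 nm). The continuous form matters numerically: a strict step at
  gap = 0 stalls Newton iterations exactly at grazing incidence.
- **Sample viscosity**: Kelvin–Voigt damping −η√(Rδ)·(dδ/dt), scaled by
  the Hertzian contact radius so it vanishes continuously at touch.
- **Solvation layers**: A_s exp(−u/λ) cos(2πu/p + φ) above the surface,
  clamped at its u = 0 value inside contact. Defaults
  A_s = 635 pN, λ = 0.40 nm, p = 0.55 nm, φ = 0 were calibrated **once**
  so that the default approach simulation (A = 1.2 nm, 0.6 N/m probe)
  shows its dominant pre-contact mean-force maximum at ≈ 20 pN with hard
  contact developing below 100 pN — the printed calibration landmarks of
  the measured curves. Note the attenuation arithmetic: averaging an
  oscillatory force of 0.55 nm period over a 2.4 nm swing suppresses it
  roughly thirtyfold, so the static force amplitude behind a 20 pN
  *cycle-averaged* elbow is several hundred pN at the apex.
- **Long-range van der Waals** (optional, off by default): Hamaker tail
  −HR/6(u+a₀)², clamped inside contact.

Sign convention: repulsion positive; gap < 0 is indentation.

## Approach curves and landmarks

An approach curve tracks resonance at fixed amplitude over a descending z
grid (default 200 points) and records mean force (⟨F_ts⟩ over the cycle),
frequency shift, and normalized drive simultaneously. The hard-contact
origin is found by a deterministic two-line rule: least-squares line
through the steep rise (points above 60% of the curve maximum),
intersected with the baseline level estimated from the flat outer half of
the pre-rise region; this reproduces the graphical "end of the elbow"
convention and returns the ramp start exactly on constructed test curves.
The solvation-elbow landmark is the dominant (largest) local maximum of
the mean force before that origin — with a decaying layered force the ring
maxima grow monotonically on approach, so the dominant crest is the
physically meaningful "first" maximum; the outermost strict local maximum
would be a sub-pN ripple.

## Parameter maps and scan scenes

Maps and scans evaluate every cell/pixel at the z that holds a **common
frequency-shift setpoint** (constant-Δf surface tracking, as recorded
during scanning). These stages use contact-only force models; the
solvation term is the approach-curve calibration. The default operating
point — A = 1 nm, Δf_set = 2 kHz — was chosen once so the mean imaging
force across the default modulus grid lands inside the 40–80 pN window
used experimentally (measured 68.6–77.1 pN). Default grids: modulus
log-spaced 100 MPa–10 GPa (below ~50 MPa the setpoint is unreachable
within a safe indentation at this amplitude), adhesion 0–200 pN, viscosity
log-spaced 0.01–1000 Pa·s. Pixels sharing an effective material are
physically identical under the per-pixel independent-solve contract, so
the scanner solves each distinct material once; topography is referenced
to the dominant material at the lowest surface level (the substrate
plane), as in leveled AFM images.

Measured behaviour at the default operating point: drive is monotone
increasing in modulus and non-decreasing in adhesion; it is invariant to
viscosity within 0.6% over five decades on stiff cells, while the
softest-modulus/highest-viscosity corner departs by tens of percent —
there, and only there, the channel really is a dissipation channel. On the
conservative line (zero adhesion, zero viscosity) the drive varies by ~8%
across the modulus grid while the tip–sample dissipation fraction stays
below 10⁻⁵: conservative-contrast in the "dissipation" channel.

### A limitation worth stating plainly

Within this reduced model the conservative drive contrast does **not**
shrink when the damping is made vacuum-like (all Q ×100). At fixed
amplitude the normalized drive is 1 + E_harm/E_fund; E_fund scales
linearly with the damping while every harmonic response amplitude can only
grow as damping falls, so the ratio is non-decreasing as Q rises — for
*any* linear-damping modal model. Numerically, the softest cells show the
contrast essentially unchanged (+0.1%), and the stiff cells lose their
quasi-static tapping branch altogether at Q ×100 because the 6th drive
harmonic crosses the then-razor-sharp second-mode resonance. The
experimentally motivated expectation that low Q *enhances* the conversion
of conservative interactions into drive contrast therefore involves
physics outside this model class (gap-dependent squeeze-film
hydrodynamics, continuum beam modes, detector dynamics). The
corresponding acceptance check is left failing by design rather than
weakened.

## Synthetic samples

Scenes are upper-envelope height maps with congruent per-pixel material
identity: flat substrates (rigid Hertz, E* = 10 GPa default) with
rectangular adhesion patches; 25 nm icosahedral particles rendered as
resting spheres (optional cosine capsomer corrugation, ~1 nm, off by
default) carrying orientation-dependent linear stiffness; and a prolate
55 × 45 nm phage head lying on its side with a cylindrical tail and collar
ring whose dimensions (tail 20 × 4 nm radius, collar 7 nm radius) are
config-exposed defaults with no claimed fidelity. All randomness (substrate
roughness) sits behind one explicit seed. Height maps round-trip through
ESRI-style ASCII grids and bare CSV matrices.

What the generator does *not* emulate: capsid faceting and true
icosahedral symmetry, particle deformation or displacement under load,
scan-direction feedback lag, tip contamination, thermal drift. Passing
scan tests therefore demonstrate the steady-state contrast mechanism and
channel separation, not instrument-limited image quality on real samples.

## Tip dilation

AFM image formation as grayscale max-plus dilation of the height map by
the apex-referenced tip (sphere or paraboloid; 0.2 nm default radius for
model-surface comparison), with reflect padding by default ("shrink",
−∞ padding, optional). The fast scipy.ndimage kernels are held to an
exact brute-force max-plus oracle on all test grids; erosion is the
adjoint, giving the standard opening inequalities used as tests. On
half-nanometre pixels a 0.2 nm tip's footprint collapses to the apex and
dilation is the identity, which bounds its sub-pixel effect exactly.

## Numerical choices and degenerate inputs

- Harmonic truncation N_h = 12 (N_t = 512 samples) resolves the force
  spectrum well past the second mode (harmonic 6–7); raising N_h to 24
  changes drive values in the fifth digit.
- Steady-state residual tolerance 10⁻⁷ nm; tracker acceptance |φ − π/2| <
  10⁻³ rad and |A − A_set|/A_set < 10⁻³; z feedback bisection to 10⁻⁴ nm.
- Indentation beyond 5 nm raises a contact-overload error (tip crash).
- Unreachable map cells are reported missing (NaN), never interpolated;
  failed scan pixels are masked.
- Zero-setpoint z feedback returns the far-field bracket start (the
  outermost point trivially satisfies Δf = 0).
- Ties in the topographic reference are broken toward the larger pixel
  count (stable sort).

## Problem sizes

Default test/pipeline sizes: 200-point approach curves, 12 × 9 parameter
maps, 64 × 64 scan scenes (material deduplication makes scene cost
independent of pixel count), morphology oracles up to 64 × 64. These are
the sizes the reported numbers were produced at; all are config-exposed.
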