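"""Synthetic sample scenes: height maps plus local mechanical identity.

The imaging scenarios emulated here are the ones used to demonstrate that
the FM-AFM drive channel maps conservative mechanical properties:

* a flat substrate with patches of different adhesion but identical
  stiffness (adhesion-contrast control scene);
* icosahedral virus-like particles, 25 nm in diameter, whose linear
  stiffness depends on which symmetry axis faces the tip (0.6 N/m on the
  fivefold axis, 0.8 N/m on the threefold axis for full parvovirus MVM
  capsids);
* a prolate phi29-like bacteriophage head (~55 nm x 45 nm) lying on its
  side, with a cylindrical tail and a collar ring.

A scene is a ``SampleField``: congruent 2-D grids of height, material
index, adhesion and viscosity, plus a material table. Heights are upper
envelopes (what a probe apex can reach), so overhangs are never generated.
Height maps round-trip through plain-text formats (ESRI ASCII grid or bare
CSV matrix) for exchange with external tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .forces import ContactMaterial, default_substrate_material, LINEAR

FIVEFOLD_SPRING = 0.6   # N/m, fivefold symmetry axis up
THREEFOLD_SPRING = 0.8  # N/m, threefold symmetry axis up


class ParseError(ValueError):
    """Malformed height-map file; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class SampleField:
    """Co-registered sample property grids over a scan area."""

    pixel_size: float                      # nm per pixel
    height: np.ndarray                     # nm, >= 0
    material_index: np.ndarray             # int index into ``materials``
    materials: dict                        # index -> ContactMaterial
    adhesion: np.ndarray                   # pN, per-pixel override
    viscosity: np.ndarray                  # Pa*s, per-pixel override

    def __post_init__(self):
        shapes = {self.height.shape, self.material_index.shape,
                  self.adhesion.shape, self.viscosity.shape}
        if len(shapes) != 1:
            raise ValueError("property grids must be congruent")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if np.any(self.height < 0):
            raise ValueError("heights must be >= 0")

    @property
    def shape(self):
        return self.height.shape

    def material_at(self, i: int, j: int) -> ContactMaterial:
        """Effective material under pixel (i, j): the referenced base
        material with the per-pixel adhesion/viscosity applied."""
        base = self.materials[int(self.material_index[i, j])]
        return replace(base, adhesion_force=float(self.adhesion[i, j]),
                       viscosity=float(self.viscosity[i, j]))


def make_substrate(size, pixel_size: float = 1.0,
                   adhesion_patches: Sequence = (),
                   substrate: Optional[ContactMaterial] = None,
                   roughness: float = 0.0,
                   seed: Optional[int] = None) -> SampleField:
    """Flat rigid substrate, optionally with rectangular adhesion patches.

    ``adhesion_patches`` is a sequence of ``((i0, i1, j0, j1), force_pN)``
    half-open pixel rectangles; overlapping patches resolve last-wins with
    a warning. ``roughness`` adds seeded Gaussian height noise (nm rms).
    """
    if np.isscalar(size):
        size = (int(size), int(size))
    ny, nx = size
    if substrate is None:
        substrate = default_substrate_material()
    height = np.zeros((ny, nx))
    if roughness > 0:
        rng = np.random.default_rng(seed)
        height = np.abs(rng.normal(0.0, roughness, (ny, nx)))
    adhesion = np.full((ny, nx), substrate.adhesion_force)
    viscosity = np.full((ny, nx), substrate.viscosity)
    covered = np.zeros((ny, nx), dtype=bool)
    for (i0, i1, j0, j1), fadh in adhesion_patches:
        if not (0 <= i0 <= i1 <= ny and 0 <= j0 <= j1 <= nx):
            raise ValueError(f"patch {(i0, i1, j0, j1)} outside {size}")
        if covered[i0:i1, j0:j1].any():
            warnings.warn("overlapping adhesion patches: last wins",
                          stacklevel=2)
        adhesion[i0:i1, j0:j1] = fadh
        covered[i0:i1, j0:j1] = True
    return SampleField(
        pixel_size=pixel_size,
        height=height,
        material_index=np.zeros((ny, nx), dtype=int),
        materials={0: substrate},
        adhesion=adhesion,
        viscosity=viscosity,
    )


@dataclass(frozen=True)
class VirusSpec:
    """Geometry, orientation and stiffness of one particle.

    ``shape`` is "icosahedral" (``diameter`` nm) or "prolate_tailed"
    (``length`` x ``equatorial_diameter`` nm, lying on its side with a tail
    along +x). ``spring_constant`` (N/m) is the orientation-dependent
    linear nanoindentation stiffness. ``center`` is (row, col) in pixels.
    """

    shape: str = "icosahedral"
    diameter: float = 25.0
    length: float = 55.0
    equatorial_diameter: float = 45.0
    orientation: str = "fivefold"
    spring_constant: float = FIVEFOLD_SPRING
    center: tuple = (0, 0)
    adhesion_force: float = 0.0
    viscosity: float = 0.0
    capsomer_amplitude: float = 0.0   # nm; optional corrugation bumps
    capsomer_period: float = 7.0      # nm
    tail_length: float = 20.0
    tail_radius: float = 4.0
    collar_radius: float = 7.0
    collar_length: float = 4.0

    def __post_init__(self):
        if self.shape not in ("icosahedral", "prolate_tailed"):
            raise ValueError(f"unknown particle shape {self.shape!r}")
        if not self.spring_constant > 0:
            raise ValueError("spring_constant must be > 0")
        if self.shape == "icosahedral" and not self.diameter > 0:
            raise ValueError("diameter must be > 0")


def mvm_particle(orientation: str, center) -> VirusSpec:
    """25 nm icosahedral particle with the orientation-matched stiffness."""
    k = {"fivefold": FIVEFOLD_SPRING, "threefold": THREEFOLD_SPRING,
         "twofold": 0.7}[orientation]
    return VirusSpec(shape="icosahedral", diameter=25.0,
                     orientation=orientation, spring_constant=k,
                     center=tuple(center))


def phi29_particle(center, spring_constant: float = 0.3) -> VirusSpec:
    """Prolate phi29-like head (55 x 45 nm) with collar and tail."""
    return VirusSpec(shape="prolate_tailed", length=55.0,
                     equatorial_diameter=45.0, spring_constant=spring_constant,
                     center=tuple(center))


def _icosahedral_height(spec: VirusSpec, rr: np.ndarray) -> np.ndarray:
    """Upper envelope of a sphere of the capsid diameter resting on the
    substrate; optional cosine capsomer corrugation."""
    radius = spec.diameter / 2.0
    h = np.zeros_like(rr)
    inside = rr < radius
    h[inside] = radius + np.sqrt(radius**2 - rr[inside] ** 2)
    if spec.capsomer_amplitude > 0:
        bump = 0.5 * spec.capsomer_amplitude * (
            np.cos(2 * np.pi * rr / spec.capsomer_period) + 1.0)
        h[inside] += bump[inside] * (h[inside] / spec.diameter)
    return h


def _prolate_height(spec: VirusSpec, dx: np.ndarray, dy: np.ndarray):
    """Upper envelope of a prolate head lying along x, plus tail/collar."""
    a = spec.length / 2.0
    b = spec.equatorial_diameter / 2.0
    s = 1.0 - (dx / a) ** 2 - (dy / b) ** 2
    head = np.where(s > 0, b * (1.0 + np.sqrt(np.maximum(s, 0.0))), 0.0)
    # tail: lying cylinder along +x from the head end
    tx0, tx1 = a, a + spec.tail_length
    in_tail = (dx >= tx0) & (dx <= tx1) & (np.abs(dy) < spec.tail_radius)
    tail = np.where(in_tail, spec.tail_radius
                    + np.sqrt(np.maximum(spec.tail_radius**2 - dy**2, 0.0)), 0.0)
    # collar ring: slightly wider short cylinder at the head-tail junction
    cx0, cx1 = a - spec.collar_length / 2.0, a + spec.collar_length / 2.0
    in_collar = (dx >= cx0) & (dx <= cx1) & (np.abs(dy) < spec.collar_radius)
    collar = np.where(in_collar, spec.collar_radius
                      + np.sqrt(np.maximum(spec.collar_radius**2 - dy**2, 0.0)),
                      0.0)
    return np.maximum(head, np.maximum(tail, collar))


def place_virus(field: SampleField, spec: VirusSpec) -> SampleField:
    """Return a new field with the particle's height and material added.

    Particle pixels (height above substrate) acquire a linear-spring
    material with the particle's stiffness, adhesion and viscosity; the
    particle height replaces the substrate height where it is taller.
    """
    ny, nx = field.shape
    ci, cj = spec.center
    p = field.pixel_size
    ii, jj = np.mgrid[0:ny, 0:nx]
    dy = (ii - ci) * p
    dx = (jj - cj) * p
    if spec.shape == "icosahedral":
        rr = np.hypot(dx, dy)
        h = _icosahedral_height(spec, rr)
        extent = spec.diameter / 2.0
        if (ci * p < extent or cj * p < extent
                or (ny - 1 - ci) * p < extent or (nx - 1 - cj) * p < extent):
            raise ValueError("particle does not fit inside the field")
    else:
        h = _prolate_height(spec, dx, dy)
        if h[0, :].any() or h[-1, :].any() or h[:, 0].any() or h[:, -1].any():
            raise ValueError("particle does not fit inside the field")
    on_particle = h > field.height
    material = ContactMaterial(
        elastic_modulus=0.0, adhesion_force=spec.adhesion_force,
        viscosity=spec.viscosity, contact_law=LINEAR,
        spring_constant=spec.spring_constant)
    new_index = max(field.materials) + 1
    materials = dict(field.materials)
    materials[new_index] = material
    height = np.where(on_particle, h, field.height)
    mat_idx = np.where(on_particle, new_index, field.material_index)
    adhesion = np.where(on_particle, spec.adhesion_force, field.adhesion)
    viscosity = np.where(on_particle, spec.viscosity, field.viscosity)
    return SampleField(pixel_size=field.pixel_size, height=height,
                       material_index=mat_idx, materials=materials,
                       adhesion=adhesion, viscosity=viscosity)


# --- plain-text height-map formats ------------------------------------------

ASCII_GRID = "ascii_grid"
CSV_MATRIX = "csv"


def write_heightmap(height: np.ndarray, path, fmt: str = ASCII_GRID,
                    pixel_size: float = 1.0, precision: int = 6) -> None:
    """Write a height grid as an ESRI-style ASCII grid or bare CSV matrix."""
    height = np.asarray(height, dtype=float)
    if fmt == ASCII_GRID:
        with open(path, "w") as fh:
            fh.write(f"ncols {height.shape[1]}\n")
            fh.write(f"nrows {height.shape[0]}\n")
            fh.write("xllcorner 0.0\n")
            fh.write("yllcorner 0.0\n")
            fh.write(f"cellsize {pixel_size!r}\n")
            fh.write("NODATA_value -9999\n")
            np.savetxt(fh, height, fmt=f"%.{precision}g")
    elif fmt == CSV_MATRIX:
        np.savetxt(path, height, fmt=f"%.{precision}g", delimiter=",")
    else:
        raise ValueError(f"unknown height-map format {fmt!r}")


def read_heightmap(path, fmt: str = ASCII_GRID):
    """Read a height grid; returns ``(height, pixel_size)``.

    CSV matrices carry no pixel size and return 1.0.
    """
    if fmt == CSV_MATRIX:
        try:
            h = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as err:
            raise ParseError(str(err)) from err
        return h, 1.0
    if fmt != ASCII_GRID:
        raise ValueError(f"unknown height-map format {fmt!r}")
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for ln, line in enumerate(lines, start=1):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as err:
                raise ParseError(f"bad header value {parts[1]!r}", ln) from err
            n_header = ln
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ParseError(f"missing required header field {key!r}", n_header)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    rows = []
    for ln, line in enumerate(lines[n_header:], start=n_header + 1):
        if not line.strip():
            continue
        vals = line.split()
        if len(vals) != ncols:
            raise ParseError(
                f"expected {ncols} columns, found {len(vals)}", ln)
        try:
            rows.append([float(v) for v in vals])
        except ValueError as err:
            raise ParseError(str(err), ln) from err
    if len(rows) != nrows:
        raise ParseError(f"expected {nrows} rows, found {len(rows)}",
                         len(lines))
    return np.array(rows), float(header["cellsize"])
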