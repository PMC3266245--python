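"""Virtual raster scanning: paired topography and drive-amplitude images.

Every pixel of a scan is an independent steady-state z-feedback solve: the
controller finds the piezo elongation that holds the frequency-shift
setpoint for the local material, the topography records that elongation
referenced to the local surface height, and the drive map records the
normalized drive amplitude at the same instant -- the two channels are
"acquired simultaneously" exactly as in the instrument.

Because each pixel is solved independently of scan order (no feedback lag,
no scan-direction dynamics), pixels sharing the same effective material are
physically identical; the scanner solves each distinct material once and
broadcasts the result, which makes virus-scene scans cheap at any image
size without changing the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .control import (OperatingSetpoint, ResonanceTracker, z_feedback_solve,
                      UnreachableSetpointError, TrackingFailureError)
from .dynamics import CantileverConfig
from .forces import ForceModel
from .samples import SampleField


@dataclass
class ScanImage:
    """Paired topography / drive images with a failed-pixel mask."""

    pixel_size: float
    topography: np.ndarray        # nm, substrate-referenced
    drive_map: np.ndarray         # normalized drive amplitude
    failed_pixels: np.ndarray     # bool mask; failed pixels hold NaN
    setpoint: OperatingSetpoint
    meta: dict = field(default_factory=dict)


def raster_scan(field: SampleField, cantilever: CantileverConfig,
                model_base: ForceModel, setpoint: OperatingSetpoint,
                **tracker_kwargs) -> ScanImage:
    """Scan a sample field at constant frequency shift.

    Per pixel: resolve the local effective material, run the z feedback,
    and record ``height + solved_z`` (referenced so the dominant substrate
    material sits at 0) plus the normalized drive. Pixels whose setpoint is
    unreachable are masked, never interpolated.
    """
    ny, nx = field.shape
    # group pixels by effective material (same key -> identical physics)
    key_of = {}       # key -> group id
    first_pixel = []  # group id -> a representative pixel
    group = np.empty((ny, nx), dtype=int)
    counts = []
    for i in range(ny):
        for j in range(nx):
            key = (int(field.material_index[i, j]),
                   float(field.adhesion[i, j]),
                   float(field.viscosity[i, j]))
            gid = key_of.get(key)
            if gid is None:
                gid = len(first_pixel)
                key_of[key] = gid
                first_pixel.append((i, j))
                counts.append(0)
            group[i, j] = gid
            counts[gid] += 1

    tracker = ResonanceTracker(cantilever, setpoint, **tracker_kwargs)
    n_groups = len(first_pixel)
    z_for = np.full(n_groups, np.nan)
    drive_for = np.full(n_groups, np.nan)
    stats = {"n_materials": n_groups, "failed_materials": 0}
    for gid, (i, j) in enumerate(first_pixel):
        material = field.material_at(i, j)
        model = model_base.with_material(material)
        try:
            z, state = z_feedback_solve(cantilever, model, setpoint,
                                        tracker=tracker)
            z_for[gid] = z
            drive_for[gid] = state.drive_amplitude
        except (UnreachableSetpointError, TrackingFailureError):
            stats["failed_materials"] += 1

    z_img = z_for[group]
    drive = drive_for[group]
    raw_topo = field.height + z_img
    # reference: the dominant material on the lowest surface level (the
    # substrate plane) defines topographic zero, as in leveled AFM images
    low = field.height <= field.height.min() + 0.1
    low_counts = np.bincount(group[low].ravel(), minlength=n_groups)
    order = np.argsort(-low_counts, kind="stable")
    ref = next((g for g in order
                if low_counts[g] > 0 and np.isfinite(z_for[g])), None)
    if ref is None:  # no solvable substrate-level pixel: fall back to area
        order = np.argsort(-np.asarray(counts), kind="stable")
        ref = next((g for g in order if np.isfinite(z_for[g])), None)
    if ref is None:
        raise TrackingFailureError("every material in the scene failed")
    topo = raw_topo - z_for[ref]
    failed = ~np.isfinite(z_img)
    return ScanImage(
        pixel_size=field.pixel_size,
        topography=topo,
        drive_map=drive,
        failed_pixels=failed,
        setpoint=setpoint,
        meta={"reference_z": z_for[ref], "solver": stats,
              "f_free": tracker.f_free},
    )


def extract_profile(image: ScanImage, start, end) -> tuple:
    """Height profile along a segment, bilinearly sampled at pixel pitch.

    ``start``/``end`` are (row, col) pixel coordinates; returns
    ``(distance_nm, height_nm)`` arrays.
    """
    ny, nx = image.topography.shape
    for pt in (start, end):
        if not (0 <= pt[0] <= ny - 1 and 0 <= pt[1] <= nx - 1):
            raise ValueError(f"profile endpoint {pt} out of bounds")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    length_px = float(np.hypot(*(end - start)))
    n = max(2, int(np.ceil(length_px)) + 1)
    t = np.linspace(0.0, 1.0, n)
    coords = start[:, None] + (end - start)[:, None] * t[None, :]
    heights = map_coordinates(image.topography, coords, order=1,
                              mode="nearest")
    return t * length_px * image.pixel_size, heights


@dataclass(frozen=True)
class CrosstalkReport:
    """Topography/composition cross-talk figures for two particle regions."""

    height_1: float
    height_2: float
    height_difference: float          # |max1 - max2| in nm
    relative_height_difference: float  # vs the taller particle
    drive_1: float
    drive_2: float
    drive_contrast_ratio: float       # mean drive region2 / region1
    passed: bool


def crosstalk_check(image: ScanImage, mask1: np.ndarray, mask2: np.ndarray,
                    height_rtol: float = 0.05,
                    drive_ratio_threshold: float = 1.0) -> CrosstalkReport:
    """Quantify the absence of cross-talk between channels.

    Passes when the two regions have equal topographic maxima within
    ``height_rtol`` while their mean drive signals differ (ratio beyond
    ``drive_ratio_threshold``): composition contrast without height
    contrast.
    """
    mask1 = np.asarray(mask1, dtype=bool)
    mask2 = np.asarray(mask2, dtype=bool)
    if not mask1.any() or not mask2.any():
        raise ValueError("region masks must be non-empty")
    if (mask1 & mask2).any():
        raise ValueError("region masks must be disjoint")
    h1 = float(np.nanmax(image.topography[mask1]))
    h2 = float(np.nanmax(image.topography[mask2]))
    d1 = float(np.nanmean(image.drive_map[mask1]))
    d2 = float(np.nanmean(image.drive_map[mask2]))
    hdiff = abs(h1 - h2)
    rel = hdiff / max(h1, h2)
    ratio = d2 / d1
    passed = rel <= height_rtol and (ratio > drive_ratio_threshold
                                     or ratio < 1.0 / drive_ratio_threshold)
    return CrosstalkReport(height_1=h1, height_2=h2, height_difference=hdiff,
                           relative_height_difference=rel,
                           drive_1=d1, drive_2=d2, drive_contrast_ratio=ratio,
                           passed=passed)
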