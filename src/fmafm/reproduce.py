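"""End-to-end reproduction of the headline simulated findings.

Chains the pipeline stages at desk scale and evaluates the checks that
summarize what the drive-amplitude ("dissipation") channel does in liquid:

* approach-curve calibration landmarks: ~20 pN solvation elbow, hard
  contact below 100 pN, sub-80 pN force while imaging at a 30 Hz shift;
* conservative drive contrast: the drive varies across a modulus sweep
  with zero adhesion, zero viscosity and negligible tip-sample dissipation;
* monotonicity/invariance: drive non-decreasing in adhesion, increasing in
  modulus at low viscosity, viscosity-invariant outside the soft/viscous
  corner;
* scan scenes: equal particle heights with stiffness-ordered drive
  contrast (no topography/composition cross-talk), and adhesion-patch
  drive contrast on a flat substrate.

Every quantity reported is computed by the run itself.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .approach import (detect_contact_origin, first_precontact_maximum,
                       force_at_setpoint, simulate_approach)
from .config import RunConfig, provenance_header
from .control import OperatingSetpoint
from .maps import (DEFAULT_MAP_SETPOINT_SHIFT, conservative_contrast,
                   monotonicity_report, sweep_drive_vs_modulus_adhesion,
                   sweep_drive_vs_modulus_viscosity)
from .samples import make_substrate, mvm_particle, place_virus, write_heightmap
from .scan import crosstalk_check, raster_scan


def _check(name, passed, value, detail=""):
    return {"name": name, "passed": bool(passed), "value": value,
            "detail": detail}


def run_reproduction(cfg: RunConfig, out: Path, fast: bool = False) -> dict:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    cant = cfg.cantilever()
    tracker_kw = cfg.tracker_options()
    checks = []

    # --- stage 1: approach curves -------------------------------------------
    model = cfg.force_model(with_default_solvation=True)
    n_app = 120 if fast else 200
    curve = simulate_approach(cant, model, OperatingSetpoint(1.2),
                              n_points=n_app, **tracker_kw)
    z0 = detect_contact_origin(curve)
    _, elbow = first_precontact_maximum(curve, z0)
    f_origin = float(np.interp(z0, curve.z[::-1], curve.mean_force[::-1]))
    with open(out / "approach.csv", "w") as fh:
        fh.write(provenance_header(cfg, f"z_origin_raw={z0:.5f}") + "\n")
        fh.write("z_nm,mean_force_pN,freq_shift_Hz,drive_norm\n")
        for row in zip(curve.z - z0, curve.mean_force, curve.frequency_shift,
                       curve.drive_amplitude):
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")
    checks.append(_check("solvation_elbow_force_20pN",
                         15.0 <= elbow <= 25.0, elbow,
                         "pre-contact mean-force maximum, pN"))
    checks.append(_check("contact_origin_force_below_100pN",
                         f_origin < 100.0, f_origin,
                         "mean force at detected contact origin, pN"))

    curve1 = simulate_approach(cant, model, OperatingSetpoint(1.0),
                               n_points=n_app, **tracker_kw)
    f_30 = force_at_setpoint(curve1, 30.0)
    checks.append(_check("imaging_force_at_30Hz_below_80pN",
                         f_30 <= 80.0, f_30,
                         "mean force at 30 Hz setpoint, A=1 nm, pN"))

    # --- stage 2: conservative contrast + parameter maps --------------------
    base = cfg.force_model()
    sw = cfg.section("sweep")
    ne, na = (5, 4) if fast else (8, 5)
    e_grid = np.asarray(sw.get("e_grid", np.logspace(8, 10, ne)))
    fadh_grid = np.asarray(sw.get("fadh_grid", np.linspace(0, 200, na)))
    eta_grid = np.asarray(sw.get("eta_grid", np.logspace(-2, 3, na + 1)))
    sp_map = cfg.setpoint(default_amplitude=1.0,
                          default_shift=DEFAULT_MAP_SETPOINT_SHIFT)

    rep = conservative_contrast(cant, base, e_grid=e_grid, setpoint=sp_map,
                                **tracker_kw)
    checks.append(_check("conservative_drive_contrast_gt_5pct",
                         rep.drive_ratio > 1.05
                         and rep.max_tipsample_fraction < 1e-3,
                         rep.drive_ratio,
                         f"max tip-sample fraction "
                         f"{rep.max_tipsample_fraction:.2e}"))

    m_ea = sweep_drive_vs_modulus_adhesion(cant, base, e_grid=e_grid,
                                           fadh_grid=fadh_grid,
                                           setpoint=sp_map, **tracker_kw)
    mono_adh = monotonicity_report(m_ea, axis=1)
    checks.append(_check("drive_nondecreasing_in_adhesion",
                         mono_adh.passed, mono_adh.monotone_fraction))

    m_ev = sweep_drive_vs_modulus_viscosity(cant, base, e_grid=e_grid,
                                            eta_grid=eta_grid,
                                            setpoint=sp_map, **tracker_kw)
    # modulus monotonicity judged at low viscosity (first half of the grid)
    low_eta = m_ev.values[:, :max(1, len(eta_grid) // 2)]
    import dataclasses
    sub = dataclasses.replace(m_ev, values=low_eta,
                              tipsample_fraction=m_ev.tipsample_fraction[:, :low_eta.shape[1]],
                              z_solved=m_ev.z_solved[:, :low_eta.shape[1]],
                              axis2_grid=m_ev.axis2_grid[:low_eta.shape[1]])
    mono_e = monotonicity_report(sub, axis=0)
    checks.append(_check("drive_increasing_in_modulus_low_viscosity",
                         mono_e.passed and mono_e.strict_fraction > 0.99,
                         mono_e.strict_fraction))

    # viscosity invariance outside the lowest-E-decade x highest-eta-decade
    e_corner = e_grid <= e_grid.min() * 10.0
    eta_corner = eta_grid >= eta_grid.max() / 10.0
    outside = ~np.logical_and.outer(e_corner, eta_corner)
    variation = []
    for i in range(len(e_grid)):
        row = m_ev.values[i, outside[i]]
        row = row[np.isfinite(row)]
        if len(row) > 1:
            variation.append(row.max() / row.min() - 1.0)
    worst = float(max(variation))
    checks.append(_check("drive_invariant_in_viscosity_outside_corner",
                         worst < 0.10, worst,
                         "max relative drive variation with viscosity"))
    for name, m in (("drive_map_modulus_adhesion", m_ea),
                    ("drive_map_modulus_viscosity", m_ev)):
        with open(out / f"{name}.csv", "w") as fh:
            fh.write(provenance_header(cfg) + "\n")
            fh.write(f"# rows: {m.axis1_name}; cols: {m.axis2_name}\n")
            fh.write("," + ",".join(f"{v:.6g}" for v in m.axis2_grid) + "\n")
            for a1, row in zip(m.axis1_grid, m.values):
                fh.write(f"{a1:.6g},"
                         + ",".join(f"{v:.8g}" for v in row) + "\n")

    # --- stage 3: scan scenes ----------------------------------------------
    n_img = 56 if fast else 64  # two 25 nm particles need >= 52 px at 1 nm/px
    field6 = make_substrate((n_img, n_img), 1.0)
    c = n_img // 2
    field6 = place_virus(field6, mvm_particle("fivefold", (c, c - 14)))
    field6 = place_virus(field6, mvm_particle("threefold", (c, c + 14)))
    img6 = raster_scan(field6, cant, base, sp_map, **tracker_kw)
    m1 = field6.material_index == 1
    m2 = field6.material_index == 2
    xt = crosstalk_check(img6, m1, m2)
    sub_mask = field6.material_index == 0
    d_sub = float(np.nanmean(img6.drive_map[sub_mask]))
    ordering = d_sub > xt.drive_2 > xt.drive_1
    checks.append(_check("virus_scene_equal_heights_5pct",
                         xt.relative_height_difference < 0.05,
                         xt.relative_height_difference))
    checks.append(_check("virus_scene_drive_ordering",
                         ordering,
                         [d_sub, xt.drive_2, xt.drive_1],
                         "substrate > threefold (0.8 N/m) > fivefold (0.6)"))
    write_heightmap(img6.topography, out / "virus_scene_topography.asc",
                    pixel_size=1.0)
    write_heightmap(img6.drive_map, out / "virus_scene_drive.asc",
                    pixel_size=1.0)

    n5 = 24 if fast else 32
    field5 = make_substrate((n5, n5), 1.0,
                            adhesion_patches=[((0, n5, 0, n5 // 2), 0.0),
                                              ((0, n5, n5 // 2, n5), 100.0)])
    img5 = raster_scan(field5, cant, base, sp_map, **tracker_kw)
    lo = float(img5.drive_map[:, :n5 // 2].mean())
    hi = float(img5.drive_map[:, n5 // 2:].mean())
    flat = float(np.ptp(img5.topography))
    checks.append(_check("adhesion_scene_flat_topography",
                         flat < 0.5, flat, "topography peak-to-peak, nm"))
    checks.append(_check("adhesion_scene_drive_contrast",
                         hi > lo, [lo, hi],
                         "mean drive on 0 pN vs 100 pN patches"))

    report = {"checks": checks,
              "all_passed": all(c["passed"] for c in checks),
              "config_hash": cfg.hash(), "seed": cfg.seed}
    with open(out / "summary_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
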