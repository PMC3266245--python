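"""Synthetic sample scenes and plain-text height-map round trips."""

import numpy as np
import pytest

from fmafm.forces import LINEAR
from fmafm.samples import (ParseError, SampleField, VirusSpec, make_substrate,
                           mvm_particle, phi29_particle, place_virus,
                           read_heightmap, write_heightmap)


class TestSubstrate:
    def test_uniform_without_patches(self):
        f = make_substrate((16, 20), 1.0)
        assert f.shape == (16, 20)
        assert np.all(f.height == 0.0)
        assert np.all(f.adhesion == f.adhesion[0, 0])
        assert np.all(f.viscosity == f.viscosity[0, 0])
        assert len(f.materials) == 1

    def test_bimodal_adhesion_constant_stiffness(self):
        f = make_substrate((8, 8), 1.0,
                           adhesion_patches=[((0, 8, 0, 4), 0.0),
                                             ((0, 8, 4, 8), 100.0)])
        assert set(np.unique(f.adhesion)) == {0.0, 100.0}
        assert np.all(f.material_index == 0)  # same substrate everywhere

    def test_patch_area_fraction(self):
        n = 20
        f = make_substrate((n, n), 1.0,
                           adhesion_patches=[((0, 10, 0, 20), 75.0)])
        frac = np.mean(f.adhesion == 75.0)
        assert frac == pytest.approx(0.5, abs=1.0 / n)

    def test_overlapping_patches_last_wins_with_warning(self):
        with pytest.warns(UserWarning, match="overlap"):
            f = make_substrate((8, 8), 1.0,
                               adhesion_patches=[((0, 8, 0, 6), 50.0),
                                                 ((0, 8, 4, 8), 90.0)])
        assert np.all(f.adhesion[:, 4:6] == 90.0)

    def test_out_of_bounds_patch_rejected(self):
        with pytest.raises(ValueError):
            make_substrate((8, 8), 1.0, adhesion_patches=[((0, 9, 0, 4), 1.0)])

    def test_seeded_roughness_reproducible(self):
        f1 = make_substrate((12, 12), 1.0, roughness=0.3, seed=7)
        f2 = make_substrate((12, 12), 1.0, roughness=0.3, seed=7)
        f3 = make_substrate((12, 12), 1.0, roughness=0.3, seed=8)
        assert np.array_equal(f1.height, f2.height)
        assert not np.array_equal(f1.height, f3.height)
        assert np.all(f1.height >= 0)


class TestPlaceVirus:
    def test_icosahedral_height_equals_diameter(self):
        f = make_substrate((40, 40), 1.0)
        f = place_virus(f, mvm_particle("fivefold", (20, 20)))
        assert f.height.max() == pytest.approx(25.0, abs=0.05)

    def test_prolate_height_and_footprint(self):
        f = make_substrate((96, 128), 1.0)
        f = place_virus(f, phi29_particle((48, 50)))
        assert f.height.max() == pytest.approx(45.0, abs=0.05)
        cols = np.where(f.height > 0)[1]
        assert np.ptp(cols) >= 55.0  # head plus tail footprint

    def test_orientation_dependent_stiffness_equal_heights(self):
        f = make_substrate((80, 80), 1.0)
        f = place_virus(f, mvm_particle("fivefold", (40, 20)))
        f = place_virus(f, mvm_particle("threefold", (40, 60)))
        h5 = f.height[:, :40].max()
        h3 = f.height[:, 40:].max()
        assert h5 == pytest.approx(h3, abs=1e-9)
        k = sorted(m.spring_constant for m in f.materials.values()
                   if m.contact_law == LINEAR)
        assert k == [0.6, 0.8]

    def test_material_maps_congruent(self):
        f = make_substrate((40, 40), 1.0)
        f = place_virus(f, mvm_particle("threefold", (20, 20)))
        assert f.material_index.shape == f.height.shape
        on = f.material_index == 1
        assert np.all(f.adhesion[~on] == 0.0)
        assert f.material_at(20, 20).spring_constant == 0.8

    def test_out_of_bounds_particle_rejected(self):
        f = make_substrate((20, 20), 1.0)
        with pytest.raises(ValueError):
            place_virus(f, mvm_particle("fivefold", (3, 3)))

    def test_capsomer_bumps_only_raise_interior(self):
        f0 = make_substrate((40, 40), 1.0)
        smooth = place_virus(f0, mvm_particle("fivefold", (20, 20)))
        spec = VirusSpec(diameter=25.0, spring_constant=0.6, center=(20, 20),
                         capsomer_amplitude=1.0)
        bumpy = place_virus(f0, spec)
        assert bumpy.height.max() <= smooth.height.max() + 1.0 + 1e-9
        assert bumpy.height.max() > smooth.height.max()

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            VirusSpec(shape="cubic")
        with pytest.raises(ValueError):
            VirusSpec(spring_constant=0.0)


class TestHeightmapIO:
    def test_ascii_roundtrip(self, tmp_path, rng):
        h = rng.uniform(0, 30, (9, 13))
        p = tmp_path / "h.asc"
        write_heightmap(h, p, pixel_size=0.8, precision=9)
        h2, pixel = read_heightmap(p)
        assert pixel == 0.8
        assert np.allclose(h, h2, rtol=0, atol=1e-6)

    def test_known_matrix_exact(self, tmp_path):
        p = tmp_path / "m.asc"
        p.write_text("ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\n"
                     "cellsize 1.5\nNODATA_value -9999\n1.0 2.0\n3.5 4.25\n")
        h, pixel = read_heightmap(p)
        assert np.array_equal(h, [[1.0, 2.0], [3.5, 4.25]])
        assert pixel == 1.5

    def test_cross_format_identical(self, tmp_path, rng):
        h = rng.uniform(0, 5, (6, 7))
        pa, pc = tmp_path / "h.asc", tmp_path / "h.csv"
        write_heightmap(h, pa, precision=10)
        write_heightmap(h, pc, fmt="csv", precision=10)
        ha, _ = read_heightmap(pa)
        hc, _ = read_heightmap(pc, fmt="csv")
        assert np.array_equal(ha, hc)

    def test_ragged_rows_report_line(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 3\nnrows 2\ncellsize 1\n1 2 3\n4 5\n")
        with pytest.raises(ParseError, match="line 5"):
            read_heightmap(p)

    def test_missing_header_field(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\n1 2\n3 4\n")
        with pytest.raises(ParseError, match="nrows"):
            read_heightmap(p)


def test_field_congruence_enforced():
    with pytest.raises(ValueError):
        SampleField(pixel_size=1.0, height=np.zeros((4, 4)),
                    material_index=np.zeros((4, 4), dtype=int),
                    materials={0: None}, adhesion=np.zeros((4, 5)),
                    viscosity=np.zeros((4, 4)))
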