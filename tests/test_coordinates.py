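"""Reduced-coordinate spaces: dimensionality accounting and realization."""

import numpy as np
import pytest

import glycosurf as g
from glycosurf.coordinates import (conformer_space, adsorption_space,
                                   measure_dihedral, realize_conformer,
                                   realize_adsorption)
from glycosurf.structures import detect_bonds
from .conftest import current_vector


class TestCountDimensions:
    def test_xylose_reduced_ring_is_6d(self, xylose):
        _, ann = xylose
        assert g.count_dimensions(ann, hydroxyls=True, ring_mode="reduced") == 6

    def test_xylotetraose_glycosidic_is_16d(self, xylotetraose):
        _, ann = xylotetraose
        assert g.count_dimensions(ann, hydroxyls=True, glycosidic=True) == 16

    def test_xylotetraose_with_rings_is_24d(self, xylotetraose):
        _, ann = xylotetraose
        assert g.count_dimensions(ann, hydroxyls=True, glycosidic=True,
                                  ring_mode="reduced") == 24

    def test_xylose_full_ring_is_10d(self, xylose):
        _, ann = xylose
        assert g.count_dimensions(ann, hydroxyls=True, ring_mode="full") == 10

    def test_everything_off_is_zero(self, xylotetraose):
        _, ann = xylotetraose
        assert g.count_dimensions(ann, hydroxyls=False) == 0

    def test_additivity(self, xylotetraose):
        _, ann = xylotetraose
        d_oh = g.count_dimensions(ann, hydroxyls=True)
        d_gly = g.count_dimensions(ann, hydroxyls=False, glycosidic=True)
        d_ring = g.count_dimensions(ann, hydroxyls=False, ring_mode="reduced")
        assert g.count_dimensions(ann, hydroxyls=True, glycosidic=True,
                                  ring_mode="reduced") == d_oh + d_gly + d_ring

    def test_bad_ring_mode(self, xylose):
        _, ann = xylose
        with pytest.raises(ValueError):
            g.count_dimensions(ann, ring_mode="bogus")


class TestRealizeConformer:
    def test_identity(self, xylose):
        mol, ann = xylose
        space = conformer_space(ann, mol, ring_mode="reduced")
        out = realize_conformer(mol, space, current_vector(space, mol))
        assert g.kabsch_rmsd(out, mol) < 1e-6

    def test_full_turn_is_identity(self, xylose):
        mol, ann = xylose
        space = conformer_space(ann, mol)
        x = current_vector(space, mol)
        out0 = realize_conformer(mol, space, x)
        x[1] += 2.0 * np.pi
        out1 = realize_conformer(mol, space, x)
        assert g.kabsch_rmsd(out0, out1) < 1e-6

    @pytest.mark.parametrize("target_deg", [60.0, -120.0, 179.0])
    def test_dihedral_set_exactly(self, xylose, target_deg):
        mol, ann = xylose
        space = conformer_space(ann, mol)
        x = current_vector(space, mol)
        x[0] = np.deg2rad(target_deg)
        out = realize_conformer(mol, space, x)
        d = space.variables[0].payload
        assert measure_dihedral(out.positions, d.i, d.j, d.k, d.l) == \
            pytest.approx(np.deg2rad(target_deg), abs=1e-6)

    def test_bond_lengths_preserved(self, xylotetraose):
        mol, ann = xylotetraose
        space = conformer_space(ann, mol, glycosidic=True)
        rng = np.random.default_rng(11)
        x = current_vector(space, mol) + rng.normal(0, 0.5, space.dimension)
        out = realize_conformer(mol, space, x)
        for i, j in detect_bonds(mol):
            d0 = np.linalg.norm(mol.positions[i] - mol.positions[j])
            d1 = np.linalg.norm(out.positions[i] - out.positions[j])
            assert abs(d1 - d0) < 1e-6

    def test_ring_flip_reaches_other_chair(self, xylose):
        mol, ann = xylose
        space = conformer_space(ann, mol, ring_mode="reduced")
        x = current_vector(space, mol)
        x[-2], x[-1] = -x[-2], -x[-1]
        out = realize_conformer(mol, space, x)
        a = ann.rings[0].atoms
        t1 = measure_dihedral(out.positions, a[0], a[1], a[2], a[3])
        t4 = measure_dihedral(out.positions, a[3], a[4], a[5], a[0])
        assert t1 == pytest.approx(x[-2], abs=1e-3)
        assert t4 == pytest.approx(x[-1], abs=1e-3)
        # bond lengths survive the rebuild
        for i, j in detect_bonds(mol):
            d0 = np.linalg.norm(mol.positions[i] - mol.positions[j])
            d1 = np.linalg.norm(out.positions[i] - out.positions[j])
            assert abs(d1 - d0) < 1e-4

    def test_dihedrals_only_change_torsions(self, xylose):
        """Rotating one hydroxyl leaves every other annotated torsion fixed."""
        mol, ann = xylose
        space = conformer_space(ann, mol)
        x = current_vector(space, mol)
        x[2] += 1.0
        out = realize_conformer(mol, space, x)
        for k, v in enumerate(space.variables):
            d = v.payload
            got = measure_dihedral(out.positions, d.i, d.j, d.k, d.l)
            want = x[k] if k == 2 else current_vector(space, mol)[k]
            delta = np.angle(np.exp(1j * (got - want)))
            assert abs(delta) < 1e-6


class TestRealizeAdsorption:
    def test_center_height_unrotated(self, xylose, small_slab):
        mol, _ = xylose
        out = realize_adsorption(mol, small_slab, [0, 0, 5.0, 0, 0, 0])
        ads = out.adsorbate_part()
        assert ads.positions[:, 2].mean() - g.top_layer_z(out) == \
            pytest.approx(5.0, abs=1e-9)
        assert len(out) == len(mol) + len(small_slab)

    def test_gamma_periodicity(self, xylose, small_slab):
        mol, _ = xylose
        x = np.array([0.5, 1.0, 4.0, 0.3, 0.6, 0.9])
        out0 = realize_adsorption(mol, small_slab, x)
        x[5] += 2.0 * np.pi
        out1 = realize_adsorption(mol, small_slab, x)
        np.testing.assert_allclose(out0.positions, out1.positions, atol=1e-9)

    def test_rigidity(self, xylose, small_slab):
        mol, _ = xylose
        rng = np.random.default_rng(3)
        d0 = np.linalg.norm(mol.positions[:, None] - mol.positions[None, :],
                            axis=-1)
        for _ in range(5):
            x = np.concatenate([rng.random(2) * 2, [3 + rng.random() * 4],
                                rng.random(3) * 2 * np.pi])
            ads = realize_adsorption(mol, small_slab, x).adsorbate_part()
            d1 = np.linalg.norm(ads.positions[:, None] - ads.positions[None, :],
                                axis=-1)
            assert np.abs(d1 - d0).max() < 1e-9


class TestSearchSpace:
    def test_wrap_periodic_and_clip(self):
        space = adsorption_space(2.0, 4.0, 3.0, 12.0)
        x = space.wrap(np.array([2.5, -0.5, 2.0, 7.0, 0.5, -0.1]))
        assert x[0] == pytest.approx(0.5)
        assert x[1] == pytest.approx(3.5)
        assert x[2] == pytest.approx(3.0)       # clipped to lower z bound
        assert x[3] == pytest.approx(7.0 - 2 * np.pi)
        assert x[5] == pytest.approx(2 * np.pi - 0.1)

    def test_periodic_distance(self):
        space = adsorption_space(2.0, 4.0)
        d = space.distance(np.array([0.1, 0.0, 5.0, 0.1, 1.0, 6.2]),
                           np.array([1.9, 0.0, 6.0, 6.2, 1.0, 0.1]))
        assert d[0] == pytest.approx(0.2)
        assert d[3] == pytest.approx(2 * np.pi - 6.1, abs=1e-9)

    def test_variable_validation(self):
        with pytest.raises(ValueError):
            g.Variable("x", 1.0, 0.0, False, "dihedral")
        with pytest.raises(ValueError):
            g.Variable("x", 0.0, 1.0, False, "warp_drive")
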