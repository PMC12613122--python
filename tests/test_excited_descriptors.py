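"""Charge-transfer indices, spectroscopic descriptors and record assembly."""

import numpy as np
import pytest

from soqy import (
    ConfigurationSet,
    QCD_COLUMNS,
    assemble_qcd_record,
    becke_grid,
    build_hole_electron,
    centroid_and_sigma,
    compute_state_descriptors,
    geometry_indices,
    mlct_fraction,
    overlap_indices,
    s_orbital,
    spectroscopic_descriptors,
)
from soqy.excited import DescriptorIntermediates
from soqy.units import ANGSTROM_PER_BOHR


def make_fields(separation=4.0, exponent=0.5, level=2):
    centers = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, separation]])
    orbs = {0: s_orbital(centers[0], exponent), 1: s_orbital(centers[1], exponent)}
    grid = becke_grid(centers if separation > 0 else centers[:1], level=level)
    return build_hole_electron(ConfigurationSet(((0, 1, 1.0),)), orbs, grid), centers


class TestCentroidSigma:
    def test_isotropic_gaussian_closed_form(self):
        # density exp(-2 a r^2): per-axis spread 1/(2 sqrt(a)) = 0.7071 at a = 0.5
        fields, _ = make_fields()
        inter = centroid_and_sigma(fields)
        np.testing.assert_allclose(inter.hole_centroid, [0, 0, 0], atol=1e-6)
        np.testing.assert_allclose(inter.ele_centroid, [0, 0, 4.0], atol=1e-5)
        np.testing.assert_allclose(inter.sigma_hole, 0.70710678, rtol=1e-4)
        np.testing.assert_allclose(inter.sigma_ele, 0.70710678, rtol=1e-4)

    def test_displaced_densities_shift_centroid_exactly(self):
        f1, _ = make_fields(separation=3.0)
        inter = centroid_and_sigma(f1)
        np.testing.assert_allclose(
            inter.ele_centroid - inter.hole_centroid, [0, 0, 3.0], atol=1e-5
        )

    def test_h_vector_equals_sigma_for_identical_spreads(self):
        fields, _ = make_fields()
        inter = centroid_and_sigma(fields)
        np.testing.assert_allclose(inter.h_vec, inter.sigma_hole, rtol=1e-6)


class TestOverlapIndices:
    def test_identical_densities_compat_sr_is_one(self):
        fields, _ = make_fields(separation=0.0)
        sr, _, _ = overlap_indices(fields, mode="compat")
        assert sr == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_supports_give_zero_overlap(self):
        fields, _ = make_fields(separation=14.0)
        for mode in ("as-printed", "compat"):
            sr, _, _ = overlap_indices(fields, mode=mode)
            assert sr == pytest.approx(0.0, abs=1e-5)

    def test_as_printed_hdi_matches_closed_form(self):
        # int rho^2 dr = (a/pi)^{3/2} for rho = (2a/pi)^{3/2} exp(-2 a r^2)
        fields, _ = make_fields(exponent=0.5)
        _, hdi, edi = overlap_indices(fields, mode="as-printed")
        expected = 100.0 * (0.5 / np.pi) ** 1.5
        assert hdi == pytest.approx(expected, rel=1e-3)
        assert edi == pytest.approx(expected, rel=1e-3)

    def test_unknown_mode_rejected(self):
        fields, _ = make_fields()
        with pytest.raises(ValueError, match="mode"):
            overlap_indices(fields, mode="sqrt")


class TestGeometryIndices:
    def test_identical_distributions_flagged_zero(self):
        fields, _ = make_fields(separation=0.0)
        inter = centroid_and_sigma(fields)
        assert inter.coincident
        d, dsig, hct, h, t = geometry_indices(inter)
        assert d == pytest.approx(0.0, abs=1e-6)
        assert dsig == pytest.approx(0.0, abs=1e-6)
        assert hct == 0.0 and t == pytest.approx(0.0, abs=1e-6)

    def test_displaced_gaussian_distance(self):
        fields, _ = make_fields(separation=4.0)
        d, _, _, _, _ = geometry_indices(centroid_and_sigma(fields))
        assert d == pytest.approx(4.0, abs=1e-4)

    def test_anisotropic_arithmetic_oracle(self):
        # sigma_ele (1,1,2), sigma_hole (1,1,1), centroids shifted 3 along z:
        # hand evaluation of the defining formulas
        inter = DescriptorIntermediates(
            hole_centroid=np.zeros(3),
            ele_centroid=np.array([0.0, 0.0, 3.0]),
            sigma_hole=np.array([1.0, 1.0, 1.0]),
            sigma_ele=np.array([1.0, 1.0, 2.0]),
            h_vec=np.array([1.0, 1.0, 1.5]),
            u_ct=np.array([0.0, 0.0, 1.0]),
        )
        d, dsig, hct, h, t = geometry_indices(inter)
        assert d == pytest.approx(3.0)
        assert dsig == pytest.approx(np.sqrt(6.0) - np.sqrt(3.0))
        assert hct == pytest.approx(1.5)  # |H . u_ct|
        assert h == pytest.approx((np.sqrt(6.0) + np.sqrt(3.0)) / 2)
        assert t == pytest.approx(3.0 - 1.5)

    def test_cross_product_variant_for_audit(self):
        inter = DescriptorIntermediates(
            hole_centroid=np.zeros(3),
            ele_centroid=np.array([0.0, 0.0, 3.0]),
            sigma_hole=np.ones(3),
            sigma_ele=np.ones(3),
            h_vec=np.array([1.0, 1.0, 1.5]),
            u_ct=np.array([0.0, 0.0, 1.0]),
        )
        _, _, hct_cross, _, _ = geometry_indices(inter, hct_variant="cross")
        assert hct_cross == pytest.approx(np.sqrt(2.0))  # |H x u| perpendicular part

    def test_t_identity_holds_exactly(self):
        for sep in (0.5, 2.0, 6.0):
            fields, _ = make_fields(separation=sep, level=1)
            d, _, hct, _, t = geometry_indices(centroid_and_sigma(fields))
            assert t == d - hct  # exact identity by construction


class TestRigidMotionInvariance:
    def test_indices_invariant_under_rotation_translation(self):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [33.0, -57.0, 110.0], degrees=True).as_matrix()
        shift = np.array([1.0, -2.0, 0.5])

        def descriptors(centers):
            orbs = {0: s_orbital(centers[0], 0.5), 1: s_orbital(centers[1], 0.7)}
            grid = becke_grid(centers, level=2)
            f = build_hole_electron(ConfigurationSet(((0, 1, 1.0),)), orbs, grid)
            inter = centroid_and_sigma(f)
            d, dsig, hct, h, t = geometry_indices(inter)
            sr, hdi, edi = overlap_indices(f)
            return np.array([d, hct, h, t, sr, hdi, edi])

        base = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 3.0]])
        moved = base @ rot.T + shift
        ref = descriptors(base)
        got = descriptors(moved)
        # D and overlap integrals are grid-limited; sigma-derived ones too
        np.testing.assert_allclose(got, ref, rtol=2e-3, atol=1e-5)


class TestMlct:
    def _fields(self):
        centers = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 10.0]])
        orbs = {0: s_orbital(centers[0], 0.8), 1: s_orbital(centers[1], 0.8)}
        grid = becke_grid(centers, level=1)
        return build_hole_electron(ConfigurationSet(((0, 1, 1.0),)), orbs, grid), centers

    def test_full_transfer_is_one(self):
        fields, centers = self._fields()
        frac = mlct_fraction(fields, {0: "metal", 1: "ligand"}, centers)
        assert frac == pytest.approx(1.0, abs=1e-3)

    def test_ligand_centered_excitation_is_zero(self):
        fields, centers = self._fields()
        # metal fragment placed where neither density lives
        centers3 = np.vstack([centers, [[0.0, 20.0, 5.0]]])
        frac = mlct_fraction(fields, {0: "ligand", 1: "ligand", 2: "metal"}, centers3)
        assert frac == pytest.approx(0.0, abs=1e-3)

    def test_missing_metal_fragment_rejected(self):
        fields, centers = self._fields()
        with pytest.raises(ValueError, match="metal"):
            mlct_fraction(fields, {0: "a", 1: "b"}, centers)


class TestSpectroscopic:
    def test_wavelength_conversion(self):
        out = spectroscopic_descriptors(2.0)
        assert out["wavelength"] == pytest.approx(619.920992)

    def test_zero_length_dipole_zero_fosc1(self):
        out = spectroscopic_descriptors(2.0, dipole_length=np.zeros(3))
        assert out["fosc1"] == 0.0

    def test_fosc_arithmetic_in_atomic_units(self):
        from soqy.units import EV_PER_HARTREE

        # E = 0.1 hartree, |mu_len|^2 = 1.5 -> fosc1 = (2/3) * 0.1 * 1.5 = 0.1
        out = spectroscopic_descriptors(
            0.1 * EV_PER_HARTREE, dipole_length=np.array([np.sqrt(1.5), 0, 0])
        )
        assert out["fosc1"] == pytest.approx(0.1, rel=1e-10)

    def test_missing_dipole_marked_absent(self):
        out = spectroscopic_descriptors(2.0)
        assert out["tedm"] is None and out["fosc1"] is None

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            spectroscopic_descriptors(-1.0)


class TestRecordAssembly:
    def _state(self, ee, mode="as-printed"):
        fields, centers = make_fields(level=1)
        return compute_state_descriptors(
            fields, energy_ev=ee, dipole_length=np.array([0.5, 0, 1.0]), mode=mode
        )

    def test_differences_and_column_order(self):
        s1, t1 = self._state(2.4), self._state(1.9)
        rec = assemble_qcd_record(s1, t1, soc_cm1=150.0, fosc1=0.1, fosc2=0.08)
        row = rec.as_row()
        assert list(row) == list(QCD_COLUMNS) and len(row) == 40
        assert row["D-ee"] == pytest.approx(0.5)
        assert row["S1"] == pytest.approx(1239.841984 / 2.4)

    def test_identical_states_zero_differences(self):
        s = self._state(2.0)
        rec = assemble_qcd_record(s, s, soc_cm1=10.0)
        assert all(
            rec.values[f"D-{k}"] == pytest.approx(0.0)
            for k in ("sr", "d", "hct", "ee", "hdi", "edi")
        )

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            assemble_qcd_record(
                self._state(2.4), self._state(1.9, mode="compat"), soc_cm1=1.0
            )

    def test_distances_reported_in_angstrom(self):
        fields, _ = make_fields(level=1)
        st = compute_state_descriptors(fields, energy_ev=2.4)
        assert st.d == pytest.approx(4.0 * ANGSTROM_PER_BOHR, rel=1e-3)
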