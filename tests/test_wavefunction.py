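"""Orbital evaluation, quadrature and hole/electron construction."""

import numpy as np
import pytest

from soqy import (
    ConfigurationSet,
    GaussianOrbital,
    Primitive,
    becke_grid,
    build_hole_electron,
    fragment_populations,
    integrate,
    p_orbital,
    s_orbital,
    uniform_grid,
)


def reference_hole_electron(configs, phi):
    """Literal double-loop over configuration pairs, exactly as the defining
    sums are written: local terms over each configuration, cross terms over
    ordered pairs sharing the virtual (hole) or the occupied (electron)
    orbital, de-excitations subtracted."""
    npts = len(next(iter(phi.values())))
    rho_hole = np.zeros(npts)
    rho_ele = np.zeros(npts)
    for sign, entries in ((1.0, configs.excitations), (-1.0, configs.deexcitations)):
        for i, a, w in entries:
            rho_hole += sign * w * w * phi[i] * phi[i]
            rho_ele += sign * w * w * phi[a] * phi[a]
        for i1, a1, w1 in entries:
            for i2, a2, w2 in entries:
                if (i1, a1) == (i2, a2):
                    continue
                if a1 == a2:
                    rho_hole += sign * w1 * w2 * phi[i1] * phi[i2]
                if i1 == i2:
                    rho_ele += sign * w1 * w2 * phi[a1] * phi[a2]
    return rho_hole, rho_ele


class TestOrbitals:
    def test_normalized_s_orbital_integrates_to_one(self):
        grid = becke_grid([[0.0, 0.0, 0.0]], level=2)
        phi = s_orbital((0, 0, 0), 0.5).evaluate(grid)
        assert integrate(phi**2, grid) == pytest.approx(1.0, abs=1e-4)

    def test_translation_covariance(self):
        grid = becke_grid([[0.0, 0.0, 0.0]], level=1)
        shift = np.array([1.3, -0.7, 2.1])
        orb = s_orbital((0, 0, 0), 0.8)
        moved = orb.translated(shift)
        np.testing.assert_allclose(
            orb.evaluate(grid), moved.evaluate(grid.translated(shift)), rtol=1e-12
        )

    def test_p_orbital_vanishes_on_nodal_plane(self):
        pts = np.array([[0.0, y, z] for y in (-1, 0.5) for z in (0.3, 2.0)])
        grid = uniform_grid((0, 0, 0), (1, 1, 1), 1.0)
        px = p_orbital((0, 0, 0), 0.6, axis=0)
        vals = px.evaluate(
            type(grid)(pts, np.ones(len(pts)))
        )
        np.testing.assert_allclose(vals, 0.0, atol=1e-14)

    @pytest.mark.parametrize("bad", [dict(exponent=-1.0), dict(exponent=np.nan),
                                     dict(coefficient=np.inf)])
    def test_invalid_primitive_rejected(self, bad):
        kwargs = dict(center=(0, 0, 0), exponent=0.5, angular=(0, 0, 0), coefficient=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            Primitive(**kwargs)


class TestIntegrate:
    def test_unit_volume_of_ones(self):
        grid = uniform_grid((0, 0, 0), (10, 10, 10), 0.1)
        assert integrate(np.ones(grid.size), grid) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        grid = uniform_grid((0, 0, 0), (2, 2, 2), 1.0)
        with pytest.raises(ValueError, match="length"):
            integrate(np.ones(5), grid)

    def test_grid_refinement_converges(self):
        # Richardson-style: finer levels must agree better with the closed form
        errs = []
        for level in (1, 2):
            grid = becke_grid([[0.0, 0.0, 0.0]], level=level)
            phi = s_orbital((0, 0, 0), 1.3).evaluate(grid)
            errs.append(abs(integrate(phi**2, grid) - 1.0))
        assert errs[1] <= errs[0]
        assert errs[1] < 1e-6


class TestHoleElectron:
    def test_single_excitation_collapses_to_orbital_densities(self):
        grid = becke_grid([[0, 0, 0], [0, 0, 3.0]], level=1)
        orbs = {0: s_orbital((0, 0, 0), 0.5), 1: s_orbital((0, 0, 3.0), 0.7)}
        f = build_hole_electron(ConfigurationSet(((0, 1, 1.0),)), orbs, grid)
        np.testing.assert_allclose(f.rho_hole, orbs[0].evaluate(grid) ** 2, atol=1e-14)
        np.testing.assert_allclose(f.rho_ele, orbs[1].evaluate(grid) ** 2, atol=1e-14)

    def test_electron_cross_term_pairs_sharing_occupied(self):
        # i->a (w1) and i->b (w2): cross term is 2 w1 w2 phi_a phi_b pointwise
        grid = becke_grid([[0, 0, 0]], level=1)
        orbs = {
            0: s_orbital((0, 0, 0), 0.5),
            1: s_orbital((0, 0, 0), 1.1),
            2: p_orbital((0, 0, 0), 0.9, axis=2),
        }
        w1, w2 = 0.8, 0.6
        f = build_hole_electron(
            ConfigurationSet(((0, 1, w1), (0, 2, w2))), orbs, grid
        )
        expected = 2 * w1 * w2 * orbs[1].evaluate(grid) * orbs[2].evaluate(grid)
        np.testing.assert_allclose(f.ele_cross, expected, atol=1e-13)

    def test_disjoint_excitations_integrate_to_norm(self):
        grid = becke_grid([[0, 0, 0], [0, 0, 2.5]], level=2)
        orbs = {
            0: s_orbital((0, 0, 0), 0.6),
            1: s_orbital((0, 0, 2.5), 0.6),
            2: s_orbital((0, 0, 0), 1.4),
            3: s_orbital((0, 0, 2.5), 1.4),
        }
        cfg = ConfigurationSet(((0, 2, 0.8), (1, 3, 0.6)))
        f = build_hole_electron(cfg, orbs, grid)
        assert cfg.norm == pytest.approx(1.0)
        assert integrate(f.rho_hole, grid) == pytest.approx(1.0, abs=2e-3)
        assert integrate(f.rho_ele, grid) == pytest.approx(1.0, abs=2e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_literal_double_loop_reference(self, seed):
        """Vectorized construction equals the literal pairwise sums, with
        excitations and de-excitations, on random small configuration sets."""
        rng = np.random.default_rng(seed)
        centers = [(0, 0, 0), (0, 0, 2.0)]
        orbs = {
            k: s_orbital(centers[k % 2], 0.4 + 0.3 * k) for k in range(5)
        }
        grid = becke_grid(centers, level=1)
        n_exc = rng.integers(1, 5)
        pairs = rng.permutation([(i, a) for i in range(2) for a in range(2, 5)])[:n_exc]
        exc = tuple((int(i), int(a), float(rng.normal(0, 0.7))) for i, a in pairs)
        dex = ()
        if rng.random() < 0.5:
            dex = ((int(pairs[0][0]), int(pairs[0][1]), 0.1),)
        try:
            cfg = ConfigurationSet(exc, dex)
        except ValueError:
            return  # random draw violated norm positivity; not this test's target
        f = build_hole_electron(cfg, orbs, grid)
        phi = {k: o.evaluate(grid) for k, o in orbs.items()}
        ref_hole, ref_ele = reference_hole_electron(cfg, phi)
        np.testing.assert_allclose(f.rho_hole, ref_hole, atol=1e-12)
        np.testing.assert_allclose(f.rho_ele, ref_ele, atol=1e-12)

    def test_include_cross_false_zeroes_cross_only(self):
        grid = becke_grid([[0, 0, 0]], level=1)
        orbs = {0: s_orbital((0, 0, 0), 0.5), 1: s_orbital((0, 0, 0), 1.1),
                2: p_orbital((0, 0, 0), 0.9, axis=0)}
        cfg = ConfigurationSet(((0, 1, 0.9), (0, 2, 0.4)))
        full = build_hole_electron(cfg, orbs, grid)
        local = build_hole_electron(cfg, orbs, grid, include_cross=False)
        np.testing.assert_allclose(local.ele_cross, 0.0)
        np.testing.assert_allclose(local.ele_local, full.ele_local)

    def test_unresolved_orbital_index_named(self):
        grid = becke_grid([[0, 0, 0]], level=1)
        with pytest.raises(KeyError, match="7"):
            build_hole_electron(
                ConfigurationSet(((0, 7, 1.0),)), {0: s_orbital((0, 0, 0), 0.5)}, grid
            )

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ConfigurationSet(((0, 1, 0.7), (0, 1, 0.2)))

    def test_nonpositive_norm_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ConfigurationSet(((0, 1, 0.3),), ((0, 1, 0.9),))


class TestFragmentPopulations:
    def _far_separated_fields(self):
        centers = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 12.0]])
        orbs = {0: s_orbital(centers[0], 0.8), 1: s_orbital(centers[1], 0.8)}
        grid = becke_grid(centers, level=2)
        return build_hole_electron(ConfigurationSet(((0, 1, 1.0),)), orbs, grid), centers

    def test_far_separated_metal_to_ligand(self):
        fields, centers = self._far_separated_fields()
        shares = fragment_populations(fields, {0: "metal", 1: "ligand"}, centers)
        assert shares["metal"][0] > 0.99  # hole on metal
        assert shares["ligand"][1] > 0.99  # electron on ligand

    def test_single_fragment_shares_are_unity(self):
        fields, centers = self._far_separated_fields()
        shares = fragment_populations(fields, {0: "all", 1: "all"}, centers)
        assert shares["all"][0] == pytest.approx(1.0)
        assert shares["all"][1] == pytest.approx(1.0)

    def test_relabeling_swaps_shares(self):
        fields, centers = self._far_separated_fields()
        a = fragment_populations(fields, {0: "x", 1: "y"}, centers)
        b = fragment_populations(fields, {0: "y", 1: "x"}, centers)
        assert a["x"] == pytest.approx(b["y"])
        assert a["y"] == pytest.approx(b["x"])

    def test_unassigned_atom_rejected(self):
        fields, centers = self._far_separated_fields()
        with pytest.raises(ValueError, match="not assigned"):
            fragment_populations(fields, {0: "metal"}, centers)
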