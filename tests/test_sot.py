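"""Self-organizing growth model: shading, allocation, pipe radii, determinism."""

import numpy as np
import pytest

import treeclone as tc
from treeclone.sot import GrowthState, ShadowGrid, _initial_state, grow_step

from conftest import make_chain, make_junction


def small_grid(a=0.1, b=2.0, depth=4, extent=6.0, voxel=0.2):
    return ShadowGrid(extent, voxel, a, b, depth)


class TestShadowGrid:
    def test_empty_scene_all_zeros(self):
        g = small_grid()
        assert g.values.sum() == 0.0

    def test_own_voxel_gains_a(self):
        g = small_grid()
        pt = np.array([0.0, 0.0, 3.0])
        tc.cast_shadow(g, pt)
        i, j, k = g.voxel_index(pt)
        assert g.values[i, j, k] == pytest.approx(0.1)

    def test_two_layers_down_decay(self):
        g = small_grid()
        pt = np.array([0.0, 0.0, 3.0])
        tc.cast_shadow(g, pt)
        i, j, k = g.voxel_index(pt)
        assert g.values[i, j, k - 2] == pytest.approx(0.1 * 2.0 ** (-2))

    def test_contributions_add(self):
        """Two buds in one voxel double the total deposited shadow mass."""
        g1, g2 = small_grid(), small_grid()
        pt = np.array([0.0, 0.0, 3.0])
        tc.cast_shadow(g1, pt)
        tc.cast_shadow(g2, pt)
        tc.cast_shadow(g2, pt)
        assert g2.values.sum() == pytest.approx(2 * g1.values.sum())
        # summation oracle: sum over layers of (2q+1)^2 * a * b^-q
        expected = sum((2 * q + 1) ** 2 * 0.1 * 2.0 ** (-q) for q in range(5))
        assert g1.values.sum() == pytest.approx(expected)

    def test_outside_point_clipped(self, caplog):
        g = small_grid()
        with caplog.at_level("WARNING"):
            tc.cast_shadow(g, np.array([100.0, 0.0, 3.0]))
        assert g.values.sum() > 0
        assert any("clipped" in r.message for r in caplog.records)


class TestLightExposure:
    def test_unshaded_full_exposure(self):
        g = small_grid()
        q = tc.light_exposure(g, np.array([0.0, 0.0, 0.0]), base_exposure=1.0,
                              light_gradient=0.0, own_shadow=False)
        assert q == pytest.approx(1.0)

    def test_vertical_gradient(self):
        g = small_grid()
        q = tc.light_exposure(g, np.array([0.0, 0.0, 3.0]), base_exposure=1.0,
                              light_gradient=0.4, own_shadow=False)
        assert q == pytest.approx(1.0 * (1 + 0.4 * 3.0 / 6.0))

    def test_heavy_shade_clamps_to_zero(self):
        g = small_grid()
        pt = np.array([0.0, 0.0, 3.0])
        for _ in range(20):
            tc.cast_shadow(g, pt)
        assert tc.light_exposure(g, pt) == 0.0

    def test_neighbor_above_reduces_exposure(self):
        g = small_grid()
        pt = np.array([0.0, 0.0, 3.0])
        tc.cast_shadow(g, pt)
        q_alone = tc.light_exposure(g, pt)
        tc.cast_shadow(g, pt + np.array([0.0, 0.0, 0.4]))
        q_shaded = tc.light_exposure(g, pt)
        assert q_shaded < q_alone


class TestAllocateResource:
    def test_lambda_one_all_terminal(self):
        vt, vl = tc.allocate_resource(1.0, [1.0, 1.0], 1.0, 5.0)
        assert vt == pytest.approx(5.0)
        assert np.allclose(vl, 0.0)

    def test_lambda_zero_all_lateral(self):
        vt, vl = tc.allocate_resource(1.0, [1.0, 3.0], 0.0, 4.0)
        assert vt == 0.0
        np.testing.assert_allclose(vl, [1.0, 3.0])

    def test_balanced_split_conserves(self):
        vt, vl = tc.allocate_resource(2.0, [2.0], 0.5, 1.0)
        assert vt == pytest.approx(0.5, abs=1e-12)
        assert vt + vl.sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_exposure_no_allocation(self):
        vt, vl = tc.allocate_resource(0.0, [0.0], 0.7, 3.0)
        assert vt == 0.0 and vl.sum() == 0.0


class TestGrowStep:
    def test_lone_seed_starts_vertical_chain(self):
        p = tc.small_sot_params(initial_metamers=1)
        state = _initial_state(p, seed=0)
        grow_step(state)
        assert state.n > 1
        # the first extension metamer keeps a strongly upward direction
        assert state.direction[1][2] > 0.7

    def test_determinism(self):
        p = tc.small_sot_params()
        s1, s2 = _initial_state(p, 5), _initial_state(p, 5)
        for _ in range(3):
            grow_step(s1)
            grow_step(s2)
        assert s1.n == s2.n
        np.testing.assert_array_equal(np.array(s1.base), np.array(s2.base))
        np.testing.assert_array_equal(np.array(s1.direction), np.array(s2.direction))

    def test_zero_resource_coeff_no_growth(self):
        p = tc.small_sot_params(resource_coeff=0.0)
        state = _initial_state(p, 0)
        n0 = state.n
        grow_step(state)
        assert state.n == n0


class TestUpdateRadii:
    def test_chain_uniform_tip_radius(self):
        tree = tc.update_radii(make_chain(5), pipe_exponent=2.0, tip_radius=0.01)
        np.testing.assert_allclose(tree.radius, 0.01)

    def test_binary_junction_3_4_5(self):
        """Children of radii 0.03 and 0.04 with exponent 2 meet in a 0.05 parent.

        Built from tips of radius 0.01: a child with 9 tip grandchildren has
        pipe radius 0.03, one with 16 has 0.04, so their parent is 0.05.
        """
        up = np.array([0.0, 0.0, 1.0])
        cyls = [tc.Cylinder(start=np.zeros(3), axis=up, length=1.0, radius=1.0, parent=None)]
        for n_tips in (9, 16):
            child = len(cyls)
            cyls.append(tc.Cylinder(start=cyls[0].end, axis=up, length=0.5, radius=1.0, parent=0))
            for _ in range(n_tips):
                cyls.append(tc.Cylinder(start=cyls[child].end, axis=up, length=0.2,
                                        radius=1.0, parent=child))
        tree = tc.update_radii(tc.Tree.from_cylinders(cyls), pipe_exponent=2.0, tip_radius=0.01)
        assert tree.radius[1] == pytest.approx(0.03, rel=1e-12)
        assert tree.radius[11] == pytest.approx(0.04, rel=1e-12)
        assert tree.radius[0] == pytest.approx(0.05, rel=1e-12)

    def test_junction_conservation_on_simulated_tree(self, sot_tree):
        kids = sot_tree.children()
        e = 2.0
        for i, ch in enumerate(kids):
            if ch:
                lhs = sot_tree.radius[i] ** e
                rhs = sum(sot_tree.radius[c] ** e for c in ch)
                assert lhs == pytest.approx(rhs, rel=1e-9)


class TestSimulate:
    def test_reproducible_cylinder_tables(self, tmp_path):
        p = tc.small_sot_params()
        t1, t2 = tc.simulate(p, 3), tc.simulate(p, 3)
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        tc.write_tree(t1, f1)
        tc.write_tree(t2, f2)
        assert f1.read_text() == f2.read_text()

    def test_distinct_seeds_differ(self, dirs4):
        p = tc.small_sot_params()
        s1 = tc.segment_table(tc.simulate(p, 1), [0, 1])
        s2 = tc.segment_table(tc.simulate(p, 2), [0, 1])
        assert tc.structural_distance(s1, s2, dirs4) > 0.0

    def test_more_iterations_more_cylinders(self):
        p = tc.small_sot_params()
        n_few = len(tc.simulate(p.with_values(n_iterations=6), 4))
        n_many = len(tc.simulate(p.with_values(n_iterations=10), 4))
        assert n_many > n_few

    def test_segment_lengths_fixed(self, sot_tree):
        np.testing.assert_allclose(sot_tree.length, 0.2)

    def test_inside_arena(self, sot_tree):
        e = 6.0
        pts = np.concatenate([sot_tree.start, sot_tree.end])
        assert np.all(np.abs(pts[:, :2]) <= e / 2 + 1e-9)
        assert np.all((pts[:, 2] >= -1e-9) & (pts[:, 2] <= e + 1e-9))

    def test_lambda_landscape_is_stochastic(self, sot_target, dirs4):
        """Replicate-to-replicate variance of the distance profile is positive."""
        tree, p = sot_target
        target = tc.segment_table(tree, [0, 1])
        vals = []
        for seed in (21, 22, 23):
            sim = tc.simulate(p.with_values(apical_lambda=0.3), seed)
            vals.append(tc.structural_distance(tc.segment_table(sim, [0, 1]), target, dirs4))
        assert np.var(vals) > 0.0

    def test_param_count_contract(self):
        """Five groups holding 23 parameters plus 4 fixed ones."""
        grouped = [f for g in tc.SOTParams.GROUPS.values() for f in g]
        assert len(grouped) == 23
        assert len(set(grouped)) == 23
        assert len(tc.SOTParams.GROUPS) == 5
        assert len(tc.SOTParams.FIXED) == 4

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            tc.SOTParams(apical_lambda=1.5)
        with pytest.raises(ValueError):
            tc.SOTParams(n_iterations=0)
        with pytest.raises(ValueError):
            tc.SOTParams(angle_noise_kind="cauchy")
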