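"""Sliced-KS structural distance and classical tree metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

import treeclone as tc
from treeclone.distance import OpCounter, sliced_distance

from conftest import make_chain


def brute_force_ks(x, y):
    """Independent oracle: max ECDF gap evaluated at every pooled point."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        gap = abs(np.mean(x <= t) - np.mean(y <= t))
        best = max(best, gap)
    return best


def gaussian_table(n, shift=0.0, seed=0):
    """2-column standard-normal segment-kind surrogate (first 2 cols vary)."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, 2))
    pts[:, 0] += shift
    return pts


class TestKS:
    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        x=st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=50),
        y=st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=50),
    )
    def test_matches_brute_force_oracle(self, x, y):
        assert tc.ks_two_sample(x, y) == pytest.approx(brute_force_ks(x, y), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        x=st.lists(st.integers(0, 5), min_size=1, max_size=30),
        y=st.lists(st.integers(0, 5), min_size=1, max_size=30),
    )
    def test_ties_match_scipy(self, x, y):
        """Heavily tied integer samples agree with an independent library."""
        assert tc.ks_two_sample(x, y) == pytest.approx(
            ks_2samp(x, y, method="asymp").statistic, abs=1e-12
        )

    def test_known_values(self):
        assert tc.ks_two_sample([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert tc.ks_two_sample([0, 0], [1, 1]) == 1.0
        assert tc.ks_two_sample([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(0.25)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            tc.ks_two_sample([], [1.0])


class TestDirections:
    def test_deterministic_regeneration(self):
        a = tc.generate_directions(3, 1000)
        b = tc.generate_directions(3, 1000)
        assert a.n == 1000 and a.vectors.shape == (1000, 3)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_unit_norm(self):
        d = tc.generate_directions(5, 777)
        np.testing.assert_allclose(np.linalg.norm(d.vectors, axis=1), 1.0, atol=1e-9)

    def test_sphere_coverage(self):
        """Monte-Carlo uniformity check: the mean direction nearly vanishes."""
        d = tc.generate_directions(2, 4096)
        assert np.linalg.norm(d.vectors.mean(axis=0)) < 0.05

    def test_offset_changes_set(self):
        a = tc.generate_directions(3, 64, "sobol:0")
        b = tc.generate_directions(3, 64, "sobol:64")
        assert not np.array_equal(a.vectors, b.vectors)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            tc.generate_directions(0, 10)
        with pytest.raises(ValueError):
            tc.generate_directions(3, 0)
        with pytest.raises(ValueError):
            tc.generate_directions(3, 10, "halton:0")


class TestStandardize:
    def _seg_table(self, arr, orders={0}):
        df = pd.DataFrame(np.asarray(arr, float), columns=["radius_m", "along_branch_m", "gamma_deg", "zeta_deg"])
        return tc.FeatureTable(kind="segment", orders=orders, data=df)

    def test_identical_tables_identical_outputs(self, sot_tree):
        s = tc.segment_table(sot_tree, [0, 1])
        a, b = tc.standardize_pair(s, s)
        np.testing.assert_array_equal(a, b)

    def test_iqr_scaling_formula(self):
        # pooled column: values {-1,-1,1,1} -> median 0, IQR 2 -> scaled +-0.5
        ta = self._seg_table([[-1, 0, 0, 0], [1, 0, 0, 0]])
        tb = self._seg_table([[-1, 0, 0, 0], [1, 0, 0, 0]])
        a, b = tc.standardize_pair(ta, tb)
        assert sorted(a[:, 0].tolist()) == [-0.5, 0.5]

    def test_constant_column_passes_through(self):
        ta = self._seg_table([[5, 1, 0, 0], [5, 2, 0, 0]])
        tb = self._seg_table([[5, 3, 0, 0], [5, 4, 0, 0]])
        a, b = tc.standardize_pair(ta, tb)
        assert np.allclose(a[:, 0], 0.0) and np.allclose(b[:, 0], 0.0)

    def test_column_mismatch(self, sot_tree):
        s = tc.segment_table(sot_tree, [0])
        b = tc.branch_table(sot_tree, [0])
        with pytest.raises(ValueError):
            tc.standardize_pair(s, b)


class TestStructuralDistance:
    def test_identity_is_exactly_zero(self, sot_tree, dirs4):
        s = tc.segment_table(sot_tree, [0, 1])
        assert tc.structural_distance(s, s, dirs4) == 0.0

    def test_symmetry_and_bounds(self, sot_tree, dirs4):
        s1 = tc.segment_table(sot_tree, [0, 1])
        other = tc.simulate(tc.small_sot_params(), seed=12)
        s2 = tc.segment_table(other, [0, 1])
        d12 = tc.structural_distance(s1, s2, dirs4)
        d21 = tc.structural_distance(s2, s1, dirs4)
        assert d12 == pytest.approx(d21, abs=1e-12)
        assert 0.0 < d12 <= 1.0

    def test_empty_table_penalty(self, sot_tree, dirs5):
        full = tc.branch_table(sot_tree, [1])
        empty = tc.branch_table(sot_tree, [9])
        assert tc.structural_distance(full, empty, dirs5) == 1.0
        assert tc.structural_distance(empty, empty, dirs5) == 0.0

    def test_shift_sensitivity_small(self):
        """Median distance grows with the mean shift between Gaussian tables."""
        dirs = tc.generate_directions(2, 256)
        medians = []
        for delta in (0.0, 1.0, 2.0):
            reps = [
                sliced_distance(
                    gaussian_table(200, 0.0, seed=100 + r),
                    gaussian_table(200, delta, seed=500 + r),
                    dirs,
                )
                for r in range(5)
            ]
            medians.append(np.median(reps))
        assert medians[0] < medians[1] < medians[2]

    def test_aggregate_mean(self, sot_tree, dirs4, dirs5):
        s = tc.segment_table(sot_tree, [0, 1])
        b = tc.branch_table(sot_tree, [1, 2])
        res = tc.aggregate_distance([(s, s), (b, b)], {4: dirs4, 5: dirs5})
        assert res.mean == 0.0
        other = tc.simulate(tc.small_sot_params(), seed=12)
        res2 = tc.aggregate_distance(
            [(s, tc.segment_table(other, [0, 1])), (b, tc.branch_table(other, [1, 2]))],
            {4: dirs4, 5: dirs5},
        )
        assert res2.mean == pytest.approx(np.mean(list(res2.per_pair.values())))
        assert 0.0 < res2.mean < 1.0
        with pytest.raises(ValueError):
            tc.aggregate_distance([], dirs4)

    def test_dimension_mismatch(self, sot_tree, dirs5):
        s = tc.segment_table(sot_tree, [0])
        with pytest.raises(ValueError):
            tc.structural_distance(s, s, dirs5)

    def test_op_counts_scale(self):
        """Work grows linearly in lines and samples-dominated n log n in rows."""
        a, b = gaussian_table(100, seed=1), gaussian_table(100, seed=2)
        d1, d2 = tc.generate_directions(2, 100), tc.generate_directions(2, 200)
        c1, c2 = OpCounter(), OpCounter()
        sliced_distance(a, b, d1, counter=c1)
        sliced_distance(a, b, d2, counter=c2)
        assert c2.total == 2 * c1.total  # linear in lines
        c3 = OpCounter()
        sliced_distance(gaussian_table(200, seed=1), gaussian_table(200, seed=2), d1, counter=c3)
        n1, n2 = 200, 400
        expected = (n2 * np.ceil(np.log2(n2))) / (n1 * np.ceil(np.log2(n1)))
        assert c3.sort_ops / c1.sort_ops == pytest.approx(expected)


class TestClassicalMetrics:
    def test_height_examples(self):
        vert = make_chain(1, length=2.0)
        assert tc.height(vert) == pytest.approx(2.0)
        tilt = tc.Tree.from_cylinders([
            tc.Cylinder(start=np.zeros(3),
                        axis=np.array([np.sqrt(0.5), 0.0, np.sqrt(0.5)]),
                        length=np.sqrt(2.0), radius=0.05, parent=None)
        ])
        assert tc.height(tilt) == pytest.approx(1.0)

    def test_height_endpoint_scan_oracle(self, sot_tree):
        zs = [max(c.start[2], c.end[2]) for c in sot_tree.cylinders()]
        assert tc.height(sot_tree) == pytest.approx(max(zs), abs=1e-12)

    def test_girth(self, sot_tree):
        chain = make_chain(3, radius=0.1)
        assert tc.girth(chain) == pytest.approx(0.2)
        root = sot_tree.root
        assert tc.girth(sot_tree) == pytest.approx(2 * sot_tree.radius[root])

    def test_crown_spread_circle(self):
        """36 points on a radius-3 circle, one per sector: spread is 6."""
        cyls = [tc.Cylinder(start=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]),
                            length=0.1, radius=0.05, parent=None)]
        for k in range(36):
            ang = np.radians(10.0 * k + 5.0)
            tip = np.array([3 * np.cos(ang), 3 * np.sin(ang), 1.0])
            d = tip - np.array([0.0, 0.0, 0.1])
            cyls.append(tc.Cylinder(start=np.array([0.0, 0.0, 0.1]),
                                    axis=d / np.linalg.norm(d),
                                    length=float(np.linalg.norm(d)),
                                    radius=0.01, parent=0))
        tree = tc.Tree.from_cylinders(cyls)
        assert tc.crown_spread(tree, 10.0) == pytest.approx(6.0, abs=1e-9)

    def test_crown_spread_center_mass_zero(self):
        tree = make_chain(4)
        assert tc.crown_spread(tree) == pytest.approx(0.0, abs=1e-12)

    def test_crown_spread_sector_count_and_rotation(self, sot_tree):
        c0 = tc.crown_spread(sot_tree, 10.0)
        rot = sot_tree.copy()
        ang = np.radians(20.0)  # multiple of the 10-degree separation
        R = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        rot.start = rot.start @ R.T
        rot.axis = rot.axis @ R.T
        assert tc.crown_spread(rot, 10.0) == pytest.approx(c0, rel=1e-9)
        with pytest.raises(ValueError):
            tc.crown_spread(sot_tree, 7.0)

    def test_classical_distances(self):
        m = tc.ClassicalMetrics(h=8.0, g=0.25, c=2.0)
        d = tc.ClassicalMetrics(h=10.0, g=0.10, c=2.0)
        dh, dg, dc = tc.classical_distances(m, d)
        assert dh == pytest.approx(0.2)
        assert dg == pytest.approx(1.5)  # errors above 100% are representable
        assert dc == 0.0
        assert tc.classical_distances(d, d) == (0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            tc.classical_distances(m, tc.ClassicalMetrics(h=0.0, g=1.0, c=1.0))
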