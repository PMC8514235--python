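"""SWC morphometry: lengths, branches, hull area, Sholl, IPL depth profiles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retinotype.morpho import (
    Arbor,
    SwcError,
    arbor_area,
    branch_statistics,
    ipl_depth_profile,
    read_swc,
    sholl,
    total_length,
    write_swc,
)
from retinotype.synthetic import generate_arbor


def dense_sholl_oracle(arbor, radii, center=None, step=0.01):
    """Independent oracle: resample every edge densely and count shell crossings
    as transitions of (distance − r) between the two sides, per sub-step, with
    the same near-side-strict / far-side-inclusive convention."""
    c = arbor.xyz[arbor.root] if center is None else np.asarray(center, float)
    counts = np.zeros(len(radii), dtype=int)
    for child in range(arbor.n_nodes):
        par = arbor.parent[child]
        if par < 0:
            continue
        a, b = arbor.xyz[par], arbor.xyz[child]
        n_sub = max(2, int(np.linalg.norm(b - a) / step))
        t = np.linspace(0.0, 1.0, n_sub + 1)
        d = np.linalg.norm(a + t[:, None] * (b - a) - c, axis=1)
        for i, r in enumerate(radii):
            lo = np.minimum(d[:-1], d[1:])
            hi = np.maximum(d[:-1], d[1:])
            counts[i] += int(np.sum((lo < r) & (r <= hi)))
    return counts


class TestLengthAndBranches:
    def test_single_edge_length(self):
        arbor = Arbor(
            np.array([[0, 0, 0], [0, 100, 0]], float), [1, 1], [-1, 0]
        )
        assert total_length(arbor) == pytest.approx(100.0)
        stats = branch_statistics(arbor)
        assert stats.n_branch_points == 0
        assert stats.n_terminals == 1
        assert list(stats.segment_lengths) == [pytest.approx(100.0)]

    def test_y_tree_three_segments(self, y_tree):
        assert total_length(y_tree) == pytest.approx(150.0)
        stats = branch_statistics(y_tree)
        assert stats.n_branch_points == 1
        assert stats.n_terminals == 2
        assert sorted(stats.segment_lengths) == pytest.approx([50.0, 50.0, 50.0])

    def test_full_binary_tree_counts(self):
        """Seven internal branch events give 7 branch points and 8 terminals."""
        xyz = [[0.0, 0.0, 0.0]]
        parent = [-1]
        frontier = [0]
        rng = np.random.default_rng(0)
        for _depth in range(3):  # 1 + 2 + 4 = 7 branch points
            nxt = []
            for node in frontier:
                for _ in range(2):
                    xyz.append(list(np.asarray(xyz[node]) + rng.uniform(1, 5, 3)))
                    parent.append(node)
                    nxt.append(len(xyz) - 1)
            frontier = nxt
        arbor = Arbor(np.asarray(xyz), np.ones(len(xyz)), np.asarray(parent))
        stats = branch_statistics(arbor)
        assert stats.n_branch_points == 7
        assert stats.n_terminals == 8

    def test_partition_identity(self):
        """Total length equals the sum of per-segment lengths for any tree."""
        for seed in range(5):
            arbor, _ = generate_arbor(4, seed=seed)
            stats = branch_statistics(arbor)
            assert stats.segment_lengths.sum() == pytest.approx(
                total_length(arbor), rel=1e-12
            )

    def test_rigid_motion_invariance(self, y_tree):
        th = np.deg2rad(33.0)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        moved = y_tree.transformed(rotation=rot, offset=(5.0, -2.0, 7.0))
        assert total_length(moved) == pytest.approx(total_length(y_tree))
        assert branch_statistics(moved).n_branch_points == 1
        assert arbor_area(moved) == pytest.approx(arbor_area(y_tree))
        np.testing.assert_array_equal(
            sholl(moved, 20.0).intersections, sholl(y_tree, 20.0).intersections
        )


class TestArborArea:
    def test_y_tree_triangle(self, y_tree):
        assert arbor_area(y_tree) == pytest.approx(2700.0)

    def test_collinear_is_zero_with_warning(self, path_arbor):
        with pytest.warns(UserWarning):
            assert arbor_area(path_arbor) == 0.0

    def test_against_shapely_hull(self):
        from shapely.geometry import MultiPoint

        rng = np.random.default_rng(3)
        xyz = rng.uniform(0, 100, (40, 3))
        arbor = Arbor(xyz, np.ones(40), np.arange(-1, 39))
        expected = MultiPoint(xyz[:, :2]).convex_hull.area
        assert arbor_area(arbor) == pytest.approx(expected, rel=1e-9)

    @given(st.floats(0.5, 3.0), st.integers(0, 50))
    def test_quadratic_scaling(self, factor, seed):
        arbor, _ = generate_arbor(3, seed=seed)
        scaled = Arbor(
            arbor.xyz * factor, arbor.radius, arbor.parent, arbor.ntype
        )
        assert arbor_area(scaled) == pytest.approx(
            factor**2 * arbor_area(arbor), rel=1e-9
        )


class TestSholl:
    def test_straight_path(self, path_arbor):
        profile = sholl(path_arbor, 20.0)
        np.testing.assert_array_equal(profile.radii, [20, 40, 60, 80])
        np.testing.assert_array_equal(profile.intersections, [1, 1, 1, 1])

    def test_y_tree(self, y_tree):
        profile = sholl(y_tree, 20.0)
        np.testing.assert_array_equal(profile.radii, [20, 40, 60, 80])
        np.testing.assert_array_equal(profile.intersections, [1, 1, 2, 2])

    def test_beyond_extent_is_zero_and_primary_dendrites_near_soma(self):
        # three primary dendrites leaving the soma, no branching
        xyz = np.array(
            [[0, 0, 0], [50, 0, 0], [0, 50, 0], [-35, -35, 0]], dtype=float
        )
        arbor = Arbor(xyz, np.ones(4), np.array([-1, 0, 0, 0]))
        profile = sholl(arbor, 10.0)
        assert profile.intersections[0] == 3  # r=10, below every terminal
        assert np.all(profile.radii < 50.0)

    def test_edge_bending_back_crosses_twice(self):
        """An edge that dips inside a shell and re-emerges crosses it twice."""
        xyz = np.array([[0, 0, 0], [31, -20, 0], [31, 20, 0]], dtype=float)
        # both endpoints of edge 1→2 sit at r≈36.9 but its midpoint is at r=31,
        # so the shell at r=33 is crossed twice by that single edge
        arbor = Arbor(xyz, np.ones(3), np.array([-1, 0, 1]))
        profile = sholl(arbor, 33.0)
        np.testing.assert_array_equal(profile.radii, [33.0])
        oracle = dense_sholl_oracle(arbor, profile.radii)
        np.testing.assert_array_equal(profile.intersections, oracle)
        assert profile.intersections[0] == 3  # stem once, bent edge twice

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generated_arbors_match_dense_oracle(self, seed):
        arbor, _ = generate_arbor(5, seed=seed)
        profile = sholl(arbor, 10.0)
        oracle = dense_sholl_oracle(arbor, profile.radii)
        np.testing.assert_array_equal(profile.intersections, oracle)


class TestSwcIO:
    def test_roundtrip(self, tmp_path):
        arbor, _ = generate_arbor(4, seed=2)
        path = tmp_path / "cell.swc"
        write_swc(arbor, path)
        back = read_swc(path)
        np.testing.assert_allclose(back.xyz, arbor.xyz, atol=1e-5)
        np.testing.assert_array_equal(back.parent, arbor.parent)
        assert total_length(back) == pytest.approx(total_length(arbor), abs=1e-3)

    def test_single_node_file(self, tmp_path):
        path = tmp_path / "soma.swc"
        path.write_text("1 1 0 0 0 5.0 -1\n")
        arbor = read_swc(path)
        assert arbor.n_nodes == 1
        assert total_length(arbor) == 0.0

    def test_cycle_rejected_with_node_named(self, tmp_path):
        path = tmp_path / "cycle.swc"
        path.write_text("1 1 0 0 0 1 -1\n2 3 1 0 0 1 3\n3 3 2 0 0 1 2\n")
        with pytest.raises(SwcError, match="cycle"):
            read_swc(path)

    def test_multi_root_rejected(self, tmp_path):
        path = tmp_path / "two_roots.swc"
        path.write_text("1 1 0 0 0 1 -1\n2 1 5 0 0 1 -1\n")
        with pytest.raises(SwcError, match="root"):
            read_swc(path)

    def test_missing_parent_names_line(self, tmp_path):
        path = tmp_path / "orphan.swc"
        path.write_text("1 1 0 0 0 1 -1\n2 3 1 0 0 1 9\n")
        with pytest.raises(SwcError, match=":2"):
            read_swc(path)

    def test_multi_sample_soma_collapsed(self, tmp_path):
        path = tmp_path / "soma3.swc"
        path.write_text(
            "1 1 0 0 0 5 -1\n"
            "2 1 2 0 0 5 1\n"
            "3 1 -2 0 0 5 1\n"
            "4 3 0 50 0 1 1\n"
        )
        arbor = read_swc(path)
        assert arbor.n_nodes == 2  # centroid soma + one dendrite node
        np.testing.assert_allclose(arbor.xyz[arbor.root], [0, 0, 0])


class TestIplDepthProfile:
    def test_reference_bands_located(self):
        x = np.linspace(0, 100, 201)
        ref = np.exp(-((x - 20) ** 2) / 18.0) + 0.9 * np.exp(-((x - 47) ** 2) / 18.0)
        rep = np.exp(-((x - 60) ** 2) / 18.0)
        profile = ipl_depth_profile(rep, ref)
        assert profile.band_depths_pct[0] == pytest.approx(20.0, abs=0.5)
        assert profile.band_depths_pct[1] == pytest.approx(47.0, abs=0.5)
        assert profile.reporter_peak_depths_pct[0] == pytest.approx(60.0, abs=0.5)

    def test_normalized_maxima_are_one(self):
        x = np.linspace(0, 100, 101)
        ref = 5.0 * (np.exp(-((x - 25) ** 2) / 20) + np.exp(-((x - 70) ** 2) / 20))
        rep = 0.3 * np.exp(-((x - 50) ** 2) / 20)
        profile = ipl_depth_profile(rep, ref)
        assert profile.reference.max() == pytest.approx(1.0)
        assert profile.reporter.max() == pytest.approx(1.0)

    def test_flat_reference_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            ipl_depth_profile(np.ones(50), np.ones(50))

    def test_averaging_reduces_noise_like_sqrt_n(self):
        """Averaging N noisy replicates shrinks the residual SD ≈ 1/√N."""
        rng = np.random.default_rng(0)
        x = np.linspace(0, 100, 201)
        clean = np.exp(-((x - 40) ** 2) / 30.0)
        reps = clean + rng.normal(0, 0.05, (64, x.size))
        sd1 = np.std(reps[0] - clean)
        sd64 = np.std(reps.mean(axis=0) - clean)
        assert sd64 == pytest.approx(sd1 / 8.0, rel=0.35)
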