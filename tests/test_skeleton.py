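import numpy as np
import pytest
from scipy import ndimage

from myeliq.segmentation import BinaryMask
from myeliq.skeleton import (
    analyze_fibers,
    count_intersections,
    fiber_diameter,
    fiber_length,
    porosity,
    prune_spurs,
    skeletonize,
)

from conftest import as_mask
from oracles import brute_path_length, brute_prune


def n_components(mask):
    return ndimage.label(mask, structure=np.ones((3, 3), int))[1]


class TestSkeletonize:
    def test_bar_thins_to_single_path(self):
        m = np.zeros((9, 25), bool)
        m[3:6, 2:23] = True
        g = skeletonize(as_mask(m))
        assert g.n_endpoints == 2
        assert g.n_branchpoints == 0
        assert len([s for s in g.segments if not s.junction_interior]) == 1

    def test_square_stays_one_component(self):
        m = np.zeros((20, 20), bool)
        m[2:17, 2:17] = True
        g = skeletonize(as_mask(m))
        assert g.skeleton_mask.any()
        assert n_components(g.skeleton_mask) == 1

    def test_cross_has_one_branchpoint_four_endpoints(self):
        m = np.zeros((31, 31), bool)
        m[14:17, 2:29] = True
        m[2:29, 14:17] = True
        g = skeletonize(as_mask(m))
        assert g.n_branchpoints == 1
        assert g.n_endpoints == 4

    def test_empty_mask_gives_empty_graph(self):
        g = skeletonize(as_mask(np.zeros((16, 16))))
        assert not g.skeleton_mask.any()
        assert g.nodes == [] and g.segments == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_component_count_preserved(self, seed):
        rng = np.random.default_rng(seed)
        m = ndimage.binary_dilation(
            rng.random((48, 48)) < 0.04, np.ones((3, 3), bool)
        )
        g = skeletonize(as_mask(m))
        assert n_components(g.skeleton_mask) == n_components(m)

    def test_segment_lengths_sum_to_total(self):
        m = np.zeros((31, 31), bool)
        m[14:17, 2:29] = True
        m[2:29, 14:17] = True
        g = skeletonize(as_mask(m))
        assert fiber_length(g) == pytest.approx(
            sum(s.length_um for s in g.segments), abs=1e-9
        )


class TestPruneSpurs:
    def test_zero_threshold_is_identity(self):
        m = np.zeros((21, 21), bool)
        m[10, :] = True
        m[8:10, 10] = True
        g = skeletonize(as_mask(m))
        assert prune_spurs(g, 0.0) is g

    def test_short_spur_dissolves_junction(self):
        m = np.zeros((21, 21), bool)
        m[10, :] = True  # through-line
        m[8:10, 10] = True  # 2-px spur
        g = prune_spurs(skeletonize(as_mask(m)), 5.0)
        assert count_intersections(g) == 0
        assert g.n_endpoints == 2

    def test_long_branches_survive(self):
        m = np.zeros((21, 21), bool)
        m[10, :] = True
        m[:10, 10] = True  # 10-px arm
        g = prune_spurs(skeletonize(as_mask(m)), 5.0)
        assert count_intersections(g) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_leaf_deletion_oracle(self, seed):
        """Pixel-exact agreement with an independent leaf-deletion oracle.

        Fixtures: a through-line with well-separated spurs clearly below
        (1-3 px) or above (>= 8 px) the 5 px cutoff, so the orthogonal-
        vs-diagonal step ambiguity at the junction cannot flip a
        decision.
        """
        rng = np.random.default_rng(seed)
        m = np.zeros((64, 64), bool)
        m[32, 2:62] = True
        cols = rng.permutation(np.arange(8, 56, 5))[:8]
        for i, c in enumerate(cols):
            length = int(rng.integers(1, 4)) if i % 2 == 0 else int(rng.integers(8, 14))
            m[32 - length : 32, c] = True
        g = prune_spurs(skeletonize(as_mask(m)), 5.0)
        oracle = brute_prune(skeletonize(as_mask(m)).skeleton_mask, 5.0)
        assert np.array_equal(g.skeleton_mask, oracle)

    def test_intersections_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        m = np.zeros((64, 64), bool)
        m[32, :] = True
        for _ in range(10):
            c = rng.integers(4, 60)
            length = rng.integers(1, 12)
            m[max(0, 32 - length) : 32, c] = True
        g = skeletonize(as_mask(m))
        counts = [
            count_intersections(prune_spurs(g, t)) for t in (0, 2, 4, 8, 16)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFiberLength:
    def test_horizontal_101px_at_half_micron(self):
        m = np.zeros((16, 103), bool)
        m[8, 1:102] = True
        g = skeletonize(BinaryMask(m, 0.5))
        assert fiber_length(g) == pytest.approx(50.0)

    def test_diagonal_weighting(self):
        m = np.zeros((16, 16), bool)
        for i in range(11):
            m[i + 2, i + 2] = True
        g = skeletonize(as_mask(m))
        assert fiber_length(g) == pytest.approx(10 * np.sqrt(2))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_neighbor_walk_oracle_on_small_paths(self, seed):
        """Exhaustive-walk oracle on 1-px paths in small masks."""
        rng = np.random.default_rng(seed)
        m = np.zeros((8, 8), bool)
        r, c = rng.integers(0, 8, 2)
        m[r, c] = True
        for _ in range(11):
            dr, dc = rng.integers(-1, 2, 2)
            r2, c2 = np.clip(r + dr, 0, 7), np.clip(c + dc, 0, 7)
            m[r2, c2] = True
            r, c = r2, c2
        g = skeletonize(as_mask(m))
        skel = g.skeleton_mask
        degs = ndimage.convolve(
            skel.astype(int), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]),
            mode="constant",
        )[skel]
        if len(degs) and degs.max() <= 2 and (degs == 2).sum() < len(degs):
            assert fiber_length(g) == pytest.approx(
                brute_path_length(skel, 1.0), abs=1e-9
            )

    def test_90_degree_rotation_exact_on_thin_structures(self):
        """Rotating a clean fiber geometry by 90° preserves total length."""
        m = np.zeros((48, 48), bool)
        m[10, 4:40] = True  # bar
        for i in range(12):
            m[20 + i, 20 + i] = True  # diagonal
        m[30:45, 8] = True
        m[37, 2:15] = True  # a crossing
        lengths = {
            fiber_length(skeletonize(as_mask(np.rot90(m, k).copy())))
            for k in range(4)
        }
        assert max(lengths) - min(lengths) < 1e-9

    def test_45_degree_fiber_within_5_percent(self):
        """A straight fiber keeps its length within 5% when drawn at 45°."""
        horiz = np.zeros((40, 40), bool)
        horiz[20, 3:31] = True  # 27 steps
        diag = np.zeros((40, 40), bool)
        for i in range(28):
            diag[5 + i, 5 + i] = True  # 27 diagonal steps = 27*sqrt(2) px
        lh = fiber_length(skeletonize(as_mask(horiz)))
        ld = fiber_length(skeletonize(as_mask(diag))) / np.sqrt(2)
        assert abs(ld - lh) / lh < 0.05

    def test_pixel_size_scaling_exact(self):
        m = np.zeros((32, 32), bool)
        m[5:25, 10:13] = True
        m[15, 5:28] = True
        fm1 = analyze_fibers(BinaryMask(m, 1.0), prune_um=0)
        fm3 = analyze_fibers(BinaryMask(m, 3.0), prune_um=0)
        assert fm3.total_fiber_length == pytest.approx(3 * fm1.total_fiber_length)
        assert fm3.mean_fiber_diameter == pytest.approx(3 * fm1.mean_fiber_diameter)
        assert fm3.n_intersections == fm1.n_intersections
        assert fm3.porosity == fm1.porosity


class TestCountIntersections:
    def test_parallel_lines_zero(self):
        m = np.zeros((20, 20), bool)
        m[5, :] = True
        m[15, :] = True
        assert count_intersections(skeletonize(as_mask(m))) == 0

    def test_x_crossing_is_one(self):
        m = np.zeros((21, 21), bool)
        for i in range(21):
            m[i, i] = True
            m[i, 20 - i] = True
        assert count_intersections(skeletonize(as_mask(m))) == 1

    def test_h_shape_is_two(self):
        m = np.zeros((21, 21), bool)
        m[:, 3] = True
        m[:, 17] = True
        m[10, 3:18] = True
        assert count_intersections(skeletonize(as_mask(m))) == 2


class TestFiberDiameter:
    def test_bar_width_five(self):
        m = np.zeros((15, 40), bool)
        m[5:10, 2:38] = True
        mk = BinaryMask(m, 1.0)
        d = fiber_diameter(mk, skeletonize(mk))
        assert d == pytest.approx(5.0, abs=1.0)

    def test_thinnest_line(self):
        m = np.zeros((16, 30), bool)
        m[8, 2:28] = True
        mk = BinaryMask(m, 1.0)
        d = fiber_diameter(mk, skeletonize(mk))
        assert 1.0 <= d <= 2.0

    def test_empty_skeleton_rejected(self):
        mk = as_mask(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            fiber_diameter(mk, skeletonize(mk))


class TestPorosity:
    def test_endpoints_and_counting(self):
        assert porosity(as_mask(np.zeros((16, 16)))) == 1.0
        assert porosity(as_mask(np.ones((16, 16)))) == 0.0
        m = np.zeros((10, 40), bool)
        m.ravel()[:100] = True
        assert porosity(as_mask(m)) == pytest.approx(0.75)


class TestAnalyzeFibers:
    def test_empty_mask(self):
        fm = analyze_fibers(as_mask(np.zeros((16, 16))))
        assert fm.total_fiber_length == 0
        assert fm.n_intersections == 0
        assert fm.mean_fiber_diameter == 0
        assert fm.porosity == 1.0

    def test_single_fiber(self):
        m = np.zeros((32, 32), bool)
        m[4:28, 15:18] = True
        fm = analyze_fibers(as_mask(m))
        assert fm.n_intersections == 0
        assert fm.total_fiber_length > 0
        assert 0 < fm.porosity < 1
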