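"""Fine boundary refinement: search space, objective, DP optimality."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemapose.coarse import CoarseInstantiation
from nemapose.edges import EdgeMap, detect_edges, edge_index
from nemapose.fine import (FineInstantiation, FineModelParams,
                           FineSearchSpace, boundaries_to_midline,
                           boundaries_to_midline_points, build_search_space,
                           dp_solve, fine_objective, segment_edge_type)

from conftest import UNIT, WIDTH, make_scene


def straight_coarse(n=20, row=30):
    """A horizontal coarse path (head first), pixel units."""
    return CoarseInstantiation(points=tuple((row, 10 + i) for i in range(n)))


def empty_edges(shape=(64, 128)):
    return EdgeMap(arrays=np.zeros((8, *shape), bool), threshold_used=1.0)


class TestSearchSpace:
    def test_straight_midline_gives_two_parallel_corridor_bands(self):
        space = build_search_space(straight_coarse(n=40), worm_width=8.0,
                                   n_segments=30, corridor_halfwidth=2.0)
        n = space.head_tip_index
        lo, hi = n // 3, 2 * n // 3
        left = np.array([space.admissible_sets[i].mean(axis=0)
                         for i in range(lo, hi)])
        right = np.array([space.admissible_sets[2 * n - i].mean(axis=0)
                          for i in range(lo, hi)])
        # interior left and right corridors sit ~8 px apart in row
        assert abs(abs(left[:, 0].mean() - right[:, 0].mean()) - 8.0) < 1.5

    def test_zero_corridor_reduces_dp_to_the_hypothesis(self):
        space = build_search_space(straight_coarse(), worm_width=8.0,
                                   corridor_halfwidth=0.0,
                                   tip_extension_frac=0.0)
        assert all(len(s) == 1 for s in space.admissible_sets)
        fine = dp_solve(empty_edges(), space, FineModelParams())
        expect = np.array([s[0] for s in space.admissible_sets])
        assert np.array_equal(fine.boundary, expect)

    def test_doubling_segments_doubles_the_chain(self):
        s1 = build_search_space(straight_coarse(), 8.0, n_segments=20)
        s2 = build_search_space(straight_coarse(), 8.0, n_segments=40)
        assert len(s2.admissible_sets) == 2 * len(s1.admissible_sets) - 1

    def test_too_short_coarse_rejected(self):
        with pytest.raises(ValueError):
            build_search_space(
                CoarseInstantiation(points=((0, 0), (0, 1))), 8.0)


class TestSegmentEdgeType:
    def test_consistent_with_detected_stripe_polarity(self):
        # dark horizontal stripe: its top boundary, traversed eastward with
        # the body below (right of travel), expects the edges actually
        # detected there
        img = np.full((32, 32), 200.0)
        img[12:20, :] = 60.0
        em = detect_edges(img, 20)
        etype = segment_edge_type(0, "right")     # east, body to the south
        rows = np.nonzero(em.arrays[etype].any(axis=1))[0]
        assert 11 in rows                          # top boundary row
        etype_bot = segment_edge_type(0, "left")   # east, body to the north
        rows_bot = np.nonzero(em.arrays[etype_bot].any(axis=1))[0]
        assert 19 in rows_bot                      # bottom boundary row

    def test_left_right_boundaries_have_opposite_polarity(self):
        for k in range(8):
            er = segment_edge_type(k, "right")
            el = segment_edge_type(k, "left")
            assert er // 2 == el // 2      # same axis
            assert er != el                # opposite polarity

    def test_invalid_side_rejected(self):
        with pytest.raises(ValueError):
            segment_edge_type(0, "top")


def tiny_space(n=4, row=10, col0=10, spacing=2, radius=1.0,
               column_only=False):
    """Small hand-made chain with corridors around a horizontal line."""
    pts = [(row, col0 + spacing * i) for i in range(2 * n + 1)]
    sets = []
    for r, c in pts:
        if column_only:
            offs = [(-1, 0), (0, 0), (1, 0)]
        else:
            offs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                    if dr * dr + dc * dc <= radius * radius]
        sets.append(np.array([(r + dr, c + dc) for dr, dc in offs]))
    dirs = np.zeros(2 * n, dtype=int)
    etypes = np.array([segment_edge_type(0, "right")] * 2 * n)
    return FineSearchSpace(admissible_sets=sets, expected_dirs=dirs,
                           edge_types=etypes, head_tip_index=n,
                           hypothesized=np.array(pts, float))


class TestFineObjective:
    def test_all_matching_edges_give_length_times_log_ratio(self):
        p = FineModelParams(B=1.0)
        space = tiny_space(n=3, radius=0.0)
        em = empty_edges((32, 64))
        et = int(space.edge_types[0])
        em.arrays[et][10, :] = True       # matching edge everywhere on row
        bd = space.hypothesized.astype(int)
        n_pix = sum(int(np.abs(b - a).max())
                    for a, b in zip(bd[:-1], bd[1:]))
        assert fine_objective(bd, em, space, p) == pytest.approx(
            n_pix * p.lr_on)

    def test_no_edges_give_length_times_off_ratio(self):
        p = FineModelParams()
        space = tiny_space(n=3, radius=0.0)
        bd = space.hypothesized.astype(int)
        n_pix = sum(int(np.abs(b - a).max())
                    for a, b in zip(bd[:-1], bd[1:]))
        assert fine_objective(bd, empty_edges((32, 64)), space, p) == \
            pytest.approx(n_pix * p.lr_off)

    def test_orientation_prior_vanishes_at_b_zero(self):
        space = tiny_space(n=3, radius=0.0)
        other = tiny_space(n=3, radius=0.0)
        other.expected_dirs = (other.expected_dirs + 2) % 8  # wrong beta
        em = empty_edges((32, 64))
        bd = space.hypothesized.astype(int)
        p0 = FineModelParams(B=0.0)
        assert fine_objective(bd, em, space, p0) == pytest.approx(
            fine_objective(bd, em, other, p0))

    def test_wrong_length_boundary_rejected(self):
        space = tiny_space(n=3, radius=0.0)
        with pytest.raises(ValueError):
            fine_objective(space.hypothesized[:3].astype(int),
                           empty_edges((32, 64)), space, FineModelParams())


class TestDPSolve:
    @given(seed=st.integers(0, 200))
    @settings(max_examples=8, deadline=None)
    def test_dp_equals_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        space = tiny_space(n=2, column_only=True)
        em = empty_edges((32, 64))
        em.arrays[:] = rng.random((8, 32, 64)) < 0.15
        p = FineModelParams(B=1.0)
        fine = dp_solve(em, space, p)
        # exhaustive enumeration over the product of admissible sets
        sets = space.admissible_sets
        best = -np.inf
        import itertools
        for combo in itertools.product(*[range(len(s)) for s in sets]):
            bd = np.array([sets[i][k] for i, k in enumerate(combo)])
            best = max(best, fine_objective(bd, em, space, p))
        assert fine.log_post == pytest.approx(best)
        # objective consistency: the reported optimum re-evaluates exactly
        assert fine_objective(fine.boundary, em, space, p) == \
            pytest.approx(fine.log_post)

    def test_large_b_pins_the_boundary_to_the_expected_orientation(self):
        space = tiny_space(n=4, radius=1.0)
        em = empty_edges((32, 64))
        et = int(space.edge_types[0])
        em.arrays[et][10, :] = True
        fine = dp_solve(em, space, FineModelParams(B=1000.0))
        d = np.diff(fine.boundary, axis=0)
        moving = d[np.abs(d).max(axis=1) > 0]
        assert np.all(moving[:, 0] == 0)     # all segments exactly eastward

    def test_rendered_straight_worm_boundaries_on_true_edges(self):
        img, gt = make_scene("straight", seed=5)
        em = detect_edges(img, 5.0)
        from nemapose.synth import resample_polyline
        dense = resample_polyline(gt.midline, 150)
        cells = [tuple(p) for p in (dense[::-1] // UNIT).astype(int)]
        path = [cells[0]]
        for c in cells[1:]:
            if c != path[-1] and max(abs(c[0] - path[-1][0]),
                                     abs(c[1] - path[-1][1])) == 1 \
                    and c not in path:
                path.append(c)
        space = build_search_space(CoarseInstantiation(points=tuple(path)),
                                   WIDTH, coarse_unit=UNIT,
                                   image_shape=img.shape)
        fine = dp_solve(em, space, FineModelParams())
        # boundary points sit on the rendered body outline within ~1 px RMS
        from scipy.ndimage import distance_transform_edt
        outline = gt.body_mask ^ (distance_transform_edt(gt.body_mask) > 1)
        dist_to_outline = distance_transform_edt(~outline)
        bd = fine.boundary
        d = dist_to_outline[bd[:, 0], bd[:, 1]]
        assert np.sqrt(np.mean(d ** 2)) < 1.6


class TestMidlineDerivation:
    def test_parallel_boundaries_give_the_central_line(self):
        n = 10
        top = [(10, c) for c in range(20, 20 + n)]
        tip = [(14, 20 + n)]
        bot = [(18, c) for c in range(20 + n - 1, 19, -1)]
        bd = np.array(top + tip + bot)
        mid = boundaries_to_midline_points(bd, n)
        assert np.allclose(mid[:-1, 0], 14.0)

    def test_circle_arc_boundaries_recover_the_central_radius(self):
        r, w, n = 30.0, 8.0, 40
        th = np.linspace(0, np.pi, n + 1)
        center = np.array([50.0, 50.0])
        outer = center + (r + w / 2) * np.stack([np.sin(th), np.cos(th)], 1)
        inner = center + (r - w / 2) * np.stack([np.sin(th), np.cos(th)], 1)
        bd = np.vstack([outer[:-1], [(center + [0, -r - w / 2])],
                        inner[::-1][1:]])
        # pair i with 2n-i directly
        mid = (bd[:n + 1] + bd[2 * n::-1][:n + 1]) / 2
        radii = np.hypot(*(mid[:-1] - center).T)
        assert np.allclose(radii, r, atol=1.0)

    def test_resampling_to_21_points_gives_20_intervals(self):
        fine = FineInstantiation(
            boundary=np.zeros((21, 2), int), midline=np.zeros((5, 2)),
            head_tip_index=10, log_post=0.0)
        fine.boundary[:, 1] = np.concatenate(
            [np.arange(10), [10], np.arange(9, -1, -1)])
        fine.boundary[:11, 0] = 5
        fine.boundary[11:, 0] = 9
        mid = boundaries_to_midline(fine, n_samples=21)
        assert mid.shape == (21, 2)
        seg = np.hypot(*np.diff(mid, axis=0).T)
        # intervals are equal in arc length along the midline polyline
        # (chords across its one corner may be marginally shorter)
        assert np.allclose(seg, seg[0], atol=0.02)

    def test_degenerate_boundary_rejected(self):
        fine = FineInstantiation(boundary=np.zeros((9, 2), int),
                                 midline=np.zeros((5, 2)),
                                 head_tip_index=4, log_post=0.0)
        with pytest.raises(ValueError):
            boundaries_to_midline(fine)
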