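"""Skeleton, curvature and spectrum similarity metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_genome
from shapevolve import (
    AlignmentConfig,
    AmplitudeSpectrum,
    SkeletonPoints,
    SynthConfig,
    contour_spectrum,
    curvature_distance,
    rasterize,
    skeleton_distance,
    skeletonize,
    spectrum_distance,
    synthesize_contour,
)
from shapevolve.similarity import SimilarityError
from shapevolve.synthesis import ShapeContour, ShapeMask


def brute_force_skeleton_distance(d_pts, t_pts, step=1.0):
    """Independent alignment oracle: centroid translation + exhaustive
    rotation grid, mean nearest-neighbor distance by explicit pairwise
    distances."""
    d = d_pts - d_pts.mean(axis=0)
    t = t_pts - t_pts.mean(axis=0)
    best = np.inf
    for deg in np.arange(0.0, 360.0, step):
        a = np.deg2rad(deg)
        rx = d[:, 0] * np.cos(a) - d[:, 1] * np.sin(a)
        ry = d[:, 0] * np.sin(a) + d[:, 1] * np.cos(a)
        rot = np.column_stack([rx, ry])
        dists = np.sqrt(((rot[:, None, :] - t[None, :, :]) ** 2).sum(-1))
        best = min(best, dists.min(axis=1).mean())
    return best


class TestSkeletonize:
    def test_horizontal_bar_skeleton_is_a_line(self):
        grid = np.zeros((9, 20), bool)
        grid[4, 2:18] = True
        sk = skeletonize(ShapeMask(grid))
        assert len(sk) <= 16
        assert np.all(sk.points[:, 1] == 4)

    def test_disc_collapses_to_central_cluster(self):
        yy, xx = np.mgrid[:61, :61]
        disc = (xx - 30) ** 2 + (yy - 30) ** 2 <= 28**2
        sk = skeletonize(ShapeMask(disc))
        span = sk.points.max(axis=0) - sk.points.min(axis=0)
        assert max(span) <= 3

    def test_thin_mask_is_a_fixed_point(self):
        grid = np.zeros((9, 20), bool)
        grid[4, 2:18] = True
        sk = skeletonize(ShapeMask(grid))
        assert len(sk) == grid.sum()

    def test_skeleton_points_are_foreground(self):
        c = synthesize_contour(make_genome({2: 30.0, 5: 12.0}))
        mask = rasterize(c, fill=True)
        sk = skeletonize(mask)
        xs = sk.points[:, 0].astype(int)
        ys = sk.points[:, 1].astype(int)
        assert np.all(mask.grid[ys, xs])

    def test_no_2x2_block_after_thinning(self):
        c = synthesize_contour(make_genome({3: 25.0}))
        mask = rasterize(c, fill=True)
        sk = skeletonize(mask)
        grid = np.zeros(mask.grid.shape, bool)
        grid[sk.points[:, 1].astype(int), sk.points[:, 0].astype(int)] = True
        blocks = grid[:-1, :-1] & grid[1:, :-1] & grid[:-1, 1:] & grid[1:, 1:]
        assert not blocks.any()


class TestSkeletonDistance:
    def test_self_distance_is_zero(self):
        pts = SkeletonPoints(np.array([[1.0, 2.0], [5.0, 7.0], [9.0, 3.0]]), (32, 32))
        assert skeleton_distance(pts, pts) == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self):
        base = np.array([[1.0, 2.0], [5.0, 7.0], [9.0, 3.0], [4.0, 4.0]])
        a = SkeletonPoints(base, (32, 32))
        b = SkeletonPoints(base + [13.0, -2.0], (32, 32))
        assert skeleton_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_rotated_copy_recovered_by_alignment_search(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 32, (15, 2))
        ang = np.deg2rad(37.0)  # multiple of the 1-degree search step
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        a = SkeletonPoints(base, (32, 32))
        b = SkeletonPoints((base - base.mean(0)) @ rot.T + base.mean(0), (32, 32))
        assert skeleton_distance(b, a) < 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0, 32, (12, 2))
        t = rng.uniform(0, 32, (12, 2))
        got = skeleton_distance(SkeletonPoints(d, (32, 32)), SkeletonPoints(t, (32, 32)))
        want = brute_force_skeleton_distance(d, t)
        assert got == pytest.approx(want, abs=1e-9)

    def test_common_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0, 32, (10, 2))
        t = rng.uniform(0, 32, (10, 2))
        base = skeleton_distance(SkeletonPoints(d, (32, 32)), SkeletonPoints(t, (32, 32)))
        ang = np.deg2rad(90.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = skeleton_distance(
            SkeletonPoints(d @ rot.T + [4, 7], (32, 32)),
            SkeletonPoints(t @ rot.T + [4, 7], (32, 32)),
        )
        assert moved == pytest.approx(base, abs=1e-6)

    def test_empty_skeleton_rejected(self):
        with pytest.raises(SimilarityError):
            SkeletonPoints(np.empty((0, 2)), (32, 32))


class TestCurvatureDistance:
    def test_self_distance_zero(self):
        c = synthesize_contour(make_genome({2: 20.0}))
        assert curvature_distance(c, c) == 0.0

    def test_circle_vs_square_closed_form(self):
        circle = synthesize_contour(make_genome({}))
        square = ShapeContour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert curvature_distance(circle, square) == pytest.approx(abs(16 - 4 * np.pi), abs=2e-3)

    def test_rigid_motion_and_scale_invariance(self):
        a = synthesize_contour(make_genome({3: 20.0}))
        b = synthesize_contour(make_genome({5: 12.0}))
        base = curvature_distance(a, b)
        assert curvature_distance(a.rotated(33.0).translated(7, -4), b) == pytest.approx(base, abs=1e-9)
        assert curvature_distance(a.scaled(2.5), b) == pytest.approx(base, abs=1e-9)


class TestContourSpectrum:
    def test_constant_radius_has_empty_spectrum(self):
        c = synthesize_contour(make_genome({}))
        spec = contour_spectrum(c, 10)
        assert np.all(spec.amps < 1e-9)

    def test_single_frequency_peak_recovery(self):
        g = make_genome({6: 40.0})
        c = synthesize_contour(g)
        spec = contour_spectrum(c, 10)
        # amp_scale (0.3) times genome amplitude recovered at f=6
        assert spec.amps[5] == pytest.approx(0.3 * 40.0, rel=1e-9)
        off = np.delete(spec.amps, 5)
        assert np.all(off < 0.01 * spec.amps[5])

    def test_rigid_rotation_invariance(self):
        c = synthesize_contour(make_genome({2: 30.0, 7: 8.0}))
        spec1 = contour_spectrum(c, 20).amps
        spec2 = contour_spectrum(c.rotated(61.3).translated(3, 9), 20).amps
        assert np.allclose(spec1, spec2, rtol=1e-6, atol=1e-12)

    def test_k_out_of_range_rejected(self):
        c = synthesize_contour(make_genome({}))
        with pytest.raises(SimilarityError):
            contour_spectrum(c, 360)
        with pytest.raises(SimilarityError):
            contour_spectrum(c, 0)


class TestSpectrumDistance:
    def test_identical_spectra(self):
        s = AmplitudeSpectrum(np.array([1.0, 2.0, 3.0]))
        assert spectrum_distance(s, s) == 0.0

    def test_single_coordinate_difference(self):
        a = AmplitudeSpectrum(np.array([5.0, 2.0]))
        b = AmplitudeSpectrum(np.array([2.0, 2.0]))
        assert spectrum_distance(a, b) == 3.0

    def test_zero_padding_of_shorter_spectrum(self):
        short = AmplitudeSpectrum(np.ones(10))
        long = AmplitudeSpectrum(np.concatenate([np.ones(10), np.full(349, 2.0)]))
        assert spectrum_distance(short, long) == pytest.approx(2.0 * np.sqrt(349))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 100), min_size=1, max_size=12),
        st.lists(st.floats(0, 100), min_size=1, max_size=12),
        st.lists(st.floats(0, 100), min_size=1, max_size=12),
    )
    def test_metric_axioms(self, xs, ys, zs):
        a, b, c = (AmplitudeSpectrum(np.array(v)) for v in (xs, ys, zs))
        dab = spectrum_distance(a, b)
        assert dab >= 0
        assert spectrum_distance(b, a) == pytest.approx(dab)
        assert spectrum_distance(a, a) == 0.0
        assert dab <= spectrum_distance(a, c) + spectrum_distance(c, b) + 1e-9
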