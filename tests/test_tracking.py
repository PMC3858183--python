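import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import directed_hausdorff

import qatract as qt
from qatract.recon import ConfigurationError
from qatract.tracking import trilinear_neighborhood

from conftest import make_field_peakmap, make_two_peak_voxel


def straight_field(tess, shape=(9, 5, 5), axis=(1.0, 0.0, 0.0)):
    dirs = np.zeros(shape + (3,))
    dirs[...] = np.asarray(axis)
    return make_field_peakmap(tess, dirs, np.ones(shape))


def smooth_random_field(tess, shape=(5, 5, 5), seed=3):
    rng = np.random.default_rng(seed)
    v = gaussian_filter(rng.normal(size=shape + (3,)), sigma=(1.5, 1.5, 1.5, 0))
    v[..., 0] += 2.0  # dominant +x so the field is trackable
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    return make_field_peakmap(tess, v, np.ones(shape)), v


def fact_track(seed, u0, dirs_field, shape, cos_ang=0.5, max_steps=500):
    """Independent FACT oracle: follow the nearest voxel's fiber to the voxel
    boundary, re-select, repeat; stop on angular failure or exit."""
    r = np.asarray(seed, float).copy()
    u = np.asarray(u0, float)
    pts = [r.copy()]
    for _ in range(max_steps):
        R = np.round(r).astype(int)
        if np.any(R < 0) or np.any(R >= np.asarray(shape)):
            break
        a = dirs_field[tuple(R)]
        d = float(a @ u)
        if abs(d) <= cos_ang:
            break
        v = a if d >= 0 else -a
        ts = []
        for c in range(3):
            if v[c] > 1e-12:
                ts.append((R[c] + 0.5 - r[c]) / v[c])
            elif v[c] < -1e-12:
                ts.append((R[c] - 0.5 - r[c]) / v[c])
        r = r + (min(ts) + 1e-6) * v
        pts.append(r.copy())
        u = v
    return np.asarray(pts)


def bidirectional_fact(seed, u0, dirs_field, shape):
    f = fact_track(seed, u0, dirs_field, shape)
    b = fact_track(seed, -np.asarray(u0), dirs_field, shape)
    return np.vstack([b[::-1], f[1:]]) if len(b) > 1 else f


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"angular_threshold": 0.0},
            {"angular_threshold": 95.0},
            {"step_size": -1.0},
            {"termination_weight": 0.0},
            {"termination_weight": 1.5},
            {"index_name": "adc"},
            {"interpolation": "spline"},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            qt.TrackingParams(index_threshold=0.1, **kw)


class TestNeighborhood:
    def test_paper_worked_example(self):
        n = trilinear_neighborhood(np.array([32.3, 12.4, 16.9]))
        got = {tuple(v) for v in n}
        want = {(x, y, z) for x in (32, 33) for y in (12, 13) for z in (16, 17)}
        assert got == want

    def test_always_eight_distinct_voxels(self):
        rng = np.random.default_rng(0)
        for r in rng.uniform(0.01, 60.0, size=(200, 3)):
            n = trilinear_neighborhood(r)
            assert len(np.unique(n, axis=0)) == 8


class TestSelectFiber:
    def test_antipodal_fiber_is_sign_flipped(self, tess3):
        pk = straight_field(tess3, (1, 1, 1))
        params = qt.TrackingParams(index_threshold=0.5)
        out = qt.select_fiber((0, 0, 0), np.array([-1.0, 0, 0]), pk, params)
        assert np.allclose(out, [-1.0, 0.0, 0.0], atol=1e-9)
        out = qt.select_fiber((0, 0, 0), np.array([1.0, 0, 0]), pk, params)
        assert np.allclose(out, [1.0, 0.0, 0.0], atol=1e-9)

    def test_smallest_turning_angle_wins(self, tess3):
        """Fibers near 30 and 70 degrees from u, 60-degree threshold: only
        the 30-degree fiber qualifies and is returned."""
        hemi = tess3.hemisphere_vertices

        def nearest(angle_deg):
            t = np.radians(angle_deg)
            target = np.array([np.cos(t), np.sin(t), 0.0])
            return int(np.argmax(np.abs(hemi @ target)))

        vert = np.full((1, 1, 1, 3), -1, dtype=np.int64)
        qa = np.zeros((1, 1, 1, 3))
        vert[0, 0, 0, :2] = [nearest(30.0), nearest(70.0)]
        qa[0, 0, 0, :2] = [1.0, 1.0]
        pk = qt.PeakMap(peak_vertex=vert, peak_qa=qa, tessellation=tess3,
                        z0=1.0, voxel_size=np.ones(3))
        params = qt.TrackingParams(index_threshold=0.5, angular_threshold=60.0)
        out = qt.select_fiber((0, 0, 0), np.array([1.0, 0, 0]), pk, params)
        ang = np.degrees(np.arccos(abs(out @ np.array([1.0, 0, 0]))))
        assert ang == pytest.approx(30.0, abs=5.0)

    def test_equal_angle_tie_breaks_to_larger_qa(self, tess3):
        """Two fibers symmetric about the z axis have identical |<u, a>|; the
        one with larger QA must be chosen (checked against enumeration)."""
        hemi = tess3.hemisphere_vertices
        u = np.array([0.0, 0.0, 1.0])
        z = np.round(np.abs(hemi @ u), 12)
        vals, counts = np.unique(z, return_counts=True)
        tied = vals[(counts >= 2) & (vals > 0.5) & (vals < 0.99)][0]
        pair = np.flatnonzero(z == tied)[:2]
        vert = np.full((1, 1, 1, 3), -1, dtype=np.int64)
        qa = np.zeros((1, 1, 1, 3))
        vert[0, 0, 0, :2] = pair
        qa[0, 0, 0, :2] = [0.6, 0.9]
        pk = qt.PeakMap(peak_vertex=vert, peak_qa=qa, tessellation=tess3,
                        z0=1.0, voxel_size=np.ones(3))
        params = qt.TrackingParams(index_threshold=0.5, angular_threshold=90.0)
        out = qt.select_fiber((0, 0, 0), u, pk, params)
        expect = hemi[pair[1]]  # enumeration: equal angle, larger qa
        assert np.allclose(np.abs(out), np.abs(expect), atol=1e-12)

    def test_no_qualifying_fiber_returns_none(self, tess3):
        pk = straight_field(tess3, (1, 1, 1))
        params = qt.TrackingParams(index_threshold=2.0)  # above every qa
        assert qt.select_fiber((0, 0, 0), np.array([1.0, 0, 0]), pk, params) is None


class TestPropagation:
    def test_all_weight_on_lattice_point(self, tess3):
        pk = straight_field(tess3, (3, 3, 3))
        params = qt.TrackingParams(index_threshold=0.5)
        u, w = qt.propagation_direction(np.array([1.0, 1.0, 1.0]),
                                        np.array([1.0, 0, 0]), pk, params)
        assert w == pytest.approx(1.0)
        assert np.allclose(u, [1.0, 0, 0], atol=1e-9)

    def test_cell_midpoint_splits_weight_eight_ways(self, tess3):
        pk = straight_field(tess3, (3, 3, 3))
        params = qt.TrackingParams(index_threshold=0.5)
        u, w = qt.propagation_direction(np.array([0.5, 0.5, 0.5]),
                                        np.array([1.0, 0, 0]), pk, params)
        assert w == pytest.approx(1.0, abs=1e-12)  # 8 x (0.5)^3
        assert np.allclose(u, [1.0, 0, 0], atol=1e-9)

    def test_out_of_bounds_terminates_with_zero_weight(self, tess3):
        pk = straight_field(tess3, (3, 3, 3))
        params = qt.TrackingParams(index_threshold=0.5)
        u, w = qt.propagation_direction(np.array([10.0, 1.0, 1.0]),
                                        np.array([1.0, 0, 0]), pk, params)
        assert u is None and w == 0.0

    def test_weight_below_half_terminates(self, tess3):
        """A point deep in empty space next to a single qualifying voxel has
        w < 0.5 and must stop."""
        shape = (5, 3, 3)
        dirs = np.zeros(shape + (3,))
        qa = np.zeros(shape)
        dirs[2, 1, 1] = [1.0, 0, 0]
        qa[2, 1, 1] = 1.0
        pk = make_field_peakmap(qt.build_tessellation(3), dirs, qa)
        params = qt.TrackingParams(index_threshold=0.5)
        u, w = qt.propagation_direction(np.array([2.6, 1.0, 1.0]),
                                        np.array([1.0, 0, 0]), pk, params)
        assert u is None and w == pytest.approx(0.4, abs=1e-12)


class TestTrackFromSeed:
    def test_straight_field_spans_bundle(self, tess3):
        pk = straight_field(tess3, (9, 5, 5))
        params = qt.TrackingParams(index_threshold=0.5, step_size=0.25,
                                   min_length=0.0, max_length=50.0)
        sl = qt.track_from_seed(np.array([4.0, 2.0, 2.0]),
                                np.array([1.0, 0, 0]), pk, params)
        extent = sl.points[-1, 0] - sl.points[0, 0]
        assert extent == pytest.approx(9.0, abs=1.0)  # bundle is 9 voxels of 1 mm
        assert len(sl.points) == pytest.approx(extent / 0.25 + 1, abs=2)
        # consecutive points are step_size apart
        seg = np.linalg.norm(np.diff(sl.points, axis=0), axis=1)
        assert np.allclose(seg, 0.25, atol=1e-6)

    def test_sharp_bend_terminates_before_elbow(self, tess3):
        """A 90-degree elbow with a 60-degree angular threshold: the track
        must stop before the corner, never turn through it."""
        shape = (10, 10, 3)
        dirs = np.zeros(shape + (3,))
        qa = np.zeros(shape)
        dirs[0:5, 2, :] = [1.0, 0, 0]
        qa[0:5, 2, :] = 1.0
        dirs[5, 2:8, :] = [0.0, 1.0, 0]
        qa[5, 2:8, :] = 1.0
        pk = make_field_peakmap(tess3, dirs, qa)
        params = qt.TrackingParams(index_threshold=0.5, angular_threshold=60.0,
                                   step_size=0.2, min_length=0.0, max_length=50.0)
        sl = qt.track_from_seed(np.array([1.0, 2.0, 1.0]),
                                np.array([1.0, 0, 0]), pk, params)
        assert sl.points[:, 0].max() <= 5.5
        assert sl.points[:, 1].max() <= 2.5  # never turned up the elbow

    def test_below_min_length_returns_none(self, tess3):
        pk = straight_field(tess3, (9, 5, 5))
        params = qt.TrackingParams(index_threshold=0.5, step_size=0.25,
                                   min_length=40.0)
        assert qt.track_from_seed(np.array([4.0, 2.0, 2.0]),
                                  np.array([1.0, 0, 0]), pk, params) is None

    def test_fact_limit_matches_oracle(self, tess3):
        pk, field = smooth_random_field(tess3, seed=3)
        pkdirs = pk.peak_dirs[..., 0, :]
        params = qt.TrackingParams(index_threshold=0.5, interpolation="nearest",
                                   step_size=0.01, min_length=0.0, max_length=30.0)
        rng = np.random.default_rng(17)
        for _ in range(5):
            seed = rng.uniform(1.0, 3.0, 3)
            u0 = pkdirs[tuple(np.round(seed).astype(int))]
            ours = qt.track_from_seed(seed, u0, pk, params).points
            ref = bidirectional_fact(seed, u0, pkdirs, (5, 5, 5))
            h = max(directed_hausdorff(ours, ref)[0],
                    directed_hausdorff(ref, ours)[0])
            assert h <= 1.0


class TestGenerateTractography:
    def test_identical_seeds_give_identical_tractograms(self, tess3):
        pk, _ = smooth_random_field(tess3, shape=(8, 8, 8), seed=5)
        params = qt.TrackingParams(index_threshold=0.5, step_size=0.4,
                                   min_length=2.0, max_length=20.0,
                                   target_track_count=40, rng_seed=123)
        t1 = qt.generate_tractography(pk, params)
        t2 = qt.generate_tractography(pk, params)
        assert len(t1) == len(t2) == 40
        for a, b in zip(t1.streamlines, t2.streamlines):
            assert np.array_equal(a.points, b.points)

    def test_target_count_is_exact_with_permissive_filters(self, tess3):
        pk = straight_field(tess3, (30, 6, 6))
        params = qt.TrackingParams(index_threshold=0.5, step_size=0.5,
                                   min_length=5.0, max_length=100.0,
                                   target_track_count=100, rng_seed=2)
        tg = qt.generate_tractography(pk, params)
        assert len(tg) == 100
        assert not tg.warnings

    def test_short_fragments_are_discarded(self, tess3):
        """20 mm fragments against a 40 mm minimum: nothing survives and the
        budget exhausts with a warning record."""
        pk = straight_field(tess3, (20, 5, 5))  # 1 mm voxels -> ~20 mm tracks
        params = qt.TrackingParams(index_threshold=0.5, step_size=0.5,
                                   min_length=40.0, target_track_count=10,
                                   seed_budget=300, rng_seed=0)
        tg = qt.generate_tractography(pk, params)
        assert len(tg) == 0
        assert tg.warnings

    def test_roi_filter_modes(self, tess3):
        pk = straight_field(tess3, (30, 6, 6))
        params = qt.TrackingParams(index_threshold=0.5, step_size=0.5,
                                   min_length=5.0, target_track_count=20,
                                   rng_seed=4)
        mid = qt.RoiFilter(center=np.array([15.0, 3.0, 3.0]), radius=4.0)
        tg = qt.generate_tractography(pk, params, roi_filters=(mid,))
        for sl in tg.streamlines:
            assert mid.accepts(sl)
        far = qt.RoiFilter(center=np.array([15.0, 50.0, 3.0]), radius=2.0)
        params2 = qt.TrackingParams(index_threshold=0.5, step_size=0.5,
                                    min_length=5.0, target_track_count=5,
                                    seed_budget=200, rng_seed=4)
        tg2 = qt.generate_tractography(pk, params2, roi_filters=(far,))
        assert len(tg2) == 0

    def test_angular_constraint_holds_along_streamlines(self, tess3):
        pk, _ = smooth_random_field(tess3, shape=(8, 8, 8), seed=9)
        params = qt.TrackingParams(index_threshold=0.5, angular_threshold=60.0,
                                   step_size=0.4, min_length=2.0,
                                   max_length=20.0, target_track_count=30,
                                   rng_seed=6)
        tg = qt.generate_tractography(pk, params)
        cos_thr = np.cos(np.radians(60.0))
        for sl in tg.streamlines:
            seg = np.diff(sl.points, axis=0)
            seg /= np.linalg.norm(seg, axis=1, keepdims=True)
            dots = np.einsum("ij,ij->i", seg[:-1], seg[1:])
            assert np.all(dots >= cos_thr - 1e-9)

    def test_termination_soundness(self, tess3):
        """At every returned endpoint, continuing is impossible: w < 0.5,
        out of bounds, or the length cap was hit."""
        pk, _ = smooth_random_field(tess3, shape=(8, 8, 8), seed=9)
        params = qt.TrackingParams(index_threshold=0.5, step_size=0.4,
                                   min_length=2.0, max_length=20.0,
                                   target_track_count=30, rng_seed=8)
        tg = qt.generate_tractography(pk, params)
        for sl in tg.streamlines:
            if sl.length >= params.max_length - params.step_size:
                continue
            for end, into in ((sl.points[0], sl.points[0] - sl.points[1]),
                              (sl.points[-1], sl.points[-1] - sl.points[-2])):
                r = end / pk.voxel_size  # mm -> voxel (identity affine)
                u = into / np.linalg.norm(into)
                d, w = qt.propagation_direction(r, u, pk, params)
                assert d is None and w < params.termination_weight

    def test_raising_threshold_never_extends_coverage(self, tess3):
        """Index monotonicity: the union of voxels visited by tracks from a
        fixed seed list shrinks (or stays) as the QA threshold rises."""
        pk, _ = smooth_random_field(tess3, shape=(8, 8, 8), seed=12)
        # graded qa so thresholds bite
        rng = np.random.default_rng(1)
        pk.peak_qa[..., 0] = rng.uniform(0.2, 1.0, pk.shape)
        seeds = [rng.uniform(1.0, 6.0, 3) for _ in range(15)]

        def visited(thr):
            params = qt.TrackingParams(index_threshold=thr, step_size=0.4,
                                       min_length=0.0, max_length=20.0)
            vox = set()
            for s in seeds:
                u0 = pk.peak_dirs[tuple(np.round(s).astype(int))][0]
                sl = qt.track_from_seed(s, u0, pk, params)
                if sl is not None:
                    for p in np.round(sl.points / pk.voxel_size).astype(int):
                        vox.add(tuple(p))
            return vox

        v_low, v_mid, v_high = visited(0.3), visited(0.5), visited(0.7)
        assert v_high <= v_mid <= v_low

    def test_voxel_level_index_swap_changes_filtering_not_algorithm(self, tess3):
        """The same tracker runs with FA as the index; with a permissive FA
        threshold it reproduces the QA run's geometry on a clean field."""
        pk = straight_field(tess3, (30, 6, 6))
        qt.attach_scalar_indices(pk, fa_map=np.full((30, 6, 6), 0.9))
        common = dict(step_size=0.5, min_length=5.0, target_track_count=25,
                      rng_seed=3)
        t_qa = qt.generate_tractography(
            pk, qt.TrackingParams(index_threshold=0.5, index_name="qa", **common))
        t_fa = qt.generate_tractography(
            pk, qt.TrackingParams(index_threshold=0.5, index_name="fa", **common))
        assert len(t_qa) == len(t_fa)
        for a, b in zip(t_qa.streamlines, t_fa.streamlines):
            assert np.array_equal(a.points, b.points)
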