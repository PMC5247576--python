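"""Video pipeline: Otsu, segmentation, linking, drift, stuck cells, speeds."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats
from skimage.filters import threshold_otsu as skimage_otsu

from electrogenetics import synth, tracking
from electrogenetics.tracking import Detection


# ---------------------------------------------------------------------------
# independent oracles


def otsu_brute_force(hist):
    """Exhaustive between-class variance maximizer, plain loops."""
    hist = [float(h) for h in hist]
    total = sum(hist)
    best_t, best_v = None, -1.0
    for t in range(1, len(hist)):
        w0 = sum(hist[:t])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(i * h for i, h in enumerate(hist[:t])) / w0
        mu1 = sum(i * hist[i] for i in range(t, len(hist))) / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-9 * max(best_v, 1.0):
            best_t, best_v = t, v
    return best_t


def assignment_brute_force(cost, forbidden=1e8):
    """Minimum-cost maximum-cardinality matching by exhaustive enumeration."""
    na, nb = cost.shape
    allowed = [(i, j) for i in range(na) for j in range(nb)
               if cost[i, j] < forbidden]
    best = (0, 0.0, [])  # (-cardinality, cost, pairs)
    best_pairs, best_card, best_cost = [], 0, 0.0
    for r in range(min(na, nb), 0, -1):
        found = False
        for combo in itertools.combinations(allowed, r):
            rows = {i for i, _ in combo}
            cols = {j for _, j in combo}
            if len(rows) < r or len(cols) < r:
                continue
            c = sum(cost[i, j] for i, j in combo)
            if not found or c < best_cost - 1e-12:
                best_pairs, best_cost = sorted(combo), c
                found = True
        if found:
            best_card = r
            break
    return best_pairs


def make_detection(frame, x, y, area=25, intensity=120.0):
    return Detection(frame_index=frame, centroid=(x, y), area=area,
                     mean_intensity=intensity)


# ---------------------------------------------------------------------------
# Otsu thresholding


class TestOtsu:
    def test_two_delta_peaks_tie_breaks_low(self):
        hist = np.zeros(256)
        hist[50] = 1000
        hist[200] = 1000
        # every threshold in (50, 200] separates the peaks equally well;
        # the tie rule picks the lowest
        assert tracking.otsu_threshold(hist) == 51

    def test_matches_brute_force_on_random_histograms(self, rng):
        for _ in range(50):
            hist = rng.integers(0, 1000, size=256)
            if np.count_nonzero(hist) < 2:
                continue
            assert tracking.otsu_threshold(hist) == otsu_brute_force(hist)

    def test_single_bin_degenerate(self):
        hist = np.zeros(256)
        hist[88] = 500
        with pytest.raises(ValueError):
            tracking.otsu_threshold(hist)

    def test_agrees_with_skimage_on_bimodal_image(self, rng):
        img = np.concatenate([rng.normal(60, 8, 3000),
                              rng.normal(190, 12, 1500)])
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        hist = np.bincount(img, minlength=256)
        ours = tracking.otsu_threshold(hist)
        ref = skimage_otsu(img)
        # conventions differ by at most one level (< vs <= split)
        assert abs(ours - ref) <= 1


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.integers(0, 500), min_size=8, max_size=64))
def test_otsu_equals_exhaustive_search(hist):
    hist = np.array(hist)
    if np.count_nonzero(hist) < 2:
        return
    assert tracking.otsu_threshold(hist) == otsu_brute_force(hist)


# ---------------------------------------------------------------------------
# segmentation


class TestSegmentFrame:
    def test_square_blob_centroid_and_area(self):
        frame = np.zeros((40, 40), dtype=np.uint8)
        frame[20:25, 10:15] = 200  # rows 20..24 (y), cols 10..14 (x)
        dets = tracking.segment_frame(frame, threshold=100)
        assert len(dets) == 1
        assert dets[0].centroid == (12.0, 22.0)
        assert dets[0].area == 25

    def test_two_blobs(self):
        frame = np.zeros((40, 40), dtype=np.uint8)
        frame[5:10, 5:10] = 200
        frame[25:30, 25:30] = 180
        assert len(tracking.segment_frame(frame, threshold=100)) == 2

    def test_min_area_boundary(self):
        frame = np.zeros((20, 20), dtype=np.uint8)
        frame[5, 5:8] = 200  # area 3 < default min_area 4
        assert tracking.segment_frame(frame, threshold=100, min_area=4) == []
        assert len(tracking.segment_frame(frame, threshold=100, min_area=3)) == 1


# ---------------------------------------------------------------------------
# linking


class TestLinkDetections:
    def test_small_displacement_linked(self):
        a = [make_detection(0, 10.0, 10.0)]
        b = [make_detection(1, 13.0, 10.0)]
        assert tracking.link_detections(a, b, gate_radius=10.0) == [(0, 0)]

    def test_gate_forbids_long_jump(self):
        a = [make_detection(0, 10.0, 10.0)]
        b = [make_detection(1, 21.0, 10.0)]
        assert tracking.link_detections(a, b, gate_radius=10.0) == []

    def test_size_classes_prevent_swap(self):
        # two cells almost swapping positions, but with areas 20 vs 60:
        # the size term keeps each in its own class, matching the
        # brute-force minimum-total-cost assignment
        a = [make_detection(0, 10.0, 10.0, area=20),
             make_detection(0, 12.0, 10.0, area=60)]
        b = [make_detection(1, 13.0, 10.0, area=20),
             make_detection(1, 9.0, 10.0, area=60)]
        got = tracking.link_detections(a, b, gate_radius=10.0)
        cost = tracking.link_cost_matrix(a, b, (1.0, 0.5, 0.25), 10.0)
        assert got == assignment_brute_force(cost)
        assert got == [(0, 0), (1, 1)]

    def test_empty_inputs(self):
        assert tracking.link_detections([], [], gate_radius=5.0) == []

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(60):
            na, nb = rng.integers(1, 7), rng.integers(1, 7)
            a = [make_detection(0, *rng.uniform(0, 60, 2),
                                area=int(rng.integers(10, 80)),
                                intensity=float(rng.uniform(80, 220)))
                 for _ in range(na)]
            b = [make_detection(1, *rng.uniform(0, 60, 2),
                                area=int(rng.integers(10, 80)),
                                intensity=float(rng.uniform(80, 220)))
                 for _ in range(nb)]
            cost = tracking.link_cost_matrix(a, b, (1.0, 0.5, 0.25), 15.0)
            got = tracking.link_detections(a, b, gate_radius=15.0)
            expect = assignment_brute_force(cost)
            got_cost = sum(cost[i, j] for i, j in got)
            exp_cost = sum(cost[i, j] for i, j in expect)
            assert len(got) == len(expect)
            assert got_cost == pytest.approx(exp_cost, abs=1e-9)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            tracking.link_detections([], [], weights=(0, 0, 0), gate_radius=5.0)


# ---------------------------------------------------------------------------
# trajectories, drift, stuck cells, velocity


def straight_video(n_frames=30, speed_px=2.0, start=(10.0, 32.0)):
    """One cell moving straight along +x at speed_px per frame."""
    frames = np.full((n_frames, 64, 96), 20, dtype=np.uint8)
    yy, xx = np.mgrid[0:64, 0:96]
    for t in range(n_frames):
        cx = start[0] + speed_px * t
        blob = 200 * np.exp(-((xx - cx) ** 2 + (yy - start[1]) ** 2) / (2 * 1.5 ** 2))
        frames[t] = np.clip(20 + blob, 0, 255).astype(np.uint8)
    return tracking.VideoStack(frames=frames, fps=10.0, pixel_size=0.32)


class TestBuildTrajectories:
    def test_single_cell_single_full_track(self):
        video = straight_video()
        trajs = tracking.build_trajectories(video)
        assert len(trajs) == 1
        assert len(trajs[0]) == video.n_frames

    def test_long_gap_splits_track(self):
        video = straight_video(n_frames=40)
        frames = video.frames.copy()
        frames[18:22] = 20  # cell vanishes for 4 > max_gap frames
        video2 = tracking.VideoStack(frames=frames, fps=10.0, pixel_size=0.32)
        trajs = tracking.build_trajectories(video2, min_length=5)
        assert len(trajs) == 2

    def test_ground_truth_identity_on_generated_video(self):
        # seed chosen so no two cells cross within a blob diameter (merged
        # detections would legitimately split tracks)
        scen = synth.MotilityScenario(n_cells=10, swim_speed=15.0,
                                      tumble_rate=1.0, stuck_fraction=0.0,
                                      drift=(0.0, 0.0), seed=2)
        video, truth = synth.gen_motility_video(scen, height=400, width=400,
                                                n_frames=40)
        trajs = tracking.build_trajectories(video)
        full = [tr for tr in trajs if len(tr) == 40]
        assert len(full) == 10
        for tr in full:
            dists = np.linalg.norm(
                truth.positions[tr.frames] - tr.xy[:, None, :], axis=2).min(axis=1)
            assert dists.max() < 1.0


class TestEstimateDrift:
    def test_uniform_translation_recovered(self):
        # every cell carried by exactly (2, 0) px/frame
        trajs = []
        for k in range(6):
            frames = np.arange(20)
            xy = np.column_stack([10.0 + 7 * k + 2.0 * frames,
                                  np.full(20, 15.0 + 5 * k)])
            trajs.append(tracking.Trajectory(frames=frames, xy=xy,
                                             areas=np.full(20, 25),
                                             intensities=np.full(20, 150.0)))
        drift, no_link = tracking.estimate_drift(trajs, 20)
        assert np.allclose(drift[:, 0], 2.0, atol=1e-9)
        assert np.allclose(drift[:, 1], 0.0, atol=1e-9)
        assert not no_link.any()

    def test_half_stationary_half_random_matches_median(self, rng):
        n_frames = 30
        trajs = []
        for k in range(10):
            frames = np.arange(n_frames)
            if k < 5:
                xy = np.tile([50.0 + k, 60.0], (n_frames, 1))
            else:
                steps = rng.uniform(-6, 6, size=(n_frames - 1, 2))
                xy = np.vstack([[100.0 + k, 100.0],
                                100.0 + np.cumsum(steps, axis=0)])
            trajs.append(tracking.Trajectory(frames=frames, xy=xy,
                                             areas=np.full(n_frames, 25),
                                             intensities=np.full(n_frames, 150.0)))
        drift, _ = tracking.estimate_drift(trajs, n_frames, smooth_window=None)
        # the stationary half pins the estimate at zero displacement, and
        # the componentwise median lands nearby (between the stationary mass
        # and the random half's spread)
        assert np.all(np.abs(drift) <= 1.0)
        for k in range(n_frames - 1):
            disp = [tr.xy[k + 1] - tr.xy[k] for tr in trajs]
            med = np.median(np.array(disp), axis=0)
            assert np.all(np.abs(drift[k] - med) <= 3.5)

    def test_no_links_flagged_zero(self):
        drift, no_link = tracking.estimate_drift([], 5)
        assert np.all(drift == 0)
        assert no_link.all()


class TestStuckAndVelocity:
    def test_straight_swimmer_speed_arithmetic(self):
        video = straight_video(speed_px=2.0)
        trajs = tracking.build_trajectories(video)
        speed = tracking.compute_velocity(trajs[0], fps=10.0, pixel_size=0.32)
        # 2 px/frame * 0.32 um/px * 10 frames/s
        assert speed == pytest.approx(6.4, rel=0.02)

    def test_straight_swimmer_not_stuck(self):
        video = straight_video(speed_px=3.0)
        tr = tracking.build_trajectories(video)[0]
        stuck, _ = tracking.filter_stuck(tr, None, 0.32, 10.0)
        assert not stuck

    def test_stationary_cell_in_drifting_field_is_stuck(self):
        scen = synth.MotilityScenario(n_cells=8, swim_speed=18.0,
                                      tumble_rate=1.0, stuck_fraction=0.25,
                                      drift=(3.0, 1.5), seed=11)
        video, truth = synth.gen_motility_video(scen, n_frames=60)
        res = tracking.track_video(video, min_length=5)
        flagged = [tr for tr in res.trajectories if tr.stuck_flag]
        assert len(flagged) == int(truth.stuck.sum())
        for tr in flagged:
            cid = np.argmin(np.linalg.norm(
                truth.positions[tr.frames[0]] - tr.xy[0], axis=1))
            assert truth.stuck[cid]

    def test_partially_stuck_cell_flagged_partial(self):
        # stuck for the first 3 s, swimming afterwards
        n = 60
        frames = np.arange(n)
        xy = np.vstack([np.tile([30.0, 30.0], (30, 1)),
                        np.column_stack([30.0 + 3.0 * np.arange(1, 31),
                                         np.full(30, 30.0)])])
        tr = tracking.Trajectory(frames=frames, xy=xy,
                                 areas=np.full(n, 25),
                                 intensities=np.full(n, 150.0))
        stuck, pair_mask = tracking.filter_stuck(tr, None, 0.32, 10.0)
        assert not stuck
        assert tr.partial_stuck
        assert pair_mask[:20].all()          # stuck portion excluded
        assert not pair_mask[35:].any()      # swimming portion kept
        speed = tracking.compute_velocity(tr, 10.0, 0.32, pair_mask=pair_mask)
        assert speed == pytest.approx(3.0 * 0.32 * 10.0, rel=0.05)

    def test_stuck_trajectory_excluded_from_velocity(self):
        tr = tracking.Trajectory(frames=np.arange(20),
                                 xy=np.tile([5.0, 5.0], (20, 1)),
                                 areas=np.full(20, 25),
                                 intensities=np.full(20, 150.0))
        tracking.filter_stuck(tr, None, 0.32, 10.0)
        with pytest.raises(ValueError):
            tracking.compute_velocity(tr, 10.0, 0.32)

    def test_temporal_subsampling_invariance_straight(self):
        video = straight_video(speed_px=2.0, n_frames=40)
        tr = tracking.build_trajectories(video)[0]
        full = tracking.compute_velocity(tr, 10.0, 0.32)
        sub = tracking.Trajectory(frames=tr.frames[::2] // 2, xy=tr.xy[::2],
                                  areas=tr.areas[::2],
                                  intensities=tr.intensities[::2])
        half = tracking.compute_velocity(sub, 5.0, 0.32)
        assert half == pytest.approx(full, rel=0.01)


class TestTrajectoryRose:
    def test_rose_starts_at_origin(self):
        video = straight_video(speed_px=2.0)
        trajs = tracking.build_trajectories(video)
        roses = tracking.trajectory_rose(trajs, fps=10.0, pixel_size=0.32)
        assert len(roses) == 1
        assert np.allclose(roses[0][0], [0.0, 0.0])

    def test_rose_duration_window(self):
        video = straight_video(n_frames=50, speed_px=1.0)
        trajs = tracking.build_trajectories(video)
        roses = tracking.trajectory_rose(trajs, fps=10.0, pixel_size=0.32,
                                         duration=3.0)
        assert len(roses[0]) == 30  # 3 s at 10 fps

    def test_rose_path_length_matches_speed(self):
        video = straight_video(n_frames=50, speed_px=2.0)
        trajs = tracking.build_trajectories(video)
        rose = tracking.trajectory_rose(trajs, fps=10.0, pixel_size=0.32)[0]
        path = np.linalg.norm(np.diff(rose, axis=0), axis=1).sum()
        # speed 6.4 um/s over (30-1)/10 s of sampled path
        assert path == pytest.approx(6.4 * 2.9, rel=0.03)


class TestVelocityStatistics:
    def test_identical_groups(self):
        a = np.array([10.0, 12.0, 14.0, 16.0])
        ga, gb, t, p = tracking.velocity_statistics(a, a.copy())
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_unequal_sample_sizes(self, rng):
        # group sizes from the published velocity comparison (79 vs 117)
        a = rng.normal(20.0, 4.0, 79)
        b = rng.normal(14.0, 4.0, 117)
        ga, gb, t, p = tracking.velocity_statistics(a, b)
        assert ga.n == 79 and gb.n == 117
        assert p < 1e-4

    def test_against_t_distribution_oracle(self):
        a = np.array([19.8, 22.1, 20.5, 23.0, 21.2, 20.0])
        b = np.array([16.2, 17.5, 18.1, 15.9, 17.0])
        ga, gb, t, p = tracking.velocity_statistics(a, b)
        # pooled-variance Student's t computed from first principles
        na, nb = len(a), len(b)
        sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
               / (na + nb - 2))
        t_ref = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_ref = 2 * sstats.t.sf(abs(t_ref), na + nb - 2)
        assert t == pytest.approx(t_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)
        assert ga.sem == pytest.approx(a.std(ddof=1) / math.sqrt(na), rel=1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            tracking.velocity_statistics(np.array([1.0]))
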