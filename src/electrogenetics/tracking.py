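"""Motility video analysis: segmentation, linking, drift, velocities.

Re-implements the study's video pipeline for swimming bacteria: each frame
is thresholded with Otsu's method and segmented into connected components;
detections are linked frame-to-frame with a nearest-neighbour cost that
combines closeness, size similarity and pixel intensity; tracks are screened
for stuck cells and background flow before per-cell velocities and
origin-translated trajectory roses are computed.

Image convention: (x = column, y = row), origin at the top-left corner,
pixel centres at integer coordinates.  16-bit inputs are min-max rescaled to
8 bits before thresholding; Otsu runs on a 256-bin histogram per frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from skimage import measure

#: cost of a forbidden (out-of-gate) pairing; must dwarf any real total cost
_FORBIDDEN = 1e9


@dataclass
class VideoStack:
    """Grayscale time-lapse stack with acquisition metadata.

    frames: (n_frames, H, W) integer array; fps frames/second; pixel_size
    in micrometres per pixel.
    """

    frames: np.ndarray
    fps: float = 10.0
    pixel_size: float = 0.32

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need a (n_frames, H, W) stack with >= 2 frames")
        if self.fps <= 0 or self.pixel_size <= 0:
            raise ValueError("fps and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass(frozen=True)
class Detection:
    """A segmented cell in one frame: continuous centroid (x, y) in pixels,
    area in pixels, mean intensity of member pixels."""

    frame_index: int
    centroid: tuple[float, float]
    area: int
    mean_intensity: float


@dataclass
class Trajectory:
    """A linked track: per-detection frame indices and centroids, with QC
    flags filled in by the drift/stuck/velocity steps."""

    frames: np.ndarray                   # strictly increasing frame indices
    xy: np.ndarray                       # (n, 2) centroids, pixels
    areas: np.ndarray
    intensities: np.ndarray
    stuck_flag: bool = False
    partial_stuck: bool = False
    drift_corrected: bool = False
    mean_speed: float = float("nan")     # um/s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.size > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.frames.size)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold on an intensity histogram.

    Returns the level ``t`` that maximizes the between-class variance of the
    split {levels < t} vs {levels >= t}; ties break toward the lower level.
    Raises on degenerate (single-valued) histograms.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("histogram must be 1-D with >= 2 bins")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be nonnegative")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: fewer than 2 nonzero bins")

    total = hist.sum()
    levels = np.arange(hist.size, dtype=float)
    w0 = np.cumsum(hist)[:-1]            # mass of {levels < t} for t = 1..L-1
    w1 = total - w0
    m0 = np.cumsum(hist * levels)[:-1]   # first moment below t
    m1 = (hist * levels).sum() - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, m1 / w1, 0.0)
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    return int(np.argmax(sigma_b)) + 1


def between_class_fraction(histogram: np.ndarray, threshold: int) -> float:
    """Between-class variance at ``threshold`` divided by total variance.

    The separation-quality score in [0, 1] used to judge bimodality.
    """
    hist = np.asarray(histogram, dtype=float)
    total = hist.sum()
    levels = np.arange(hist.size, dtype=float)
    mu = (hist * levels).sum() / total
    var_total = (hist * (levels - mu) ** 2).sum() / total
    if var_total == 0:
        return 0.0
    w0 = hist[:threshold].sum() / total
    w1 = 1.0 - w0
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (hist[:threshold] * levels[:threshold]).sum() / (w0 * total)
    mu1 = (hist[threshold:] * levels[threshold:]).sum() / (w1 * total)
    return float(w0 * w1 * (mu0 - mu1) ** 2 / var_total)


def rescale_to_uint8(frame: np.ndarray) -> np.ndarray:
    """Min-max rescale any integer frame to the 0..255 range."""
    frame = np.asarray(frame)
    lo, hi = int(frame.min()), int(frame.max())
    if hi == lo:
        return np.zeros_like(frame, dtype=np.uint8)
    scaled = (frame.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.round(scaled).astype(np.uint8)


def frame_threshold(frame: np.ndarray,
                    max_foreground_fraction: float = 0.2) -> tuple[np.ndarray, int]:
    """Per-frame Otsu threshold on the 8-bit rescaled image.

    Fluorescent cells cover a tiny fraction of the field; with such extreme
    class imbalance a single global Otsu pass can land inside the
    background noise.  When the above-threshold fraction exceeds
    ``max_foreground_fraction`` the threshold is therefore re-derived from
    the upper part of the histogram (iterated Otsu), which climbs out of
    the background mode.  Returns the rescaled frame and the threshold.
    """
    frame8 = frame if (frame.dtype == np.uint8) else rescale_to_uint8(frame)
    hist = np.bincount(frame8.ravel(), minlength=256)
    total = hist.sum()
    lo = 0
    thr = otsu_threshold(hist)
    for _ in range(8):
        if hist[thr:].sum() / total <= max_foreground_fraction:
            break
        if np.count_nonzero(hist[thr:]) < 2:
            break
        lo = thr
        thr = lo + otsu_threshold(hist[lo:])
    return frame8, thr


def segment_frame(frame: np.ndarray, threshold: float, min_area: int = 4,
                  frame_index: int = 0) -> list[Detection]:
    """Connected components (8-connectivity) of the at-or-above-threshold
    mask; components smaller than ``min_area`` pixels are discarded.

    Centroids are intensity-unweighted means of member pixel coordinates,
    reported as (x = column, y = row).
    """
    frame = np.asarray(frame)
    mask = frame >= threshold
    labels = measure.label(mask, connectivity=2)
    out: list[Detection] = []
    for region in measure.regionprops(labels, intensity_image=frame):
        if region.area < min_area:
            continue
        row, col = region.centroid
        out.append(Detection(frame_index=frame_index,
                             centroid=(float(col), float(row)),
                             area=int(region.area),
                             mean_intensity=float(region.intensity_mean)))
    return out


def link_cost_matrix(dets_a: list[Detection], dets_b: list[Detection],
                     weights: tuple[float, float, float],
                     gate_radius: float) -> np.ndarray:
    """Pairwise linking costs; out-of-gate pairs get the forbidden cost."""
    w_d, w_s, w_i = weights
    na, nb = len(dets_a), len(dets_b)
    cost = np.full((na, nb), _FORBIDDEN)
    if na == 0 or nb == 0:
        return cost
    areas = [d.area for d in dets_a] + [d.area for d in dets_b]
    ints = [d.mean_intensity for d in dets_a] + [d.mean_intensity for d in dets_b]
    max_area = max(areas) or 1.0
    max_int = max(ints) or 1.0
    for i, a in enumerate(dets_a):
        for j, b in enumerate(dets_b):
            dist = math.hypot(a.centroid[0] - b.centroid[0],
                              a.centroid[1] - b.centroid[1])
            if dist > gate_radius:
                continue
            cost[i, j] = (w_d * dist / gate_radius
                          + w_s * abs(a.area - b.area) / max_area
                          + w_i * abs(a.mean_intensity - b.mean_intensity) / max_int)
    return cost


def link_detections(
    dets_a: list[Detection],
    dets_b: list[Detection],
    weights: tuple[float, float, float] = (1.0, 0.5, 0.25),
    gate_radius: float = 10.0,
) -> list[tuple[int, int]]:
    """Nearest-neighbour linking of detections between consecutive frames.

    Cost combines normalized centroid distance, area difference and mean
    intensity difference; pairs farther apart than ``gate_radius`` are
    forbidden.  Solved as a minimum-cost maximum-cardinality assignment
    (each detection used at most once), which on small instances coincides
    with exhaustive minimization of the total cost.  Returns ``(index_a,
    index_b)`` pairs sorted by ``index_a``.
    """
    if gate_radius <= 0:
        raise ValueError("gate_radius must be positive")
    if any(w < 0 for w in weights) or not any(weights):
        raise ValueError("weights must be nonnegative and not all zero")
    if not dets_a or not dets_b:
        return []
    cost = link_cost_matrix(dets_a, dets_b, weights, gate_radius)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols)
             if cost[i, j] < _FORBIDDEN]
    return sorted(pairs)


def detect_stack(video: VideoStack, min_area: int = 4) -> list[list[Detection]]:
    """Per-frame Otsu segmentation of the whole stack.

    Degenerate frames (essentially single-valued, nothing to threshold)
    contribute no detections.
    """
    out = []
    for idx in range(video.n_frames):
        try:
            frame8, thr = frame_threshold(video.frames[idx])
        except ValueError:
            out.append([])
            continue
        out.append(segment_frame(frame8, thr, min_area=min_area, frame_index=idx))
    return out


def build_trajectories(
    video: VideoStack,
    min_area: int = 4,
    weights: tuple[float, float, float] = (1.0, 0.5, 0.25),
    gate_radius: float = 10.0,
    max_gap: int = 1,
    min_length: int = 10,
    detections: list[list[Detection]] | None = None,
) -> list[Trajectory]:
    """Chain frame-pair links into trajectories.

    Tracks that miss up to ``max_gap`` consecutive frames are bridged (the
    gate grows proportionally with the gap); shorter chains than
    ``min_length`` detections are discarded.  Deterministic.
    """
    dets = detections if detections is not None else detect_stack(video, min_area)

    # active track: dict(frames=[], dets=[]); keyed by creation order
    active: list[dict] = []
    finished: list[dict] = []
    for d in dets[0]:
        active.append({"frames": [0], "dets": [d]})

    for t in range(1, video.n_frames):
        new_dets = dets[t]
        unmatched = list(range(len(new_dets)))
        # try shortest gaps first so fresh tracks get priority
        for gap in range(1, max_gap + 2):
            if not unmatched:
                break
            cand = [tr for tr in active if t - tr["frames"][-1] == gap]
            if not cand:
                continue
            ends = [tr["dets"][-1] for tr in cand]
            pool = [new_dets[j] for j in unmatched]
            pairs = link_detections(ends, pool, weights, gate_radius * gap)
            taken = set()
            for ia, ib in pairs:
                j = unmatched[ib]
                cand[ia]["frames"].append(t)
                cand[ia]["dets"].append(new_dets[j])
                taken.add(ib)
            unmatched = [j for k, j in enumerate(unmatched) if k not in taken]
        # retire tracks that fell too far behind
        still = []
        for tr in active:
            if t - tr["frames"][-1] > max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        for j in unmatched:
            active.append({"frames": [t], "dets": [new_dets[j]]})
    finished.extend(active)

    out = []
    for tr in finished:
        if len(tr["frames"]) < min_length:
            continue
        ds = tr["dets"]
        out.append(Trajectory(
            frames=np.array(tr["frames"]),
            xy=np.array([d.centroid for d in ds]),
            areas=np.array([d.area for d in ds]),
            intensities=np.array([d.mean_intensity for d in ds]),
        ))
    # deterministic order: by first frame, then first x, then first y
    out.sort(key=lambda tr: (tr.frames[0], tr.xy[0, 0], tr.xy[0, 1]))
    return out


def _smooth_rows(rows: np.ndarray, window: int | None,
                 fill: np.ndarray | None = None) -> np.ndarray:
    """Centred moving nanmean over axis 0; NaN-only windows get ``fill``
    (default 0)."""
    n = rows.shape[0]
    if fill is None:
        fill = np.zeros(rows.shape[1])
    if not window or window <= 1:
        out = rows.copy()
        bad = np.isnan(out[:, 0])
        out[bad] = fill
        return out
    half = window // 2
    out = np.empty_like(rows)
    for k in range(n):
        chunk = rows[max(0, k - half): min(n, k + half + 1)]
        if np.all(np.isnan(chunk[:, 0])):
            out[k] = fill
        else:
            out[k] = np.nanmean(chunk, axis=0)
    return out


def estimate_drift(
    trajectories: list[Trajectory],
    n_frames: int,
    smooth_window: int | None = 15,
    anchor_radii: tuple[float, ...] = (2.5, 1.2, 0.6),
    pair_radius: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame-pair background drift (pixels/frame).

    A swimming cell displaces by a full step every frame whatever its
    tumble rate, so its displacements lie on a ring of radius (speed/fps)
    around the drift vector; anything carried passively — stuck or
    sedimented cells, debris — lands within fractions of a pixel of the
    drift itself.  The estimator finds that passive cluster globally: the
    video-wide mean displacement (to which swimmers contribute only noise,
    since their directions decorrelate) anchors a shrinking sequence of
    trimmed means (``anchor_radii``) that converges onto the cluster.
    Slow variation of the flow is then captured by averaging, per frame
    pair, the links within ``pair_radius`` of the anchor and smoothing over
    ``smooth_window`` frames (pairs without passive links inherit the
    anchor).

    When no link anywhere sits near the anchor there is no passive
    reference and the flow is not identifiable from freely swimming cells;
    the drift then falls back to zero everywhere.  Pairs with no links at
    all are flagged in the returned ``no_link`` array.  Returns
    ``(drift, no_link)`` with shapes (n_frames-1, 2) and (n_frames-1,).
    """
    disp: list[list[np.ndarray]] = [[] for _ in range(n_frames - 1)]
    for tr in trajectories:
        df = np.diff(tr.frames)
        for k in np.flatnonzero(df == 1):
            disp[tr.frames[k]].append(tr.xy[k + 1] - tr.xy[k])

    no_link = np.array([not d for d in disp])
    if no_link.all():
        return np.zeros((n_frames - 1, 2)), no_link
    arrs = [np.array(d) if d else None for d in disp]

    pooled = np.concatenate([a for a in arrs if a is not None])
    anchor = pooled.mean(axis=0)
    for radius in anchor_radii:
        near = np.linalg.norm(pooled - anchor, axis=1) <= radius
        if not near.any():
            return np.zeros((n_frames - 1, 2)), no_link
        anchor = pooled[near].mean(axis=0)

    # Plausibility guard: a persistent straight swimmer is formally
    # indistinguishable from a stuck cell in a fast flow, so only accept the
    # cluster if it moves slowly relative to typical cell displacement (flow
    # well below swimming speed) or if it holds a large share of all links
    # (a passively carried majority, e.g. a rigid field translation).
    share = float(np.mean(np.linalg.norm(pooled - anchor, axis=1) <= pair_radius))
    typical = float(np.median(np.linalg.norm(pooled, axis=1)))
    if np.linalg.norm(anchor) > 0.5 * typical and share < 0.4:
        return np.zeros((n_frames - 1, 2)), no_link

    refined = np.full((n_frames - 1, 2), np.nan)
    for k, arr in enumerate(arrs):
        if arr is None:
            continue
        near = np.linalg.norm(arr - anchor, axis=1) <= pair_radius
        if near.any():
            refined[k] = arr[near].mean(axis=0)
    if np.all(np.isnan(refined[:, 0])):
        return np.zeros((n_frames - 1, 2)), no_link
    drift = _smooth_rows(refined, smooth_window, fill=anchor)
    return drift, no_link


def _corrected_positions(traj: Trajectory, drift: np.ndarray | None) -> np.ndarray:
    """Centroids with the cumulative background drift removed."""
    if drift is None:
        return traj.xy.copy()
    cum = np.vstack([np.zeros(2), np.cumsum(drift, axis=0)])  # (n_frames, 2)
    return traj.xy - cum[traj.frames]


def filter_stuck(
    traj: Trajectory,
    drift: np.ndarray | None,
    pixel_size: float,
    fps: float,
    net_disp_threshold: float = 2.0,
    window: float = 3.0,
) -> tuple[bool, np.ndarray]:
    """Flag stuck cells from drift-corrected net displacement.

    A trajectory is fully stuck when its corrected net displacement over its
    whole span is below ``net_disp_threshold`` micrometres, or when *every*
    ``window``-second stretch along it is sub-threshold (a cell pinned in
    place for the whole video, robust to slow residual drift error).
    Otherwise, sub-threshold windows mark the frame pairs inside them as a
    stuck portion (partial sticking), excluded from velocity statistics.
    The default 3-s window targets surface-attachment episodes; shorter
    windows start flagging transient loitering of healthy swimmers.

    Returns ``(stuck_flag, pair_stuck)`` where ``pair_stuck`` has one bool
    per consecutive detection pair.  Sets the trajectory's flags in place.
    """
    if len(traj) < 2:
        raise ValueError("trajectory needs at least 2 detections")
    pos = _corrected_positions(traj, drift) * pixel_size
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    stuck = net < net_disp_threshold

    n_pairs = len(traj) - 1
    pair_stuck = np.zeros(n_pairs, dtype=bool)
    w_frames = max(1, round(window * fps))
    for start in range(len(traj)):
        f0 = traj.frames[start]
        end = start
        while end + 1 < len(traj) and traj.frames[end + 1] - f0 <= w_frames:
            end += 1
        if end == start:
            continue
        span = traj.frames[end] - f0
        if span < w_frames:
            continue  # window not fully covered by the trajectory
        if np.linalg.norm(pos[end] - pos[start]) < net_disp_threshold:
            pair_stuck[start:end] = True

    if pair_stuck.size and pair_stuck.any() and pair_stuck.all():
        stuck = True

    traj.stuck_flag = bool(stuck)
    traj.partial_stuck = bool((not stuck) and pair_stuck.any())
    traj.drift_corrected = drift is not None
    return bool(stuck), pair_stuck


def compute_velocity(
    traj: Trajectory,
    fps: float,
    pixel_size: float,
    drift: np.ndarray | None = None,
    pair_mask: np.ndarray | None = None,
) -> float:
    """Mean swimming speed of a (non-stuck) trajectory in um/s.

    Mean over consecutive detection pairs of |drift-corrected displacement|
    x pixel_size x fps; bridged gaps use the elapsed frame count in the
    denominator.  ``pair_mask`` (True = exclude) drops stuck portions.
    """
    if traj.stuck_flag:
        raise ValueError("stuck trajectory is excluded from velocity statistics")
    if len(traj) < 2:
        raise ValueError("trajectory needs at least 2 detections")
    pos = _corrected_positions(traj, drift)
    disp = np.diff(pos, axis=0)
    gaps = np.diff(traj.frames)
    speeds = np.linalg.norm(disp, axis=1) * pixel_size * fps / gaps
    if pair_mask is not None and pair_mask.any() and not pair_mask.all():
        speeds = speeds[~pair_mask]
    speed = float(speeds.mean())
    traj.mean_speed = speed
    return speed


def trajectory_rose(
    trajectories: list[Trajectory],
    fps: float,
    pixel_size: float,
    duration: float = 3.0,
) -> list[np.ndarray]:
    """Origin-translated first-``duration``-seconds of each trajectory.

    Each returned array is (n, 2) in micrometres with the first point at
    (0, 0); the conventional window is 3 s.  Trajectories with fewer than 2
    points inside the window are skipped.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_pts = math.ceil(duration * fps)
    roses = []
    for tr in trajectories:
        keep = tr.frames - tr.frames[0] < n_pts
        if keep.sum() < 2:
            continue
        pts = tr.xy[keep]
        roses.append((pts - pts[0]) * pixel_size)
    return roses


@dataclass(frozen=True)
class GroupStats:
    mean: float
    sem: float
    n: int


def velocity_statistics(
    speeds_a: np.ndarray,
    speeds_b: np.ndarray | None = None,
) -> tuple[GroupStats, GroupStats | None, float | None, float | None]:
    """Summary statistics for per-cell speeds, with an optional two-sample
    comparison.

    Returns (stats_a, stats_b, t, p) where the comparison is a two-tailed
    two-sample Student's t-test (pooled variance). ``stats_b``/``t``/``p``
    are None when only one group is given.
    """
    a = np.asarray(speeds_a, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 samples per condition")
    ga = GroupStats(mean=float(a.mean()), sem=float(stats.sem(a)), n=int(a.size))
    if speeds_b is None:
        return ga, None, None, None
    b = np.asarray(speeds_b, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 samples per condition")
    gb = GroupStats(mean=float(b.mean()), sem=float(stats.sem(b)), n=int(b.size))
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return ga, gb, float(t), float(p)


@dataclass
class TrackingResult:
    """Full tracking pipeline output for one video."""

    trajectories: list[Trajectory]
    drift: np.ndarray
    drift_no_link: np.ndarray
    speeds: np.ndarray          # um/s, one per non-stuck trajectory
    speed_track_index: np.ndarray


def track_video(
    video: VideoStack,
    min_area: int = 4,
    weights: tuple[float, float, float] = (1.0, 0.5, 0.25),
    gate_radius: float = 10.0,
    max_gap: int = 1,
    min_length: int = 10,
    net_disp_threshold: float = 2.0,
    stuck_window: float = 3.0,
    drift_smooth_window: int | None = 15,
) -> TrackingResult:
    """Segment, link, drift-correct and score a motility video end-to-end."""
    trajs = build_trajectories(video, min_area=min_area, weights=weights,
                               gate_radius=gate_radius, max_gap=max_gap,
                               min_length=min_length)
    drift, no_link = estimate_drift(trajs, video.n_frames,
                                    smooth_window=drift_smooth_window)
    if no_link.any():
        warnings.warn(f"{int(no_link.sum())} frame pair(s) had no links; "
                      "drift set to 0 there", stacklevel=2)
    speeds = []
    idx = []
    for i, tr in enumerate(trajs):
        stuck, pair_mask = filter_stuck(tr, drift, video.pixel_size, video.fps,
                                        net_disp_threshold=net_disp_threshold,
                                        window=stuck_window)
        if stuck:
            continue
        speeds.append(compute_velocity(tr, video.fps, video.pixel_size,
                                       drift=drift, pair_mask=pair_mask))
        idx.append(i)
    return TrackingResult(trajectories=trajs, drift=drift,
                          drift_no_link=no_link,
                          speeds=np.array(speeds),
                          speed_track_index=np.array(idx, dtype=int))
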