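"""Synthetic data generators with ground truth.

Every input the analysis pipeline consumes can be generated here with known
ground truth: noisy reporter time series from a prescribed synthesis
profile, run-and-tumble motility movies rendered as blurred blobs, cytometry
event tables from log-normal population mixtures, and noisy current traces.
All generators are deterministic given their seed.

The motility generator emulates the CheZ link to swimming: tumble events
arrive as a Poisson process (rate per phenotype; CheZ-null cells tumble far
more often), each tumble redirects the cell uniformly, runs proceed at the
scenario swim speed, and a configurable fraction of cells is stuck to the
slide.  Uniform background drift moves everything, including stuck cells.
Tumbles are resolved at frame boundaries, so a swimmer's path speed equals
the scenario swim speed exactly — that is the per-cell ground truth the
tracker is measured against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import ExpressionTrace
from .electrochem import (
    CurrentTrace,
    ElectrolysisState,
    SignalSchedule,
    integrate_charge,
    simulate_bulk_electrolysis,
)
from .tracking import VideoStack


# ---------------------------------------------------------------------------
# reporter expression traces


@dataclass
class ExpressionScenario:
    """Ground-truth synthesis profile and noise model for a reporter trace.

    ``segments`` is a piecewise-constant synthesis profile [(rate au/s,
    duration s), ...]; noise is multiplicative (``noise_cv``) and/or
    additive (``noise_sd``) Gaussian.
    """

    segments: list[tuple[float, float]]
    k_deg: float = math.log(2) / 1500.0
    noise_cv: float = 0.0
    noise_sd: float = 0.0
    sample_dt: float = 30.0
    P0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one synthesis segment")
        for s, d in self.segments:
            if s < 0 or d <= 0:
                raise ValueError("synthesis rates must be >= 0, durations > 0")
        if self.k_deg < 0 or self.noise_cv < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise parameters must be nonnegative")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be positive")


def _propagate(P: float, s: float, k: float, dt: float) -> float:
    """Exact step of dP/dt = s - k P over dt with constant s."""
    if k == 0:
        return P + s * dt
    return s / k + (P - s / k) * math.exp(-k * dt)


def gen_expression_trace(
    scenario: ExpressionScenario,
) -> tuple[ExpressionTrace, np.ndarray]:
    """Simulate a noisy reporter trace and its degradation-free synthesis.

    The ODE dP/dt = s(t) - k P is integrated with the exact piecewise
    closed form (no discretization error), then noise is applied to the
    samples.  Returns the noisy :class:`ExpressionTrace` and the noiseless
    cumulative synthesis S(t) = integral of s, evaluated at the sample
    times (piecewise linear).
    """
    total = sum(d for _, d in scenario.segments)
    n = int(math.floor(total / scenario.sample_dt + 1e-9))
    times = np.arange(n + 1) * scenario.sample_dt

    bounds = np.cumsum([0.0] + [d for _, d in scenario.segments])
    rates = [s for s, _ in scenario.segments]

    P = scenario.P0
    P_clean = np.empty(n + 1)
    S_true = np.empty(n + 1)
    P_clean[0] = P
    S_true[0] = 0.0
    k = scenario.k_deg
    for i in range(1, n + 1):
        t0, t1 = times[i - 1], times[i]
        # walk across any segment boundaries inside (t0, t1]
        t = t0
        seg = int(np.searchsorted(bounds, t0, side="right")) - 1
        seg = min(seg, len(rates) - 1)
        S = S_true[i - 1]
        while t < t1 - 1e-12:
            seg_end = bounds[seg + 1]
            step_end = min(t1, seg_end)
            dt = step_end - t
            P = _propagate(P, rates[seg], k, dt)
            S += rates[seg] * dt
            t = step_end
            if t >= seg_end - 1e-12 and seg < len(rates) - 1:
                seg += 1
        P_clean[i] = P
        S_true[i] = S

    rng = np.random.default_rng(scenario.seed)
    noisy = P_clean.copy()
    if scenario.noise_cv > 0:
        noisy = noisy * (1.0 + scenario.noise_cv * rng.standard_normal(n + 1))
    if scenario.noise_sd > 0:
        noisy = noisy + scenario.noise_sd * rng.standard_normal(n + 1)
    noisy = np.clip(noisy, 0.0, None)
    return ExpressionTrace(times=times, fluorescence=noisy), S_true


# ---------------------------------------------------------------------------
# motility videos


@dataclass
class MotilityScenario:
    """Run-and-tumble population for one imaging condition.

    Rates are per second; ``drift`` is the uniform background flow in um/s;
    ``psf_sigma`` the Gaussian blob width in pixels; ``noise_sd`` the shot
    noise (8-bit intensity units).  ``tumble_rate_ko`` carries the
    CheZ-null tumble rate for building the matched uninduced condition
    (use it as ``tumble_rate`` in a second scenario).
    """

    n_cells: int = 20
    swim_speed: float = 20.0
    tumble_rate: float = 1.0
    tumble_rate_ko: float = 10.0
    stuck_fraction: float = 0.1
    drift: tuple[float, float] = (0.0, 0.0)
    psf_sigma: float = 2.0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if min(self.swim_speed, self.tumble_rate, self.tumble_rate_ko,
               self.psf_sigma, self.noise_sd) < 0:
            raise ValueError("rates and noise must be nonnegative")
        if not 0.0 <= self.stuck_fraction <= 1.0:
            raise ValueError("stuck_fraction must lie in [0, 1]")


@dataclass
class MotilityTruth:
    """Ground truth emitted with every generated video.

    ``speeds`` are the *realized* drift-corrected path speeds (mean per-frame
    displacement after removing drift): border reflections can fold a step,
    so a wall-riding cell's realized speed sits below the nominal swim
    speed, and that realized value is what a tracker can recover.
    """

    positions: np.ndarray      # (n_frames, n_cells, 2) pixels, (x, y)
    stuck: np.ndarray          # (n_cells,) bool
    speeds: np.ndarray         # (n_cells,) realized um/s (0 for stuck cells)
    drift_px: np.ndarray       # (2,) drift in pixels/frame
    pixel_size: float = 0.32
    fps: float = 10.0

    def segment_speed(self, cell: int, frame_lo: int, frame_hi: int) -> float:
        """Realized drift-corrected speed of one cell over [frame_lo, frame_hi]."""
        pos = self.positions[frame_lo:frame_hi + 1, cell]
        disp = np.diff(pos, axis=0) - self.drift_px
        return float(np.linalg.norm(disp, axis=1).mean() * self.pixel_size * self.fps)

    def to_dataframe(self) -> pd.DataFrame:
        n_frames, n_cells, _ = self.positions.shape
        frames = np.repeat(np.arange(n_frames), n_cells)
        cells = np.tile(np.arange(n_cells), n_frames)
        flat = self.positions.reshape(-1, 2)
        return pd.DataFrame({
            "frame": frames, "cell_id": cells,
            "x_px": flat[:, 0], "y_px": flat[:, 1],
            "stuck": self.stuck[cells].astype(int),
            "speed_um_s": self.speeds[cells],
        })


def gen_motility_video(
    scenario: MotilityScenario,
    height: int = 512,
    width: int = 680,
    fps: float = 10.0,
    pixel_size: float = 0.32,
    n_frames: int = 100,
    background: float = 20.0,
) -> tuple[VideoStack, MotilityTruth]:
    """Render a run-and-tumble population as a noisy 8-bit video.

    Cells are Gaussian blobs on a noisy background.  The default geometry
    (680 x 512 at 0.32 um/px, 10 fps, ~100 frames) reflects a standard
    microscope camera field at 20x and the usual acquisition length.  The
    background drift is a rigid stage/camera pan: cell kinematics are
    simulated pan-free and the pan is added at render time, so stuck cells
    translate rigidly with the field for the whole video.  Warns when the
    per-frame displacement approaches the tracker's default gate.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_cells
    n_stuck = int(round(scenario.stuck_fraction * n))
    stuck = np.zeros(n, dtype=bool)
    stuck[:n_stuck] = True

    step_px = scenario.swim_speed / pixel_size / fps
    drift_px = np.array(scenario.drift) / pixel_size / fps
    if step_px + np.linalg.norm(drift_px) > 10.0:
        import warnings
        warnings.warn("per-frame displacement exceeds the default tracking "
                      "gate; tracking may fragment", stacklevel=2)

    margin = int(math.ceil(4 * scenario.psf_sigma)) + 1
    lo = float(margin)
    hi_x, hi_y = float(width - 1 - margin), float(height - 1 - margin)

    # The drift is a rigid stage/camera pan applied at render time; cell
    # kinematics live in pan-free world coordinates inside a box inset so
    # that world + cumulative pan always stays inside the rendered frame.
    td = drift_px * (n_frames - 1)
    world_lo = np.array([lo - min(0.0, td[0]), lo - min(0.0, td[1])])
    world_hi = np.array([hi_x - max(0.0, td[0]), hi_y - max(0.0, td[1])])
    if np.any(world_hi - world_lo < 32.0):
        raise ValueError("drift too large for the frame: cells cannot stay "
                         "in view for the whole video")

    world = np.empty((n_frames, n, 2))
    world[0] = rng.uniform(world_lo + 15, world_hi - 15, size=(n, 2))
    theta = rng.uniform(0, 2 * math.pi, n)
    heading = np.column_stack([np.cos(theta), np.sin(theta)])
    p_tumble = 1.0 - math.exp(-scenario.tumble_rate / fps)

    for t in range(1, n_frames):
        tumble = rng.uniform(size=n) < p_tumble
        new_theta = rng.uniform(0, 2 * math.pi, n)
        heading[tumble] = np.column_stack([np.cos(new_theta[tumble]),
                                           np.sin(new_theta[tumble])])
        step = np.where(stuck[:, None], 0.0, step_px * heading)
        new = world[t - 1] + step
        # swimmers scatter off the border: fold the overshoot back and flip
        # the heading along the violated axis
        for ax in range(2):
            low = new[:, ax] < world_lo[ax]
            high = new[:, ax] > world_hi[ax]
            new[low, ax] = 2 * world_lo[ax] - new[low, ax]
            new[high, ax] = 2 * world_hi[ax] - new[high, ax]
            heading[low | high, ax] *= -1.0
        world[t] = new

    pan = drift_px[None, :] * np.arange(n_frames)[:, None]   # (n_frames, 2)
    pos = world + pan[:, None, :]

    amplitudes = rng.uniform(140.0, 220.0, n)
    frames = np.empty((n_frames, height, width), dtype=np.uint8)
    r = int(math.ceil(4 * scenario.psf_sigma))
    ax = np.arange(-r, r + 1)
    for t in range(n_frames):
        img = background + scenario.noise_sd * rng.standard_normal((height, width))
        for i in range(n):
            cx, cy = pos[t, i]
            ix, iy = int(round(cx)), int(round(cy))
            gx = np.exp(-((ax + ix - cx) ** 2) / (2 * scenario.psf_sigma ** 2))
            gy = np.exp(-((ax + iy - cy) ** 2) / (2 * scenario.psf_sigma ** 2))
            img[iy - r: iy + r + 1, ix - r: ix + r + 1] += (
                amplitudes[i] * np.outer(gy, gx))
        frames[t] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    corrected = np.diff(pos, axis=0) - drift_px
    realized = np.linalg.norm(corrected, axis=2).mean(axis=0) * pixel_size * fps
    speeds = np.where(stuck, 0.0, realized)
    video = VideoStack(frames=frames, fps=fps, pixel_size=pixel_size)
    return video, MotilityTruth(positions=pos, stuck=stuck, speeds=speeds,
                                drift_px=drift_px, pixel_size=pixel_size, fps=fps)


def evaluate_tracking(
    result,
    truth: MotilityTruth,
    match_radius: float = 3.0,
    consistency_radius: float = 2.0,
    min_consistency: float = 0.95,
) -> dict:
    """Score a tracking result against generator ground truth.

    A ground-truth link (cell c, frames t -> t+1) counts as recovered when
    some trajectory holds detections within ``match_radius`` pixels of the
    cell at both frames.  A trajectory is *matched* to its majority cell
    when it stays within ``consistency_radius`` pixels of that cell for at
    least ``min_consistency`` of its samples; identity-mixed trajectories
    (crossing swaps) are scored by the link metric instead of the per-cell
    speed metric.  Speed errors compare each matched trajectory's mean
    speed with the cell's realized drift-corrected speed over the same
    frame span.

    Returns a dict with ``link_recovery``, ``speed_errors``,
    ``matched_fraction``, ``stuck_cells_with_speed``, ``n_stuck_flagged``,
    ``n_stuck_true`` and ``full_track_speeds`` (cell -> um/s for matched
    full-length tracks).
    """
    n_frames, n_cells, _ = truth.positions.shape
    per_frame: dict[int, dict[int, np.ndarray]] = {}
    for tid, tr in enumerate(result.trajectories):
        for k, f in enumerate(tr.frames):
            per_frame.setdefault(int(f), {})[tid] = tr.xy[k]

    hit = 0
    for c in range(n_cells):
        for t in range(n_frames - 1):
            p0, p1 = truth.positions[t, c], truth.positions[t + 1, c]
            for tid, xy0 in per_frame.get(t, {}).items():
                xy1 = per_frame.get(t + 1, {}).get(tid)
                if (xy1 is not None
                        and np.linalg.norm(xy0 - p0) < match_radius
                        and np.linalg.norm(xy1 - p1) < match_radius):
                    hit += 1
                    break
    link_recovery = hit / (n_cells * (n_frames - 1))

    speed_errors: list[float] = []
    full_track_speeds: dict[int, float] = {}
    matched = 0
    stuck_with_speed = 0
    for i in result.speed_track_index:
        tr = result.trajectories[i]
        dist = np.linalg.norm(
            truth.positions[tr.frames] - tr.xy[:, None, :], axis=2)
        cid = int(np.bincount(np.argmin(dist, axis=1)).argmax())
        consistency = float((dist[:, cid] < consistency_radius).mean())
        if consistency < min_consistency:
            continue
        matched += 1
        if truth.stuck[cid]:
            stuck_with_speed += 1
            continue
        ref = truth.segment_speed(cid, int(tr.frames[0]), int(tr.frames[-1]))
        speed_errors.append(abs(tr.mean_speed - ref) / ref)
        if len(tr) == n_frames:
            full_track_speeds[cid] = float(tr.mean_speed)

    n_speed_tracks = len(result.speed_track_index)
    return {
        "link_recovery": link_recovery,
        "speed_errors": speed_errors,
        "matched_fraction": matched / n_speed_tracks if n_speed_tracks else 1.0,
        "stuck_cells_with_speed": stuck_with_speed,
        "n_stuck_flagged": int(sum(tr.stuck_flag for tr in result.trajectories)),
        "n_stuck_true": int(truth.stuck.sum()),
        "full_track_speeds": full_track_speeds,
    }


# ---------------------------------------------------------------------------
# cytometry event tables


@dataclass(frozen=True)
class CytoPopulation:
    """One log-normal fluorescence population with its scatter cluster."""

    fraction: float
    log10_mean: float
    log10_sd: float
    fsc_mean: float = 5e4
    fsc_sd: float = 8e3
    ssc_mean: float = 3e4
    ssc_sd: float = 6e3


#: 1:1 relay:receiver style mixture, receivers induced 10x above baseline
DEFAULT_MIXTURE = (
    CytoPopulation(fraction=0.5, log10_mean=2.5, log10_sd=0.2),
    CytoPopulation(fraction=0.5, log10_mean=3.5, log10_sd=0.2),
)


def gen_cytometry_events(
    n_events: int = 50_000,
    populations: tuple[CytoPopulation, ...] = DEFAULT_MIXTURE,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw labelled events from a mixture of log-normal populations.

    Default acquisition size is 50,000 events; fractions must sum to 1.
    Returns the event table (fsc, ssc, green) and the per-event population
    labels.
    """
    fracs = np.array([p.fraction for p in populations])
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("population fractions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(populations), size=n_events, p=fracs)
    green = np.empty(n_events)
    fsc = np.empty(n_events)
    ssc = np.empty(n_events)
    for i, p in enumerate(populations):
        m = labels == i
        k = int(m.sum())
        green[m] = 10 ** rng.normal(p.log10_mean, p.log10_sd, k)
        fsc[m] = np.abs(rng.normal(p.fsc_mean, p.fsc_sd, k))
        ssc[m] = np.abs(rng.normal(p.ssc_mean, p.ssc_sd, k))
    return pd.DataFrame({"fsc": fsc, "ssc": ssc, "green": green}), labels


# ---------------------------------------------------------------------------
# current traces


def gen_current_trace(
    schedule: SignalSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
    **electro_kwargs,
) -> tuple[CurrentTrace, float]:
    """Simulated current trace with additive Gaussian noise.

    Extra keyword arguments are forwarded to
    :func:`~electrogenetics.electrochem.simulate_bulk_electrolysis`.
    Returns the noisy trace and the true total charge of the noiseless one.
    """
    electro_kwargs.setdefault("state", ElectrolysisState())
    res = simulate_bulk_electrolysis(schedule=schedule, **electro_kwargs)
    true_charge = float(integrate_charge(res.trace)[-1])
    rng = np.random.default_rng(seed)
    currents = res.trace.currents.copy()
    if noise_sd > 0:
        currents = currents + noise_sd * rng.standard_normal(currents.size)
    return CurrentTrace(times=res.trace.times.copy(), currents=currents), true_charge
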