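#!/usr/bin/env python
"""CheZ-dependent swimming measured by the video-tracking pipeline.

Generates matched motility videos for three conditions — smooth-swimming
induced cells (low tumble rate), CheZ-null cells (high tumble rate), and an
intermediate partial induction — tracks them, verifies recovery against the
generator's ground truth, and compares per-cell velocity statistics with a
two-tailed Student's t-test.  Also writes the origin-translated 3-s
trajectory roses that visualize run length differences.

Writes results/velocity_stats.csv and results/trajectory_roses.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from electrogenetics import synth, tracking

RESULTS = Path(__file__).resolve().parent.parent / "results"

CONDITIONS = {
    # tumble rates: smooth swimmers run ~1 s between tumbles; CheZ-null
    # cells tumble an order of magnitude more often
    "induced": dict(tumble_rate=1.0, swim_speed=20.0),
    "partial": dict(tumble_rate=3.0, swim_speed=16.0),
    "cheZ_null": dict(tumble_rate=10.0, swim_speed=10.0),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    speeds = {}
    rose_rows = []
    stats_rows = []
    for k, (name, kw) in enumerate(CONDITIONS.items()):
        scen = synth.MotilityScenario(n_cells=20, stuck_fraction=0.1,
                                      drift=(1.0, -0.5), seed=400 + k, **kw)
        video, truth = synth.gen_motility_video(scen)
        res = tracking.track_video(video)
        score = synth.evaluate_tracking(res, truth)
        speeds[name] = res.speeds
        stats_rows.append({
            "condition": name,
            "n_tracks": len(res.speeds),
            "mean_speed_um_s": float(res.speeds.mean()),
            "sem_um_s": float(np.std(res.speeds, ddof=1) / np.sqrt(len(res.speeds))),
            "link_recovery_pct": 100 * score["link_recovery"],
            "stuck_flagged": score["n_stuck_flagged"],
        })
        swimmers = [tr for tr in res.trajectories if not tr.stuck_flag]
        for rid, pts in enumerate(tracking.trajectory_rose(
                swimmers, fps=video.fps, pixel_size=video.pixel_size)):
            for j, (x, y) in enumerate(pts):
                rose_rows.append({"condition": name, "rose_id": rid,
                                  "point": j, "x_um": x, "y_um": y})

    stats = pd.DataFrame(stats_rows)
    ga, gb, t, p = tracking.velocity_statistics(speeds["induced"],
                                                speeds["cheZ_null"])
    stats.to_csv(RESULTS / "velocity_stats.csv", index=False)
    pd.DataFrame(rose_rows).to_csv(RESULTS / "trajectory_roses.csv",
                                   index=False, float_format="%.2f")

    print(stats.round(2).to_string(index=False))
    print(f"\nInduced vs CheZ-null: t = {t:.2f}, two-tailed p = {p:.3g}"
          f" (n = {ga.n} vs {gb.n})")
    roses = pd.DataFrame(rose_rows)
    ends = roses.sort_values("point").groupby(["condition", "rose_id"]).last()
    reach = np.hypot(ends.x_um, ends.y_um).groupby("condition").mean()
    print("\nMean 3-s net reach of the trajectory roses (um):")
    print(reach.round(2).to_string())
    print("Smoother swimming (more CheZ) -> longer, straighter 3-s paths.")


if __name__ == "__main__":
    main()
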