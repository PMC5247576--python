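"""Configurable stage runner tying the analysis steps into pipelines.

A run configuration names an ordered list of stages (generation, simulation,
tracking, summarization), a base seed and an output directory.  Stages read
and write the plain-text formats in :mod:`electrogenetics.io`; the runner
derives a deterministic per-stage seed from the base seed, validates stage
parameters before executing anything, and writes a manifest with the
parameters and SHA-256 checksums of every output so identical configs
produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circuit, cytometry, io, synth, tracking
from .electrochem import SignalSchedule


class ConfigError(ValueError):
    """A run configuration violated the schema; message carries the path."""


@dataclass
class RunConfig:
    stages: list[dict]
    seed: int = 0
    outdir: str = "pipeline_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict) or "stages" not in data:
            raise ConfigError(f"{path}: config must be a mapping with 'stages'")
        return cls(stages=data["stages"], seed=int(data.get("seed", 0)),
                   outdir=str(data.get("outdir", "pipeline_out")),
                   log_level=str(data.get("log_level", "INFO")))


def stage_seed(base_seed: int, stage_name: str, index: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (base_seed + zlib.crc32(f"{index}:{stage_name}".encode())) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _schedule_from(params: dict, where: str) -> SignalSchedule:
    segs = params.get("schedule")
    if not isinstance(segs, list) or not segs:
        raise ConfigError(f"{where}.schedule: need a non-empty segment list")
    parsed = []
    for i, seg in enumerate(segs):
        try:
            E, d = seg["potential_V"], seg["duration_s"]
        except (TypeError, KeyError) as exc:
            raise ConfigError(f"{where}.schedule[{i}]: need potential_V and "
                              f"duration_s") from exc
        parsed.append((None if E is None else float(E), float(d)))
    return SignalSchedule(parsed)


# --------------------------------------------------------------------------
# stage implementations: each takes (params, outdir, seed) and returns the
# list of files it wrote


def _stage_gen_current(params, outdir: Path, seed: int) -> list[Path]:
    schedule = _schedule_from(params, "gen-current")
    trace, true_q = synth.gen_current_trace(
        schedule, noise_sd=float(params.get("noise_sd", 0.0)), seed=seed)
    out = outdir / params.get("out", "current.csv")
    io.write_current_trace(out, trace)
    meta = outdir / (out.stem + "_truth.json")
    meta.write_text(json.dumps({"true_charge_C": true_q}))
    return [out, meta]


def _stage_gen_expression(params, outdir: Path, seed: int) -> list[Path]:
    segs = params.get("synthesis_segments")
    if not isinstance(segs, list) or not segs:
        raise ConfigError("gen-expression.synthesis_segments: need a list of "
                          "[rate_au_s, duration_s]")
    scenario = synth.ExpressionScenario(
        segments=[(float(s), float(d)) for s, d in segs],
        k_deg=float(params.get("k_deg", np.log(2) / 1500)),
        noise_cv=float(params.get("noise_cv", 0.0)),
        noise_sd=float(params.get("noise_sd", 0.0)),
        sample_dt=float(params.get("sample_dt", 30.0)),
        seed=seed)
    trace, S_true = synth.gen_expression_trace(scenario)
    out = outdir / params.get("out", "expression.csv")
    io.write_expression_trace(out, trace)
    truth = outdir / (out.stem + "_truth.csv")
    io.write_series(truth, trace.times, S_true, "synthesis_au")
    return [out, truth]


def _stage_gen_video(params, outdir: Path, seed: int) -> list[Path]:
    scen_keys = ("n_cells", "swim_speed", "tumble_rate", "tumble_rate_ko",
                 "stuck_fraction", "psf_sigma", "noise_sd")
    kwargs = {k: params[k] for k in scen_keys if k in params}
    if "drift" in params:
        kwargs["drift"] = tuple(params["drift"])
    scenario = synth.MotilityScenario(seed=seed, **kwargs)
    video, truth = synth.gen_motility_video(
        scenario,
        height=int(params.get("height", 512)),
        width=int(params.get("width", 680)),
        fps=float(params.get("fps", 10.0)),
        pixel_size=float(params.get("pixel_size", 0.32)),
        n_frames=int(params.get("n_frames", 100)))
    out = outdir / params.get("out", "video.tif")
    io.write_video(out, video)
    truth_path = outdir / (out.stem + "_truth.csv")
    truth.to_dataframe().to_csv(truth_path, index=False)
    return [out, out.with_suffix(".yaml"), truth_path]


def _stage_gen_events(params, outdir: Path, seed: int) -> list[Path]:
    pops = params.get("populations")
    if pops is None:
        populations = synth.DEFAULT_MIXTURE
    else:
        populations = tuple(synth.CytoPopulation(**p) for p in pops)
    events, labels = synth.gen_cytometry_events(
        n_events=int(params.get("n_events", 50_000)),
        populations=populations, seed=seed)
    out = outdir / params.get("out", "events.csv")
    io.write_events(out, events)
    lab = outdir / (out.stem + "_labels.csv")
    pd.DataFrame({"label": labels}).to_csv(lab, index=False)
    return [out, lab]


def _stage_simulate_circuit(params, outdir: Path, seed: int) -> list[Path]:
    schedule = _schedule_from(params, "simulate-circuit")
    cp_kwargs = {k: float(v) for k, v in params.get("circuit", {}).items()}
    cparams = circuit.CircuitParams(**cp_kwargs)
    res = circuit.simulate_expression(schedule, cparams,
                                      P0=float(params.get("P0", 0.0)))
    stem = params.get("out_prefix", "circuit")
    fluor = outdir / f"{stem}_fluorescence.csv"
    cur = outdir / f"{stem}_current.csv"
    frac = outdir / f"{stem}_frac_ox.csv"
    io.write_expression_trace(fluor, res.trace)
    io.write_current_trace(cur, res.current)
    io.write_series(frac, res.times, res.frac_ox, "frac_ox")
    return [fluor, cur, frac]


def _stage_deconvolve(params, outdir: Path, seed: int) -> list[Path]:
    trace = io.read_expression_trace(outdir / params["trace"])
    S = circuit.integrated_synthesis(trace, k_deg=float(params["k_deg"]))
    out = outdir / params.get("out", "synthesis.csv")
    io.write_series(out, trace.times, S, "synthesis_au")
    return [out]


def _stage_cycle_sweep(params, outdir: Path, seed: int) -> list[Path]:
    cycle_times = [float(c) for c in params["cycle_times"]]
    results = circuit.cycle_experiment(cycle_times)
    out = outdir / params.get("out", "cycles.csv")
    pd.DataFrame([{"cycle_time_s": r.cycle_time,
                   "half_cycle_fluor_au": r.half_cycle_fluor,
                   "end_cycle_fluor_au": r.end_cycle_fluor}
                  for r in results]).to_csv(out, index=False)
    return [out]


_TRACK_KEYS = ("min_area", "gate_radius", "max_gap", "min_length",
               "net_disp_threshold", "stuck_window", "drift_smooth_window")


def _stage_track(params, outdir: Path, seed: int) -> list[Path]:
    video = io.read_video(outdir / params["video"])
    kwargs = {k: params[k] for k in _TRACK_KEYS if k in params}
    result = tracking.track_video(video, **kwargs)
    stem = params.get("out_prefix", "tracks")
    rows = []
    for tid, tr in enumerate(result.trajectories):
        for k in range(len(tr)):
            rows.append({"frame": int(tr.frames[k]), "track_id": tid,
                         "x_px": tr.xy[k, 0], "y_px": tr.xy[k, 1],
                         "area": int(tr.areas[k]),
                         "intensity": tr.intensities[k],
                         "stuck": int(tr.stuck_flag)})
    tracks_path = outdir / f"{stem}.csv"
    pd.DataFrame(rows).to_csv(tracks_path, index=False)
    speeds_path = outdir / f"{stem}_speeds.csv"
    pd.DataFrame({"track_id": result.speed_track_index,
                  "speed_um_s": result.speeds}).to_csv(speeds_path, index=False)
    drift_path = outdir / f"{stem}_drift.csv"
    pd.DataFrame({"frame_pair": np.arange(result.drift.shape[0]),
                  "dx_px": result.drift[:, 0],
                  "dy_px": result.drift[:, 1]}).to_csv(drift_path, index=False)
    return [tracks_path, speeds_path, drift_path]


def _stage_velocity_stats(params, outdir: Path, seed: int) -> list[Path]:
    a = pd.read_csv(outdir / params["speeds"])["speed_um_s"].to_numpy()
    b = None
    if "speeds_b" in params:
        b = pd.read_csv(outdir / params["speeds_b"])["speed_um_s"].to_numpy()
    ga, gb, t, p = tracking.velocity_statistics(a, b)
    rows = [{"group": "a", "mean_um_s": ga.mean, "sem_um_s": ga.sem, "n": ga.n}]
    if gb is not None:
        rows.append({"group": "b", "mean_um_s": gb.mean, "sem_um_s": gb.sem,
                     "n": gb.n})
        rows.append({"group": "a_vs_b", "mean_um_s": t, "sem_um_s": p,
                     "n": ga.n + gb.n})
    out = outdir / params.get("out", "velocity_stats.csv")
    pd.DataFrame(rows).to_csv(out, index=False)
    return [out]


def _stage_rose(params, outdir: Path, seed: int) -> list[Path]:
    df = pd.read_csv(outdir / params["tracks"])
    fps = float(params.get("fps", 10.0))
    pixel_size = float(params.get("pixel_size", 0.32))
    trajs = []
    for tid, sub in df.groupby("track_id"):
        sub = sub.sort_values("frame")
        trajs.append(tracking.Trajectory(
            frames=sub["frame"].to_numpy(),
            xy=sub[["x_px", "y_px"]].to_numpy(),
            areas=sub["area"].to_numpy(),
            intensities=sub["intensity"].to_numpy()))
    roses = tracking.trajectory_rose(trajs, fps=fps, pixel_size=pixel_size,
                                     duration=float(params.get("duration", 3.0)))
    rows = []
    for rid, pts in enumerate(roses):
        for k, (x, y) in enumerate(pts):
            rows.append({"rose_id": rid, "point": k, "x_um": x, "y_um": y})
    out = outdir / params.get("out", "rose.csv")
    pd.DataFrame(rows).to_csv(out, index=False)
    return [out]


def _stage_gate(params, outdir: Path, seed: int) -> list[Path]:
    events = io.read_events(outdir / params["events"])
    gated = cytometry.gate_events(events,
                                  fsc_bounds=tuple(params["fsc_bounds"]),
                                  ssc_bounds=tuple(params["ssc_bounds"]))
    out = outdir / params.get("out", "gated.csv")
    io.write_events(out, gated)
    return [out]


def _stage_cyto_summary(params, outdir: Path, seed: int) -> list[Path]:
    events = io.read_events(outdir / params["events"])
    summary = {"n_events": int(len(events)),
               "mean_green_au": cytometry.mean_fluorescence(events)}
    if len(events) >= 100:
        split = cytometry.population_split(events)
        summary.update({
            "split_threshold_au": split.threshold,
            "low_fraction": split.low_fraction,
            "high_fraction": split.high_fraction,
            "low_mean_au": split.low_mean,
            "high_mean_au": split.high_mean,
            "separation_score": split.separation_score,
            "is_bimodal": split.is_bimodal,
        })
    out = outdir / params.get("out", "cyto_summary.json")
    out.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return [out]


STAGES = {
    "gen-current": _stage_gen_current,
    "gen-expression": _stage_gen_expression,
    "gen-video": _stage_gen_video,
    "gen-events": _stage_gen_events,
    "simulate-circuit": _stage_simulate_circuit,
    "deconvolve": _stage_deconvolve,
    "cycle-sweep": _stage_cycle_sweep,
    "track": _stage_track,
    "velocity-stats": _stage_velocity_stats,
    "rose": _stage_rose,
    "gate": _stage_gate,
    "cyto-summary": _stage_cyto_summary,
}


def validate_config(config: RunConfig) -> None:
    """Schema check before any computation runs."""
    if not isinstance(config.stages, list) or not config.stages:
        raise ConfigError("stages: must be a non-empty list")
    for i, st in enumerate(config.stages):
        if not isinstance(st, dict) or "name" not in st:
            raise ConfigError(f"stages[{i}]: each stage needs a 'name'")
        if st["name"] not in STAGES:
            raise ConfigError(f"stages[{i}].name: unknown stage {st['name']!r}; "
                              f"known: {sorted(STAGES)}")
        if "params" in st and not isinstance(st["params"], dict):
            raise ConfigError(f"stages[{i}].params: must be a mapping")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write a manifest.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    Identical config + seed reproduce identical output checksums.
    """
    validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    for i, st in enumerate(config.stages):
        name = st["name"]
        params = st.get("params", {})
        seed = stage_seed(config.seed, name, i)
        outputs = STAGES[name](params, outdir, seed)
        manifest["stages"].append({
            "name": name,
            "params": params,
            "seed": seed,
            "outputs": {p.name: _sha256(p) for p in outputs},
        })
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
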