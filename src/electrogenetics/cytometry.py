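"""Flow-cytometry event summaries: scatter gating, mean fluorescence, and
emergent-subpopulation detection.

Event tables carry one row per event with forward scatter (``fsc``), side
scatter (``ssc``) and green fluorescence (``green``) columns, matching the
acquisition convention of collecting ~50,000 events gated consistently by
forward and side scatter before fluorescence summarization.

The subpopulation detector addresses the relay/receiver co-culture readout,
where electronically induced relay cells drive a distinct high-fluorescence
receiver population: it thresholds the log10 fluorescence histogram with
Otsu's method and scores the split by the fraction of variance explained
(between-class / total).  A unimodal (Gaussian-like) distribution cannot
exceed ~2/pi ~ 0.64 on that score, so the default bimodality cutoff of 0.70
separates genuine two-population mixtures from single populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import between_class_fraction, otsu_threshold

REQUIRED_COLUMNS = ("fsc", "ssc", "green")

#: separation-quality score above which a split is called bimodal
BIMODALITY_CUTOFF = 0.70


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    if not all(c in events.columns for c in REQUIRED_COLUMNS):
        raise ValueError(f"event table needs columns {REQUIRED_COLUMNS}")
    if len(events) < 1:
        raise ValueError("event table must contain at least 1 event")
    vals = events[list(REQUIRED_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("event table contains non-finite values")
    return events


def gate_events(
    events: pd.DataFrame,
    fsc_bounds: tuple[float, float],
    ssc_bounds: tuple[float, float],
) -> pd.DataFrame:
    """Rectangular scatter gate: keep events strictly inside both bounds."""
    validate_events(events)
    for name, (lo, hi) in (("fsc", fsc_bounds), ("ssc", ssc_bounds)):
        if not lo < hi:
            raise ValueError(f"{name} bounds must be ordered (lo < hi)")
    keep = ((events["fsc"] > fsc_bounds[0]) & (events["fsc"] < fsc_bounds[1])
            & (events["ssc"] > ssc_bounds[0]) & (events["ssc"] < ssc_bounds[1]))
    gated = events[keep].reset_index(drop=True)
    if len(gated) == 0:
        warnings.warn("scatter gate excluded every event", stacklevel=2)
    return gated


def mean_fluorescence(events: pd.DataFrame) -> float:
    """Arithmetic mean of the green channel over all events."""
    if len(events) < 1:
        raise ValueError("cannot average an empty event table")
    validate_events(events)
    return float(events["green"].mean())


@dataclass(frozen=True)
class PopulationSplit:
    """Result of the log-fluorescence Otsu split."""

    threshold: float          # green units (linear scale)
    low_fraction: float
    high_fraction: float
    low_mean: float           # arithmetic means on the linear scale
    high_mean: float
    separation_score: float   # between-class / total variance of log green
    is_bimodal: bool


def population_split(events: pd.DataFrame, bins: int = 256,
                     bimodality_cutoff: float = BIMODALITY_CUTOFF) -> PopulationSplit:
    """Split events into low/high fluorescence modes via Otsu on log10(green).

    On unimodal input the split is still returned, but the separation score
    stays below the bimodality cutoff so callers can disregard it.
    Nonpositive fluorescence values are handled by shifting the channel to
    positive values before taking logs (with a warning).
    """
    validate_events(events)
    if len(events) < 100:
        raise ValueError("need at least 100 events for a population split")
    green = events["green"].to_numpy(dtype=float)
    shift = 0.0
    if green.min() <= 0:
        span = green.max() - green.min()
        shift = -green.min() + max(span, 1.0) * 1e-6
        warnings.warn("nonpositive fluorescence values; applying shifted-log "
                      "handling", stacklevel=2)
    logg = np.log10(green + shift)

    lo, hi = logg.min(), logg.max()
    if hi == lo:
        raise ValueError("degenerate fluorescence distribution")
    edges = np.linspace(lo, hi, bins + 1)
    hist, _ = np.histogram(logg, bins=edges)
    t = otsu_threshold(hist)
    score = between_class_fraction(hist, t)
    thr_log = edges[t]

    high = logg >= thr_log
    n = len(green)
    high_frac = float(high.sum()) / n
    low_mean = float(green[~high].mean()) if (~high).any() else float("nan")
    high_mean = float(green[high].mean()) if high.any() else float("nan")
    return PopulationSplit(
        threshold=float(10 ** thr_log - shift),
        low_fraction=1.0 - high_frac,
        high_fraction=high_frac,
        low_mean=low_mean,
        high_mean=high_mean,
        separation_score=score,
        is_bimodal=bool(score >= bimodality_cutoff),
    )
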