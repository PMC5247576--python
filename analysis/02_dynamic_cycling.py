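#!/usr/bin/env python
"""ON/OFF cycling dynamics and the cycle-time sweep.

Simulates an extended culture cycled between the oxidizing (+0.5 V, 'ON')
and reducing (-0.3 V, 'OFF') potentials, then sweeps the cycle time and
records fluorescence at the half-cycle and cycle end.  The expected shape:
half-cycle fluorescence rises monotonically with cycle time, and the
end-of-cycle drop becomes significant only once the OFF phase outlasts the
~15-min mediator interconversion and ssrA degradation takes over.

Writes results/cycling_trace.csv and results/cycle_sweep.csv.
"""

from pathlib import Path

import pandas as pd

from electrogenetics import circuit as cm
from electrogenetics import electrochem as ec
from electrogenetics import io as eio

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = cm.CircuitParams()

    # four 2-h ON/OFF cycles, as in an extended continuous culture
    segs = [(cm.ON_POTENTIAL, 3600.0), (cm.OFF_POTENTIAL, 3600.0)] * 4
    res = cm.simulate_expression(ec.SignalSchedule(segs), params)
    # store the trace at 60-s sampling (the simulation grid is 1 s)
    keep = slice(None, None, 60)
    eio.write_expression_trace(
        RESULTS / "cycling_trace.csv",
        cm.ExpressionTrace(times=res.times[keep],
                           fluorescence=res.trace.fluorescence[keep]))
    peaks = []
    for c in range(4):
        sel = (res.times >= 7200.0 * c) & (res.times <= 7200.0 * c + 3600.0)
        peaks.append(float(res.trace.fluorescence[sel].max()))
    spread = (max(peaks[1:]) - min(peaks[1:])) / (sum(peaks[1:]) / 3)
    print("ON/OFF cycling (1-h phases, 4 cycles):")
    print(f"  per-cycle peaks (au): {[round(p, 1) for p in peaks]}")
    print(f"  peak-to-peak spread after the first cycle: {spread * 100:.1f}%"
          " (cells respond reproducibly each cycle)")

    halves_min = [7.5, 15, 22.5, 30, 45, 60, 90]
    results = cm.cycle_experiment([2 * h * 60.0 for h in halves_min], params)
    df = pd.DataFrame([{
        "half_cycle_min": h,
        "half_cycle_fluor_au": r.half_cycle_fluor,
        "end_cycle_fluor_au": r.end_cycle_fluor,
        "end_decay_pct": 100 * (r.half_cycle_fluor - r.end_cycle_fluor)
                         / r.half_cycle_fluor,
    } for h, r in zip(halves_min, results)])
    df.to_csv(RESULTS / "cycle_sweep.csv", index=False)
    print("\nCycle-time sweep:")
    print(df.round(2).to_string(index=False))
    print("\nHalf-cycle fluorescence is monotone in cycle time:",
          bool(df.half_cycle_fluor_au.is_monotonic_increasing))
    thr = df[df.end_decay_pct > 10].half_cycle_min.min()
    print(f"End-of-cycle decay exceeds 10% from half-cycle ~{thr:g} min"
          " upward — fully developed switching needs the OFF phase to"
          " outlast the ~15-min interconversion.")


if __name__ == "__main__":
    main()
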