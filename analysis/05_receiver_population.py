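#!/usr/bin/env python
"""Emergence of the fluorescent receiver population in relay co-cultures.

Generates cytometry event tables for a 1:1 relay:receiver co-culture at
increasing induction levels (the receiver population migrating up in
fluorescence), gates on scatter, and summarizes each sample: mean green
fluorescence and the low/high population split with its separation score.
The high-fluorescence fraction should track the induced receiver fraction,
and the uninduced sample should score below the bimodality cutoff.

Writes results/receiver_population.csv.
"""

from pathlib import Path

import pandas as pd

from electrogenetics import cytometry, synth

RESULTS = Path(__file__).resolve().parent.parent / "results"

# receiver induction time course: fraction of receivers that have turned on
TIMEPOINTS = {"0h": 0.0, "1h": 0.15, "2h": 0.35, "3h": 0.5}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for k, (label, induced) in enumerate(TIMEPOINTS.items()):
        pops = [synth.CytoPopulation(1.0 - induced, 2.5, 0.2)]
        if induced > 0:
            pops.append(synth.CytoPopulation(induced, 3.5, 0.2))
        events, _ = synth.gen_cytometry_events(50_000, tuple(pops), seed=900 + k)
        gated = cytometry.gate_events(events, (2e4, 9e4), (8e3, 6e4))
        row = {"sample": label, "nominal_induced_fraction": induced,
               "n_gated": len(gated),
               "mean_green_au": cytometry.mean_fluorescence(gated)}
        split = cytometry.population_split(gated)
        row.update(high_fraction=split.high_fraction,
                   separation_score=split.separation_score,
                   is_bimodal=split.is_bimodal)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "receiver_population.csv", index=False)
    print(df.round(4).to_string(index=False))
    print("\nMean fluorescence and the detected high fraction rise with"
          " induction; the uninduced sample stays below the bimodality"
          " cutoff while induced samples show a distinct receiver"
          " population.")


if __name__ == "__main__":
    main()
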