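#!/usr/bin/env python
"""Spatial tuning of spiking inside sharp-wave ripples (STS).

For each unit, within-ripple firing rates per quadrant (300-ms windows
around detected event peaks, overlaps removed), the spatial tuning score
(max rate ratio), and its significance against 1000 quadrant-label
permutations that keep per-quadrant event counts fixed.
"""

import json
from pathlib import Path

import thermomaze as tm
from thermomaze import io as tmio
from thermomaze import pipeline as pl

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    sess = ROOT / "session_5min"
    spikes = tmio.read_spikes(sess / "spikes.csv")
    events = tmio.read_events(ROOT / "ripple_events.csv")
    truth = json.loads((sess / "ground_truth.json").read_text())
    tuned = {u["unit_id"] for u in truth["units"] if u["tuned"]}

    sts = pl.sts_table(spikes, events, n_shuffles=1000, rng=3)
    sts.to_csv(ROOT / "sts_table.csv", index=False)

    sig = sts["p"] < 0.05
    print(f"{len(sts)} units scored on {len(events)} SPW-Rs; "
          f"median STS {sts['sts'].median():.3f}; "
          f"{100 * sig.mean():.0f}% significant at p < 0.05")
    is_tuned = sts["unit_id"].isin(tuned)
    print(f"median STS: tuned units {sts.loc[is_tuned, 'sts'].median():.3f} "
          f"vs untuned {sts.loc[~is_tuned, 'sts'].median():.3f} "
          f"(0.25 = no quadrant preference)")
    stat, p = tm.compare_sts_groups(sts.loc[is_tuned, "sts"],
                                    sts.loc[~is_tuned, "sts"])
    print(f"one-sided rank-sum tuned > untuned: p = {p:.2g}")


if __name__ == "__main__":
    main()
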