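#!/usr/bin/env python
"""Locomotion and warm-spot-seeking behavior of the simulated animal.

Reads the 5-min session written by 01, preprocesses the trajectory,
splits it into movement/immobility at 2.5 cm/s, and reports per
sub-session locomotion fractions plus the latency to leave a switched-off
warm spot and to reach the next one.
"""

from pathlib import Path

import numpy as np

import thermomaze as tm
from thermomaze import io as tmio
from thermomaze import pipeline as pl

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    cfg = tm.SessionConfig(rng_seed=1)
    raw = tmio.read_trajectory(ROOT / "session_5min" / "trajectory.csv")
    beh = pl.analyze_behavior(raw, cfg)
    beh.summary.to_csv(ROOT / "behavior_summary.csv", index=False)
    beh.transitions.to_csv(ROOT / "warm_spot_transitions.csv", index=False)

    print(beh.summary.to_string(index=False))
    dep = np.nanmedian(beh.transitions["departure_latency_s"])
    arr = np.nanmedian(beh.transitions["arrival_latency_s"])
    print(f"\nwarm-spot transitions (n={len(beh.transitions)}): "
          f"median departure latency {dep:.2f} s, "
          f"median arrival latency {arr:.2f} s")
    cool = beh.summary.set_index("sub_session")
    print(f"Cooling immobility: "
          f"{100 * cool.loc['Cooling', 'immobility_fraction']:.1f}% "
          f"(warm spots pin the animal in place between transitions)")


if __name__ == "__main__":
    main()
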