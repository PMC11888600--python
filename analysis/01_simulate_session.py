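#!/usr/bin/env python
"""Generate the synthetic sessions used by the downstream analyses.

Writes a standard 5-min corner-schedule session (with two-channel LFP)
and a 20-min sleep-permissive session (spikes/states only) under
``results/``, as the delimited-text / flat-binary file set a recorded
session would arrive in.
"""

from pathlib import Path

import thermomaze as tm
from thermomaze import io as tmio

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    cfg = tm.SessionConfig(rng_seed=SEED)
    session = tm.simulate_session(cfg, n_units=50, tuned_fraction=0.45,
                                  with_lfp=True)
    tmio.write_session(session, ROOT / "session_5min")
    print(f"5-min schedule session: {len(session.spikes)} units, "
          f"{len(session.true_ripples)} ground-truth ripples, "
          f"LFP {session.lfp.samples.shape[1]} samples x 2 channels "
          f"-> {ROOT / 'session_5min'}")

    cfg2 = tm.SessionConfig(rng_seed=SEED + 1)
    cfg2.warm_spot_schedule = tm.corner_schedule(
        cfg2.sub_session("Cooling"), epoch_s=1200.0, n_cycles=1)
    cfg2.validate()
    s2 = tm.simulate_session(cfg2, n_units=100, with_lfp=False)
    tmio.write_session(s2, ROOT / "session_20min")
    nrem = s2.ripple_events["brain_state"].eq("NREM").mean()
    print(f"20-min schedule session: {len(s2.spikes)} units, "
          f"{len(s2.true_ripples)} ripples ({nrem:.0%} in NREM) "
          f"-> {ROOT / 'session_20min'}")


if __name__ == "__main__":
    main()
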