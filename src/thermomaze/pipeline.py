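"""High-level per-session analysis drivers.

These functions chain the module-level operations into the standard
per-session analyses — behavior metrics, ripple detection and
localization, place-cell identification, within-ripple spatial tuning,
quadrant decoding, and population-vector comparison — and return plain
tables.  The numbered scripts under ``analysis/`` and the acceptance
script are thin wrappers around them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import (MotionSegments, Trajectory, compute_speed,
                       immobility_fraction, preprocess_trajectory,
                       segment_states, warm_spot_metrics)
from .config import SessionConfig
from .decoding import chance_level, cross_validate
from .population import (build_population_vectors, movement_rate_ratios,
                         pv_correlation_matrix, ratio_correlation,
                         same_vs_different_quadrant_test)
from .ripple_tuning import sts_null, within_ripple_rates
from .ripples import (assign_ripple_location, detect_ripples,
                      exclude_noise_events, ripple_properties)
from .spatial import SpikeTrain, identify_place_cells, shuffle_significance


@dataclass
class BehaviorAnalysis:
    trajectory: Trajectory       # preprocessed
    speed: np.ndarray
    segments: MotionSegments
    summary: pd.DataFrame        # per-sub-session locomotion fractions
    transitions: pd.DataFrame    # warm-spot latencies


def analyze_behavior(raw: Trajectory, config: SessionConfig) -> BehaviorAnalysis:
    """Preprocess, segment, and summarize locomotion per sub-session."""
    traj = preprocess_trajectory(raw)
    speed = compute_speed(traj)
    segments = segment_states(traj, speed, config.speed_threshold)
    rows = []
    for lab, lo, hi in config.sub_sessions:
        f = immobility_fraction(traj, segments, (lo, hi))
        rows.append((lab, hi - lo, f, 1.0 - f))
    summary = pd.DataFrame(rows, columns=["sub_session", "duration_s",
                                          "immobility_fraction",
                                          "movement_fraction"])
    recs = warm_spot_metrics(traj, config.warm_spot_schedule, speed=speed,
                             threshold=config.speed_threshold)
    transitions = pd.DataFrame({
        "off_time": [r.off_time for r in recs],
        "departure_latency_s": [r.departure_latency for r in recs],
        "arrival_latency_s": [r.arrival_latency for r in recs],
    })
    return BehaviorAnalysis(traj, speed, segments, summary, transitions)


def detect_and_localize_ripples(lfp, beh: BehaviorAnalysis,
                                config: SessionConfig,
                                state_bouts: pd.DataFrame = None):
    """Detect on the pyramidal-layer channel, veto noise-channel events,
    attach properties and locations.  Returns (events, count_map, rate_map)."""
    events = detect_ripples(lfp)
    if "noise" in lfp.channel_roles:
        noise_events = detect_ripples(lfp, channel_role="noise")
        events = exclude_noise_events(events, noise_events)
    events = ripple_properties(events, lfp)
    return assign_ripple_location(events, beh.trajectory, beh.segments,
                                  config, state_bouts=state_bouts)


def sub_session_view(traj: Trajectory, speed: np.ndarray, span):
    """Restrict a trajectory and its speed series to one sub-session."""
    sel = (traj.t >= span[0]) & (traj.t < span[1])
    sub = Trajectory(traj.t[sel], traj.x[sel], traj.y[sel],
                     traj.likelihood[sel])
    return sub, speed[sel]


def place_cell_table(spikes, beh: BehaviorAnalysis, config: SessionConfig,
                     n_shuffles: int = 100, rng=None) -> pd.DataFrame:
    """Per-unit place-cell metrics and flags for all three sub-sessions."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rows = []
    for st in spikes:
        per_sub, usable = {}, True
        for lab, lo, hi in config.sub_sessions:
            sub, sub_speed = sub_session_view(beh.trajectory, beh.speed, (lo, hi))
            sub_seg = segment_states(sub, sub_speed, config.speed_threshold)
            sub_spk = SpikeTrain(st.unit_id, st.in_span(lo, hi), st.cell_type)
            try:
                per_sub[lab] = shuffle_significance(sub_spk, sub, sub_seg,
                                                    config,
                                                    n_shuffles=n_shuffles,
                                                    rng=rng)
            except ValueError:
                usable = False
                break
        if not usable:
            continue
        flags, overall = identify_place_cells(per_sub)
        row = {"unit_id": st.unit_id, "cell_type": st.cell_type,
               "place_cell": overall}
        for lab, res in per_sub.items():
            row[f"si_{lab}"] = res.si
            row[f"peak_{lab}"] = res.peak_rate
            row[f"z_{lab}"] = res.z
            row[f"flag_{lab}"] = flags[lab]
        rows.append(row)
    return pd.DataFrame(rows)


def sts_table(spikes, events: pd.DataFrame, n_shuffles: int = 1000,
              rng=None) -> pd.DataFrame:
    """Per-unit STS, preferred quadrant, and permutation p."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rows = []
    for st in spikes:
        try:
            res = sts_null(st, events, n_shuffles=n_shuffles, rng=rng)
        except ValueError:
            continue
        rows.append({"unit_id": st.unit_id, "cell_type": st.cell_type,
                     "sts": res.sts, "preferred_quadrant": res.preferred_quadrant,
                     "p": res.p, "n_events": len(events)})
    return pd.DataFrame(rows)


def decode_session(spikes, events: pd.DataFrame, n_folds: int = 100,
                   prior_mode: str = "uniform", rng=None,
                   chance_runs: int = 100):
    """Cross-validated decoding accuracy and permutation chance level."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cv = cross_validate(spikes, events, n_folds=n_folds,
                        prior_mode=prior_mode, rng=rng)
    chance = chance_level(spikes, events, prior_mode=prior_mode,
                          mode="permutation", n_runs=chance_runs,
                          n_folds=n_folds, rng=rng)
    return cv, chance


def condition_profiles(spikes, beh: BehaviorAnalysis, events: pd.DataFrame,
                       config: SessionConfig) -> dict:
    """Quadrant rate-ratio profiles for movement and per brain state.

    Returns ``{"movement": [...], "awake_ripple": [...]}`` plus
    ``"nrem_ripple"`` when NREM-labeled events exist.
    """
    out = {"movement": [movement_rate_ratios(st, beh.trajectory,
                                             beh.segments, config)
                        for st in spikes]}
    if "brain_state" in events.columns:
        awake = events[events["brain_state"] == "WAKE"]
        nrem = events[events["brain_state"] == "NREM"]
    else:
        awake, nrem = events, events.iloc[0:0]
    out["awake_ripple"] = [within_ripple_rates(st, awake,
                                               condition="awake_ripple")
                           for st in spikes] if len(awake) else []
    if len(nrem):
        out["nrem_ripple"] = [within_ripple_rates(st, nrem,
                                                  condition="nrem_ripple")
                              for st in spikes]
    return out


def population_summary(profiles: dict) -> dict:
    """Ratio correlation and PV-matrix summaries over available conditions."""
    out = {}
    if profiles.get("movement") and profiles.get("awake_ripple"):
        r, p, n = ratio_correlation(profiles["awake_ripple"],
                                    profiles["movement"])
        out["ratio_correlation_r"] = r
        out["ratio_correlation_p"] = p
        out["ratio_correlation_n_units"] = n
    present = {k: v for k, v in profiles.items() if v}
    if len(present) >= 2:
        vectors = build_population_vectors(present)
        pv = pv_correlation_matrix(vectors)
        out["pv"] = pv
        stat, p = same_vs_different_quadrant_test(pv)
        out["same_vs_diff_p"] = p
    return out
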