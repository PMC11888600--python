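"""Synthetic ThermoMaze sessions with known ground truth.

The generator emulates the statistical structure of a recorded session so
every downstream stage can be validated against known parameters:

* a thermotaxis trajectory at 25 Hz — during Cooling the animal dwells on
  the active warm spot with micro-movements, waits a lognormal latency
  (median 12.99 s) after the spot turns off, wanders, and runs to the
  next spot so it arrives around a median 23.45 s; exploratory bouts
  punctuate dwells so that roughly 77% of Cooling is spent immobile
  (speed < 2.5 cm/s).  Pre/Post are rest/explore alternations.
* place-tuned units — inhomogeneous Poisson spiking with rate
  baseline + (peak - baseline) * exp(-d^2 / 2 w^2) around a 2-D Gaussian
  tuning center evaluated along the trajectory.
* an LFP pair at 1250 Hz — 1/f-shaped Gaussian background on a detection
  and a noise channel, ripple-band bursts (150-180 Hz sinusoids, 50-100
  ms, amplitude in background-SD units) added only to the detection
  channel during immobility at 0.136 Hz in Cooling, plus occasional
  broadband artifacts shared by both channels.
* quadrant-biased within-ripple participation — for each ripple a unit
  emits >= 1 spike with the participation probability of the quadrant the
  animal occupies at the ripple peak; participating spike counts are
  zero-truncated Poisson (mean 1.5).
* brain-state bouts — all WAKE under the 5-min schedule; under the
  20-min two-spot schedule, NREM fills the second half of each warm-spot
  epoch.

All generators are deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import intervals as iv
from .behavior import Trajectory, compute_speed, segment_states
from .config import QUADRANT_LABELS, SessionConfig
from .spatial import SpikeTrain


@dataclass
class BehaviorParams:
    """Tunable behavioral statistics of the simulated animal."""

    departure_median_s: float = 12.99   # stay on spot after heat off
    departure_sigma: float = 0.1        # lognormal spread (log units)
    arrival_median_s: float = 23.45     # heat off -> on the new spot
    arrival_sigma: float = 0.2
    explore_bout_rate_hz: float = 1.0 / 32.0  # exploratory-bout hazard during dwell
    explore_bout_mean_s: float = 8.0
    rest_bout_mean_s: float = 9.0       # Pre/Post rest bouts
    move_bout_mean_s: float = 6.0
    run_speed_cm_s: float = 8.0         # direct-run speed toward a spot
    explore_speed_sd_cm_s: float = 5.0  # OU stationary velocity SD
    jitter_step_cm: float = 0.04        # micro-movement per-frame step SD
    glitch_fraction: float = 0.02       # tracking dropouts (likelihood < 0.5)


@dataclass
class UnitTuning:
    unit_id: int
    center: tuple            # (x, y) cm; ignored for untuned units
    width_cm: float          # Gaussian tuning width; inf = untuned
    peak_rate_hz: float
    baseline_rate_hz: float
    cell_type: str = "pyramidal"
    tuned: bool = True


@dataclass
class SyntheticGroundTruth:
    """Generative parameters against which recovery is tested."""

    units: list                      # UnitTuning
    participation: np.ndarray        # (n_units, 4) in [0, 1]
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    ripple_rate_hz: float = 0.136    # during Cooling
    ripple_amplitude_sd: float = 8.0
    ripple_freq_range: tuple = (150.0, 180.0)
    ripple_duration_range: tuple = (0.05, 0.1)
    within_ripple_count_mean: float = 1.5
    nrem_attenuation: float = 0.5    # bias contrast retained in NREM ripples
    ripple_times: np.ndarray = None  # filled by the LFP generator
    ripple_durations: np.ndarray = None
    ripple_quadrants: np.ndarray = None
    state_bouts: pd.DataFrame = None

    def __post_init__(self):
        p = np.asarray(self.participation, dtype=float)
        if p.size != len(self.units) * 4:
            raise ValueError("participation must be (n_units, 4)")
        p = p.reshape(len(self.units), 4)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("participation probabilities must lie in [0, 1]")
        for u in self.units:
            if u.baseline_rate_hz < 0 or u.peak_rate_hz < u.baseline_rate_hz:
                raise ValueError("need peak rate >= baseline >= 0")
        self.participation = p


def make_ground_truth(config: SessionConfig, rng: np.random.Generator,
                      n_units: int = 50, tuned_fraction: float = 0.45,
                      interneuron_fraction: float = 0.2,
                      preferred_participation: float = 0.5,
                      other_participation: float = 1.0 / 6.0,
                      behavior: BehaviorParams = None) -> SyntheticGroundTruth:
    """Draw a unit population with tuning-matched ripple participation.

    Tuned units get a Gaussian place field inside the walkable square and
    a participation bias toward the quadrant containing their field
    center; untuned units fire homogeneously and participate uniformly.
    """
    margin = (config.arena_extent - config.maze_extent) / 2.0
    units, part = [], []
    n_tuned = int(round(n_units * tuned_fraction))
    for uid in range(n_units):
        tuned = uid < n_tuned
        cx, cy = rng.uniform(margin + 1, config.arena_extent - margin - 1, size=2)
        is_int = rng.uniform() < interneuron_fraction
        ctype = "narrow_interneuron" if is_int else "pyramidal"
        if tuned:
            peak = rng.uniform(8.0, 20.0)
            base = rng.uniform(0.1, 0.5)
            width = rng.uniform(2.0, 4.0)
            units.append(UnitTuning(uid, (cx, cy), width, peak, base, ctype, True))
            q = int(config.quadrant_of(cx, cy))
            row = np.full(4, other_participation)
            row[q] = preferred_participation
        else:
            rate = rng.uniform(0.5, 3.0)
            units.append(UnitTuning(uid, (cx, cy), np.inf, rate, rate, ctype, False))
            row = np.full(4, 0.25)
        part.append(row)
    return SyntheticGroundTruth(units, np.asarray(part),
                                behavior=behavior or BehaviorParams())


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _ou_walk(p0, n, dt, rng, bounds, speed_sd, tau_v=0.5):
    """Reflected random walk with OU-correlated velocity."""
    rho = np.exp(-dt / tau_v)
    sig = speed_sd / np.sqrt(2.0) * np.sqrt(1 - rho ** 2)  # per-component
    pos = np.empty((n, 2))
    p = np.array(p0, dtype=float)
    v = rng.normal(0, speed_sd / np.sqrt(2.0), size=2)
    lo, hi = bounds
    for k in range(n):
        v = rho * v + rng.normal(0, sig, size=2) * np.sqrt(2.0)
        p = p + v * dt
        for d in range(2):
            if p[d] < lo:
                p[d] = 2 * lo - p[d]
                v[d] = -v[d]
            elif p[d] > hi:
                p[d] = 2 * hi - p[d]
                v[d] = -v[d]
        pos[k] = p
    return pos


def _jitter(center, p0, n, dt, rng, step_cm, pull=2.0):
    """Micro-movements around a point (speeds mostly below threshold)."""
    pos = np.empty((n, 2))
    p = np.array(p0, dtype=float)
    c = np.array(center, dtype=float)
    for k in range(n):
        p = p + pull * (c - p) * dt + rng.normal(0, step_cm, size=2)
        pos[k] = p
    return pos


def _run_to(p0, p1, n, rng, wobble_cm=0.3):
    """Smooth direct run from p0 to p1 over n frames (minimum-jerk profile)."""
    u = np.linspace(0, 1, max(n, 2))
    s = 3 * u ** 2 - 2 * u ** 3
    path = np.outer(1 - s, p0) + np.outer(s, p1)
    lateral = np.sin(np.pi * u) * rng.normal(0, wobble_cm)
    d = np.asarray(p1, dtype=float) - np.asarray(p0, dtype=float)
    norm = np.hypot(*d)
    if norm > 0:
        perp = np.array([-d[1], d[0]]) / norm
        path = path + np.outer(lateral, perp)
    return path[:n]


def generate_trajectory(config: SessionConfig, truth: SyntheticGroundTruth,
                        rng: np.random.Generator):
    """Simulate the session trajectory; returns (observed, clean) pair.

    The clean trajectory (likelihood 1 everywhere) drives spike and
    ripple generation; the observed copy carries tracking glitches
    (displaced samples with likelihood below 0.5) for the preprocessing
    stage to repair.
    """
    bp = truth.behavior
    dt = 1.0 / config.frame_rate
    t0, t1 = config.session_span
    t = t0 + np.arange(int(round((t1 - t0) * config.frame_rate))) * dt
    pos = np.empty((len(t), 2))
    margin = (config.arena_extent - config.maze_extent) / 2.0
    bounds = (margin + 0.5, config.arena_extent - margin - 0.5)

    def frames(span):
        return np.flatnonzero((t >= span[0] - 1e-9) & (t < span[1] - 1e-9))

    cursor = np.array([config.arena_extent / 2.0, config.arena_extent / 2.0])

    def fill_rest_move(idx):
        nonlocal cursor
        k = 0
        while k < len(idx):
            n_rest = max(1, int(round(rng.exponential(bp.rest_bout_mean_s) / dt)))
            n_rest = min(n_rest, len(idx) - k)
            pos[idx[k:k + n_rest]] = _jitter(cursor, cursor, n_rest, dt, rng,
                                             bp.jitter_step_cm)
            cursor = pos[idx[k + n_rest - 1]]
            k += n_rest
            if k >= len(idx):
                break
            n_move = max(1, int(round(rng.exponential(bp.move_bout_mean_s) / dt)))
            n_move = min(n_move, len(idx) - k)
            pos[idx[k:k + n_move]] = _ou_walk(cursor, n_move, dt, rng, bounds,
                                              bp.explore_speed_sd_cm_s)
            cursor = pos[idx[k + n_move - 1]]
            k += n_move

    for lab in ("Pre", "Post"):
        fill_rest_move(frames(config.sub_session(lab)))

    # Cooling: event-driven dwell / depart / wander / run cycle
    for i, spot in enumerate(config.warm_spot_schedule):
        idx = frames((spot.on, spot.off))
        if len(idx) == 0:
            continue
        k = 0
        target = np.array([spot.x, spot.y])
        dep = (rng.lognormal(np.log(bp.departure_median_s), bp.departure_sigma)
               if i > 0 else 0.0)
        arr = rng.lognormal(np.log(bp.arrival_median_s), bp.arrival_sigma)
        n_dep = min(int(round(dep / dt)), len(idx))
        if n_dep > 0:  # linger on the old spot after its heat turns off
            pos[idx[:n_dep]] = _jitter(cursor, cursor, n_dep, dt, rng,
                                       bp.jitter_step_cm)
            cursor = pos[idx[n_dep - 1]]
            k = n_dep
        run_s = np.hypot(*(target - cursor)) / bp.run_speed_cm_s
        n_wander = max(0, int(round((arr - dep - run_s) / dt)))
        n_wander = min(n_wander, len(idx) - k)
        if n_wander > 0:
            pos[idx[k:k + n_wander]] = _ou_walk(cursor, n_wander, dt, rng,
                                                bounds, bp.explore_speed_sd_cm_s)
            cursor = pos[idx[k + n_wander - 1]]
            k += n_wander
        n_run = min(max(1, int(round(np.hypot(*(target - cursor))
                                     / bp.run_speed_cm_s / dt))), len(idx) - k)
        if n_run > 0 and k < len(idx):
            pos[idx[k:k + n_run]] = _run_to(cursor, target, n_run, rng)
            cursor = pos[idx[k + n_run - 1]]
            k += n_run
        # dwell with exploratory bouts until the epoch ends
        while k < len(idx):
            if bp.explore_bout_rate_hz > 0:
                wait = rng.exponential(1.0 / bp.explore_bout_rate_hz)
            else:
                wait = np.inf
            n_dwell = min(int(round(wait / dt)) if np.isfinite(wait) else len(idx),
                          len(idx) - k)
            n_dwell = max(n_dwell, 1)
            pos[idx[k:k + n_dwell]] = _jitter(target, cursor, n_dwell, dt, rng,
                                              bp.jitter_step_cm)
            cursor = pos[idx[k + n_dwell - 1]]
            k += n_dwell
            if k >= len(idx):
                break
            n_bout = min(max(1, int(round((2.0 + rng.exponential(
                bp.explore_bout_mean_s - 2.0)) / dt))), len(idx) - k)
            n_back = min(max(1, int(round(2.0 / dt))), len(idx) - k - n_bout)
            pos[idx[k:k + n_bout]] = _ou_walk(cursor, n_bout, dt, rng, bounds,
                                              bp.explore_speed_sd_cm_s)
            cursor = pos[idx[k + n_bout - 1]]
            k += n_bout
            if n_back > 0:
                pos[idx[k:k + n_back]] = _run_to(cursor, target, n_back, rng)
                cursor = pos[idx[k + n_back - 1]]
                k += n_back

    pos = np.clip(pos, 0.0, np.nextafter(config.arena_extent, 0.0))
    clean = Trajectory(t, pos[:, 0], pos[:, 1], np.ones(len(t)))

    lik = np.ones(len(t))
    xo, yo = pos[:, 0].copy(), pos[:, 1].copy()
    if truth.behavior.glitch_fraction > 0:
        bad = rng.uniform(size=len(t)) < truth.behavior.glitch_fraction
        bad[[0, -1]] = False
        lik[bad] = rng.uniform(0.0, 0.49, size=bad.sum())
        xo[bad] = np.clip(xo[bad] + rng.normal(0, 3.0, size=bad.sum()),
                          0, config.arena_extent - 1e-9)
        yo[bad] = np.clip(yo[bad] + rng.normal(0, 3.0, size=bad.sum()),
                          0, config.arena_extent - 1e-9)
    observed = Trajectory(t.copy(), xo, yo, lik)
    return observed, clean


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def tuning_rate(unit: UnitTuning, x, y) -> np.ndarray:
    """Instantaneous rate of a unit at positions (x, y)."""
    if not np.isfinite(unit.width_cm):
        return np.full(np.shape(x), float(unit.peak_rate_hz))
    d2 = (np.asarray(x) - unit.center[0]) ** 2 + (np.asarray(y) - unit.center[1]) ** 2
    return unit.baseline_rate_hz + (unit.peak_rate_hz - unit.baseline_rate_hz) \
        * np.exp(-d2 / (2.0 * unit.width_cm ** 2))


def _strictly_increasing(times: np.ndarray) -> np.ndarray:
    t = np.sort(times)
    for _ in range(100):
        bad = np.flatnonzero(np.diff(t) <= 0)
        if len(bad) == 0:
            return t
        t[bad + 1] = t[bad] + 1e-9
    return t


def generate_units(config: SessionConfig, truth: SyntheticGroundTruth,
                   traj: Trajectory, rng: np.random.Generator) -> list:
    """Inhomogeneous Poisson spike trains along the trajectory."""
    dt = float(np.median(np.diff(traj.t)))
    trains = []
    for unit in truth.units:
        lam = tuning_rate(unit, traj.x, traj.y)
        if np.any(lam < 0):
            raise ValueError("negative instantaneous rate")
        counts = rng.poisson(lam * dt)
        reps = np.repeat(np.arange(len(traj.t)), counts)
        times = traj.t[reps] + rng.uniform(0, dt, size=len(reps))
        trains.append(SpikeTrain(unit.unit_id, _strictly_increasing(times),
                                 unit.cell_type))
    return trains


# ---------------------------------------------------------------------------
# brain states
# ---------------------------------------------------------------------------

def generate_state_bouts(config: SessionConfig,
                         truth: SyntheticGroundTruth,
                         nrem_threshold_s: float = 1200.0) -> pd.DataFrame:
    """WAKE/NREM bouts partitioning the session.

    Under the standard 5-min schedule the animal never sleeps (single
    WAKE bout).  Under long (>= 20 min) warm-spot epochs, NREM fills the
    second half of each epoch, mirroring sleep onset after prolonged
    dwells; WAKE fills the rest.
    """
    t0, t1 = config.session_span
    nrem = []
    for spot in config.warm_spot_schedule:
        if spot.off - spot.on >= nrem_threshold_s:
            nrem.append((spot.on + (spot.off - spot.on) / 2.0, spot.off - 30.0))
    rows = []
    cur = t0
    for s, e in nrem:
        if s > cur:
            rows.append(("WAKE", cur, s))
        rows.append(("NREM", s, e))
        cur = e
    if cur < t1:
        rows.append(("WAKE", cur, t1))
    bouts = pd.DataFrame(rows, columns=["state", "start", "end"])
    truth.state_bouts = bouts
    return bouts


# ---------------------------------------------------------------------------
# LFP and ripples
# ---------------------------------------------------------------------------

def one_over_f_noise(n: int, fs: float, rng: np.random.Generator,
                     sd: float = 1.0, f_floor: float = 1.0) -> np.ndarray:
    """Spectrally shaped Gaussian noise with ~1/f amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec /= np.sqrt(np.maximum(f, f_floor))
    out = np.fft.irfft(spec, n=n)
    return out * (sd / out.std())


def generate_ripples_and_lfp(config: SessionConfig,
                             truth: SyntheticGroundTruth,
                             traj: Trajectory, rng: np.random.Generator,
                             n_ripples: int = None,
                             background_sd_uv: float = 20.0,
                             artifact_rate_hz: float = 0.005,
                             min_separation_s: float = 0.4,
                             sub_session: str = "Cooling"):
    """Embed ripple bursts in 1/f background; returns (LFP, times, durations).

    Ripples are placed only during immobility within the requested
    sub-session, at ``truth.ripple_rate_hz`` relative to the sub-session
    duration (or exactly ``n_ripples`` when given).  The noise channel
    shares background statistics and broadband artifacts but carries no
    ripple bursts.
    """
    from .ripples import LFPRecording  # deferred to avoid import cycle

    if truth.ripple_amplitude_sd <= 0:
        raise ValueError("ripple amplitude must be positive")
    fs = config.lfp_rate
    t0, t1 = config.session_span
    n_samp = int(round((t1 - t0) * fs))

    speed = compute_speed(traj)
    segments = segment_states(traj, speed, config.speed_threshold)
    span = config.sub_session(sub_session)
    imm = iv.clip(segments.intervals("immobility"), span[0], span[1])
    if iv.total_duration(imm) <= 0:
        raise ValueError("no immobility available for ripple placement")

    n = n_ripples if n_ripples is not None else int(
        rng.poisson(truth.ripple_rate_hz * (span[1] - span[0])))
    times = iv.sample_uniform(imm, n, rng)
    for _ in range(200):  # enforce a minimum separation between bursts
        close = np.flatnonzero(np.diff(times) < min_separation_s)
        if len(close) == 0:
            break
        times[close + 1] = iv.sample_uniform(imm, len(close), rng)
        times = np.sort(times)
    durations = rng.uniform(*truth.ripple_duration_range, size=n)
    freqs = rng.uniform(*truth.ripple_freq_range, size=n)
    phases = rng.uniform(0, 2 * np.pi, size=n)

    ripple_ch = one_over_f_noise(n_samp, fs, rng, sd=background_sd_uv)
    noise_ch = one_over_f_noise(n_samp, fs, rng, sd=background_sd_uv)
    amp = truth.ripple_amplitude_sd * background_sd_uv
    for tc, dur, f0, ph in zip(times, durations, freqs, phases):
        s = int(round((tc - dur / 2 - t0) * fs))
        e = min(s + int(round(dur * fs)), n_samp)
        s = max(s, 0)
        if e <= s:
            continue
        tt = np.arange(e - s) / fs
        ripple_ch[s:e] += amp * np.hanning(e - s) * np.sin(2 * np.pi * f0 * tt + ph)

    n_art = int(rng.poisson(artifact_rate_hz * (t1 - t0)))
    art_times = rng.uniform(t0, t1, size=n_art)
    for ta in art_times:
        s = max(0, int(round((ta - t0) * fs)))
        e = min(s + int(round(0.05 * fs)), n_samp)
        if e <= s:
            continue
        burst = 9.0 * background_sd_uv * np.hanning(e - s) \
            * rng.standard_normal(e - s)
        ripple_ch[s:e] += burst
        noise_ch[s:e] += burst

    lfp = LFPRecording(np.vstack([ripple_ch, noise_ch]), fs,
                       ["pyramidal_layer", "noise"], uv_per_count=0.195)
    truth.ripple_times = times
    truth.ripple_durations = durations
    qi = traj.nearest_index(times)
    truth.ripple_quadrants = config.quadrant_of(traj.x[qi], traj.y[qi])
    return lfp, times, durations


def generate_within_ripple_spikes(truth: SyntheticGroundTruth,
                                  ripple_times: np.ndarray,
                                  ripple_durations: np.ndarray,
                                  rng: np.random.Generator,
                                  spike_trains: list = None,
                                  traj: Trajectory = None,
                                  config: SessionConfig = None,
                                  quadrants: np.ndarray = None,
                                  brain_states: np.ndarray = None) -> list:
    """Add quadrant-biased participation spikes inside ripple windows.

    Quadrants come from the trajectory at each ripple peak unless given
    directly.  For ripples labeled NREM, the participation bias contrast
    is attenuated toward uniform by ``truth.nrem_attenuation`` (place
    coding persists into sleep, weakened).  When ``spike_trains`` is
    None, fresh empty trains are created (ripple-only sessions used in
    decoder tests).
    """
    if quadrants is None:
        if traj is None or config is None:
            raise ValueError("need either quadrants or (traj, config)")
        idx = traj.nearest_index(ripple_times)
        quadrants = config.quadrant_of(traj.x[idx], traj.y[idx])
    quadrants = np.asarray(quadrants, dtype=int)
    nrem = (np.zeros(len(quadrants), dtype=bool) if brain_states is None
            else np.asarray(brain_states) == "NREM")
    if spike_trains is None:
        spike_trains = [SpikeTrain(u.unit_id, np.array([]), u.cell_type)
                        for u in truth.units]
    lam = truth.within_ripple_count_mean
    out = []
    for ui, st in enumerate(spike_trains):
        p = truth.participation[ui, quadrants]       # per-event probability
        p = np.where(nrem, 0.25 + truth.nrem_attenuation * (p - 0.25), p)
        participate = rng.uniform(size=len(ripple_times)) < p
        n_part = int(participate.sum())
        counts = rng.poisson(lam, size=n_part)
        for _ in range(100):                          # zero-truncate
            zero = counts == 0
            if not zero.any():
                break
            counts[zero] = rng.poisson(lam, size=int(zero.sum()))
        centers = np.repeat(ripple_times[participate], counts)
        halves = np.repeat(ripple_durations[participate] / 2.0, counts)
        new = centers + rng.uniform(-1, 1, size=len(centers)) * halves
        out.append(SpikeTrain(st.unit_id,
                              _strictly_increasing(np.concatenate([st.times, new])),
                              st.cell_type))
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSession:
    """One complete generated session plus its ground truth."""

    config: SessionConfig
    truth: SyntheticGroundTruth
    trajectory: Trajectory           # observed (with tracking glitches)
    clean_trajectory: Trajectory     # glitch-free generative trajectory
    spikes: list                     # SpikeTrain per unit (incl. ripple spikes)
    state_bouts: pd.DataFrame
    lfp: object = None               # LFPRecording when generated
    true_ripples: pd.DataFrame = None  # time, duration, quadrant label

    @property
    def ripple_events(self) -> pd.DataFrame:
        """Ground-truth ripples shaped like a detector event table."""
        t = self.true_ripples
        out = pd.DataFrame({
            "start_s": t["time"] - t["duration"] / 2,
            "peak_s": t["time"],
            "end_s": t["time"] + t["duration"] / 2,
            "duration_s": t["duration"],
            "quadrant": t["quadrant"],
        })
        if "brain_state" in t.columns:
            out["brain_state"] = t["brain_state"]
        return out


def simulate_session(config: SessionConfig = None, seed: int = None,
                     n_units: int = 50, tuned_fraction: float = 0.45,
                     with_lfp: bool = True, n_ripples: int = None,
                     truth: SyntheticGroundTruth = None,
                     **truth_kwargs) -> SyntheticSession:
    """Generate a full session: trajectory, units, states, ripples, LFP."""
    if config is None:
        config = SessionConfig(rng_seed=seed or 0)
    elif seed is not None:
        config = replace(config, rng_seed=seed)
    ss = np.random.SeedSequence(config.rng_seed)
    r_truth, r_traj, r_units, r_lfp, r_part = (
        np.random.default_rng(s) for s in ss.spawn(5))
    if truth is None:
        truth = make_ground_truth(config, r_truth, n_units=n_units,
                                  tuned_fraction=tuned_fraction, **truth_kwargs)
    observed, clean = generate_trajectory(config, truth, r_traj)
    trains = generate_units(config, truth, clean, r_units)
    bouts = generate_state_bouts(config, truth)

    lfp = None
    if with_lfp:
        lfp, times, durations = generate_ripples_and_lfp(
            config, truth, clean, r_lfp, n_ripples=n_ripples)
    else:
        speed = compute_speed(clean)
        segments = segment_states(clean, speed, config.speed_threshold)
        span = config.sub_session("Cooling")
        imm = iv.clip(segments.intervals("immobility"), span[0], span[1])
        n = n_ripples if n_ripples is not None else int(
            r_lfp.poisson(truth.ripple_rate_hz * (span[1] - span[0])))
        times = iv.sample_uniform(imm, n, r_lfp)
        durations = r_lfp.uniform(*truth.ripple_duration_range, size=n)
        truth.ripple_times, truth.ripple_durations = times, durations
        idx = clean.nearest_index(times)
        truth.ripple_quadrants = config.quadrant_of(clean.x[idx], clean.y[idx])

    starts = bouts["start"].to_numpy()
    bi = np.clip(np.searchsorted(starts, times, side="right") - 1, 0,
                 len(starts) - 1)
    ripple_states = bouts["state"].to_numpy()[bi]
    trains = generate_within_ripple_spikes(
        truth, times, durations, r_part, spike_trains=trains,
        traj=clean, config=config, brain_states=ripple_states)
    true_ripples = pd.DataFrame({
        "time": times,
        "duration": durations,
        "quadrant": [QUADRANT_LABELS[q] for q in truth.ripple_quadrants],
        "brain_state": ripple_states,
    })
    return SyntheticSession(config, truth, observed, clean, trains, bouts,
                            lfp=lfp, true_ripples=true_ripples)
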