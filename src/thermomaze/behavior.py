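"""Trajectory preprocessing, movement/immobility segmentation, occupancy.

The behavioral readout is a 25 Hz video trajectory with a per-frame
tracking likelihood.  Frames below the likelihood floor are discarded and
refilled by shape-preserving piecewise-cubic (pchip) interpolation on the
original timestamps, then each coordinate is passed through a 7-point
median filter.  Speed splits the session into movement (>= 2.5 cm/s) and
immobility (< 2.5 cm/s); occupancy maps accumulate per-frame dwell time
into the 25 x 25 bin grid restricted to one motion state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import uniform_filter1d
from scipy.signal import medfilt

from .config import SessionConfig


class UnprocessableTrajectoryError(ValueError):
    """Too few valid detections to reconstruct a trajectory."""


@dataclass
class Trajectory:
    """Timestamped 2-D position in the ROI frame with tracking likelihood."""

    t: np.ndarray          # s, strictly increasing
    x: np.ndarray          # cm
    y: np.ndarray          # cm
    likelihood: np.ndarray  # in [0, 1]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.likelihood) == n):
            raise ValueError("trajectory series must share one length")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self):
        return len(self.t)

    def nearest_index(self, times) -> np.ndarray:
        """Index of the trajectory sample nearest each query time."""
        t = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.t, t)
        idx = np.clip(idx, 1, len(self.t) - 1)
        left_closer = (t - self.t[idx - 1]) < (self.t[idx] - t)
        return np.where(left_closer, idx - 1, idx)

    def frame_durations(self) -> np.ndarray:
        """Per-sample dwell time: half-gap to each neighbor (edges one-sided)."""
        t = self.t
        if len(t) == 1:
            return np.zeros(1)
        d = np.empty(len(t))
        d[1:-1] = (t[2:] - t[:-2]) / 2.0
        d[0] = (t[1] - t[0]) / 2.0
        d[-1] = (t[-1] - t[-2]) / 2.0
        return d


@dataclass
class MotionSegments:
    """Movement/immobility intervals tiling the trajectory span."""

    starts: np.ndarray
    ends: np.ndarray
    states: np.ndarray      # str array: "movement" | "immobility"
    sample_movement: np.ndarray = field(default=None, repr=False)  # per-frame bool

    def intervals(self, state: str) -> np.ndarray:
        m = self.states == state
        return np.column_stack([self.starts[m], self.ends[m]])

    def state_at(self, times) -> np.ndarray:
        """State label for arbitrary times (clamped to the span)."""
        t = np.asarray(times, dtype=float)
        idx = np.clip(np.searchsorted(self.starts, t, side="right") - 1, 0,
                      len(self.starts) - 1)
        return self.states[idx]


@dataclass
class OccupancyMap:
    """Per-bin dwell time (s) in one motion state."""

    grid: np.ndarray        # (n_bins, n_bins), rows index y from the bottom
    bin_edges: np.ndarray
    state: str
    n_clamped: int = 0      # out-of-ROI samples clamped to edge bins

    def total(self) -> float:
        return float(self.grid.sum())


def preprocess_trajectory(raw: Trajectory,
                          likelihood_floor: float = 0.5) -> Trajectory:
    """Discard low-likelihood detections, refill by pchip, median-filter.

    Refilled samples keep their original timestamps; their likelihood is
    set to the floor so a second pass leaves the refill stage a no-op.
    Query times outside the valid range are held at the nearest valid
    position (no extrapolation overshoot).
    """
    ok = raw.likelihood >= likelihood_floor
    if ok.sum() < 2:
        raise UnprocessableTrajectoryError(
            f"only {int(ok.sum())} detections at likelihood >= {likelihood_floor}"
        )
    tq = np.clip(raw.t, raw.t[ok][0], raw.t[ok][-1])
    x = PchipInterpolator(raw.t[ok], raw.x[ok])(tq)
    y = PchipInterpolator(raw.t[ok], raw.y[ok])(tq)
    x = medfilt(x, kernel_size=7)
    y = medfilt(y, kernel_size=7)
    lik = np.maximum(raw.likelihood, likelihood_floor)
    return Trajectory(raw.t.copy(), x, y, lik)


def compute_speed(traj: Trajectory, smooth_s: float = 0.5) -> np.ndarray:
    """Speed (cm/s): centered finite differences, 0.5-s moving average.

    Edge samples use one-sided differences.  The estimator is a design
    choice of this package; window and method are exposed here.
    """
    t, x, y = traj.t, traj.x, traj.y
    if len(t) < 2:
        return np.zeros(len(t))
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotonic timestamps")
    v = np.empty(len(t))
    v[1:-1] = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2]) / (t[2:] - t[:-2])
    v[0] = np.hypot(x[1] - x[0], y[1] - y[0]) / (t[1] - t[0])
    v[-1] = np.hypot(x[-1] - x[-2], y[-1] - y[-2]) / (t[-1] - t[-2])
    if smooth_s > 0:
        dt = np.median(np.diff(t))
        win = max(1, int(round(smooth_s / dt)))
        v = uniform_filter1d(v, size=win, mode="nearest")
    return v


def segment_states(traj: Trajectory, speed: np.ndarray,
                   threshold: float = 2.5) -> MotionSegments:
    """Per-sample threshold (>= is movement), runs merged into intervals.

    Interval boundaries sit at midpoints between samples of different
    state; the first/last intervals extend to the trajectory span so the
    segmentation tiles it exactly.
    """
    moving = np.asarray(speed) >= threshold
    t = traj.t
    change = np.flatnonzero(np.diff(moving.astype(int)) != 0)
    bounds = np.concatenate([[t[0]], (t[change] + t[change + 1]) / 2.0, [t[-1]]])
    run_starts = np.concatenate([[0], change + 1])
    states = np.where(moving[run_starts], "movement", "immobility")
    return MotionSegments(bounds[:-1], bounds[1:], states, sample_movement=moving)


def occupancy_map(traj: Trajectory, segments: MotionSegments, state: str,
                  config: SessionConfig) -> OccupancyMap:
    """Accumulate per-frame durations into the bin grid for one state."""
    if segments.sample_movement is not None:
        in_state = segments.sample_movement == (state == "movement")
    else:
        in_state = segments.state_at(traj.t) == state
    dur = traj.frame_durations()
    row, col = config.bin_of(traj.x, traj.y)
    n = config.n_bins
    outside = ((traj.x < 0) | (traj.x >= config.arena_extent) |
               (traj.y < 0) | (traj.y >= config.arena_extent))
    grid = np.zeros((n, n))
    np.add.at(grid, (row[in_state], col[in_state]), dur[in_state])
    return OccupancyMap(grid, config.bin_edges, state,
                        n_clamped=int(np.count_nonzero(outside & in_state)))


@dataclass
class WarmSpotTransition:
    """Behavioral record of one warm-spot switch."""

    off_time: float                 # previous spot turned off (s)
    prev_center: tuple
    new_center: tuple
    t: np.ndarray                   # times of the distance series
    distance_from_prev: np.ndarray  # cm from previous spot center
    departure_latency: float        # first speed >= threshold after off (s)
    arrival_latency: float          # first entry into new spot footprint (s); nan if never


def warm_spot_metrics(traj: Trajectory, schedule, speed: np.ndarray = None,
                      threshold: float = 2.5, footprint_side: float = 4.0,
                      window_s: float = 120.0) -> list:
    """Per-transition distance series and departure/arrival latencies.

    The departure latency is the first time speed crosses the movement
    threshold after the old spot turns off; the arrival latency is the
    first entry into the new spot's 4 x 4 cm element footprint.  A
    transition the animal never completes gets ``arrival_latency = nan``.
    """
    if speed is None:
        speed = compute_speed(traj)
    records = []
    for prev, new in zip(schedule[:-1], schedule[1:]):
        t0 = prev.off
        sel = (traj.t >= t0) & (traj.t <= min(t0 + window_s, new.off))
        tt = traj.t[sel]
        dist = np.hypot(traj.x[sel] - prev.x, traj.y[sel] - prev.y)
        sp = speed[sel]
        dep = tt[sp >= threshold]
        x0, x1, y0, y1 = new.footprint(footprint_side)
        inside = ((traj.x[sel] >= x0) & (traj.x[sel] <= x1) &
                  (traj.y[sel] >= y0) & (traj.y[sel] <= y1))
        arr = tt[inside]
        records.append(WarmSpotTransition(
            off_time=t0, prev_center=(prev.x, prev.y), new_center=(new.x, new.y),
            t=tt, distance_from_prev=dist,
            departure_latency=float(dep[0] - t0) if len(dep) else np.nan,
            arrival_latency=float(arr[0] - t0) if len(arr) else np.nan,
        ))
    return records


def immobility_fraction(traj: Trajectory, segments: MotionSegments,
                        span=None) -> float:
    """Fraction of (frame-weighted) time at speed below threshold."""
    dur = traj.frame_durations()
    if span is not None:
        sel = (traj.t >= span[0]) & (traj.t < span[1])
    else:
        sel = np.ones(len(traj.t), dtype=bool)
    imm = ~segments.sample_movement
    tot = dur[sel].sum()
    return float(dur[sel & imm].sum() / tot) if tot > 0 else np.nan
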