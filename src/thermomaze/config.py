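"""Session configuration and arena geometry.

The arena is a square ThermoMaze box whose floor is a 5 x 5 grid of
4 x 4 cm Peltier elements (20 x 20 cm of walkable floor), tracked inside a
25 x 25 cm camera region of interest (ROI).  All analysis works in the ROI
frame: origin at the lower-left ROI corner, x rightward, y upward, 25 x 25
spatial bins of 1 cm, and a 2 x 2 quadrant grid split at the ROI midlines.
Quadrants are labeled Q1..Q4 row-major from the bottom row:
Q1 = lower-left, Q2 = lower-right, Q3 = upper-left, Q4 = upper-right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SUB_SESSION_LABELS = ("Pre", "Cooling", "Post")
QUADRANT_LABELS = ("Q1", "Q2", "Q3", "Q4")


class ScheduleBoundsError(ValueError):
    """Warm-spot schedule falls outside its sub-session."""


@dataclass(frozen=True)
class WarmSpot:
    """One heated Peltier element epoch: center (cm) and on/off times (s)."""

    x: float
    y: float
    on: float
    off: float

    def footprint(self, side: float = 4.0):
        h = side / 2.0
        return (self.x - h, self.x + h, self.y - h, self.y + h)


@dataclass
class SessionConfig:
    """Parameters of one recording day in the maze.

    Defaults reproduce the standard protocol: 10 min Pre at room
    temperature, 80 min Cooling during which four corner warm spots are
    heated for 5 min each in a fixed 1-2-3-4 order repeated four times,
    and 10 min Post.
    """

    arena_extent: float = 25.0          # ROI side (cm)
    maze_extent: float = 20.0           # walkable inner square side (cm)
    bin_size: float = 1.0               # spatial bin edge (cm)
    sub_sessions: list = field(default_factory=list)  # (label, start, end)
    warm_spot_schedule: list = field(default_factory=list)
    frame_rate: float = 25.0            # video frames / s
    lfp_rate: float = 1250.0            # LFP samples / s
    speed_threshold: float = 2.5        # cm/s movement cutoff
    rng_seed: int = 0

    def __post_init__(self):
        if not self.sub_sessions:
            self.sub_sessions = [
                ("Pre", 0.0, 600.0),
                ("Cooling", 600.0, 5400.0),
                ("Post", 5400.0, 6000.0),
            ]
        if not self.warm_spot_schedule:
            self.warm_spot_schedule = corner_schedule(
                self.sub_session("Cooling"), self.arena_extent, self.maze_extent
            )
        self.validate()

    # -- derived geometry -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return int(round(self.arena_extent / self.bin_size))

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1, dtype=float) * self.bin_size

    @property
    def session_span(self):
        return self.sub_sessions[0][1], self.sub_sessions[-1][2]

    def sub_session(self, label: str):
        for lab, s, e in self.sub_sessions:
            if lab == label:
                return (s, e)
        raise KeyError(label)

    def validate(self) -> None:
        prev_end = None
        for lab, s, e in self.sub_sessions:
            if e <= s:
                raise ValueError(f"empty sub-session {lab}")
            if prev_end is not None and not np.isclose(s, prev_end):
                raise ValueError("sub-sessions must be contiguous and ascending")
            prev_end = e
        cool = self.sub_session("Cooling")
        for spot in self.warm_spot_schedule:
            if spot.on < cool[0] - 1e-9 or spot.off > cool[1] + 1e-9 or spot.off <= spot.on:
                raise ScheduleBoundsError(
                    f"warm spot [{spot.on}, {spot.off}] outside Cooling {cool}"
                )
        n = self.arena_extent / self.bin_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin_size must divide arena_extent")
        if self.lfp_rate <= 2 * 200.0:
            raise ValueError("lfp_rate must exceed twice the 200 Hz band edge")

    # -- binning ----------------------------------------------------------
    def bin_of(self, x, y):
        """Half-open 1-cm bins; out-of-ROI positions clamp to edge bins.

        Returns (row, col) with row indexing y from the bottom.
        """
        n = self.n_bins
        col = np.clip(np.floor(np.asarray(x) / self.bin_size).astype(int), 0, n - 1)
        row = np.clip(np.floor(np.asarray(y) / self.bin_size).astype(int), 0, n - 1)
        return row, col

    def quadrant_of(self, x, y):
        """Quadrant index 0..3 (Q1..Q4), split at the ROI midlines."""
        mid = self.arena_extent / 2.0
        return (2 * (np.asarray(y) >= mid) + (np.asarray(x) >= mid)).astype(int)


def corner_schedule(cooling_span, arena_extent: float = 25.0,
                    maze_extent: float = 20.0, epoch_s: float = 300.0,
                    n_cycles: int = 4) -> list:
    """Four corner warm spots heated ``epoch_s`` each, order 1-2-3-4, repeated.

    Spot centers sit at the centers of the four corner Peltier elements of
    the walkable inner square.
    """
    margin = (arena_extent - maze_extent) / 2.0
    lo = margin + 2.0
    hi = arena_extent - margin - 2.0
    corners = [(lo, lo), (hi, lo), (hi, hi), (lo, hi)]
    start, end = cooling_span
    spots, t = [], start
    for _ in range(n_cycles):
        for cx, cy in corners:
            if t + epoch_s > end + 1e-9:
                break
            spots.append(WarmSpot(cx, cy, t, t + epoch_s))
            t += epoch_s
    return spots


def two_spot_schedule(cooling_span, arena_extent: float = 25.0,
                      maze_extent: float = 20.0, epoch_s: float = 1200.0,
                      n_cycles: int = 2) -> list:
    """20-min two-spot variant: two opposite corners alternately heated."""
    margin = (arena_extent - maze_extent) / 2.0
    lo = margin + 2.0
    hi = arena_extent - margin - 2.0
    corners = [(lo, lo), (hi, hi)]
    start, end = cooling_span
    spots, t = [], start
    for _ in range(n_cycles):
        for cx, cy in corners:
            if t + epoch_s > end + 1e-9:
                break
            spots.append(WarmSpot(cx, cy, t, t + epoch_s))
            t += epoch_s
    return spots


def two_spot_config(rng_seed: int = 0) -> SessionConfig:
    """Session with the 20-min warm-spot protocol (sleep-permissive)."""
    cfg = SessionConfig(rng_seed=rng_seed)
    cfg.warm_spot_schedule = two_spot_schedule(cfg.sub_session("Cooling"),
                                               cfg.arena_extent, cfg.maze_extent)
    cfg.validate()
    return cfg
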