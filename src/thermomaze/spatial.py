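"""Movement firing-rate maps, spatial information, place-cell rules.

Rate maps divide a movement spike-count map by the movement occupancy map
on the 25 x 25 bin grid.  Spatial information is the Skaggs measure

    SI = sum_i p_i (lambda_i / lambda_bar) log2(lambda_i / lambda_bar),

with p_i the occupancy probability of bin i, lambda_i its firing rate and
lambda_bar the occupancy-weighted mean rate; bins with lambda_i = 0
contribute zero.  Significance comes from a 5-s block shuffle of the
position/spike correspondence during movement.  A pyramidal unit counts as
a place cell in a sub-session when peak rate >= 0.4 Hz, SI >= 0.25
bits/spike and the shuffle z-score >= 1.65, and session-wide when it
passes in all three sub-sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

from .behavior import MotionSegments, OccupancyMap, Trajectory
from .config import SessionConfig

CELL_TYPES = ("pyramidal", "narrow_interneuron", "wide_interneuron", "unclassified")


@dataclass
class SpikeTrain:
    """Sorted-unit spike times (s) with a putative cell-type label."""

    unit_id: int
    times: np.ndarray
    cell_type: str = "unclassified"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be non-decreasing")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")

    def in_span(self, lo: float, hi: float) -> np.ndarray:
        return self.times[(self.times >= lo) & (self.times < hi)]


@dataclass
class RateMap:
    """Binned firing-rate surface (Hz) with a valid-occupancy mask."""

    rate: np.ndarray            # smoothed (Hz)
    rate_unsmoothed: np.ndarray
    valid: np.ndarray           # occupancy > 0
    sub_session: str = ""
    smoothing: str = "gaussian(sigma=2)"

    def peak(self) -> float:
        return float(self.rate_unsmoothed[self.valid].max()) if self.valid.any() else np.nan


@dataclass
class SpatialInfoResult:
    si: float                   # bits/spike
    peak_rate: float            # Hz, unsmoothed
    z: float = np.nan           # vs block-shuffle null
    n_shuffles: int = 0
    significant: bool = False
    null_si: np.ndarray = field(default=None, repr=False)


def spike_count_map(spikes: SpikeTrain, traj: Trajectory,
                    segments: MotionSegments, config: SessionConfig,
                    state: str = "movement"):
    """Spikes binned at the position of the nearest trajectory sample.

    Only spikes whose nearest sample is in the requested motion state are
    counted; spikes outside the trajectory span are dropped (tallied).
    """
    n = config.n_bins
    t = spikes.times
    inside = (t >= traj.t[0]) & (t <= traj.t[-1])
    idx = traj.nearest_index(t[inside])
    want_move = state == "movement"
    keep = segments.sample_movement[idx] == want_move
    idx = idx[keep]
    row, col = config.bin_of(traj.x[idx], traj.y[idx])
    grid = np.zeros((n, n))
    np.add.at(grid, (row, col), 1.0)
    return grid, int(np.count_nonzero(~inside))


def smooth_masked(values: np.ndarray, weights: np.ndarray,
                  sigma: float = 2.0, truncate: float = 4.0,
                  kernel: str = "gaussian") -> np.ndarray:
    """Weight-renormalized smoothing; zero-weight bins contribute nothing.

    Returns smooth(values * weights) / smooth(weights), i.e. the classic
    occupancy-weighted rate-map smoother.  Constant fields are preserved
    exactly and masked-out bins neither receive nor donate mass.
    """
    w = np.asarray(weights, dtype=float)
    vw = np.asarray(values, dtype=float) * w
    if kernel == "gaussian":
        num = gaussian_filter(vw, sigma=sigma, truncate=truncate, mode="constant")
        den = gaussian_filter(w, sigma=sigma, truncate=truncate, mode="constant")
    elif kernel == "boxcar":
        num = uniform_filter(vw, size=int(sigma), mode="constant")
        den = uniform_filter(w, size=int(sigma), mode="constant")
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    out = np.zeros_like(num)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


class EmptyMapError(ValueError):
    """All-zero occupancy: no rate map can be formed."""


def rate_map(counts: np.ndarray, occupancy: OccupancyMap,
             sigma: float = 2.0, kernel: str = "gaussian",
             sub_session: str = "") -> RateMap:
    """Bin-wise counts/occupancy with 2-bin smoothing on valid bins."""
    occ = occupancy.grid
    valid = occ > 0
    if not valid.any():
        raise EmptyMapError("occupancy map is everywhere zero")
    raw = np.zeros_like(occ)
    raw[valid] = counts[valid] / occ[valid]
    smoothed = smooth_masked(raw, occ * valid, sigma=sigma, kernel=kernel)
    return RateMap(smoothed, raw, valid, sub_session=sub_session,
                   smoothing=f"{kernel}(sigma={sigma})")


def map_correlation(map_a: RateMap, map_b: RateMap, min_bins: int = 10) -> float:
    """Pearson r over jointly valid bins; nan when a map is constant."""
    joint = map_a.valid & map_b.valid
    if joint.sum() < min_bins:
        raise ValueError(f"fewer than {min_bins} jointly valid bins")
    a = map_a.rate[joint]
    b = map_b.rate[joint]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def spatial_information(rate_unsmoothed: np.ndarray,
                        occupancy: OccupancyMap) -> float:
    """Skaggs information in bits/spike on unsmoothed rates; nan if silent."""
    occ = occupancy.grid
    valid = occ > 0
    if not valid.any():
        return np.nan
    p = occ[valid] / occ[valid].sum()
    lam = rate_unsmoothed[valid]
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        return np.nan
    pos = lam > 0
    ratio = lam[pos] / lam_bar
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def _si_from_binned(spike_bins: np.ndarray, occ_flat: np.ndarray,
                    n_cells: int, total_time_per_frame: float) -> float:
    """SI from flat spike-bin assignments against a flat occupancy vector."""
    counts = np.bincount(spike_bins, minlength=n_cells).astype(float)
    valid = occ_flat > 0
    p = occ_flat[valid] / occ_flat[valid].sum()
    lam = np.zeros(n_cells)
    lam[valid] = counts[valid] / occ_flat[valid]
    lam_bar = float(np.sum(p * lam[valid]))
    if lam_bar <= 0:
        return np.nan
    lv = lam[valid]
    pos = lv > 0
    ratio = lv[pos] / lam_bar
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def shuffle_significance(spikes: SpikeTrain, traj: Trajectory,
                         segments: MotionSegments, config: SessionConfig,
                         n_shuffles: int = 100, block_s: float = 5.0,
                         rng: np.random.Generator = None,
                         z_crit: float = 1.65) -> SpatialInfoResult:
    """Block-shuffle null for spatial information during movement.

    Movement frames are concatenated and cut into 5-s blocks; each shuffle
    circularly rotates the block order of the position stream relative to
    the spikes (offset >= 1 block, drawn at random), recomputes SI, and the
    observed SI is z-scored against that null.  One-sided significance at
    z >= 1.65.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    move = segments.sample_movement
    move_idx = np.flatnonzero(move)
    dt = float(np.median(np.diff(traj.t)))
    frames_per_block = max(1, int(round(block_s / dt)))
    n_blocks = len(move_idx) // frames_per_block
    if n_blocks < 20:
        raise ValueError(f"only {n_blocks} movement blocks; need >= 20")
    used = move_idx[: n_blocks * frames_per_block]

    n = config.n_bins
    row, col = config.bin_of(traj.x[used], traj.y[used])
    pos_bin = row * n + col                       # flat bin per movement frame
    occ_flat = np.bincount(pos_bin, minlength=n * n).astype(float) * dt

    # spikes -> concatenated movement-frame index
    t = spikes.times
    inside = (t >= traj.t[0]) & (t <= traj.t[-1])
    samp = traj.nearest_index(t[inside])
    frame_rank = np.full(len(traj.t), -1, dtype=int)
    frame_rank[used] = np.arange(len(used))
    spike_frames = frame_rank[samp]
    spike_frames = spike_frames[spike_frames >= 0]

    si_obs = _si_from_binned(pos_bin[spike_frames], occ_flat, n * n, dt)
    counts_obs = np.bincount(pos_bin[spike_frames], minlength=n * n).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam_obs = np.where(occ_flat > 0, counts_obs / occ_flat, 0.0)
    peak = float(lam_obs.max()) if np.any(occ_flat > 0) else np.nan

    block_of = np.arange(len(used)) // frames_per_block
    within = np.arange(len(used)) % frames_per_block
    offsets = rng.integers(1, n_blocks, size=n_shuffles)
    null = np.empty(n_shuffles)
    for k, off in enumerate(offsets):
        rot_frame = ((block_of + off) % n_blocks) * frames_per_block + within
        null[k] = _si_from_binned(pos_bin[rot_frame[spike_frames]],
                                  occ_flat, n * n, dt)
    sd = float(np.std(null))
    if sd == 0 or not np.isfinite(si_obs):
        return SpatialInfoResult(si_obs, peak, np.nan, n_shuffles, False, null)
    z = float((si_obs - null.mean()) / sd)
    return SpatialInfoResult(si_obs, peak, z, n_shuffles, z >= z_crit, null)


def identify_place_cells(results_by_sub_session: dict,
                         peak_min: float = 0.4, si_min: float = 0.25,
                         z_crit: float = 1.65):
    """Threshold rules per sub-session; place cell iff passed in all three.

    ``results_by_sub_session`` maps sub-session label to a
    :class:`SpatialInfoResult` with ``peak_rate`` filled in.
    """
    flags = {}
    for lab, res in results_by_sub_session.items():
        flags[lab] = bool(res.peak_rate >= peak_min and res.si >= si_min
                          and np.isfinite(res.z) and res.z >= z_crit)
    missing = [lab for lab in ("Pre", "Cooling", "Post")
               if lab not in results_by_sub_session]
    overall = None if missing else all(
        flags[lab] for lab in ("Pre", "Cooling", "Post"))
    return flags, overall


def classify_cell_type(trough_to_peak_ms: float, acg_rise_ms: float) -> str:
    """Waveform/autocorrelogram rule for putative cell types.

    Trough-to-peak < 0.425 ms -> narrow interneuron; otherwise an
    autocorrelogram rise time > 6 ms -> wide interneuron; else pyramidal.
    """
    if trough_to_peak_ms < 0 or acg_rise_ms < 0:
        raise ValueError("waveform metrics must be non-negative")
    if trough_to_peak_ms < 0.425:
        return "narrow_interneuron"
    if acg_rise_ms > 6.0:
        return "wide_interneuron"
    return "pyramidal"
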