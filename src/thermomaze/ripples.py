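"""Sharp-wave ripple (SPW-R) detection and event properties.

The LFP from a CA1 pyramidal-layer channel is band-pass filtered between
130 and 200 Hz with a third-order Chebyshev type-I filter applied
forward-backward (zero phase), squared, smoothed with a ~12.8 ms moving
average, and z-scored over the whole trace.  Candidate events are
excursions above the 2-SD edge threshold whose maximum exceeds 5 SD; the
excursion bounds are the event start/end, the maximum is the power peak.
Events shorter than 20 ms or longer than 200 ms are discarded.  A
designated noise channel (no ripples, shared artifacts) vetoes
coincident false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import cheby1, periodogram, sosfiltfilt

from .behavior import MotionSegments, Trajectory
from .config import QUADRANT_LABELS, SessionConfig
from .spatial import smooth_masked

EVENT_COLUMNS = ["start_s", "peak_s", "end_s", "duration_s"]


class DegenerateSignalError(ValueError):
    """Flat LFP: the SD-based threshold is undefined."""


@dataclass
class LFPRecording:
    """Multi-channel LFP in microvolts with per-channel roles."""

    samples: np.ndarray         # (n_channels, n_samples), µV
    rate: float                 # samples/s
    channel_roles: list         # "pyramidal_layer" | "noise"
    uv_per_count: float = 1.0   # scaling used on disk

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate <= 400:
            raise ValueError("LFP rate must exceed 400 samples/s")
        if len(self.channel_roles) != self.samples.shape[0]:
            raise ValueError("one role per channel required")
        if "pyramidal_layer" not in self.channel_roles:
            raise ValueError("need at least one pyramidal_layer channel")

    def channel(self, role: str) -> np.ndarray:
        return self.samples[self.channel_roles.index(role)]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.rate


def ripple_bandpass(signal: np.ndarray, fs: float,
                    band=(130.0, 200.0), order: int = 3,
                    ripple_db: float = 1.0) -> np.ndarray:
    """Zero-phase third-order Chebyshev type-I band-pass."""
    if band[1] >= fs / 2:
        raise ValueError("band edge above Nyquist")
    sos = cheby1(order, ripple_db, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, signal)


def detect_ripples(lfp: LFPRecording, channel_role: str = "pyramidal_layer",
                   band=(130.0, 200.0), peak_sd: float = 5.0,
                   edge_sd: float = 2.0, smooth_s: float = 0.0128,
                   duration_limits=(0.02, 0.2),
                   smooth_before_z: bool = False) -> pd.DataFrame:
    """Detect SPW-Rs on one channel; returns start/peak/end/duration (s).

    ``smooth_before_z`` selects whether the squared trace is smoothed
    before z-scoring or z-scored raw and then smoothed (default); both
    are defensible readings of "normalized squared signal".  The default
    references the SD of the unsmoothed squared trace, which keeps
    isolated single-sample power spikes in background noise from
    crossing the peak threshold after smoothing.
    """
    fs = lfp.rate
    sig = lfp.channel(channel_role)
    if len(sig) < 10 * fs:
        raise ValueError("need >= 10 s of signal for a stable SD estimate")
    filt = ripple_bandpass(sig, fs, band=band)
    power = filt ** 2
    win = max(1, int(round(smooth_s * fs)))
    if smooth_before_z:
        power = uniform_filter1d(power, size=win)
    sd = power.std()
    if sd == 0:
        raise DegenerateSignalError("flat signal: zero variance in ripple band")
    z = (power - power.mean()) / sd
    if not smooth_before_z:
        z = uniform_filter1d(z, size=win)

    above = z >= edge_sd
    if not above.any():
        return pd.DataFrame(columns=EVENT_COLUMNS)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1     # exclusive
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(z)]])

    rows = []
    for s, e in zip(starts, ends):
        seg = z[s:e]
        if seg.max() < peak_sd:
            continue
        dur = (e - s) / fs
        if not duration_limits[0] <= dur <= duration_limits[1]:
            continue
        p = s + int(np.argmax(seg))
        rows.append((s / fs, p / fs, e / fs, dur))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def exclude_noise_events(events: pd.DataFrame, noise_events: pd.DataFrame,
                         tolerance_s: float = 0.025) -> pd.DataFrame:
    """Drop ripple-channel events coincident (±25 ms) with noise-channel ones."""
    if noise_events is None or len(noise_events) == 0 or len(events) == 0:
        return events.reset_index(drop=True)
    np_peaks = np.sort(noise_events["peak_s"].to_numpy())
    peaks = events["peak_s"].to_numpy()
    idx = np.searchsorted(np_peaks, peaks)
    near = np.full(len(peaks), np.inf)
    ok = idx < len(np_peaks)
    near[ok] = np.abs(np_peaks[idx[ok]] - peaks[ok])
    ok = idx > 0
    near[ok] = np.minimum(near[ok], np.abs(np_peaks[idx[ok] - 1] - peaks[ok]))
    return events[near > tolerance_s].reset_index(drop=True)


def ripple_properties(events: pd.DataFrame, lfp: LFPRecording,
                      channel_role: str = "pyramidal_layer",
                      band=(130.0, 200.0)) -> pd.DataFrame:
    """Amplitude (µV, peak of band-passed trace) and peak frequency (Hz).

    Peak frequency is the argmax of a zero-padded periodogram of the
    band-passed event snippet at 1 Hz resolution, restricted to the band.
    Events spanning fewer than three oscillation cycles of the low band
    edge are flagged ``freq_low_confidence``.
    """
    fs = lfp.rate
    filt = ripple_bandpass(lfp.channel(channel_role), fs, band=band)
    nfft = int(fs)  # 1 Hz resolution
    amps, freqs, lowconf = [], [], []
    for _, ev in events.iterrows():
        s, e = int(round(ev.start_s * fs)), int(round(ev.end_s * fs))
        snip = filt[s:e]
        amps.append(float(np.abs(snip).max()) if len(snip) else np.nan)
        if len(snip) < 4:
            freqs.append(np.nan)
            lowconf.append(True)
            continue
        f, pxx = periodogram(snip, fs=fs, nfft=max(nfft, len(snip)))
        in_band = (f >= band[0]) & (f <= band[1])
        freqs.append(float(f[in_band][np.argmax(pxx[in_band])]))
        lowconf.append(bool(ev.duration_s < 3.0 / band[0]))
    out = events.copy()
    out["amplitude_uv"] = amps
    out["peak_frequency_hz"] = freqs
    out["freq_low_confidence"] = lowconf
    return out


def assign_ripple_location(events: pd.DataFrame, traj: Trajectory,
                           segments: MotionSegments, config: SessionConfig,
                           state_bouts: pd.DataFrame = None):
    """Localize events on the trajectory and build the SPW-R rate map.

    Each event takes the position of the trajectory sample nearest its
    power peak, hence a spatial bin and quadrant; a brain-state label
    (WAKE/NREM) comes from ``state_bouts`` (``state, start, end`` rows;
    all-WAKE when absent).  The SPW-R rate map divides the per-bin event
    count by per-bin immobility occupancy, 2-bin smoothed.  Events whose
    peak lies outside the trajectory span are dropped (tallied in
    ``attrs['n_dropped']``).
    """
    from .behavior import occupancy_map  # local import to avoid cycle at module load

    ev = events.copy()
    peaks = ev["peak_s"].to_numpy()
    inside = (peaks >= traj.t[0]) & (peaks <= traj.t[-1])
    ev = ev[inside].reset_index(drop=True)
    idx = traj.nearest_index(ev["peak_s"].to_numpy())
    ev["x"] = traj.x[idx]
    ev["y"] = traj.y[idx]
    row, col = config.bin_of(ev["x"].to_numpy(), ev["y"].to_numpy())
    ev["bin_row"], ev["bin_col"] = row, col
    q = config.quadrant_of(ev["x"].to_numpy(), ev["y"].to_numpy())
    ev["quadrant"] = [QUADRANT_LABELS[i] for i in q]
    ev["motion_state"] = segments.state_at(ev["peak_s"].to_numpy())
    if state_bouts is not None and len(state_bouts):
        starts = state_bouts["start"].to_numpy()
        labels = state_bouts["state"].to_numpy()
        order = np.argsort(starts)
        bi = np.clip(np.searchsorted(starts[order], ev["peak_s"].to_numpy(),
                                     side="right") - 1, 0, len(starts) - 1)
        ev["brain_state"] = labels[order][bi]
    else:
        ev["brain_state"] = "WAKE"
    ev.attrs["n_dropped"] = int(np.count_nonzero(~inside))

    n = config.n_bins
    count_map = np.zeros((n, n))
    imm = ev["motion_state"] == "immobility"
    np.add.at(count_map, (row[imm.to_numpy()], col[imm.to_numpy()]), 1.0)
    occ = occupancy_map(traj, segments, "immobility", config)
    valid = occ.grid > 0
    raw = np.zeros_like(count_map)
    raw[valid] = count_map[valid] / occ.grid[valid]
    rate_map = smooth_masked(raw, occ.grid * valid, sigma=2.0)
    return ev, count_map, rate_map
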