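"""Plain-text and flat-binary session I/O.

Formats: trajectory, spikes, motion segments, events and state bouts as
delimited text (CSV); LFP as channel-interleaved little-endian int16 with
a JSON sidecar carrying sampling rate, scaling and channel roles; ground
truth as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import Trajectory
from .ripples import LFPRecording
from .spatial import SpikeTrain


def write_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y,
                  "likelihood": traj.likelihood}).to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(df["t"].to_numpy(), df["x"].to_numpy(),
                      df["y"].to_numpy(), df["likelihood"].to_numpy())


def write_spikes(trains, path) -> None:
    rows = [(st.unit_id, t, st.cell_type) for st in trains for t in st.times]
    pd.DataFrame(rows, columns=["unit_id", "t", "cell_type"]).to_csv(
        path, index=False)


def read_spikes(path) -> list:
    df = pd.read_csv(path)
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        trains.append(SpikeTrain(int(uid), np.sort(grp["t"].to_numpy()),
                                 grp["cell_type"].iloc[0]))
    return trains


def write_state_bouts(bouts: pd.DataFrame, path) -> None:
    bouts.to_csv(path, index=False)


def read_state_bouts(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_lfp(lfp: LFPRecording, dat_path, sidecar_path=None) -> None:
    """Channel-interleaved int16 counts plus a JSON sidecar."""
    dat_path = Path(dat_path)
    if sidecar_path is None:
        sidecar_path = dat_path.with_suffix(".json")
    counts = np.round(lfp.samples / lfp.uv_per_count)
    counts = np.clip(counts, -32768, 32767).astype("<i2")
    counts.T.reshape(-1).tofile(dat_path)  # sample-major, channel-interleaved
    sidecar = {
        "n_channels": lfp.samples.shape[0],
        "rate": lfp.rate,
        "uv_per_count": lfp.uv_per_count,
        "channel_roles": list(lfp.channel_roles),
        "dtype": "int16",
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_lfp(dat_path, sidecar_path=None) -> LFPRecording:
    dat_path = Path(dat_path)
    if sidecar_path is None:
        sidecar_path = dat_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    raw = np.fromfile(dat_path, dtype="<i2").reshape(-1, meta["n_channels"]).T
    return LFPRecording(raw.astype(float) * meta["uv_per_count"], meta["rate"],
                        meta["channel_roles"], uv_per_count=meta["uv_per_count"])


def write_ground_truth(truth, path) -> None:
    doc = {
        "units": [dataclasses.asdict(u) for u in truth.units],
        "participation": truth.participation.tolist(),
        "behavior": dataclasses.asdict(truth.behavior),
        "ripple_rate_hz": truth.ripple_rate_hz,
        "ripple_times": None if truth.ripple_times is None
        else truth.ripple_times.tolist(),
        "ripple_durations": None if truth.ripple_durations is None
        else truth.ripple_durations.tolist(),
        "ripple_quadrants": None if truth.ripple_quadrants is None
        else [int(q) for q in truth.ripple_quadrants],
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=float))


def write_session(session, out_dir) -> None:
    """Write a synthetic session as the standard per-session file set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trajectory(session.trajectory, out / "trajectory.csv")
    write_spikes(session.spikes, out / "spikes.csv")
    write_state_bouts(session.state_bouts, out / "state_bouts.csv")
    if session.true_ripples is not None:
        session.true_ripples.to_csv(out / "true_ripples.csv", index=False)
    if session.lfp is not None:
        write_lfp(session.lfp, out / "lfp.dat")
    write_ground_truth(session.truth, out / "ground_truth.json")
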