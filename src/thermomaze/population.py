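"""Rate-ratio correlations and population-vector analysis across conditions.

A unit's firing-rate ratio in a quadrant is its rate there divided by the
sum of its rates over the four quadrants, computed per condition
(movement, awake SPW-R, NREM SPW-R).  Single-unit similarity pools the
(unit, quadrant) ratio pairs of two conditions into one Pearson
correlation.  Population vectors concatenate all units' ratios for one
(condition, quadrant); their pairwise Pearson correlations quantify
whether quadrant-specific firing structure is shared across conditions.

The sum (rather than mean) denominator is used for every condition so
ratios live in [0, 1] on a common scale; Pearson correlation is
scale-invariant, so this differs from a mean-normalized convention by an
irrelevant factor of 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import MotionSegments, Trajectory
from .config import QUADRANT_LABELS, SessionConfig
from .ripple_tuning import N_QUADRANTS, QuadrantProfile
from .spatial import SpikeTrain


def movement_rate_ratios(spikes: SpikeTrain, traj: Trajectory,
                         segments: MotionSegments,
                         config: SessionConfig) -> QuadrantProfile:
    """Per-quadrant movement firing rates and ratios for one unit.

    Rates use movement-state spikes over movement occupancy per quadrant;
    a unit whose session lacks movement time in some quadrant is
    undefined (``profile.defined`` False) and excluded downstream.
    """
    move = segments.sample_movement
    dur = traj.frame_durations()
    q_frames = config.quadrant_of(traj.x, traj.y)
    exposure = np.bincount(q_frames[move], weights=dur[move],
                           minlength=N_QUADRANTS)

    t = spikes.times
    inside = (t >= traj.t[0]) & (t <= traj.t[-1])
    idx = traj.nearest_index(t[inside])
    idx = idx[move[idx]]
    counts = np.bincount(q_frames[idx], minlength=N_QUADRANTS).astype(float)
    rates = np.zeros(N_QUADRANTS)
    ok = exposure > 0
    rates[ok] = counts[ok] / exposure[ok]
    return QuadrantProfile(spikes.unit_id, "movement", rates, exposure,
                           n_spikes=int(counts.sum()))


def ratio_correlation(profiles_a, profiles_b, min_units: int = 10):
    """Pearson r over pooled (unit, quadrant) ratio pairs of two conditions."""
    a_by_id = {p.unit_id: p for p in profiles_a if p.defined and p.rates.sum() > 0}
    xs, ys = [], []
    for pb in profiles_b:
        if not (pb.defined and pb.rates.sum() > 0):
            continue
        pa = a_by_id.get(pb.unit_id)
        if pa is None:
            continue
        xs.append(pa.ratios)
        ys.append(pb.ratios)
    if len(xs) < min_units:
        raise ValueError(f"only {len(xs)} units with both conditions defined")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate ratio vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(xs)


@dataclass
class PopulationVector:
    condition: str
    quadrant: str
    values: np.ndarray     # per-unit ratios, shared unit order
    unit_ids: list


def build_population_vectors(profiles_by_condition: dict) -> list:
    """One vector per (condition, quadrant), listwise over the conditions given.

    A unit enters only if its profile is defined (non-zero total rate and
    full quadrant exposure) under every requested condition; exclusion is
    scoped to the condition set actually compared.
    """
    conditions = list(profiles_by_condition)
    by_cond = {
        c: {p.unit_id: p for p in profiles_by_condition[c]
            if p.defined and p.rates.sum() > 0}
        for c in conditions
    }
    shared = sorted(set.intersection(*(set(d) for d in by_cond.values())))
    if not shared:
        raise ValueError("no unit defined under all requested conditions")
    vectors = []
    for c in conditions:
        ratios = np.vstack([by_cond[c][u].ratios for u in shared])
        for qi, q in enumerate(QUADRANT_LABELS):
            vectors.append(PopulationVector(c, q, ratios[:, qi], list(shared)))
    return vectors


@dataclass
class PVCorrelationMatrix:
    matrix: pd.DataFrame           # Pearson r, (condition, quadrant) x same
    n_units: int
    summaries: dict                # grouped medians, see pv_correlation_matrix


def pv_correlation_matrix(vectors, min_units: int = 3) -> PVCorrelationMatrix:
    """All pairwise PV correlations plus grouped summaries.

    Summaries: ``same_quadrant_cross_condition`` and
    ``different_quadrant_cross_condition`` pooled r values, and per
    condition pair the median cross-condition same-quadrant r under key
    ``median(condA|condB)``.  Constant vectors yield NaN entries.
    """
    labels = [(v.condition, v.quadrant) for v in vectors]
    n_units = len(vectors[0].values)
    if n_units < min_units:
        raise ValueError(f"population vectors have only {n_units} units")
    vals = np.vstack([v.values for v in vectors])
    with np.errstate(invalid="ignore"):
        sd = vals.std(axis=1)
        mat = np.corrcoef(vals)
    mat[sd == 0, :] = np.nan
    mat[:, sd == 0] = np.nan
    idx = pd.MultiIndex.from_tuples(labels, names=["condition", "quadrant"])
    df = pd.DataFrame(mat, index=idx, columns=idx)

    same_q, diff_q = [], []
    pair_vals = {}
    for i, (ci, qi) in enumerate(labels):
        for j, (cj, qj) in enumerate(labels):
            if j <= i or ci == cj:
                continue
            r = mat[i, j]
            (same_q if qi == qj else diff_q).append(r)
            if qi == qj:
                pair_vals.setdefault(frozenset((ci, cj)), []).append(r)
    summaries = {
        "same_quadrant_cross_condition": np.asarray(same_q),
        "different_quadrant_cross_condition": np.asarray(diff_q),
    }
    for pair, rs in pair_vals.items():
        a, b = sorted(pair)
        summaries[f"median({a}|{b})"] = float(np.nanmedian(rs))
    return PVCorrelationMatrix(df, n_units, summaries)


def same_vs_different_quadrant_test(pv: PVCorrelationMatrix,
                                    alternative: str = "greater"):
    """One-sided rank test: same-quadrant r above different-quadrant r."""
    a = pv.summaries["same_quadrant_cross_condition"]
    b = pv.summaries["different_quadrant_cross_condition"]
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
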