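"""Bayesian decoding of the animal's quadrant from within-ripple spikes.

For quadrant x and spike-count vector n over N units, the posterior is

    P(x|n) = C(tau, n) P(x) (prod_i f_i(x)^{n_i}) exp(-tau sum_i f_i(x)),

the Poisson population likelihood with time window tau = 300 ms (the
within-ripple analysis window), firing-rate templates f_i(x) estimated
from training SPW-Rs, normalization C taken as 1, and prior P(x) either
uniform or the training-event quadrant proportions.  Decoding is the
posterior argmax.  Session accuracy uses 100-fold cross-validation:
templates from 99 folds, accuracy on the held-out fold, averaged.

Computation is in log space; template rates are floored at 0.01 Hz inside
the likelihood (both terms) so a zero-rate template with an observed
spike yields a finite, strongly unfavorable log-likelihood rather than
-inf.  Stored templates keep their exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ripple_tuning import (EventDesign, N_QUADRANTS, event_design,
                            quadrant_exposure, spike_counts_per_event)

RATE_FLOOR_HZ = 0.01


class TemplateUndefinedError(ValueError):
    """A quadrant has no training window time; templates undefined."""


@dataclass
class DecodingTemplates:
    """Per-unit, per-quadrant within-ripple rate templates f_i(x)."""

    f: np.ndarray                  # (n_units, 4), Hz
    unit_ids: list
    training_event_ids: np.ndarray = None

    def __post_init__(self):
        if np.any(self.f < 0):
            raise ValueError("templates must be non-negative")


@dataclass
class PosteriorResult:
    posterior: np.ndarray          # len 4, sums to 1
    decoded: int                   # quadrant index 0..3
    tie: bool = False
    log_likelihood: np.ndarray = field(default=None, repr=False)


@dataclass
class CVResult:
    accuracy: float                # mean of per-fold accuracies
    fold_accuracies: np.ndarray
    decoded: np.ndarray            # per event, -1 for skipped folds
    true_quadrant: np.ndarray
    n_folds: int
    n_skipped_folds: int
    prior_mode: str


def _counts_matrix(spike_trains, design: EventDesign) -> np.ndarray:
    return np.vstack([spike_counts_per_event(st, design) for st in spike_trains])


def build_templates(spike_trains, events: pd.DataFrame,
                    window: float = 0.3) -> DecodingTemplates:
    """Templates from all (or training-subset) events, shared rate machinery."""
    design = event_design(events, window=window)
    exposure = quadrant_exposure(design)
    if np.any(exposure <= 0):
        raise TemplateUndefinedError("a quadrant has zero training window time")
    counts = _counts_matrix(spike_trains, design)
    num = np.zeros((counts.shape[0], N_QUADRANTS))
    for q in range(N_QUADRANTS):
        num[:, q] = counts[:, design.quadrants == q].sum(axis=1)
    return DecodingTemplates(num / exposure, [st.unit_id for st in spike_trains],
                             training_event_ids=np.arange(len(design)))


def decode_event(n: np.ndarray, templates, prior=None, tau: float = 0.3,
                 rate_floor: float = RATE_FLOOR_HZ) -> PosteriorResult:
    """Posterior over quadrants for one spike-count vector (log-space)."""
    f = templates.f if isinstance(templates, DecodingTemplates) else np.asarray(templates)
    n = np.asarray(n, dtype=float)
    if np.any(n < 0) or np.any(n != np.round(n)):
        raise ValueError("spike counts must be non-negative integers")
    if prior is None:
        prior = np.full(N_QUADRANTS, 1.0 / N_QUADRANTS)
    prior = np.asarray(prior, dtype=float)
    fe = np.maximum(f, rate_floor)
    loglik = n @ np.log(fe) - tau * fe.sum(axis=0)
    w = prior * np.exp(loglik - loglik.max())
    posterior = w / w.sum()
    best = int(np.argmax(posterior))
    tie = bool(np.count_nonzero(posterior == posterior[best]) > 1)
    return PosteriorResult(posterior, best, tie=tie, log_likelihood=loglik)


def _fold_assignment(n_events: int, n_folds: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Random near-equal partition of events into folds."""
    fold = np.arange(n_events) % n_folds
    return fold[rng.permutation(n_events)]


def cross_validate(spike_trains, events: pd.DataFrame, n_folds: int = 100,
                   prior_mode: str = "uniform", rng=None, window: float = 0.3,
                   tau: float = 0.3, rate_floor: float = RATE_FLOOR_HZ) -> CVResult:
    """100-fold cross-validated quadrant decoding accuracy.

    Per-event windows (overlap-trimmed over the full event set) and spike
    counts are computed once; each fold's templates aggregate training
    events only.  A fold whose training set leaves a quadrant without
    window time is skipped and tallied.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    design = event_design(events, window=window)
    if len(design) < n_folds:
        raise ValueError("need at least one event per fold")
    counts = _counts_matrix(spike_trains, design)
    return _cross_validate_design(counts, design, n_folds, prior_mode, rng,
                                  tau, rate_floor)


def _cross_validate_design(counts: np.ndarray, design: EventDesign,
                           n_folds: int, prior_mode: str,
                           rng: np.random.Generator, tau: float,
                           rate_floor: float,
                           quadrants: np.ndarray = None) -> CVResult:
    quads = design.quadrants if quadrants is None else quadrants
    n_ev = len(design)
    fold = _fold_assignment(n_ev, n_folds, rng)

    onehot = np.zeros((n_ev, N_QUADRANTS))
    onehot[np.arange(n_ev), quads] = 1.0
    tot_num = counts @ onehot                       # (units, 4)
    tot_dur = design.durations @ onehot             # (4,)
    tot_nev = onehot.sum(axis=0)

    decoded = np.full(n_ev, -1, dtype=int)
    fold_acc, skipped = [], 0
    for k in range(n_folds):
        test = fold == k
        num = tot_num - counts[:, test] @ onehot[test]
        dur = tot_dur - design.durations[test] @ onehot[test]
        nev = tot_nev - onehot[test].sum(axis=0)
        if np.any(dur <= 0):
            skipped += 1
            continue
        f = num / dur
        if prior_mode == "uniform":
            prior = np.full(N_QUADRANTS, 0.25)
        elif prior_mode == "occupancy":
            prior = nev / nev.sum()
        else:
            raise ValueError(f"unknown prior mode {prior_mode!r}")
        fe = np.maximum(f, rate_floor)
        loglik = counts[:, test].T @ np.log(fe) - tau * fe.sum(axis=0)
        with np.errstate(under="ignore"):
            w = prior * np.exp(loglik - loglik.max(axis=1, keepdims=True))
        decoded[test] = np.argmax(w, axis=1)
        fold_acc.append(float(np.mean(decoded[test] == quads[test])))
    if not fold_acc:
        raise ValueError("every fold was skipped; decoding undefined")
    return CVResult(float(np.mean(fold_acc)), np.asarray(fold_acc), decoded,
                    quads.copy(), n_folds, skipped, prior_mode)


def chance_level(spike_trains, events: pd.DataFrame, prior_mode: str = "uniform",
                 mode: str = "permutation", n_runs: int = 100, n_folds: int = 100,
                 rng=None, window: float = 0.3, tau: float = 0.3) -> float:
    """Decoding chance level.

    ``permutation`` (default): mean cross-validated accuracy over
    ``n_runs`` random permutations of the event quadrant labels.
    ``closed_form``: sum_x q_x^2 for guessing from the label distribution.
    """
    design = event_design(events, window=window)
    quads = design.quadrants
    if mode == "closed_form":
        q = np.bincount(quads, minlength=N_QUADRANTS) / len(quads)
        return float(np.sum(q ** 2))
    if mode != "permutation":
        raise ValueError(f"unknown chance mode {mode!r}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    counts = _counts_matrix(spike_trains, design)
    accs = []
    for _ in range(n_runs):
        perm_q = quads[rng.permutation(len(quads))]
        res = _cross_validate_design(counts, design, n_folds, prior_mode, rng,
                                     tau, RATE_FLOOR_HZ, quadrants=perm_q)
        accs.append(res.accuracy)
    return float(np.mean(accs))
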