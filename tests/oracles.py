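"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain-Python loops over the
definitions, sharing no code path with the package implementation.
"""

import math

import numpy as np


def sts_brute_force(peaks, quadrants, spike_times, window=0.3):
    """STS from the definition: per-quadrant within-window rate, overlap
    between consecutive windows split at the midpoint of the two peaks.

    Returns (rates[4], ratios[4], sts) or None when undefined.
    """
    order = sorted(range(len(peaks)), key=lambda i: peaks[i])
    peaks = [float(peaks[i]) for i in order]
    quadrants = [int(quadrants[i]) for i in order]
    half = window / 2.0
    windows = []
    for i, p in enumerate(peaks):
        lo, hi = p - half, p + half
        if i > 0:
            lo = max(lo, (peaks[i - 1] + p) / 2.0)
        if i < len(peaks) - 1:
            hi = min(hi, (p + peaks[i + 1]) / 2.0)
        windows.append((lo, hi))
    dur = [0.0] * 4
    cnt = [0] * 4
    for (lo, hi), q in zip(windows, quadrants):
        dur[q] += hi - lo
        for t in spike_times:
            if lo <= t < hi:
                cnt[q] += 1
    if any(d <= 0 for d in dur):
        return None
    rates = [c / d for c, d in zip(cnt, dur)]
    tot = sum(rates)
    if tot <= 0:
        return None
    ratios = [r / tot for r in rates]
    return rates, ratios, max(ratios)


def posterior_brute_force(n, f, prior, tau=0.3, floor=0.01):
    """Direct evaluation of P(x|n) = C P(x) (prod f^n) exp(-tau sum f)."""
    n_units, n_quads = f.shape
    like = []
    for x in range(n_quads):
        v = prior[x]
        for i in range(n_units):
            fe = max(f[i, x], floor)
            v *= fe ** n[i]
        v *= math.exp(-tau * sum(max(f[i, x], floor) for i in range(n_units)))
        like.append(v)
    z = sum(like)
    return np.array([v / z for v in like])


def leave_one_out_accuracy(counts, durations, quadrants, tau=0.3, floor=0.01):
    """Direct leave-one-out decoding accuracy from the counts matrix."""
    n_units, n_ev = counts.shape
    correct = 0
    for e in range(n_ev):
        num = [[0.0] * 4 for _ in range(n_units)]
        dur = [0.0] * 4
        for j in range(n_ev):
            if j == e:
                continue
            q = quadrants[j]
            dur[q] += durations[j]
            for i in range(n_units):
                num[i][q] += counts[i, j]
        if any(d <= 0 for d in dur):
            continue
        best, best_ll = None, -np.inf
        for x in range(4):
            ll = math.log(0.25)
            for i in range(n_units):
                fe = max(num[i][x] / dur[x], floor)
                ll += counts[i, e] * math.log(fe) - tau * fe
            if ll > best_ll:
                best_ll, best = ll, x
        if best == quadrants[e]:
            correct += 1
    return correct / n_ev


def pearson_brute_force(x, y):
    """Pearson r from the definitional sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def skaggs_brute_force(rates, occupancy):
    """SI (bits/spike) from the definition over occupied bins."""
    pairs = [(r, o) for r, o in zip(rates, occupancy) if o > 0]
    tot = sum(o for _, o in pairs)
    p = [o / tot for _, o in pairs]
    lam_bar = sum(pi * r for pi, (r, _) in zip(p, pairs))
    si = 0.0
    for pi, (r, _) in zip(p, pairs):
        if r > 0:
            si += pi * (r / lam_bar) * math.log2(r / lam_bar)
    return si
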