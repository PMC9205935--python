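"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

OFFSETS_26 = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) != (0, 0, 0)]

DIRS_13 = [d for d in OFFSETS_26 if d > (0, 0, 0)]


def glcm_pairs(levels: np.ndarray, k: int) -> np.ndarray:
    """Symmetric co-occurrence counts by looping over every voxel pair."""
    mat = np.zeros((k, k), dtype=int)
    shape = levels.shape
    for idx in np.ndindex(shape):
        a = levels[idx]
        if a == 0:
            continue
        for d in OFFSETS_26:
            nb = tuple(i + o for i, o in zip(idx, d))
            if all(0 <= n < s for n, s in zip(nb, shape)):
                b = levels[nb]
                if b > 0:
                    mat[a - 1, b - 1] += 1
    return mat


def glrlm_runs(levels: np.ndarray, k: int, max_len: int) -> np.ndarray:
    """Run-length counts by walking every line in all 13 directions."""
    mat = np.zeros((k, max_len), dtype=int)
    shape = levels.shape
    for d in DIRS_13:
        for idx in np.ndindex(shape):
            a = levels[idx]
            if a == 0:
                continue
            prev = tuple(i - o for i, o in zip(idx, d))
            if (all(0 <= p < s for p, s in zip(prev, shape))
                    and levels[prev] == a):
                continue  # not a run start
            length = 1
            cur = idx
            while True:
                nxt = tuple(i + o for i, o in zip(cur, d))
                if (all(0 <= n < s for n, s in zip(nxt, shape))
                        and levels[nxt] == a):
                    length += 1
                    cur = nxt
                else:
                    break
            mat[a - 1, length - 1] += 1
    return mat


def zones(levels: np.ndarray, grey: int) -> list[set]:
    """26-connected zones of one grey level, by flood fill."""
    shape = levels.shape
    todo = {idx for idx in np.ndindex(shape) if levels[idx] == grey}
    out = []
    while todo:
        seed = todo.pop()
        zone = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for d in OFFSETS_26:
                nb = tuple(i + o for i, o in zip(cur, d))
                if nb in todo:
                    todo.discard(nb)
                    zone.add(nb)
                    frontier.append(nb)
        out.append(zone)
    return out


def city_block_distance_to_edge(mask: np.ndarray, idx) -> int:
    """Min city-block steps from idx to any out-of-mask (or out-of-grid)
    voxel, with edge voxels at distance 1."""
    shape = mask.shape
    best = None
    for other in np.ndindex(shape):
        if not mask[other]:
            d = sum(abs(a - b) for a, b in zip(idx, other))
            best = d if best is None else min(best, d)
    # distance to beyond-grid background
    for ax in range(3):
        best_ax = min(idx[ax] + 1, shape[ax] - idx[ax])
        best = best_ax if best is None else min(best, best_ax)
    return best


def ngtdm_table(levels: np.ndarray, k: int):
    n_k = np.zeros(k)
    s_k = np.zeros(k)
    shape = levels.shape
    for idx in np.ndindex(shape):
        a = levels[idx]
        if a == 0:
            continue
        nbs = []
        for d in OFFSETS_26:
            nb = tuple(i + o for i, o in zip(idx, d))
            if all(0 <= n < s for n, s in zip(nb, shape)) and levels[nb] > 0:
                nbs.append(levels[nb])
        if nbs:
            n_k[a - 1] += 1
            s_k[a - 1] += abs(a - np.mean(nbs))
    return n_k, s_k


def ngldm_counts(levels: np.ndarray, k: int) -> np.ndarray:
    """Dependence matrix: count = 1 + number of equal in-ROI neighbours."""
    mat = np.zeros((k, 27), dtype=int)
    shape = levels.shape
    for idx in np.ndindex(shape):
        a = levels[idx]
        if a == 0:
            continue
        dep = 1
        for d in OFFSETS_26:
            nb = tuple(i + o for i, o in zip(idx, d))
            if all(0 <= n < s for n, s in zip(nb, shape)) and levels[nb] == a:
                dep += 1
        mat[a - 1, dep - 1] += 1
    return mat


def icc_oneway(data: np.ndarray) -> float:
    """Textbook one-way ANOVA ICC(1,1)."""
    n, k = data.shape
    grand = data.mean()
    msb = k * sum((row.mean() - grand) ** 2 for row in data) / (n - 1)
    msw = sum((v - row.mean()) ** 2 for row in data for v in row) / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


def auc_pairs(scores, labels) -> float:
    """AUC by looping over every (positive, negative) pair."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def harrell_c(scores, times, events) -> float:
    """Harrell's C by exhaustive pair enumeration."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j or not events[i]:
                continue
            if times[i] < times[j] or (times[i] == times[j] and not events[j]):
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def logrank_table(times, events, groups):
    """(O1 - E1, variance) from the explicit risk-set table."""
    o_e = var = 0.0
    for u in sorted({t for t, e in zip(times, events) if e}):
        n = sum(1 for t in times if t >= u)
        n1 = sum(1 for t, g in zip(times, groups) if t >= u and g == 1)
        d = sum(1 for t, e in zip(times, events) if t == u and e)
        d1 = sum(1 for t, e, g in zip(times, events, groups)
                 if t == u and e and g == 1)
        o_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_e, var


def km_survival(times, events, t_star) -> float:
    s = 1.0
    for u in sorted({t for t, e in zip(times, events) if e}):
        if u > t_star:
            break
        n = sum(1 for t in times if t >= u)
        d = sum(1 for t, e in zip(times, events) if t == u and e)
        s *= 1 - d / n
    return s


def cox_loglik(beta, x, times, events):
    """Efron partial log-likelihood for one covariate (for grid search)."""
    eta = beta * np.asarray(x, float)
    ll = 0.0
    for u in sorted({t for t, e in zip(times, events) if e}):
        tied = [i for i, (t, e) in enumerate(zip(times, events))
                if t == u and e]
        risk = [i for i, t in enumerate(times) if t >= u]
        d = len(tied)
        s_risk = sum(np.exp(eta[i]) for i in risk)
        s_tied = sum(np.exp(eta[i]) for i in tied)
        ll += sum(eta[i] for i in tied)
        for l in range(d):
            ll -= np.log(s_risk - (l / d) * s_tied)
    return ll
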