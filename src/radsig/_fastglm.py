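"""Lightweight Newton fitters for univariable screening.

The cross-validated feature-selection loop evaluates thousands of
univariable logistic and Cox models; these fitters avoid the per-call
overhead of the full modelling stacks. They are intentionally minimal:
one covariate, Wald statistics only. The final models in
``models_eval`` use statsmodels / lifelines.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def uni_logistic_wald(x: np.ndarray, y: np.ndarray, max_iter: int = 30,
                      tol: float = 1e-8) -> tuple[float, float]:
    """(slope, two-sided Wald p) of a univariable logistic fit."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    beta = np.zeros(2)
    design = np.column_stack([np.ones_like(x), x])
    for _ in range(max_iter):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = p * (1 - p)
        grad = design.T @ (y - p)
        hess = (design * w[:, None]).T @ design
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return 0.0, 1.0
        beta = beta + step
        if np.abs(step).max() < tol:
            break
        if np.abs(beta).max() > 50:  # separation
            return float(beta[1]), 1.0
    eta = design @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = p * (1 - p)
    hess = (design * w[:, None]).T @ design
    try:
        se = np.sqrt(np.linalg.inv(hess)[1, 1])
    except np.linalg.LinAlgError:
        return float(beta[1]), 1.0
    z = beta[1] / se if se > 0 else 0.0
    return float(beta[1]), float(2 * stats.norm.sf(abs(z)))


def _cox_derivs(b: float, x: np.ndarray, times: np.ndarray,
                events: np.ndarray) -> tuple[float, float]:
    """(gradient, information) of a 1-covariate Cox partial likelihood
    with the Efron tie correction. Arrays must be sorted by ascending
    time. (The log-likelihood itself is not needed for Newton/Wald.)"""
    eta = b * x
    r = np.exp(eta - eta.max())
    xr = x * r
    x2r = x * xr
    # suffix sums: risk set of subject i = subjects with time >= t_i
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum(xr[::-1])[::-1]
    s2 = np.cumsum(x2r[::-1])[::-1]
    grad = info = 0.0
    i = 0
    n = len(x)
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        ev = np.flatnonzero(events[i:j]) + i
        d = len(ev)
        if d:
            r0, r1, r2 = s0[i], s1[i], s2[i]
            t0, t1, t2 = r[ev].sum(), xr[ev].sum(), x2r[ev].sum()
            for l in range(d):
                f = l / d
                z0 = r0 - f * t0
                z1 = r1 - f * t1
                z2 = r2 - f * t2
                grad -= z1 / z0
                info += z2 / z0 - (z1 / z0) ** 2
            grad += x[ev].sum()
        i = j
    return grad, info


def uni_cox_wald(x: np.ndarray, times: np.ndarray, events: np.ndarray,
                 max_iter: int = 25, tol: float = 1e-8) -> tuple[float, float]:
    """(coefficient, two-sided Wald p) of a univariable Cox fit (Efron)."""
    order = np.argsort(times, kind="stable")
    x = np.asarray(x, float)[order]
    times = np.asarray(times, float)[order]
    events = np.asarray(events, int)[order]
    if events.sum() == 0:
        return 0.0, 1.0
    sd = x.std()
    if sd == 0:
        return 0.0, 1.0
    b = 0.0
    info = 1.0
    for _ in range(max_iter):
        grad, info = _cox_derivs(b, x, times, events)
        if info <= 0:
            return float(b), 1.0
        step = grad / info
        step = float(np.clip(step, -2.0, 2.0))
        b += step
        if abs(step) < tol:
            break
        if abs(b) * sd > 50:
            return float(b), 1.0
    se = 1.0 / np.sqrt(info)
    z = b / se
    return float(b), float(2 * stats.norm.sf(abs(z)))
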