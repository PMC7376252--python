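"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: each oracle takes a different computational path from
the code under test (profiled grid search instead of closed-form harmonic
regression; explicit enumeration of group assignments instead of rank
statistics; direct SSE arithmetic instead of library calls).
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats


def grid_search_cosinor(
    t: np.ndarray,
    y: np.ndarray,
    period: float = 24.0,
    phi_step: float = 0.001,
    refine: bool = True,
) -> tuple[float, float, float]:
    """Brute-force least-squares cosinor: scan acrophase on a fine grid.

    For each candidate acrophase the regressor cos(omega*(t - phi)) is fixed,
    so the optimal (M, A) is a one-variable OLS solved in closed form; the
    scan keeps the acrophase minimizing the SSE (lowest phi wins ties) and
    optionally refines around it.  Negative fitted A is folded to A > 0 by
    a half-period phase shift.
    """

    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    omega = 2.0 * math.pi / period

    def scan(phis: np.ndarray) -> tuple[float, float, float, float]:
        C = np.cos(omega * (t[:, None] - phis[None, :]))  # n x P
        c_mean = C.mean(axis=0)
        y_mean = y.mean()
        sxx = ((C - c_mean) ** 2).sum(axis=0)
        sxy = ((C - c_mean) * (y - y_mean)[:, None]).sum(axis=0)
        amp = np.divide(sxy, sxx, out=np.zeros_like(sxy), where=sxx > 0)
        mesor = y_mean - amp * c_mean
        resid = y[:, None] - (mesor[None, :] + amp[None, :] * C)
        sse = (resid**2).sum(axis=0)
        best = int(np.argmin(sse))  # argmin takes the first (lowest-phi) minimizer
        return float(mesor[best]), float(amp[best]), float(phis[best]), float(sse[best])

    phis = np.arange(0.0, period, phi_step)
    m, a, phi, _ = scan(phis)
    if refine:
        local = np.arange(phi - phi_step, phi + phi_step, phi_step / 100.0)
        m, a, phi, _ = scan(local)
    if a < 0:
        a, phi = -a, phi + period / 2.0
    return m, a, float(np.mod(phi, period))


def f_test_oracle(t: np.ndarray, y: np.ndarray, m: float, a: float, phi: float,
                  period: float = 24.0) -> tuple[float, float]:
    """Zero-amplitude F and p straight from the SSE definitions."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    fitted = m + a * np.cos(2.0 * math.pi * (t - phi) / period)
    sse_full = float(((y - fitted) ** 2).sum())
    sse_mesor = float(((y - y.mean()) ** 2).sum())
    f = ((sse_mesor - sse_full) / 2.0) / (sse_full / (n - 3))
    return f, float(stats.f.sf(f, 2, n - 3))


def mann_whitney_enumeration(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating every group assignment.

    U is computed from midranks of the pooled sample; the null distribution
    is built by assigning each C(n1+n2, n1) subset to the first group.
    Two-sided p doubles the smaller tail (capped at 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(pooled)  # midranks

    def u_of(idx: tuple[int, ...]) -> float:
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(tuple(range(n1)))
    us = np.array([u_of(idx) for idx in combinations(range(n1 + n2), n1)])
    lo = np.mean(us <= u_obs + 1e-12)
    hi = np.mean(us >= u_obs - 1e-12)
    return float(u_obs), float(min(1.0, 2.0 * min(lo, hi)))


def percentile_ci_oracle(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """One-line percentile interval on stored bootstrap draws."""
    lo, hi = np.percentile(draws, [50 * (1 - level), 50 * (1 + level)])
    return float(lo), float(hi)
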