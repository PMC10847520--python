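"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own code paths: the Wilcoxon
oracle enumerates all 2^n sign assignments, and the fit oracle scans an
exhaustive fine parameter grid before local refinement.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def brute_force_wilcoxon(x, y, alternative="two-sided"):
    """Exact signed-rank p-value by enumerating every sign assignment."""
    d = np.asarray(x, float) - np.asarray(y, float)
    nz = d[d != 0.0]
    n = len(nz)
    absd = np.abs(nz)
    order = np.argsort(absd, kind="mergesort")
    sorted_abs = absd[order]
    r = np.arange(1, n + 1, dtype=float)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        r[i : j + 1] = 0.5 * (i + 1 + j + 1)
        i = j + 1
    ranks = np.empty(n)
    ranks[order] = r
    w_plus = ranks[nz > 0].sum()
    all_w = np.array(
        [
            sum(rank for rank, bit in zip(ranks, bits) if bit)
            for bits in itertools.product((0, 1), repeat=n)
        ]
    )
    p_ge = float((all_w >= w_plus - 1e-9).mean())
    p_le = float((all_w <= w_plus + 1e-9).mean())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


def _sse(params, dstar, theta):
    a, b = params
    resid = theta - (np.tanh((dstar + a) / b) - 1.0)
    return float(np.dot(resid, resid))


def grid_oracle_fit(dstar, theta):
    """Global tanh-collapse optimum: 1e-3-step grid scan plus refinement.

    Scans alpha in [-0.5, 0.5] and beta in (0, 2] at step 1e-3 (2 million
    candidates), then polishes the best cell with a bounded local search.
    Returns ((alpha, beta), sse).
    """
    d = np.asarray(dstar, float)
    t = np.asarray(theta, float)
    beta_grid = np.arange(1e-3, 2.0 + 1e-12, 1e-3)
    best_x, best_s = None, np.inf
    for alpha_chunk in np.array_split(np.arange(-0.5, 0.5 + 1e-12, 1e-3), 25):
        A, B = np.meshgrid(alpha_chunk, beta_grid, indexing="ij")
        resid = t[None, None, :] - (np.tanh((d[None, None, :] + A[..., None]) / B[..., None]) - 1.0)
        sse = np.einsum("ijk,ijk->ij", resid, resid)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        if sse[i, j] < best_s:
            best_s = float(sse[i, j])
            best_x = [A[i, j], B[i, j]]
    res = minimize(
        _sse,
        best_x,
        args=(d, t),
        method="Powell",
        bounds=[(-2, 2), (1e-4, 50)],
        options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 10000},
    )
    return (float(res.x[0]), float(res.x[1])), float(res.fun)
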