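"""Statistical comparison of specimen states.

Two tools: an exact Wilcoxon signed-rank test for paired theta data
(small samples, ties handled by mid-ranks, zeros dropped and counted),
and OLS/Pearson concordance between sibling specimens. The exact null
distribution of the signed-rank sum is computed by dynamic programming
over the (doubled, hence integer) ranks, which is equivalent to full
enumeration of all 2^n sign assignments but runs in O(n^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .collapse_fit import compare_curves, fit_hyperbola
from .errors import ValidationError
from .profile_io import ProfileSet

MAX_EXACT_N = 25


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-)
    w_plus: float
    w_minus: float
    p_value: float
    n_effective: int
    n_zero: int
    degenerate: bool = False


def _midranks(absdiff: np.ndarray) -> np.ndarray:
    order = np.argsort(absdiff, kind="mergesort")
    sorted_abs = absdiff[order]
    n = len(absdiff)
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
    return ranks


def _exact_distribution(ranks: np.ndarray) -> np.ndarray:
    """PMF of W+ over doubled-rank support, by subset-sum convolution."""
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = nxt
    return pmf / 2.0 ** len(ranks)


def wilcoxon_signed_rank(x, y, alternative: str = "two-sided") -> WilcoxonResult:
    """Exact Wilcoxon signed-rank test on paired data.

    ``alternative='greater'`` tests for x tending to exceed y. Zero
    differences are dropped (their count is reported); ties among the
    remaining absolute differences receive mid-ranks, and the exact
    p-value is computed from the conditional null distribution given the
    observed rank multiset. Two-sided p doubles the smaller tail, capped
    at 1.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.ndim != 1:
        raise ValidationError("paired inputs must be 1-D and equal length")
    nonzero = d[d != 0.0]
    n_zero = len(d) - len(nonzero)
    n = len(nonzero)
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 0.0, 1.0, 0, n_zero, degenerate=True)
    if n < 3:
        raise ValidationError(f"need >= 3 nonzero differences, got {n}")
    if n > MAX_EXACT_N:
        raise ValidationError(f"exact test limited to n <= {MAX_EXACT_N}")
    ranks = _midranks(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    w_minus = float(ranks[nonzero < 0].sum())
    pmf = _exact_distribution(ranks)
    w2 = int(round(2 * w_plus))
    p_le = float(pmf[: w2 + 1].sum())
    p_ge = float(pmf[w2:].sum())
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonResult(
        statistic=min(w_plus, w_minus),
        w_plus=w_plus,
        w_minus=w_minus,
        p_value=p,
        n_effective=n,
        n_zero=n_zero,
    )


def replicate_concordance(x, y) -> dict:
    """OLS slope/intercept of y on x plus the Pearson correlation."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or len(xa) < 3:
        raise ValidationError("need equal-length 1-D series of length >= 3")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sxx = float(np.dot(xc, xc))
    if sxx == 0.0:
        raise ValidationError("zero variance in x; slope undefined")
    slope = float(np.dot(xc, yc)) / sxx
    intercept = float(ya.mean() - slope * xa.mean())
    syy = float(np.dot(yc, yc))
    r = float(np.dot(xc, yc) / np.sqrt(sxx * syy)) if syy > 0 else float("nan")
    return {"slope": slope, "intercept": intercept, "pearson_r": r}


def pooled_average_theta(profiles) -> np.ndarray:
    """Concatenate the average-theta columns of the given ProfileSets."""
    return np.concatenate([p.average for p in profiles])


def state_comparison_report(profiles_by_state: dict, alpha: float = 0.05) -> dict:
    """Pairwise Wilcoxon + concordance + curve comparison across states.

    ``profiles_by_state`` maps a state name to a sequence of ProfileSets
    (typically the temperature and humidity profiles of one specimen);
    their average-theta columns are pooled for the statistics, while the
    collapse fit/curve comparison uses each quantity's own profile.
    """
    states = list(profiles_by_state)
    if len(states) < 2:
        raise ValidationError("need at least two states to compare")
    pooled = {}
    fits = {}
    for state, profiles in profiles_by_state.items():
        profiles = list(profiles)
        grids = [tuple(np.round(p.distance, 12)) for p in profiles]
        if len(set(grids)) != 1:
            raise ValidationError(f"mismatched slice grids within state {state!r}")
        pooled[state] = pooled_average_theta(profiles)
        fits[state] = {
            p.quantity: fit_hyperbola(p.distance, p.average) for p in profiles
        }
    grid_lens = {len(v) for v in pooled.values()}
    if len(grid_lens) != 1:
        raise ValidationError("mismatched slice grids across states")

    report = {"alpha": alpha, "states": states, "pairwise": {}}
    for i, a in enumerate(states):
        for b in states[i + 1 :]:
            if np.array_equal(pooled[a], pooled[b]):
                wres = WilcoxonResult(0.0, 0.0, 0.0, 1.0, 0, len(pooled[a]), degenerate=True)
            else:
                wres = wilcoxon_signed_rank(pooled[a], pooled[b])
            entry = {
                "wilcoxon": {
                    "statistic": wres.statistic,
                    "p_value": wres.p_value,
                    "n_effective": wres.n_effective,
                    "n_zero": wres.n_zero,
                    "degenerate": wres.degenerate,
                    "significant": bool(wres.p_value < alpha and not wres.degenerate),
                },
                "concordance": replicate_concordance(pooled[a], pooled[b]),
                "curves": {},
            }
            for q in fits[a]:
                if q in fits[b]:
                    entry["curves"][q] = compare_curves(fits[a][q], fits[b][q])
            report["pairwise"][f"{a}_vs_{b}"] = entry
    report["fits"] = {
        state: {
            q: {
                "alpha": f.alpha,
                "beta": f.beta,
                "sse": f.sse,
                "n_points": f.n_points,
                "slope_at_origin": f.slope_at_origin,
            }
            for q, f in qf.items()
        }
        for state, qf in fits.items()
    }
    return report
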