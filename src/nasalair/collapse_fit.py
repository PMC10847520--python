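"""Least-squares collapse of theta(d*) profiles onto a tanh curve.

Standardized profiles are summarized by two operators (alpha, beta) of the
acclimatization curve

    theta(d*) = tanh((d* + alpha) / beta) - 1

which runs from about -1 at the nares (alpha near 0) toward 0 at the
choana. beta controls how quickly the air equilibrates: the slope of the
curve at the inlet, (1/beta) * sech^2(alpha/beta), is the scalar
efficiency descriptor used to compare specimen states.

The optimizer is deterministic and derivative-free: an exhaustive coarse
grid over (alpha, beta) followed by bounded Powell refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .errors import FitConvergenceError, ValidationError

# search domain; beta strictly positive via bound, not transform
ALPHA_BOUNDS = (-2.0, 2.0)
BETA_BOUNDS = (1e-4, 50.0)
_GRID_ALPHA = np.arange(-0.5, 0.5 + 1e-12, 0.01)
_GRID_BETA = np.geomspace(0.02, 2.0, 50)


@dataclass(frozen=True)
class HyperbolicFit:
    """Fitted operators of the acclimatization curve."""

    alpha: float
    beta: float
    sse: float
    n_points: int

    def __post_init__(self):
        if self.beta <= 0:
            raise ValidationError(f"beta must be positive, got {self.beta}")
        if self.sse < 0:
            raise ValidationError("sse cannot be negative")

    @property
    def slope_at_origin(self) -> float:
        """d(theta)/d(d*) at d* = 0: (1/beta) sech^2(alpha/beta)."""
        return (1.0 / self.beta) / np.cosh(self.alpha / self.beta) ** 2

    def __call__(self, dstar):
        return evaluate_hyperbola(self.alpha, self.beta, dstar)


def evaluate_hyperbola(alpha: float, beta: float, dstar):
    """tanh((d* + alpha)/beta) - 1; strictly increasing in d*, range (-2, 0)."""
    if beta <= 0:
        raise ValidationError(f"beta must be positive, got {beta}")
    d = np.asarray(dstar, dtype=float)
    out = np.tanh((d + alpha) / beta) - 1.0
    return float(out) if out.ndim == 0 else out


def _sse(params, dstar, theta):
    a, b = params
    resid = theta - (np.tanh((dstar + a) / b) - 1.0)
    return float(np.dot(resid, resid))


def _grid_minimum(dstar, theta, alpha_grid, beta_grid):
    # vectorized SSE over the full grid; beta ascending so that argmin's
    # first-hit rule breaks exact ties toward the smaller beta
    A, B = np.meshgrid(alpha_grid, beta_grid, indexing="ij")
    resid = theta[None, None, :] - (
        np.tanh((dstar[None, None, :] + A[..., None]) / B[..., None]) - 1.0
    )
    sse = np.einsum("ijk,ijk->ij", resid, resid)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return np.array([A[i, j], B[i, j]]), float(sse[i, j])


def _refine(x0, dstar, theta):
    return optimize.minimize(
        _sse,
        x0,
        args=(dstar, theta),
        method="Powell",
        bounds=[ALPHA_BOUNDS, BETA_BOUNDS],
        options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 10000},
    )


def fit_hyperbola(dstar, theta) -> HyperbolicFit:
    """Fit (alpha, beta) minimizing sum of squared theta residuals.

    Raises :class:`FitConvergenceError` (carrying the best fit so far) when
    the optimum sits on the beta search bound, which happens for profiles
    with no acclimatization signal (e.g. constant theta = -1).
    """
    d = np.asarray(dstar, dtype=float)
    t = np.asarray(theta, dtype=float)
    if d.ndim != 1 or d.shape != t.shape:
        raise ValidationError("dstar and theta must be 1-D arrays of equal length")
    if len(d) < 3:
        raise ValidationError("need at least 3 points to fit the hyperbola")
    if np.any(d < -1e-9) or np.any(d > 1 + 1e-9):
        raise ValidationError("d* must lie in [0, 1]")
    order = np.argsort(d, kind="mergesort")
    d, t = d[order], t[order]

    x0, _ = _grid_minimum(d, t, _GRID_ALPHA, _GRID_BETA)
    res = _refine(x0, d, t)
    alpha, beta = float(res.x[0]), float(res.x[1])
    fit = HyperbolicFit(alpha=alpha, beta=max(beta, BETA_BOUNDS[0]), sse=float(res.fun), n_points=len(d))
    if beta >= 0.98 * BETA_BOUNDS[1] or not res.success:
        raise FitConvergenceError(
            "optimizer hit the beta bound (profile carries no acclimatization "
            "signal) or failed to converge",
            best=fit,
        )
    return fit


def compare_curves(fit_a: HyperbolicFit, fit_b: HyperbolicFit) -> dict:
    """Compare two fitted curves on d* in [0, 1].

    Returns the slope-at-origin difference and ratio, the signed area
    between curve A and curve B (positive when A lies above B), and an
    above/below/coincident verdict from the sign of the mean difference.
    """
    area, _err = integrate.quad(
        lambda x: fit_a(x) - fit_b(x), 0.0, 1.0, epsabs=1e-9, epsrel=1e-9
    )
    slope_a, slope_b = fit_a.slope_at_origin, fit_b.slope_at_origin
    if abs(area) < 1e-9 and abs(slope_a - slope_b) < 1e-9:
        verdict = "coincident"
    else:
        verdict = "above" if area > 0 else "below"
    return {
        "slope_diff": slope_a - slope_b,
        "slope_ratio": slope_a / slope_b,
        "signed_area": area,
        "verdict": verdict,
    }


def efficiency_improvement(fit_pre: HyperbolicFit, fit_post: HyperbolicFit) -> float:
    """Percent change in inlet slope from the pre to the post state."""
    pre, post = fit_pre.slope_at_origin, fit_post.slope_at_origin
    return 100.0 * (post - pre) / pre


def plot_collapse(dstar, theta, fit: HyperbolicFit, ax=None, label: str = ""):
    """Basic points-plus-curve plot of a collapse fit (returns the Axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(0, 1, 200)
    ax.plot(dstar, theta, "o", label=f"{label} data".strip())
    ax.plot(grid, fit(grid), "-", label=f"{label} fit".strip())
    ax.set_xlabel("dimensionless distance d*")
    ax.set_ylabel("dimensionless theta")
    ax.legend()
    return ax
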