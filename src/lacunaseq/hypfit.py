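"""Hyperbola-model fit of a lacunarity curve.

The sampled lacunarity function Lambda(b) of CGR images decays like a
hyperbola toward a large-b asymptote, consistent with the asymptotic
power-law lacunarity of self-similar sets.  We fit the three-parameter
model

    L(b) = beta * b**(-alpha) + gamma

by nonlinear least squares.  alpha (>= 0) is the decay exponent, related to
the fractal dimension of the set; gamma (>= 0) is the asymptote; beta, the
amplitude, characterizes the lacunarity of the set and is the per-subject
biomarker.

Initialization is deterministic so fits are bit-reproducible: gamma0 is the
curve minimum and (log beta0, -alpha0) come from an ordinary linear
regression of log(Lambda - gamma0 + eps) on log b.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .lacunarity import LacunarityCurve

_LOG_EPS = 1e-9  # tolerates points with Lambda == gamma0 in the init regression


@dataclass(frozen=True)
class HyperbolaFit:
    """Fitted (alpha, beta, gamma) triplet with diagnostics."""

    alpha: float
    beta: float
    gamma: float
    residual_norm: float  # sum of squared residuals at the optimum
    converged: bool
    n_points: int
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "n_points": self.n_points,
            "r_squared": self.r_squared,
        }


def hyperbola_model(b, alpha: float, beta: float, gamma: float):
    """Evaluate L(b) = beta * b**(-alpha) + gamma."""
    return beta * np.asarray(b, dtype=float) ** (-alpha) + gamma


def _initial_guess(b: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Deterministic starting point: gamma0 = min Lambda, (log beta0, -alpha0)
    by linear regression of log(Lambda - gamma0 + eps) on log b.

    Points at (or numerically near) the curve minimum are excluded from the
    regression: their log residual is dominated by eps and would drag the
    slope to an arbitrarily steep power law, parking the optimizer in a flat
    local optimum where b**(-alpha) underflows.  alpha0 is capped at 10 for
    the same reason.
    """
    gamma0 = float(lam.min())
    resid = lam - gamma0
    spread = float(resid.max())
    if spread <= 0:  # constant curve: beta = 0, gamma = the constant
        return np.array([1.0, 0.0, gamma0])
    mask = resid > 1e-3 * spread
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(np.log(b[mask]), np.log(resid[mask] + _LOG_EPS), 1)
        alpha0 = min(10.0, max(0.0, -float(slope)))
        beta0 = float(np.exp(intercept))
    else:
        alpha0 = 1.0
        beta0 = spread * float(b[0])
    return np.array([alpha0, beta0, gamma0])


def fit_hyperbola(curve: LacunarityCurve) -> HyperbolaFit:
    """Least-squares fit of the hyperbola model to a lacunarity curve.

    Requires at least 4 points (three parameters plus one).  alpha and gamma
    are bounded below by 0; beta is unconstrained.
    """
    b = np.asarray(curve.b, dtype=float)
    lam = np.asarray(curve.lam, dtype=float)
    if b.size < 4:
        raise ValueError(f"need at least 4 curve points to fit, got {b.size}")
    if not np.all(np.isfinite(lam)):
        raise ValueError("curve contains non-finite lacunarity values")

    def residuals(p):
        return hyperbola_model(b, *p) - lam

    x0 = _initial_guess(b, lam)
    res = least_squares(
        residuals,
        x0,
        bounds=([0.0, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        ftol=1e-10,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=500,
    )
    rss = float(2 * res.cost)
    tss = float(((lam - lam.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    return HyperbolaFit(
        alpha=float(res.x[0]),
        beta=float(res.x[1]),
        gamma=float(res.x[2]),
        residual_norm=rss,
        converged=bool(res.success and np.all(np.isfinite(res.x))),
        n_points=int(b.size),
        r_squared=r2,
    )


def write_fit_json(fit: HyperbolaFit, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)


def read_fit_json(path: str | Path) -> HyperbolaFit:
    with open(path) as fh:
        d = json.load(fh)
    return HyperbolaFit(**d)
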