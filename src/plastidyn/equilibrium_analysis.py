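"""Equilibria of the plasticity model and their analysis.

The untreated model has two equilibria: extinction (the origin, always
unstable, so an untreated tumor always progresses) and a coexistence
equilibrium at which the total abundance equals the carrying capacity and
the phenotype *frequencies* form a geometric profile determined solely by
the transition bias:

    x_i* = K (1 - lambda)^(N-i) (1 + lambda)^(i-1) / sum_j (...)

Notably the equilibrium distribution is independent of the growth-rate
ladder — only the transitions, not the growth dynamics, set the stable
phenotype composition.  This module provides the closed form, distribution
summary statistics (mean phenotype, variance, skewness of the trait
distribution), linear stability via the analytic Jacobian, and the
treatment decision boundary: the bias value at which growth-dependent and
growth-independent treatment exert equal total mortality at equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
import enum

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    ModelParams,
    TreatmentKind,
    effective_intensities,
    growth_rates,
    _transition_prefactors,
)

__all__ = [
    "DistributionSummary",
    "StabilityVerdict",
    "StabilityReport",
    "coexistence_equilibrium",
    "distribution_moments",
    "trait_scores",
    "jacobian",
    "stability_report",
    "decision_boundary",
]

#: verdict band on the leading real part of the Jacobian spectrum
STABILITY_TOL = 1e-9


@dataclass(frozen=True)
class DistributionSummary:
    """Summary statistics of a phenotype abundance vector.

    Moments are taken over the frequency vector ``p_i = x_i / X`` with trait
    scores ``s_i = (i - 1) / (N - 1)`` mapping the E-M axis onto [0, 1]
    (0 = fully epithelial, 1 = fully mesenchymal), so that mean and central
    moments are comparable across compartment counts N.
    """

    total: float
    frequencies: np.ndarray
    mean_trait: float
    variance: float
    third_central_moment: float


class StabilityVerdict(str, enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    MARGINAL = "marginal"


@dataclass(frozen=True)
class StabilityReport:
    equilibrium_point: np.ndarray
    eigenvalues: np.ndarray
    max_real_part: float
    verdict: StabilityVerdict


def _require_default_competition(params: ModelParams, what: str) -> None:
    a = params.competition_matrix
    if a is not None and not np.allclose(a, 1.0):
        raise ValueError(
            f"{what} assumes the shared-carrying-capacity model "
            "(all-ones competition matrix); no closed form is available for "
            "general competition coefficients"
        )


def coexistence_equilibrium(params: ModelParams) -> np.ndarray:
    """Closed-form coexistence equilibrium abundances.

    Requires transition_speed c > 0: without transitions every frequency
    vector on the carrying-capacity simplex is an equilibrium and the
    asymptotic distribution depends on the initial condition, so a single
    closed form does not exist.

    The result sums to K and does not involve the growth rates or treatment
    intensities.
    """
    if params.transition_speed <= 0:
        raise ValueError(
            "coexistence equilibrium requires transition_speed c > 0; at c = 0 "
            "the equilibrium distribution is initial-condition-dependent"
        )
    _require_default_competition(params, "the closed-form equilibrium")
    n = params.n_phenotypes
    lam = params.transition_bias
    i = np.arange(1, n + 1)
    # 0**0 == 1 covers the unidirectional limits lambda = +/-1
    weights = (1.0 - lam) ** (n - i) * (1.0 + lam) ** (i - 1)
    return params.carrying_capacity * weights / weights.sum()


def trait_scores(n: int) -> np.ndarray:
    """Normalized trait axis s_i = (i - 1)/(N - 1); a single 0 for N = 1."""
    if n == 1:
        return np.zeros(1)
    return np.arange(n) / (n - 1)


def distribution_moments(abundances: np.ndarray) -> DistributionSummary:
    """Mean, variance, and third central moment of the trait distribution."""
    x = np.asarray(abundances, dtype=float)
    total = float(x.sum())
    if total <= 0:
        raise ValueError("distribution moments are undefined for zero total abundance")
    p = x / total
    s = trait_scores(x.size)
    mean = float(p @ s)
    d = s - mean
    return DistributionSummary(
        total=total,
        frequencies=p,
        mean_trait=mean,
        variance=float(p @ d**2),
        third_central_moment=float(p @ d**3),
    )


def jacobian(
    params: ModelParams,
    x: np.ndarray,
    treatment: TreatmentKind = TreatmentKind.NONE,
) -> np.ndarray:
    """Analytic Jacobian of the right-hand side at state ``x``.

    Growth contributes ``delta_ij r_i (1 - load_i/K) - r_i x_i a_ij / K``
    with ``load_i = sum_j a_ij x_j``; transitions are linear, so their
    contribution is the constant tridiagonal transition operator; treatment
    mortality contributes ``-(mD_eff r_i + mI_eff)`` on the diagonal.
    """
    x = np.asarray(x, dtype=float)
    n = params.n_phenotypes
    if x.shape != (n,):
        raise ValueError(f"point must have shape ({n},), got {x.shape}")
    r = growth_rates(params)
    K = params.carrying_capacity
    a = params.competition()

    load = a @ x
    J = np.diag(r * (1.0 - load / K)) - (r * x)[:, None] * a / K

    lam = params.transition_bias
    pref = _transition_prefactors(params)
    rate_up = pref * (1.0 + lam)
    rate_down = pref * (1.0 - lam)
    for i in range(n - 1):
        J[i + 1, i] += rate_up[i]
        J[i, i] -= rate_up[i]
    for i in range(1, n):
        J[i - 1, i] += rate_down[i]
        J[i, i] -= rate_down[i]

    mD_eff, mI_eff = effective_intensities(params, treatment)
    J -= np.diag(mD_eff * r + mI_eff)
    return J


def stability_report(
    params: ModelParams, point: np.ndarray, tol: float = STABILITY_TOL
) -> StabilityReport:
    """Linear stability of an equilibrium of the *untreated* system.

    The verdict compares the leading real part of the Jacobian spectrum to a
    tolerance band: stable below -tol, unstable above +tol, marginal inside.
    """
    point = np.asarray(point, dtype=float)
    J = jacobian(params, point, TreatmentKind.NONE)
    eig = np.linalg.eigvals(J)
    max_real = float(eig.real.max())
    if max_real < -tol:
        verdict = StabilityVerdict.STABLE
    elif max_real > tol:
        verdict = StabilityVerdict.UNSTABLE
    else:
        verdict = StabilityVerdict.MARGINAL
    return StabilityReport(
        equilibrium_point=point,
        eigenvalues=eig,
        max_real_part=max_real,
        verdict=verdict,
    )


def decision_boundary(
    params: ModelParams, grid_points: int = 1001, ftol: float = 1e-12
):
    """Transition bias at which both treatment types kill equally fast.

    Solves f(lambda) = sum_i (mD r_i - mI) x_i*(lambda) = 0 on [-1, 1].
    Below the root, growth-dependent treatment exerts the higher total
    mortality on the equilibrium distribution (the tumor is epithelial
    enough that targeting proliferation wins); above it, growth-independent
    treatment wins.  Returns ``None`` when one treatment dominates for every
    bias.  f is a low-degree polynomial in lambda with (for the reference
    growth ladder) a monotone weighted-mean structure, so sign-change
    bracketing on a fine grid plus Brent polishing is robust.
    """
    if params.mI is None:
        raise ValueError("decision boundary needs mI; calibrate or set it first")
    if params.mD <= 0 and params.mI <= 0:
        raise ValueError("decision boundary needs at least one positive intensity")
    if params.transition_speed <= 0:
        raise ValueError("decision boundary requires transition_speed c > 0")

    r = growth_rates(params)
    mD, mI = params.mD, params.mI

    def f(lam: float) -> float:
        xs = coexistence_equilibrium(params.replace(transition_bias=lam))
        return float(((mD * r - mI) * xs).sum())

    grid = np.linspace(-1.0, 1.0, grid_points)
    values = np.array([f(g) for g in grid])

    roots: list[float] = []
    for k in range(grid_points - 1):
        a, b = values[k], values[k + 1]
        if a == 0.0:
            roots.append(float(grid[k]))
        elif a * b < 0:
            roots.append(float(brentq(f, grid[k], grid[k + 1], xtol=ftol)))
    if values[-1] == 0.0:
        roots.append(float(grid[-1]))
    # collapse duplicates from a root sitting on a grid point
    deduped: list[float] = []
    for root in roots:
        if not deduped or abs(root - deduped[-1]) > 1e-9:
            deduped.append(root)

    if not deduped:
        return None
    if len(deduped) > 1:
        raise ValueError(
            f"multiple mortality-balance roots found on [-1, 1]: {deduped}"
        )
    return deduped[0]
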