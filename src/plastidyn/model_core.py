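"""Core population model of epithelial-mesenchymal phenotypic plasticity.

The tumor cell population is discretized into ``N`` phenotype compartments
along the epithelial-mesenchymal axis.  Compartment 1 is the most epithelial
(fast-growing, non-motile) and compartment ``N`` the most mesenchymal
(slow-growing, invasive); compartments in between are hybrid phenotypes.
All compartments compete for a shared carrying capacity ``K`` (competitive
logistic growth), and cells switch between *adjacent* compartments:
mesenchymal-ward at rate ``T_EM = c (1 + lambda) r1`` and epithelial-ward at
rate ``T_ME = c (1 - lambda) r1``, where ``c`` scales transition speed
relative to the epithelial growth rate and ``lambda`` in [-1, 1] biases the
direction.  Two treatment types act as extra mortality: growth-dependent
(chemotherapy-like, death rate ``mD * r_i``) and growth-independent
(immunotherapy-like, death rate ``mI``).

This module defines the parameter and state containers, the growth-rate
ladder, the transition rates, and the ODE right-hand side; integration lives
in :mod:`plastidyn.dynamics_engine`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "TreatmentKind",
    "TransitionScaling",
    "ModelParams",
    "PhenotypeState",
    "growth_rates",
    "transition_rates",
    "effective_intensities",
    "rhs",
]


class TreatmentKind(str, enum.Enum):
    """Treatment type active at an instant (or assigned to a schedule block).

    ``ADAPTIVE`` is only meaningful as a *block* annotation: it is resolved
    to one of the concrete kinds at block start and never reaches the ODE
    right-hand side.
    """

    NONE = "none"
    GROWTH_DEPENDENT = "growth_dependent"
    GROWTH_INDEPENDENT = "growth_independent"
    ADAPTIVE = "adaptive"


class TransitionScaling(str, enum.Enum):
    """Which growth rate scales the transition propensity.

    ``EPITHELIAL_RATE`` (default): every compartment transitions with
    prefactor ``c * r1``, the standard phenotype-independent assumption.
    ``OWN_RATE``: a variant hook where the outflux of compartment ``i`` is
    scaled by its own growth rate ``r_i`` instead of ``r1``, modelling
    transition machinery coupled to the proliferation rate.
    """

    EPITHELIAL_RATE = "epithelial_rate"
    OWN_RATE = "own_rate"


@dataclass(frozen=True, eq=False)
class ModelParams:
    """Reference parameters of the plasticity model.

    Defaults are the reference configuration: three phenotypes (E, H, M),
    epithelial growth rate 1 (all times are r1-scaled), mesenchymal growth
    rate 1/5, unit carrying capacity, unbiased transitions at speed c = 1,
    growth-dependent intensity 1.  ``mI`` has no universal default: it is
    obtained by calibration (see
    :func:`plastidyn.treatment_schemes.calibrate_mI`) and is ``None`` until
    set.

    ``competition_matrix`` is a variant hook: entry ``(i, j)`` weights the
    competitive load of phenotype j on phenotype i.  ``None`` means all-ones,
    i.e. the shared-carrying-capacity model.
    """

    n_phenotypes: int = 3
    r1: float = 1.0
    rN: float = 0.2
    carrying_capacity: float = 1.0
    transition_speed: float = 1.0
    transition_bias: float = 0.0
    mD: float = 1.0
    mI: Optional[float] = None
    competition_matrix: Optional[np.ndarray] = None
    transition_scaling: TransitionScaling = TransitionScaling.EPITHELIAL_RATE

    def __post_init__(self) -> None:
        if int(self.n_phenotypes) != self.n_phenotypes or self.n_phenotypes < 1:
            raise ValueError(f"n_phenotypes must be an integer >= 1, got {self.n_phenotypes}")
        if self.r1 <= 0 or self.rN <= 0:
            raise ValueError("growth rates r1 and rN must be positive")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")
        if self.transition_speed < 0:
            raise ValueError("transition_speed must be >= 0")
        if not -1.0 <= self.transition_bias <= 1.0:
            raise ValueError(
                f"transition_bias must lie in [-1, 1], got {self.transition_bias}"
            )
        if self.mD < 0:
            raise ValueError("mD must be >= 0")
        if self.mI is not None and self.mI < 0:
            raise ValueError("mI must be >= 0")
        if self.competition_matrix is not None:
            a = np.asarray(self.competition_matrix, dtype=float)
            n = self.n_phenotypes
            if a.shape != (n, n):
                raise ValueError(
                    f"competition_matrix must be {n}x{n}, got shape {a.shape}"
                )
            if np.any(a < 0):
                raise ValueError("competition_matrix entries must be >= 0")
            object.__setattr__(self, "competition_matrix", a)
        if not isinstance(self.transition_scaling, TransitionScaling):
            object.__setattr__(
                self, "transition_scaling", TransitionScaling(self.transition_scaling)
            )

    # dataclasses.replace works on frozen dataclasses; expose it for fluency
    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    @property
    def N(self) -> int:
        return self.n_phenotypes

    def competition(self) -> np.ndarray:
        """Effective competition matrix (all-ones unless the hook is set)."""
        if self.competition_matrix is None:
            n = self.n_phenotypes
            return np.ones((n, n))
        return self.competition_matrix


@dataclass(frozen=True)
class PhenotypeState:
    """Abundance vector at a time point.

    ``abundances[0]`` is the most epithelial compartment (phenotype 1 in
    1-based reporting), ``abundances[-1]`` the most mesenchymal.
    """

    time: float
    abundances: np.ndarray = field()

    def __post_init__(self) -> None:
        x = np.asarray(self.abundances, dtype=float)
        if x.ndim != 1:
            raise ValueError("abundances must be a 1-D vector")
        if np.any(x < 0):
            raise ValueError("abundances must be nonnegative")
        object.__setattr__(self, "abundances", x)

    @property
    def total(self) -> float:
        return float(self.abundances.sum())


def growth_rates(params: ModelParams) -> np.ndarray:
    """Linearly decreasing growth-rate ladder from epithelial to mesenchymal.

    r_i = r1 - (r1 - rN) * (i - 1) / (N - 1) for i = 1..N; for N = 1 the
    single compartment grows at r1.
    """
    n = params.n_phenotypes
    if n == 1:
        return np.array([params.r1])
    i = np.arange(n)
    return params.r1 - (params.r1 - params.rN) * i / (n - 1)


def transition_rates(params: ModelParams) -> tuple[float, float]:
    """Mesenchymal-ward and epithelial-ward transition rates.

    Returns (T_EM, T_ME) = (c (1 + lambda) r1, c (1 - lambda) r1).
    """
    c, lam, r1 = params.transition_speed, params.transition_bias, params.r1
    return c * (1.0 + lam) * r1, c * (1.0 - lam) * r1


def effective_intensities(
    params: ModelParams, kind: TreatmentKind
) -> tuple[float, float]:
    """Map a treatment kind to effective (mD, mI) intensities.

    Exactly one kind is active at any instant: no treatment gives (0, 0),
    growth-dependent (mD, 0), growth-independent (0, mI).
    """
    kind = TreatmentKind(kind)
    if kind is TreatmentKind.NONE:
        return 0.0, 0.0
    if kind is TreatmentKind.GROWTH_DEPENDENT:
        return params.mD, 0.0
    if kind is TreatmentKind.GROWTH_INDEPENDENT:
        if params.mI is None:
            raise ValueError(
                "mI is unset; calibrate it first (treatment_schemes.calibrate_mI) "
                "or set ModelParams.mI explicitly"
            )
        return 0.0, params.mI
    raise ValueError(
        "adaptive is a schedule-block annotation, not an instantaneous treatment kind"
    )


def _transition_prefactors(params: ModelParams) -> np.ndarray:
    """Per-source-compartment transition prefactor c * r (length N)."""
    c = params.transition_speed
    if params.transition_scaling is TransitionScaling.OWN_RATE:
        return c * growth_rates(params)
    return np.full(params.n_phenotypes, c * params.r1)


def rhs(
    x: np.ndarray,
    params: ModelParams,
    treatment: TreatmentKind = TreatmentKind.NONE,
) -> np.ndarray:
    """Time derivative of the abundance vector.

    Three contributions per compartment: competitive logistic growth
    ``r_i x_i (1 - X_i / K)`` where ``X_i`` is the competitive load
    (the plain total abundance under the default all-ones competition
    matrix), nearest-neighbour transitions written as explicit fluxes so the
    terms telescope to zero exactly, and treatment mortality
    ``-(mD_eff r_i + mI_eff) x_i``.
    """
    x = np.asarray(x, dtype=float)
    n = params.n_phenotypes
    if x.shape != (n,):
        raise ValueError(f"state vector must have shape ({n},), got {x.shape}")

    r = growth_rates(params)
    lam = params.transition_bias
    pref = _transition_prefactors(params)
    rate_up = pref * (1.0 + lam)   # i -> i+1 (mesenchymal-ward)
    rate_down = pref * (1.0 - lam)  # i -> i-1 (epithelial-ward)

    # flux formulation: conservation across compartments is exact
    flux_up = rate_up[:-1] * x[:-1]
    flux_down = rate_down[1:] * x[1:]
    trans = np.zeros(n)
    trans[1:] += flux_up
    trans[:-1] -= flux_up
    trans[:-1] += flux_down
    trans[1:] -= flux_down

    load = params.competition() @ x
    growth = r * x * (1.0 - load / params.carrying_capacity)

    mD_eff, mI_eff = effective_intensities(params, treatment)
    mortality = (mD_eff * r + mI_eff) * x

    return growth + trans - mortality
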