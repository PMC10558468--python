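"""Treatment types, schedules, and the growth-independent intensity calibration.

Two treatment types are modelled.  Growth-dependent treatment
(chemotherapy-like) kills phenotype i at rate ``mD * r_i``, so it hits the
fast-growing epithelial compartments hardest.  Growth-independent treatment
(immunotherapy-like) kills every phenotype at the same rate ``mI``.  To make
the two comparable, ``mI`` is calibrated so that a single block of either
type, applied for the standard duration starting from the coexistence
equilibrium at (c = 1, lambda = 0), leaves the same total abundance.

Schedules tile a fixed treatment duration (default 10 time units) with
equal-length contiguous blocks: a single block of one type, alternating
fixed sequences, or adaptive blocks whose type is chosen at block start by
comparing the instantaneous mortality the two types would exert on the
current phenotype distribution.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import ModelParams, TreatmentKind, growth_rates

__all__ = [
    "DEFAULT_DURATION",
    "Scheme",
    "TreatmentBlock",
    "TreatmentSchedule",
    "build_schedule",
    "instantaneous_mortality",
    "adaptive_choice",
    "calibrate_mI",
]

#: standard treatment duration in model time units (r1-scaled)
DEFAULT_DURATION = 10.0


class Scheme(str, enum.Enum):
    """Named treatment schemes; the values double as CLI spellings."""

    SINGLE_GD = "single_GD"
    SINGLE_GI = "single_GI"
    ALTERNATING_GD_FIRST = "alternating_GD_first"
    ALTERNATING_GI_FIRST = "alternating_GI_first"
    ADAPTIVE = "adaptive"


@dataclass(frozen=True)
class TreatmentBlock:
    start: float
    end: float
    kind: TreatmentKind

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"block must have start < end, got [{self.start}, {self.end}]")
        object.__setattr__(self, "kind", TreatmentKind(self.kind))


@dataclass(frozen=True)
class TreatmentSchedule:
    """Ordered, contiguous blocks tiling [0, duration]."""

    blocks: tuple[TreatmentBlock, ...]
    duration: float

    def __post_init__(self) -> None:
        blocks = tuple(self.blocks)
        object.__setattr__(self, "blocks", blocks)
        if not blocks:
            raise ValueError("schedule needs at least one block")
        if abs(blocks[0].start) > 1e-12:
            raise ValueError("first block must start at t = 0")
        for a, b in zip(blocks, blocks[1:]):
            if abs(a.end - b.start) > 1e-12:
                raise ValueError(
                    f"blocks must be contiguous; gap/overlap between {a.end} and {b.start}"
                )
        if abs(blocks[-1].end - self.duration) > 1e-12:
            raise ValueError("blocks must tile [0, duration] exactly")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def is_adaptive(self) -> bool:
        return any(b.kind is TreatmentKind.ADAPTIVE for b in self.blocks)


def build_schedule(
    scheme: Scheme | str, n_blocks: int = 1, duration: float = DEFAULT_DURATION
) -> TreatmentSchedule:
    """Construct the standard schedules: n_blocks equal-length blocks.

    Fixed alternating schemes pre-assign kinds; the adaptive scheme marks
    every block adaptive, to be resolved against the state at block start
    during simulation.
    """
    scheme = Scheme(scheme)
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if scheme in (Scheme.SINGLE_GD, Scheme.SINGLE_GI) and n_blocks != 1:
        raise ValueError(f"{scheme.value} is a one-block scheme; got n_blocks={n_blocks}")

    edges = np.linspace(0.0, duration, n_blocks + 1)
    if scheme is Scheme.SINGLE_GD:
        kinds = [TreatmentKind.GROWTH_DEPENDENT]
    elif scheme is Scheme.SINGLE_GI:
        kinds = [TreatmentKind.GROWTH_INDEPENDENT]
    elif scheme is Scheme.ADAPTIVE:
        kinds = [TreatmentKind.ADAPTIVE] * n_blocks
    else:
        first, second = (
            (TreatmentKind.GROWTH_DEPENDENT, TreatmentKind.GROWTH_INDEPENDENT)
            if scheme is Scheme.ALTERNATING_GD_FIRST
            else (TreatmentKind.GROWTH_INDEPENDENT, TreatmentKind.GROWTH_DEPENDENT)
        )
        kinds = [first if k % 2 == 0 else second for k in range(n_blocks)]

    blocks = tuple(
        TreatmentBlock(float(edges[k]), float(edges[k + 1]), kinds[k])
        for k in range(n_blocks)
    )
    return TreatmentSchedule(blocks=blocks, duration=duration)


def instantaneous_mortality(
    x: np.ndarray, params: ModelParams, kind: TreatmentKind | str
) -> float:
    """Total death flux the given treatment type exerts on state ``x``.

    sum_i mD r_i x_i for growth-dependent, sum_i mI x_i for
    growth-independent, 0 for no treatment.
    """
    x = np.asarray(x, dtype=float)
    kind = TreatmentKind(kind)
    if kind is TreatmentKind.NONE:
        return 0.0
    if kind is TreatmentKind.GROWTH_DEPENDENT:
        return float(params.mD * (growth_rates(params) @ x))
    if kind is TreatmentKind.GROWTH_INDEPENDENT:
        if params.mI is None:
            raise ValueError("mI is unset; calibrate or set it first")
        return float(params.mI * x.sum())
    raise ValueError("instantaneous mortality is undefined for the adaptive marker")


def adaptive_choice(x: np.ndarray, params: ModelParams) -> TreatmentKind:
    """Pick the treatment type with the higher instantaneous mortality.

    Exact ties go to growth-dependent treatment: the tie is a measure-zero
    event and a deterministic rule keeps runs reproducible.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x > 0):
        raise ValueError("adaptive choice is undefined for an extinct tumor")
    gd = instantaneous_mortality(x, params, TreatmentKind.GROWTH_DEPENDENT)
    gi = instantaneous_mortality(x, params, TreatmentKind.GROWTH_INDEPENDENT)
    return TreatmentKind.GROWTH_INDEPENDENT if gi > gd else TreatmentKind.GROWTH_DEPENDENT


def calibrate_mI(
    params: ModelParams,
    duration: float = DEFAULT_DURATION,
    tol: float = 1e-10,
) -> float:
    """Growth-independent intensity matching the growth-dependent endpoint.

    Both single-block runs start from the coexistence equilibrium of the
    calibration configuration (c = 1, lambda = 0, mD as given) and run for
    ``duration``; mI is the root of the monotone gap
    ``X_GI(duration; mI) - X_GD(duration)`` found by bracketing + Brent.
    With the reference parameters this lands near 0.64.
    """
    from .dynamics_engine import simulate  # deferred: avoids an import cycle

    if duration <= 0:
        raise ValueError("duration must be positive")
    if params.mD == 0:
        return 0.0

    base = params.replace(transition_speed=1.0, transition_bias=0.0, mI=None)
    x0 = _calibration_equilibrium(base)

    gd_schedule = build_schedule(Scheme.SINGLE_GD, 1, duration)
    target = simulate(base, x0, gd_schedule, horizon=duration).final_total

    def gap(mi: float) -> float:
        trial = base.replace(mI=float(mi))
        schedule = build_schedule(Scheme.SINGLE_GI, 1, duration)
        return simulate(trial, x0, schedule, horizon=duration).final_total - target

    hi = params.mD * params.r1 * 10.0
    g0 = gap(0.0)
    if g0 <= 0:
        raise RuntimeError(
            "calibration bracket invalid: untreated endpoint does not exceed "
            "the growth-dependent endpoint"
        )
    if gap(hi) >= 0:
        raise RuntimeError(
            f"calibration failed: no sign change of the endpoint gap on [0, {hi}]"
        )
    return float(brentq(gap, 0.0, hi, xtol=tol))


def _calibration_equilibrium(base: ModelParams) -> np.ndarray:
    from .equilibrium_analysis import coexistence_equilibrium

    return coexistence_equilibrium(base)
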