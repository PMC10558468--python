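"""Scenario fixtures and computational experiments.

Covers the study's standard in-silico scenarios: primary-site seeding (a
small purely epithelial founder population), secondary-site seeding (a
small purely mesenchymal founder, reflecting selection for invasiveness
during dissemination), phenotype-ablation perturbations of the coexistence
equilibrium, burden-reduction sweeps over the transition bias/speed plane
for each treatment scheme, and adjuvant-therapy comparisons in which a
transition-modulating drug shifts lambda and/or c before and during
treatment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics_engine import SolverOptions, burden_reduction, simulate
from .equilibrium_analysis import coexistence_equilibrium
from .model_core import ModelParams, TreatmentKind
from .treatment_schemes import DEFAULT_DURATION, Scheme, build_schedule

__all__ = [
    "ScenarioKind",
    "SweepResult",
    "AdjuvantComparison",
    "scenario_initial_condition",
    "sweep_burden_reduction",
    "adjuvant_shift",
    "default_lambda_grid",
    "default_c_grid",
]

#: founder fraction of carrying capacity for site-seeding scenarios
FOUNDER_FRACTION = 0.1


class ScenarioKind(str, enum.Enum):
    PRIMARY_SITE = "primary_site"
    SECONDARY_SITE = "secondary_site"
    ABLATE_E = "ablate_E"
    ABLATE_H = "ablate_H"
    ABLATE_M = "ablate_M"
    EQUILIBRIUM = "equilibrium"


def default_lambda_grid(n: int = 41) -> np.ndarray:
    return np.linspace(-1.0, 1.0, n)


def default_c_grid(n: int = 25) -> np.ndarray:
    """Log-spaced transition speeds spanning the slow (c<1) and fast (c>1) regimes."""
    return np.logspace(-2, 2, n)


def scenario_initial_condition(
    kind: ScenarioKind | str,
    params: ModelParams,
    ablate_index: Optional[int] = None,
) -> np.ndarray:
    """Initial abundance vector for a named scenario.

    ``primary_site``: K/10 of purely epithelial cells — an early tumor at
    its site of origin.  ``secondary_site``: K/10 of purely mesenchymal
    cells — a freshly seeded metastasis.  ``ablate_*``: the coexistence
    equilibrium with one compartment removed, modelling a hypothetical
    phenotype-specific intervention (``ablate_H`` requires N = 3 unless a
    1-based ``ablate_index`` is given).  ``equilibrium``: the closed-form
    coexistence state.
    """
    kind = ScenarioKind(kind)
    n = params.n_phenotypes
    K = params.carrying_capacity
    if kind is ScenarioKind.PRIMARY_SITE:
        x0 = np.zeros(n)
        x0[0] = FOUNDER_FRACTION * K
        return x0
    if kind is ScenarioKind.SECONDARY_SITE:
        x0 = np.zeros(n)
        x0[-1] = FOUNDER_FRACTION * K
        return x0
    if kind is ScenarioKind.EQUILIBRIUM:
        return coexistence_equilibrium(params)

    if ablate_index is None:
        if kind is ScenarioKind.ABLATE_E:
            ablate_index = 1
        elif kind is ScenarioKind.ABLATE_M:
            ablate_index = n
        else:  # ABLATE_H
            if n != 3:
                raise ValueError(
                    "ablate_H needs an explicit 1-based ablate_index when N != 3"
                )
            ablate_index = 2
    if not 1 <= ablate_index <= n:
        raise ValueError(f"ablate_index {ablate_index} out of range 1..{n}")
    x0 = coexistence_equilibrium(params)
    x0[ablate_index - 1] = 0.0
    return x0


@dataclass(frozen=True)
class SweepResult:
    """Burden reductions on a (lambda, c) grid for one scheme.

    ``reduction[i, j]`` is the end-of-treatment reduction (K - X)/K at
    ``c_grid[i]``, ``lambda_grid[j]``.  For adaptive schemes,
    ``resolved_sequences[i][j]`` records the treatment kinds actually chosen
    per block.
    """

    lambda_grid: np.ndarray
    c_grid: np.ndarray
    scheme: Scheme
    n_blocks: int
    reduction: np.ndarray
    resolved_sequences: Optional[tuple[tuple[tuple[TreatmentKind, ...], ...], ...]] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.c_grid):
            for j, lam in enumerate(self.lambda_grid):
                seq = ""
                if self.resolved_sequences is not None:
                    seq = "+".join(k.value for k in self.resolved_sequences[i][j])
                rows.append(
                    {
                        "lambda": lam,
                        "c": c,
                        "scheme": self.scheme.value,
                        "n_blocks": self.n_blocks,
                        "reduction": self.reduction[i, j],
                        "sequence": seq,
                    }
                )
        return pd.DataFrame(rows)


def sweep_burden_reduction(
    scheme: Scheme | str,
    n_blocks: int,
    lambda_grid: np.ndarray,
    c_grid: np.ndarray,
    params: ModelParams,
    duration: float = DEFAULT_DURATION,
    solver_opts: Optional[SolverOptions] = None,
) -> SweepResult:
    """End-of-treatment burden reduction over a (lambda, c) grid.

    Every cell starts from the coexistence equilibrium at its own (lambda,
    c) — the tumor is assumed to have settled to its stable phenotype
    distribution before treatment begins — then applies the scheme's
    schedule for ``duration`` and records (K - X(duration))/K.
    """
    scheme = Scheme(scheme)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    c_grid = np.asarray(c_grid, dtype=float)
    schedule = build_schedule(scheme, n_blocks, duration)

    reduction = np.empty((c_grid.size, lambda_grid.size))
    sequences: list[list[tuple[TreatmentKind, ...]]] = []
    for i, c in enumerate(c_grid):
        seq_row: list[tuple[TreatmentKind, ...]] = []
        for j, lam in enumerate(lambda_grid):
            cell = params.replace(transition_speed=float(c), transition_bias=float(lam))
            x0 = coexistence_equilibrium(cell)
            try:
                traj = simulate(cell, x0, schedule, horizon=duration, solver_opts=solver_opts)
            except Exception as exc:  # annotate with grid coordinates
                raise RuntimeError(
                    f"sweep cell failed at lambda={lam}, c={c}: {exc}"
                ) from exc
            reduction[i, j] = burden_reduction(traj, cell, duration)
            seq_row.append(tuple(b.kind for b in traj.schedule_applied.blocks))
        sequences.append(seq_row)

    resolved = None
    if scheme is Scheme.ADAPTIVE:
        resolved = tuple(tuple(row) for row in sequences)
    return SweepResult(
        lambda_grid=lambda_grid,
        c_grid=c_grid,
        scheme=scheme,
        n_blocks=n_blocks,
        reduction=reduction,
        resolved_sequences=resolved,
    )


@dataclass(frozen=True)
class AdjuvantComparison:
    baseline_reduction: float
    shifted_reduction: float
    difference: float


def adjuvant_shift(
    params: ModelParams,
    delta_lambda: float,
    delta_c: float,
    scheme: Scheme | str,
    n_blocks: int = 1,
    duration: float = DEFAULT_DURATION,
    solver_opts: Optional[SolverOptions] = None,
) -> AdjuvantComparison:
    """Effect of a transition-modulating adjuvant on burden reduction.

    The adjuvant is modelled as a persistent parameter shift (lambda + dl,
    c + dc) applied before and during treatment, so the shifted run starts
    from the coexistence equilibrium of the *shifted* parameters.  Positive
    ``difference`` means the adjuvant improved the outcome.
    """
    scheme = Scheme(scheme)
    new_lambda = params.transition_bias + delta_lambda
    new_c = params.transition_speed + delta_c
    if not -1.0 <= new_lambda <= 1.0:
        raise ValueError(f"shifted transition bias {new_lambda} outside [-1, 1]")
    if new_c <= 0:
        raise ValueError(f"shifted transition speed {new_c} must be positive")

    schedule = build_schedule(scheme, n_blocks, duration)

    def run(p: ModelParams) -> float:
        x0 = coexistence_equilibrium(p)
        traj = simulate(p, x0, schedule, horizon=duration, solver_opts=solver_opts)
        return burden_reduction(traj, p, duration)

    baseline = run(params)
    shifted = run(params.replace(transition_bias=new_lambda, transition_speed=new_c))
    return AdjuvantComparison(
        baseline_reduction=baseline,
        shifted_reduction=shifted,
        difference=shifted - baseline,
    )
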