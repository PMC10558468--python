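"""Numerical integration of the plasticity model over treatment schedules.

Integration uses :func:`scipy.integrate.solve_ivp` with a stiff-capable
adaptive-step method and tight tolerances (the system is small and smooth,
so accuracy is cheap).  A schedule is integrated piecewise: the solver is
restarted at every block boundary so that the discontinuous switch in
treatment intensity is resolved exactly, and adaptive blocks pick their
treatment type from the state at block start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .equilibrium_analysis import distribution_moments
from .model_core import ModelParams, TreatmentKind, rhs
from .treatment_schemes import (
    TreatmentBlock,
    TreatmentSchedule,
    adaptive_choice,
)

__all__ = ["SolverOptions", "Trajectory", "simulate", "equilibrate", "burden_reduction"]

logger = logging.getLogger(__name__)

#: floor of the round-off guard band; the effective band scales with the
#: solver's absolute tolerance (negatives within it are clamped to 0,
#: anything more negative is treated as a solver failure)
NEGATIVE_CLAMP = 1e-12


def _clamp_band(opts: "SolverOptions") -> float:
    return max(NEGATIVE_CLAMP, 100.0 * opts.atol)


@dataclass(frozen=True)
class SolverOptions:
    """Integration settings.

    ``dt_out`` is the output sampling interval; it does not constrain the
    internal adaptive step.  LSODA switches between Adams and BDF so both
    the transition-dominated (c >> 1) and growth-dominated regimes are
    handled without tuning.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    dt_out: float = 0.1


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered states with per-time treatment annotation.

    ``states`` is (n_times, N); ``kinds`` holds the treatment kind active at
    each output time (block kind on [start, end), ``none`` after the
    schedule).  ``schedule_applied`` is the schedule actually executed, with
    adaptive blocks resolved to concrete kinds.
    """

    times: np.ndarray
    states: np.ndarray
    kinds: tuple[TreatmentKind, ...]
    schedule_applied: Optional[TreatmentSchedule]
    params: ModelParams = field(repr=False)

    @property
    def totals(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    @property
    def final_total(self) -> float:
        return float(self.states[-1].sum())

    def state_at(self, t: float) -> np.ndarray:
        """Componentwise linear interpolation at time ``t``."""
        t0, t1 = self.times[0], self.times[-1]
        if not t0 <= t <= t1:
            raise ValueError(f"time {t} outside trajectory range [{t0}, {t1}]")
        return np.array(
            [np.interp(t, self.times, self.states[:, j]) for j in range(self.states.shape[1])]
        )

    def total_at(self, t: float) -> float:
        return float(self.state_at(t).sum())

    def to_frame(self) -> pd.DataFrame:
        """Long export: time, x_1..x_N, X, trait moments, active treatment.

        Moment columns are NaN where the population is extinct.
        """
        n = self.states.shape[1]
        data = {"time": self.times}
        for j in range(n):
            data[f"x_{j + 1}"] = self.states[:, j]
        data["X"] = self.totals
        mean = np.full(len(self.times), np.nan)
        var = np.full(len(self.times), np.nan)
        m3 = np.full(len(self.times), np.nan)
        for k, x in enumerate(self.states):
            if x.sum() > 0:
                s = distribution_moments(x)
                mean[k], var[k], m3[k] = s.mean_trait, s.variance, s.third_central_moment
        data["mean_trait"] = mean
        data["variance"] = var
        data["third_central_moment"] = m3
        data["active_treatment"] = [k.value for k in self.kinds]
        return pd.DataFrame(data)


def _clamp_negatives(x: np.ndarray, t: float, band: float = NEGATIVE_CLAMP) -> np.ndarray:
    low = x.min()
    if low < -band:
        raise RuntimeError(
            f"state went negative beyond round-off at t={t}: min component {low}"
        )
    if low < 0:
        logger.debug("clamping round-off negative %.3e at t=%.6g", low, t)
        x = np.clip(x, 0.0, None)
    return x


def _segment_times(start: float, end: float, dt_out: float) -> np.ndarray:
    n = max(int(round((end - start) / dt_out)), 1)
    return np.linspace(start, end, n + 1)


def _integrate_segment(
    params: ModelParams,
    x0: np.ndarray,
    kind: TreatmentKind,
    t_span: tuple[float, float],
    opts: SolverOptions,
) -> tuple[np.ndarray, np.ndarray]:
    t_eval = _segment_times(t_span[0], t_span[1], opts.dt_out)
    sol = solve_ivp(
        lambda t, y: rhs(y, params, kind),
        t_span,
        x0,
        method=opts.method,
        rtol=opts.rtol,
        atol=opts.atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed on [{t_span[0]}, {t_span[1]}] ({kind.value}): "
            f"{sol.message}; last state {sol.y[:, -1] if sol.y.size else x0}"
        )
    return sol.t, sol.y.T


def simulate(
    params: ModelParams,
    x0: np.ndarray,
    schedule: Optional[TreatmentSchedule] = None,
    horizon: float = 100.0,
    solver_opts: Optional[SolverOptions] = None,
) -> Trajectory:
    """Integrate the model from ``x0`` over ``[0, horizon]``.

    The schedule's blocks are applied in order; after the treatment duration
    the system runs untreated until ``horizon``.  ``schedule=None`` means an
    entirely untreated run.
    """
    opts = solver_opts or SolverOptions()
    x0 = np.asarray(x0, dtype=float)
    n = params.n_phenotypes
    if x0.shape != (n,):
        raise ValueError(f"x0 must have shape ({n},), got {x0.shape}")
    if np.any(x0 < 0):
        raise ValueError("x0 must be nonnegative")
    if schedule is not None and horizon < schedule.duration - 1e-12:
        raise ValueError("horizon must cover the schedule duration")

    # assemble the piecewise-constant treatment segments
    segments: list[TreatmentBlock] = []
    if schedule is not None:
        segments.extend(schedule.blocks)
        tail_start = schedule.duration
    else:
        tail_start = 0.0
    if horizon > tail_start + 1e-12:
        segments.append(TreatmentBlock(tail_start, horizon, TreatmentKind.NONE))
    if not segments:
        raise ValueError("nothing to integrate: horizon is 0 and no schedule given")

    times_parts: list[np.ndarray] = []
    states_parts: list[np.ndarray] = []
    kinds: list[TreatmentKind] = []
    resolved: list[TreatmentBlock] = []
    x = x0
    for seg in segments:
        kind = seg.kind
        if kind is TreatmentKind.ADAPTIVE:
            kind = adaptive_choice(x, params)
        t_seg, y_seg = _integrate_segment(params, x, kind, (seg.start, seg.end), opts)
        band = _clamp_band(opts)
        y_seg = np.vstack([_clamp_negatives(row, t, band) for t, row in zip(t_seg, y_seg)])
        x = y_seg[-1]
        if times_parts:  # drop the duplicated boundary point
            t_seg, y_seg = t_seg[1:], y_seg[1:]
        times_parts.append(t_seg)
        states_parts.append(y_seg)
        kinds.extend([kind] * len(t_seg))
        resolved.append(TreatmentBlock(seg.start, seg.end, kind))

    applied = None
    if schedule is not None:
        applied = TreatmentSchedule(
            blocks=tuple(resolved[: schedule.n_blocks]), duration=schedule.duration
        )
    return Trajectory(
        times=np.concatenate(times_parts),
        states=np.vstack(states_parts),
        kinds=tuple(kinds),
        schedule_applied=applied,
        params=params,
    )


def equilibrate(
    params: ModelParams,
    x0: np.ndarray,
    max_horizon: float = 1000.0,
    chunk: float = 50.0,
    rhs_tol: float = 1e-10,
    freq_tol: float = 1e-10,
    solver_opts: Optional[SolverOptions] = None,
) -> tuple[np.ndarray, float, bool]:
    """Run untreated dynamics until the state settles (or the horizon caps).

    Convergence requires both a small derivative (max-norm of the rhs below
    ``rhs_tol``) and a small frequency drift per unit time, so transients
    that merely sit near the carrying capacity with an unsettled phenotype
    mix are not mistaken for equilibrium.  Returns (state, time, converged).
    """
    opts = solver_opts or SolverOptions(dt_out=chunk)
    x = np.asarray(x0, dtype=float)
    t = 0.0
    while t < max_horizon - 1e-9:
        t_next = min(t + chunk, max_horizon)
        _, y = _integrate_segment(params, x, TreatmentKind.NONE, (t, t_next), opts)
        x_new = _clamp_negatives(y[-1], t_next, _clamp_band(opts))
        deriv = np.abs(rhs(x_new, params, TreatmentKind.NONE)).max()
        tot_old, tot_new = x.sum(), x_new.sum()
        if tot_old > 0 and tot_new > 0:
            drift = np.abs(x_new / tot_new - x / tot_old).max() / (t_next - t)
        else:
            drift = 0.0
        x, t = x_new, t_next
        if deriv < rhs_tol and drift < freq_tol:
            return x, t, True
    return x, t, False


def burden_reduction(
    traj: Trajectory, params: ModelParams, at_time: float
) -> float:
    """Tumor burden reduction (K - X)/K at ``at_time``.

    Clipped to [0, 1] only when numerical noise pushes X marginally past K
    or below 0 (logged); a genuinely super-K state raises.
    """
    X = traj.total_at(at_time)
    K = params.carrying_capacity
    value = (K - X) / K
    if value < 0 or value > 1:
        if -1e-9 <= value < 0 or 1 < value <= 1 + 1e-9:
            logger.debug("clipping burden reduction %.3e to [0, 1]", value)
            return float(np.clip(value, 0.0, 1.0))
        raise ValueError(f"burden reduction {value} far outside [0, 1]")
    return float(value)
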