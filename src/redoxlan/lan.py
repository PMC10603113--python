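"""Coupled co-culture ODE model of the iron redox communication loop.

State is (cells_S, cells_R, fe2): reducer density, oxidizer density (both
in OD600 units) and the shared Fe2+ pool (mM).  Fe3+ is never integrated;
it is derived as ``fe_total - fe2``, which enforces the closed two-state
redox cycle exactly.

    d cells_S / dt = fe2 * cells_S * g_S(t)
    d cells_R / dt = (fe_total - fe2) * cells_R * g_R(t)
    d fe2     / dt = cells_S * f_S(t) - cells_R * f_R(t)

Each per-cell coefficient g/f is a "rate block": a constant amplitude
over a 4PL-shaped denominator, so the coefficient moves smoothly from
``amplitude / early_denom`` at t = 0 to ``amplitude / late_denom`` as
t -> infinity.  The reducer produces Fe2+ (its growth is driven by the
Fe2+ it has made), the oxidizer consumes Fe2+ and grows on the Fe3+-
position driver ``fe_total - fe2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ParameterDomainError

#: Largest post-hoc clamp of fe2 into [0, fe_total] that goes unflagged (mM).
CLAMP_WARN_THRESHOLD = 1e-6


@dataclass(frozen=True)
class RateBlock:
    """Time-varying per-cell rate coefficient amplitude / (4PL denominator).

    ``early_denom`` is the denominator at t = 0, ``late_denom`` its
    t -> infinity limit; both must be positive so the coefficient is
    finite and positive everywhere.  ``half_time`` (hours) locates the
    denominator's half-transition and ``exponent`` its sharpness.
    """

    amplitude: float
    early_denom: float
    late_denom: float
    half_time: float
    exponent: float

    def __post_init__(self) -> None:
        if not (self.early_denom > 0 and self.late_denom > 0):
            raise ParameterDomainError("denominator asymptotes must be > 0")
        if not self.half_time > 0:
            raise ParameterDomainError(f"half_time must be > 0, got {self.half_time}")
        if not self.exponent > 0:
            raise ParameterDomainError(f"exponent must be > 0, got {self.exponent}")
        if not np.isfinite(self.amplitude):
            raise ParameterDomainError("amplitude must be finite")


def rate_coefficient(block: RateBlock, t):
    """Evaluate a rate block at time(s) ``t`` >= 0.

    Continuous in t; equals ``amplitude / early_denom`` at t = 0 and
    approaches ``amplitude / late_denom`` as t grows.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    power = np.where(t > 0, (t / block.half_time) ** block.exponent, 0.0)
    denom = block.late_denom + (block.early_denom - block.late_denom) / (1.0 + power)
    out = block.amplitude / denom
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LanParameters:
    """Full parameter set of the co-culture model."""

    growth_S: RateBlock
    growth_R: RateBlock
    ferate_S: RateBlock
    ferate_R: RateBlock
    fe_total: float = 2.0
    cells_S0: float = 0.01
    cells_R0: float = 0.01
    fe2_0: float = 0.0

    def __post_init__(self) -> None:
        if not self.fe_total > 0:
            raise ParameterDomainError(f"fe_total must be > 0, got {self.fe_total}")
        if not 0.0 <= self.fe2_0 <= self.fe_total:
            raise ParameterDomainError("fe2_0 must lie within [0, fe_total]")
        if self.cells_S0 < 0 or self.cells_R0 < 0:
            raise ParameterDomainError("initial densities must be >= 0")

    def with_block(self, name: str, block: RateBlock) -> "LanParameters":
        """Return a copy with one rate block replaced."""
        return replace(self, **{name: block})


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course of the co-culture state."""

    times: np.ndarray
    cells_S: np.ndarray
    cells_R: np.ndarray
    fe2: np.ndarray
    fe3: np.ndarray
    fe_total: float
    max_clamp: float = 0.0
    clamp_warning: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("cells_S", "cells_R", "fe2", "fe3"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length mismatch with times")


def rhs(state: Sequence[float], t: float, params: LanParameters) -> tuple[float, float, float]:
    """Time derivatives of (cells_S, cells_R, fe2) at time ``t``."""
    cells_S, cells_R, fe2 = state
    for name, v in (("cells_S", cells_S), ("cells_R", cells_R), ("fe2", fe2)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite state component {name} = {v}")
    d_cells_S = fe2 * cells_S * rate_coefficient(params.growth_S, t)
    d_cells_R = (params.fe_total - fe2) * cells_R * rate_coefficient(params.growth_R, t)
    d_fe2 = (
        cells_S * rate_coefficient(params.ferate_S, t)
        - cells_R * rate_coefficient(params.ferate_R, t)
    )
    return d_cells_S, d_cells_R, d_fe2


def simulate(
    params: LanParameters,
    t_max: float = 96.0,
    output_grid: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the co-culture model over [0, t_max].

    Uses an adaptive explicit Runge-Kutta scheme (Dormand-Prince 4(5)).
    Fe2+ is clamped into [0, fe_total] in post-processing; the largest
    clamp magnitude is recorded and flagged when it exceeds
    :data:`CLAMP_WARN_THRESHOLD`.

    Raises
    ------
    IntegrationError
        If the solver cannot advance the solution.
    """
    if not t_max > 0:
        raise ValueError(f"t_max must be > 0, got {t_max}")
    if output_grid is None:
        grid = np.linspace(0.0, float(t_max), int(round(t_max)) * 4 + 1)
    else:
        grid = np.asarray(output_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("output grid must be strictly increasing with >= 2 points")
        if grid[0] < 0 or grid[-1] > t_max:
            raise ValueError("output grid must lie within [0, t_max]")

    sol = solve_ivp(
        lambda t, y: rhs(y, t, params),
        (0.0, float(t_max)),
        [params.cells_S0, params.cells_R0, params.fe2_0],
        method="RK45",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or sol.y.shape[1] != grid.size:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(f"ODE integration failed near t = {t_fail:.3f} h: {sol.message}")

    cells_S, cells_R, fe2_raw = sol.y
    fe2 = np.clip(fe2_raw, 0.0, params.fe_total)
    max_clamp = float(np.max(np.abs(fe2 - fe2_raw)))
    return Trajectory(
        times=grid,
        cells_S=cells_S,
        cells_R=cells_R,
        fe2=fe2,
        fe3=params.fe_total - fe2,
        fe_total=params.fe_total,
        max_clamp=max_clamp,
        clamp_warning=max_clamp > CLAMP_WARN_THRESHOLD,
        metadata={"rtol": rtol, "atol": atol},
    )


def conservation_report(traj: Trajectory, fe_total: float) -> float:
    """Maximum pointwise deviation of fe2 + fe3 from the fixed iron pool."""
    return float(np.max(np.abs(traj.fe2 + traj.fe3 - fe_total)))
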