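"""Four-parameter logistic (4PL) transduction curves for monocultures.

In the bare reducer culture the Fe2+ signal accumulates sigmoidally from
the 2 mM Fe3+ pool; in the bare oxidizer culture the complementary
quantity ``fe_total - fe2`` follows the same family.  Both are described
by the 4PL sigmoid

    f(t) = B + (A - B) / (1 + (t / C)**D)

with early asymptote A (value at t -> 0+), late asymptote B, half-
transition time C (hours) and shape exponent D.  For D > 0 the curve is
monotone between A and B and passes through (A + B)/2 exactly at t = C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, ParameterDomainError

Role = Literal["router", "actuator"]


@dataclass(frozen=True)
class FourPL:
    """Parameters of the four-parameter logistic sigmoid."""

    A: float  # early asymptote, value at t -> 0+
    B: float  # late asymptote, value at t -> inf
    C: float  # half-transition time, hours; > 0
    D: float  # shape exponent; > 0

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ParameterDomainError(f"C must be > 0, got {self.C}")
        if not self.D > 0:
            raise ParameterDomainError(f"D must be > 0, got {self.D}")
        for name in ("A", "B"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterDomainError(f"{name} must be finite")


def fourpl_eval(params: FourPL, t):
    """Evaluate the 4PL curve at time(s) ``t`` (hours, >= 0).

    At t = 0 the power term is taken as 0 (valid for D > 0) so the curve
    returns A exactly.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    with np.errstate(divide="ignore"):
        power = np.where(t > 0, (t / params.C) ** params.D, 0.0)
    out = params.B + (params.A - params.B) / (1.0 + power)
    return out if out.ndim else float(out)


def transduction_curve(params: FourPL, role: Role, fe_total: float, t):
    """Fe2+ concentration (mM) in a bare monoculture at time ``t``.

    ``router`` (the Fe3+-reducing species): Fe2+ accumulates, the curve
    is the 4PL itself.  ``actuator`` (the Fe2+-oxidizing species): the
    4PL describes ``fe_total - fe2``, so Fe2+ is its complement.
    """
    if fe_total <= 0:
        raise ValueError(f"fe_total must be positive, got {fe_total}")
    value = fourpl_eval(params, t)
    if role == "router":
        return value
    if role == "actuator":
        return fe_total - value
    raise ValueError(f"unknown role {role!r}")


@dataclass(frozen=True)
class FourPLFit:
    """Result of a nonlinear least-squares 4PL fit."""

    params: FourPL
    rss: float
    converged: bool
    n_iter: int
    degenerate: bool = False

    @property
    def residual_norm(self) -> float:
        return float(np.sqrt(self.rss))


def _default_init(times: np.ndarray, values: np.ndarray) -> FourPL:
    # A from the earliest, B from the latest observation; C where the
    # data most closely approach the midpoint; D = 2 as a neutral shape.
    order = np.argsort(times)
    a, b = values[order[0]], values[order[-1]]
    mid = 0.5 * (a + b)
    positive = times[times > 0]
    c = float(times[np.argmin(np.abs(values - mid))])
    if c <= 0:
        c = float(np.median(positive)) if positive.size else 1.0
    return FourPL(float(a), float(b), c, 2.0)


def fourpl_fit(
    times: Sequence[float],
    values: Sequence[float],
    init: FourPL | None = None,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    max_nfev: int = 2000,
) -> FourPLFit:
    """Fit a 4PL curve by unweighted nonlinear least squares.

    Requires at least four points at four distinct times.  Constant data
    are flat in (C, D); such fits return the canonical tie-break
    ``C = median(times), D = 1`` flagged ``degenerate`` so the output is
    deterministic.  Non-convergence within the iteration cap is reported
    through the ``converged`` flag rather than raised.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and equally long")
    if np.unique(t).size < 4:
        raise InsufficientDataError(
            f"need >= 4 points at >= 4 distinct times, got {np.unique(t).size}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")

    if np.ptp(y) == 0.0:
        v = float(y[0])
        c = float(np.median(t[t > 0])) if np.any(t > 0) else 1.0
        return FourPLFit(FourPL(v, v, c, 1.0), 0.0, True, 0, degenerate=True)

    p0 = init if init is not None else _default_init(t, y)
    if bounds is None:
        span = np.ptp(y)
        t_max = float(t.max())
        lo = [y.min() - span, y.min() - span, 1e-6, 1e-6]
        hi = [y.max() + span, y.max() + span, 10.0 * t_max, 20.0]
    else:
        lo, hi = bounds
    x0 = np.clip([p0.A, p0.B, p0.C, p0.D], lo, hi)

    def resid(theta):
        p = FourPL(*theta)
        return fourpl_eval(p, t) - y

    sol = least_squares(
        resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
        max_nfev=max_nfev,
    )
    fitted = FourPL(*(float(v) for v in sol.x))
    rss = float(2.0 * sol.cost)
    return FourPLFit(fitted, rss, bool(sol.status > 0), int(sol.nfev))
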