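"""Model fitting, model-data agreement metrics and small derived quantities.

The co-culture fit is a bounded nonlinear least-squares problem: free
parameters are addressed by their conventional letter symbols (E..I for
growth blocks, J..N for Fe-rate blocks, suffixed _S/_R), every trial
point triggers a fresh simulation, and each observed channel is
standardized by its observed range before residuals are pooled, since
the channels carry different units (mM versus OD600).

Joint fitting of all 20 block constants on a single-condition time
course is ill-posed; the intended workflow fixes the Fe-rate blocks
from monoculture pre-fits and frees (a subset of) the growth blocks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .calibration import LinearCalibration
from .errors import InsufficientDataError, IntegrationError, UndefinedStatisticError
from .lan import LanParameters, RateBlock, simulate
from .synthetic import DEFAULT_GRID, NoiseSpec, default_truth, generate_coculture_series
from .timeseries import TimeSeries

#: OD600-to-cell-count convention: 1 OD600 corresponds to 1e9 cells.
CELLS_PER_OD = 1e9

#: Channels the co-culture fit can consume, with the trajectory field each maps to.
FITTABLE_CHANNELS = {"fe2_mM": "fe2", "cells_S_od": "cells_S", "cells_R_od": "cells_R"}

_LETTER_FIELDS = ("amplitude", "late_denom", "early_denom", "half_time", "exponent")
_BLOCK_FOR_LETTER = {"E": "growth", "F": "growth", "G": "growth", "H": "growth",
                     "I": "growth", "J": "ferate", "K": "ferate", "L": "ferate",
                     "M": "ferate", "N": "ferate"}
_FIELD_FOR_LETTER = {"E": "amplitude", "F": "late_denom", "G": "early_denom",
                     "H": "half_time", "I": "exponent",
                     "J": "amplitude", "K": "late_denom", "L": "early_denom",
                     "M": "half_time", "N": "exponent"}

#: Default free mask: the two per-species growth blocks in full.
DEFAULT_FREE = ("E_S", "F_S", "G_S", "H_S", "I_S", "E_R", "F_R", "G_R", "H_R", "I_R")


def _resolve(symbol: str) -> tuple[str, str]:
    """Map a letter symbol like ``E_S`` to (block attribute, field name)."""
    letter, _, species = symbol.partition("_")
    if letter not in _BLOCK_FOR_LETTER or species not in ("S", "R"):
        raise ValueError(f"unknown parameter symbol {symbol!r}")
    return f"{_BLOCK_FOR_LETTER[letter]}_{species}", _FIELD_FOR_LETTER[letter]


def get_symbol(params: LanParameters, symbol: str) -> float:
    attr, fieldname = _resolve(symbol)
    return getattr(getattr(params, attr), fieldname)


def set_symbols(params: LanParameters, updates: dict[str, float]) -> LanParameters:
    """Return a copy of ``params`` with the given letter symbols replaced."""
    by_block: dict[str, dict[str, float]] = {}
    for symbol, value in updates.items():
        attr, fieldname = _resolve(symbol)
        by_block.setdefault(attr, {})[fieldname] = float(value)
    for attr, fields in by_block.items():
        block: RateBlock = getattr(params, attr)
        params = replace(params, **{attr: dataclasses.replace(block, **fields)})
    return params


@dataclass(frozen=True)
class LanFitResult:
    """Outcome of a co-culture least-squares fit."""

    estimate: LanParameters
    free: tuple[str, ...]
    values: dict[str, float]
    rss: float
    init_rss: float
    converged: bool
    n_iter: int
    residuals: dict[str, np.ndarray] = field(repr=False)


def _channel_residuals(params, ts, channels, scales, times):
    try:
        traj = simulate(params, t_max=float(times[-1]), output_grid=times)
    except (IntegrationError, ValueError):
        return None
    out = {}
    for name in channels:
        model = getattr(traj, FITTABLE_CHANNELS[name])
        out[name] = (model - ts.channel(name)) / scales[name]
    return out


def fit_lan_model(
    obs: TimeSeries,
    init: LanParameters,
    free: Sequence[str] = DEFAULT_FREE,
    bounds_factor: tuple[float, float] = (1.0 / 3.0, 3.0),
    max_nfev: int = 400,
) -> LanFitResult:
    """Fit the co-culture model to observed channels by least squares.

    Free parameters start at their values in ``init`` and are bounded
    multiplicatively by ``bounds_factor``.  A trial point where the
    integration fails contributes large finite residuals, so the
    optimizer retreats rather than aborting.  The returned RSS is never
    above the RSS at the initialization point.
    """
    channels = [c for c in FITTABLE_CHANNELS if obs.has_channel(c)]
    if not channels:
        raise InsufficientDataError("no fittable channel present in the observations")
    times = obs.times
    if times.size < 6:
        raise InsufficientDataError(f"need >= 6 time points, got {times.size}")
    if times[0] < 0:
        raise ValueError("observation times must be >= 0")

    scales = {}
    for name in channels:
        span = float(np.ptp(obs.channel(name)))
        scales[name] = span if span > 0 else 1.0

    free = tuple(free)
    x0 = np.array([get_symbol(init, s) for s in free], dtype=float)
    lo = x0 * bounds_factor[0]
    hi = x0 * bounds_factor[1]
    n_res = len(channels) * times.size

    def objective(theta):
        params = set_symbols(init, dict(zip(free, theta)))
        res = _channel_residuals(params, obs, channels, scales, times)
        if res is None:
            return np.full(n_res, 1e6)
        return np.concatenate([res[c] for c in channels])

    r0 = objective(x0)
    init_rss = float(r0 @ r0)
    sol = least_squares(objective, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12,
                        gtol=1e-12, max_nfev=max_nfev)
    values = dict(zip(free, (float(v) for v in sol.x)))
    estimate = set_symbols(init, values)
    per_channel = _channel_residuals(estimate, obs, channels, scales, times)
    rss = float(2.0 * sol.cost)
    return LanFitResult(
        estimate=estimate,
        free=free,
        values=values,
        rss=min(rss, init_rss),
        init_rss=init_rss,
        converged=bool(sol.status > 0),
        n_iter=int(sol.nfev),
        residuals=per_channel if per_channel is not None else {},
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two equally long series (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 points, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a sample correlation via the t transform (n-2 df)."""
    if n < 3:
        raise InsufficientDataError("need n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class PeakResult:
    t_peak: float
    value: float
    interior: bool  # False when the maximum sits on a boundary of the series


def find_peak(times: Sequence[float], values: Sequence[float]) -> PeakResult:
    """Locate the maximum of a sampled series; ties break to the earliest time."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.size < 3:
        raise ValueError("need >= 3 equally long times/values")
    idx = int(np.argmax(v))  # argmax returns the first of tied maxima
    return PeakResult(float(t[idx]), float(v[idx]), 0 < idx < t.size - 1)


def od_to_cells(od: float) -> float:
    """Convert OD600 to a cell count under the 1 OD = 1e9 cells convention."""
    if od < 0:
        raise ValueError(f"od must be >= 0, got {od}")
    return od * CELLS_PER_OD


def relative_abundance(cells_S: float, cells_R: float) -> tuple[float, float]:
    """Fractions of the two species in the community (sum to 1)."""
    if cells_S < 0 or cells_R < 0:
        raise ValueError("densities must be >= 0")
    total = cells_S + cells_R
    if total == 0:
        raise UndefinedStatisticError("composition undefined for an empty community")
    return cells_S / total, cells_R / total


def co2_fixation_rate(bicarbonate_consumed: float, interval: float, dcw: float) -> float:
    """CO2 fixation rate: bicarbonate consumed (mM) per hour per gram dry cell weight."""
    if interval <= 0:
        raise ValueError(f"interval must be > 0, got {interval}")
    if dcw <= 0:
        raise ValueError(f"dcw must be > 0, got {dcw}")
    if bicarbonate_consumed < 0:
        raise ValueError("consumption must be >= 0")
    return bicarbonate_consumed / interval / dcw


@dataclass(frozen=True)
class RecoveryReport:
    """Aggregate of a multi-seed simulate-perturb-refit experiment."""

    free: tuple[str, ...]
    seeds: tuple[int, ...]
    truth_values: dict[str, float]
    estimates: list[dict[str, float]]
    bias: dict[str, float]                 # mean(estimate - truth) per free parameter
    relative_rmse: dict[str, float]        # RMSE / |truth| per free parameter
    channel_r: dict[str, list[float]]      # per-seed fit-vs-observation Pearson R
    median_r: dict[str, float]
    pvalues: dict[str, list[float]]
    non_converged: tuple[int, ...]


def recovery_experiment(
    truth: LanParameters | None = None,
    noise: NoiseSpec | None = None,
    seeds: Sequence[int] = tuple(range(25)),
    free: Sequence[str] = ("E_S", "E_R"),
    times=None,
    calib: LinearCalibration | None = None,
    init_perturbation: float = 0.2,
) -> RecoveryReport:
    """Simulate noisy co-culture observations per seed, refit, aggregate.

    For each seed a synthetic table is generated, the free parameters
    are perturbed uniformly within ``+-init_perturbation`` of truth to
    form the initialization, and the model is refit.  The report
    collects per-parameter bias and relative RMSE and, per channel, the
    Pearson correlation between the fitted trajectory and the noisy
    observations.  A seed whose fit does not converge is recorded, not
    fatal.
    """
    truth = default_truth() if truth is None else truth
    noise = NoiseSpec() if noise is None else noise
    times = DEFAULT_GRID if times is None else np.asarray(times, dtype=float)
    free = tuple(free)
    truth_values = {s: get_symbol(truth, s) for s in free}

    estimates: list[dict[str, float]] = []
    channel_r: dict[str, list[float]] = {c: [] for c in FITTABLE_CHANNELS}
    pvalues: dict[str, list[float]] = {c: [] for c in FITTABLE_CHANNELS}
    non_converged = []

    for seed in seeds:
        spec = dataclasses.replace(noise, seed=int(seed))
        obs = generate_coculture_series(truth, times=times, noise=spec, calib=calib)
        rng = np.random.default_rng(int(seed) + 2**20)
        init = set_symbols(truth, {
            s: truth_values[s] * rng.uniform(1 - init_perturbation, 1 + init_perturbation)
            for s in free
        })
        result = fit_lan_model(obs, init, free=free)
        if not result.converged:
            non_converged.append(int(seed))
        estimates.append(result.values)

        traj = simulate(result.estimate, t_max=float(times[-1]), output_grid=times)
        for name, attr in FITTABLE_CHANNELS.items():
            r = pearson_r(getattr(traj, attr), obs.channel(name))
            channel_r[name].append(r)
            pvalues[name].append(correlation_pvalue(r, times.size))

    bias = {}
    rel_rmse = {}
    for s in free:
        err = np.array([e[s] for e in estimates]) - truth_values[s]
        bias[s] = float(np.mean(err))
        rel_rmse[s] = float(np.sqrt(np.mean(err**2)) / abs(truth_values[s]))
    return RecoveryReport(
        free=free,
        seeds=tuple(int(s) for s in seeds),
        truth_values=truth_values,
        estimates=estimates,
        bias=bias,
        relative_rmse=rel_rmse,
        channel_r=channel_r,
        median_r={c: float(np.median(v)) for c, v in channel_r.items()},
        pvalues=pvalues,
        non_converged=tuple(non_converged),
    )
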