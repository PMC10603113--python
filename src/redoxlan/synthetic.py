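"""Synthetic observation tables with the noise structure the analysis assumes.

The generator emulates the measured channels of the co-culture study:
Fe2+ concentration (via a simulated trajectory or a monoculture 4PL
curve), per-species OD600, raw nanoprobe luminescence linked to
Fe2+/Fe_total through the log-linear calibration, and a phenanthroline-
style absorbance channel that is an affine map of Fe2+.  Concentration
and OD channels carry additive Gaussian noise; raw intensity carries
multiplicative log-normal noise, since intensities are positive and span
about a decade.

Default noise magnitudes (od_sd 0.02, fe2_sd 0.08 mM, lum_cv 5 %,
abs_sd 0.01) are calibrated so that model-fit trajectories correlate
with the noisy observations at the fidelity levels the verification
workflow expects (R ~ 0.90 on Fe2+, ~ 0.99 on OD); replicate-level noise
magnitudes were not available to estimate directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import LinearCalibration, predict_log_intensity, reference_calibration
from .defaults import default_lan_parameters
from .lan import LanParameters, simulate
from .timeseries import TimeSeries, make_timeseries
from .transduction import FourPL, Role, transduction_curve

#: Default sampling grid: a 96-h incubation sampled every 12 h.
DEFAULT_GRID = np.arange(0.0, 97.0, 12.0)

#: Affine map used for the synthetic absorbance channel (AU per mM, AU).
ABSORBANCE_SLOPE = 0.35
ABSORBANCE_INTERCEPT = 0.02


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes and the seed that makes a table reproducible."""

    od_sd: float = 0.02          # additive Gaussian sd on OD600 channels
    fe2_sd: float = 0.08         # additive Gaussian sd on Fe2+ (mM)
    lum_cv: float = 0.05         # multiplicative log-normal CV on raw intensity
    abs_sd: float = 0.01         # additive Gaussian sd on absorbance (AU)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("od_sd", "fe2_sd", "lum_cv", "abs_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, factor: float) -> "NoiseSpec":
        """All noise magnitudes multiplied by ``factor`` (same seed)."""
        return NoiseSpec(
            self.od_sd * factor, self.fe2_sd * factor,
            self.lum_cv * factor, self.abs_sd * factor, self.seed,
        )


ZERO_NOISE = NoiseSpec(0.0, 0.0, 0.0, 0.0, 0)


def default_truth() -> LanParameters:
    """The packaged co-culture parameter set used as ground truth."""
    return default_lan_parameters()


def _truncate_fe2(values: np.ndarray, fe_total: float) -> tuple[np.ndarray, int]:
    clipped = np.clip(values, 0.0, fe_total)
    return clipped, int(np.sum(clipped != values))


def generate_monoculture_series(
    truth: FourPL,
    role: Role,
    fe_total: float = 2.0,
    times=None,
    noise: NoiseSpec = ZERO_NOISE,
) -> TimeSeries:
    """Noisy Fe2+ measurements from a bare monoculture transduction curve.

    Negative or above-pool noisy concentrations are truncated into
    [0, fe_total]; the truncation count is recorded in the metadata.
    """
    t = DEFAULT_GRID if times is None else np.asarray(times, dtype=float)
    rng = np.random.default_rng(noise.seed)
    clean = np.asarray(transduction_curve(truth, role, fe_total, t), dtype=float)
    noisy = clean + rng.normal(0.0, noise.fe2_sd, t.shape) if noise.fe2_sd else clean.copy()
    noisy, n_trunc = _truncate_fe2(noisy, fe_total)
    return make_timeseries(
        t,
        metadata={
            "role": role, "fe_total": fe_total, "noise": noise,
            "truncated": n_trunc, "truth": truth,
        },
        fe2_mM=noisy,
    )


def generate_coculture_series(
    truth: LanParameters | None = None,
    times=None,
    noise: NoiseSpec = ZERO_NOISE,
    calib: LinearCalibration | None = None,
) -> TimeSeries:
    """Noisy multi-channel observations from a simulated co-culture run.

    Channels: ``fe2_mM``, ``cells_S_od``, ``cells_R_od``, plus the two
    paired optical readouts — ``luminescence_counts`` derived from the
    noise-free Fe2+/Fe_total ratio through the calibration (then
    log-normally perturbed) and ``absorbance_510`` as an affine map of
    noise-free Fe2+ with additive noise.  The pairing mimics measuring
    the same pool with the nanoprobe and the phenanthroline assay.
    """
    truth = default_truth() if truth is None else truth
    calib = reference_calibration() if calib is None else calib
    t = DEFAULT_GRID if times is None else np.asarray(times, dtype=float)
    rng = np.random.default_rng(noise.seed)

    traj = simulate(truth, t_max=float(t[-1]), output_grid=t)
    ratio = traj.fe2 / truth.fe_total * calib.ratio_max
    log_i = np.array([predict_log_intensity(calib, r) for r in ratio])
    lum = np.power(10.0, log_i)
    if noise.lum_cv:
        sigma = np.sqrt(np.log1p(noise.lum_cv**2))
        lum = lum * rng.lognormal(-0.5 * sigma**2, sigma, t.shape)
    absorb = ABSORBANCE_SLOPE * traj.fe2 + ABSORBANCE_INTERCEPT
    if noise.abs_sd:
        absorb = absorb + rng.normal(0.0, noise.abs_sd, t.shape)

    fe2 = traj.fe2 + rng.normal(0.0, noise.fe2_sd, t.shape) if noise.fe2_sd else traj.fe2.copy()
    fe2, n_trunc = _truncate_fe2(fe2, truth.fe_total)
    cs = traj.cells_S + rng.normal(0.0, noise.od_sd, t.shape) if noise.od_sd else traj.cells_S.copy()
    cr = traj.cells_R + rng.normal(0.0, noise.od_sd, t.shape) if noise.od_sd else traj.cells_R.copy()

    return make_timeseries(
        t,
        metadata={
            "noise": noise, "calibration": calib, "truth": truth,
            "truncated": n_trunc, "fe_total": truth.fe_total,
        },
        fe2_mM=fe2,
        cells_S_od=cs,
        cells_R_od=cr,
        luminescence_counts=lum,
        absorbance_510=absorb,
    )
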