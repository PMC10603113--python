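"""Model fitting, agreement metrics and small derived quantities."""

import dataclasses

import numpy as np
import pytest

from redoxlan import (
    NoiseSpec,
    co2_fixation_rate,
    correlation_pvalue,
    find_peak,
    fit_lan_model,
    generate_coculture_series,
    od_to_cells,
    pearson_r,
    recovery_experiment,
    relative_abundance,
)
from redoxlan.errors import InsufficientDataError, UndefinedStatisticError
from redoxlan.inference import get_symbol, set_symbols
from redoxlan.synthetic import ZERO_NOISE


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # direct formula: cov/sd_x/sd_y for x=(1,2,3), y=(1,2,4)
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y) == pytest.approx(num / den, rel=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r = pearson_r(x, y)
        assert pearson_r(3.0 * x + 1.0, y) == pytest.approx(r, rel=1e-10)
        assert pearson_r(x, 0.5 * y - 4.0) == pytest.approx(r, rel=1e-10)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_pvalue_t_transform(self):
        # cross-check against scipy's exact test
        from scipy.stats import pearsonr as scipy_pearsonr

        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([2.0, 1.5, 4.0, 4.5, 9.0])
        r = pearson_r(x, y)
        assert correlation_pvalue(r, len(x)) == pytest.approx(
            scipy_pearsonr(x, y)[1], rel=1e-9
        )


class TestPeak:
    def test_direct_maximum(self):
        res = find_peak([0, 12, 24, 36], [0.0, 0.5, 0.76, 0.6])
        assert (res.t_peak, res.value) == (24.0, 0.76)
        assert res.interior

    def test_boundary_flagged(self):
        res = find_peak([0, 12, 24], [0.1, 0.2, 0.3])
        assert not res.interior

    def test_tie_breaks_to_earliest(self):
        res = find_peak([0, 12, 24, 36], [0.0, 0.7, 0.7, 0.1])
        assert res.t_peak == 12.0


class TestSmallMetrics:
    @pytest.mark.parametrize("od, cells", [(1.0, 1e9), (0.0, 0.0), (0.5, 5e8)])
    def test_od_convention(self, od, cells):
        assert od_to_cells(od) == cells

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            od_to_cells(-0.1)

    @pytest.mark.parametrize(
        "cs, cr, expected",
        [((1, 1), (0.5, 0.5), None), ((0, 2), (0.0, 1.0), None),
         ((0.3, 0.9), (0.25, 0.75), None)],
    )
    def test_relative_abundance(self, cs, cr, expected):
        fs, fr = relative_abundance(*cs)
        assert (fs, fr) == pytest.approx(cr)
        assert fs + fr == pytest.approx(1.0)

    def test_empty_community_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            relative_abundance(0.0, 0.0)

    @pytest.mark.parametrize(
        "consumed, hours, dcw, expected",
        [(10.0, 96.0, 0.5, 10 / 96 / 0.5), (0.0, 96.0, 1.0, 0.0),
         (30.0, 96.0, 1.0, 0.3125)],
    )
    def test_co2_fixation_rate(self, consumed, hours, dcw, expected):
        assert co2_fixation_rate(consumed, hours, dcw) == pytest.approx(expected)

    def test_co2_rate_domain(self):
        with pytest.raises(ValueError):
            co2_fixation_rate(10.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            co2_fixation_rate(10.0, 96.0, 0.0)


class TestLanFit:
    def test_zero_residual_at_truth(self, lan_truth):
        obs = generate_coculture_series(lan_truth, noise=ZERO_NOISE)
        result = fit_lan_model(obs, lan_truth, free=("E_S", "E_R"))
        assert result.rss < 1e-10
        assert result.values["E_S"] == pytest.approx(
            get_symbol(lan_truth, "E_S"), rel=1e-4
        )

    def test_recovery_from_perturbed_init(self, lan_truth):
        obs = generate_coculture_series(lan_truth, noise=ZERO_NOISE)
        init = set_symbols(lan_truth, {
            "E_S": get_symbol(lan_truth, "E_S") * 1.2,
            "E_R": get_symbol(lan_truth, "E_R") * 0.8,
        })
        result = fit_lan_model(obs, init, free=("E_S", "E_R"))
        for symbol in ("E_S", "E_R"):
            assert result.values[symbol] == pytest.approx(
                get_symbol(lan_truth, symbol), rel=0.01
            )

    def test_monotone_improvement_contract(self, lan_truth):
        obs = generate_coculture_series(
            lan_truth, noise=NoiseSpec(seed=3)
        )
        init = set_symbols(lan_truth, {"E_S": get_symbol(lan_truth, "E_S") * 1.15})
        result = fit_lan_model(obs, init, free=("E_S", "E_R"))
        assert result.rss <= result.init_rss

    def test_no_channels_rejected(self, lan_truth):
        from redoxlan import make_timeseries

        ts = make_timeseries(np.linspace(0, 96, 9), other=np.zeros(9))
        with pytest.raises(InsufficientDataError):
            fit_lan_model(ts, lan_truth)

    def test_too_few_timepoints_rejected(self, lan_truth):
        obs = generate_coculture_series(
            lan_truth, times=np.array([0.0, 24.0, 48.0, 72.0, 96.0]),
            noise=ZERO_NOISE,
        )
        with pytest.raises(InsufficientDataError):
            fit_lan_model(obs, lan_truth)


class TestRecoveryExperiment:
    def test_zero_noise_single_seed_is_exact(self, lan_truth):
        report = recovery_experiment(
            lan_truth, noise=dataclasses.replace(ZERO_NOISE), seeds=[0],
            free=("E_S", "E_R"),
        )
        for symbol in report.free:
            assert abs(report.bias[symbol]) < 1e-5 * abs(report.truth_values[symbol])
        for channel, values in report.channel_r.items():
            assert values[0] == pytest.approx(1.0, abs=1e-9)

    def test_noise_degrades_monotonically(self, lan_truth):
        seeds = range(6)
        base = recovery_experiment(lan_truth, NoiseSpec(), seeds=seeds)
        double = recovery_experiment(lan_truth, NoiseSpec().scaled(2.0), seeds=seeds)
        for channel in base.median_r:
            assert double.median_r[channel] <= base.median_r[channel] + 1e-9
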