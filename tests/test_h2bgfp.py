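"""H2B-GFP inference: normalization, modality tests, division-rate and
cycle-shape estimation, and label-retaining-cell detection."""

import numpy as np
import pandas as pd
import pytest

import epiclone as ec
from epiclone.cellcycle import InvalidParameterError
from epiclone.h2bgfp_inference import (
    LRT_HALF_CHI2_95,
    NormalizationError,
    _field_means,
    detect_lrcs,
    dip_test,
    estimate_division_rate,
    fit_cycle_shape,
    normalize_intensities,
    silverman_test,
)


def _mini_table(intensities, times=None, leuko=None):
    n = len(intensities)
    return pd.DataFrame(
        {
            "mouse_id": ["m1"] * n,
            "time_days": times if times is not None else [0.0] * n,
            "fov_id": ["f1"] * n,
            "cell_id": [f"c{i}" for i in range(n)],
            "intensity": intensities,
            "is_leukocyte": leuko if leuko is not None else [False] * n,
        }
    )


class TestNormalization:
    def test_time0_keratinocyte_mean_becomes_one(self, small_chase_table):
        norm = normalize_intensities(small_chase_table)
        ker0 = norm[(norm.time_days == 0) & (~norm.is_leukocyte)]
        assert ker0["intensity"].mean() == pytest.approx(1.0)

    def test_idempotent(self, small_chase_table):
        once = normalize_intensities(small_chase_table)
        twice = normalize_intensities(once)
        assert np.allclose(once["intensity"], twice["intensity"])

    def test_leukocyte_only_time0_fails(self):
        t = _mini_table([1.0, 2.0], leuko=[True, True])
        with pytest.raises(NormalizationError):
            normalize_intensities(t)

    def test_leukocytes_excluded_from_statistics(self):
        t = pd.concat(
            [
                _mini_table([1.0, 3.0]),
                _mini_table([100.0], leuko=[True]),
            ],
            ignore_index=True,
        )
        norm = normalize_intensities(t)
        # factor is the keratinocyte mean (2.0), untouched by the leukocyte
        assert norm.loc[~norm.is_leukocyte, "intensity"].tolist() == [0.5, 1.5]
        fm = _field_means(norm)
        assert fm["n_cells"].sum() == 2  # leukocyte dropped downstream


class TestModality:
    def test_gaussian_null_rarely_rejected(self, rng):
        rejections = 0
        for k in range(10):
            v = rng.normal(size=500)
            res = silverman_test(v, n_bootstrap=200, rng=rng)
            rejections += res.p_value < 0.05
        assert rejections <= 1  # >= 90% of seeded repeats keep the null

    def test_separated_mixture_rejected(self, rng):
        v = np.r_[rng.normal(0, 0.1, 250), rng.normal(1, 0.1, 250)]
        assert silverman_test(v, n_bootstrap=200, rng=rng).p_value < 0.05
        assert dip_test(v, n_bootstrap=200, rng=rng).p_value < 0.05

    def test_gaussian_null_dip(self, rng):
        ps = [dip_test(rng.normal(size=500), n_bootstrap=200, rng=rng).p_value for _ in range(5)]
        assert sum(p < 0.05 for p in ps) <= 1

    def test_constant_input_is_unimodal(self, rng):
        v = np.ones(50)
        assert silverman_test(v, n_bootstrap=100, rng=rng).p_value == 1.0
        assert dip_test(v, n_bootstrap=100, rng=rng).p_value == 1.0

    def test_too_few_values(self, rng):
        with pytest.raises(InvalidParameterError):
            silverman_test(np.ones(5), rng=rng)
        with pytest.raises(InvalidParameterError):
            silverman_test(np.ones(50), n_bootstrap=10, rng=rng)

    def test_silverman_type_one_error_calibrated(self, rng):
        """Empirical type-I error at nominal alpha=0.05 stays <= 0.10 (the
        variance-rescaled smoothed bootstrap is known to be conservative)."""
        n_reject = 0
        n_runs = 100
        for _ in range(n_runs):
            v = rng.normal(size=120)
            if silverman_test(v, n_bootstrap=120, rng=rng).p_value < 0.05:
                n_reject += 1
        assert n_reject / n_runs <= 0.10


class TestDivisionRate:
    def test_exact_halving_gives_unit_rate(self):
        # every intensity halves every 7 days -> lambda = 1/week exactly
        frames = []
        for k, t in enumerate([0.0, 7.0, 14.0]):
            frames.append(_mini_table(np.full(30, 2.0**-k), times=[t] * 30))
        est = estimate_division_rate(pd.concat(frames, ignore_index=True), rng=0)
        assert est.rate_per_week == pytest.approx(1.0)

    def test_single_time_errors(self):
        with pytest.raises(InvalidParameterError):
            estimate_division_rate(_mini_table([1.0, 2.0]), rng=0)

    def test_esophageal_rate_recovery(self, small_chase_table):
        norm = normalize_intensities(small_chase_table)
        est = estimate_division_rate(norm, rng=1)
        lo, hi = est.ci95
        assert lo <= 2.9 <= hi or abs(est.rate_per_week - 2.9) < 0.15

    def test_simulation_fit_agrees_with_slope(self, small_chase_table):
        norm = normalize_intensities(small_chase_table)
        slope = estimate_division_rate(norm, method="log2_slope", rng=2)
        sim = estimate_division_rate(
            norm,
            method="simulation_fit",
            model_partial={"r": 0.10, "rho": 0.65, "shape": 8.0, "t_min": 0.5},
            rng=2,
            n_sim=1500,
            lambda_grid=np.linspace(2.2, 3.6, 8),
        )
        assert abs(sim.rate_per_week - slope.rate_per_week) < 0.4


class TestCycleShape:
    def test_self_recovery_and_exponential_rejection(self, small_chase_table):
        """Data simulated at gamma shape 8: the fitted shape lands within one
        grid step, and the exponential law (shape 1) is firmly rejected —
        the dilution histograms it predicts are far too broad."""
        norm = normalize_intensities(small_chase_table)
        fit = fit_cycle_shape(
            norm, 2.9, shape_grid=[1, 2, 4, 8, 16], t_min_grid=[0.0, 0.5],
            n_sim=2500, rng=3, r=0.10, rho=0.65,
        )
        assert fit.best.shape in (4.0, 8.0, 16.0)
        by_shape = fit.profile.groupby("shape")["nll"].min()
        assert by_shape[1.0] - by_shape.min() > LRT_HALF_CHI2_95
        assert fit.conservative.shape <= fit.best.shape

    def test_empty_grid_errors(self, small_chase_table):
        norm = normalize_intensities(small_chase_table)
        with pytest.raises(InvalidParameterError):
            fit_cycle_shape(norm, 2.9, shape_grid=[], t_min_grid=[0.0], rng=0)


class TestLRC:
    def test_spike_in_fraction(self):
        # 4 undiluted keratinocytes among 1923 at 18 d chase -> 0.21%
        n = 1923
        diluted = np.full(n - 4, 2.0**-7)
        lrc = np.ones(4)
        t = pd.concat(
            [
                _mini_table(np.ones(200)),  # time-0 reference
                _mini_table(np.r_[diluted, lrc], times=[18.0] * n),
            ],
            ignore_index=True,
        )
        out = detect_lrcs(normalize_intensities(t), at_time=18.0)
        assert out["keratinocyte_lrc_fraction"] == pytest.approx(4 / 1923)
        assert round(100 * out["keratinocyte_lrc_fraction"], 2) == 0.21

    def test_simulated_esophagus_has_no_keratinocyte_lrcs(self, small_chase_table):
        out = detect_lrcs(normalize_intensities(small_chase_table), at_time=18.0)
        assert out["keratinocyte_lrc_fraction"] < 0.005
        assert out["leukocyte_lrc_fraction"] > 0.8  # leukocytes retain label

    def test_absent_time_errors(self, small_chase_table):
        with pytest.raises(InvalidParameterError):
            detect_lrcs(normalize_intensities(small_chase_table), at_time=99.0)


def test_sp_unimodal_but_two_rate_mixture_bimodal(rng):
    """Width separation after 18 d of dilution: a single population stays
    unimodal while two populations with 4x separated rates do not."""
    sp = ec.SPParams.homeostatic(2.9, 0.10, 0.65, shape=8.0, t_min=0.5)
    slow = ec.SPParams.homeostatic(2.9 / 4, 0.10, 0.65, shape=8.0, t_min=2.0)
    uni_fail = 0
    bi_detect = 0
    n_rep = 5
    for k in range(n_rep):
        tidy = ec.simulate_dilution(
            sp, [0.0, 18.0], 900, rng=200 + k, measurement_noise_cv=0.2
        )
        v = np.log2(tidy.loc[tidy.time_days == 18.0, "intensity"].to_numpy())
        if silverman_test(v, n_bootstrap=150, rng=rng).p_value < 0.05:
            uni_fail += 1
        fast_t = ec.simulate_dilution(
            sp, [0.0, 18.0], 630, rng=300 + k, measurement_noise_cv=0.2
        )
        slow_t = ec.simulate_dilution(
            slow, [0.0, 18.0], 270, rng=400 + k, measurement_noise_cv=0.2
        )
        mix = np.r_[
            fast_t.loc[fast_t.time_days == 18.0, "intensity"].to_numpy(),
            slow_t.loc[slow_t.time_days == 18.0, "intensity"].to_numpy(),
        ]
        if silverman_test(np.log2(mix), n_bootstrap=150, rng=rng).p_value < 0.05:
            bi_detect += 1
    assert uni_fail <= 1  # SP histograms unimodal in >= ~90% of runs
    assert bi_detect >= 4  # 4x-separated two-population histograms rejected
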