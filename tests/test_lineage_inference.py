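"""Clone-size likelihood machinery: binning, multinomial scoring, profile
CIs, goodness of fit, and CI-coverage calibration."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epiclone as ec
from epiclone.cellcycle import InvalidParameterError
from epiclone.lineage_inference import (
    ObservedCloneDistribution,
    bin_clone_sizes,
    ci_coverage,
    clone_size_loglik,
    goodness_of_fit,
    mle_grid_search,
    profile_ci,
)
from epiclone.simulator import CloneSizeDistribution


def _clone_table(sizes_by_time):
    rows = []
    for t, sizes in sizes_by_time.items():
        for i, s in enumerate(sizes):
            rows.append(
                {"mouse_id": "m1", "time_days": float(t), "clone_id": f"{t}_{i}",
                 "n_basal": int(s), "n_suprabasal": 0}
            )
    return pd.DataFrame(rows)


class TestBinning:
    def test_basic_arithmetic(self):
        obs = bin_clone_sizes(_clone_table({10: [1, 1, 2, 5]}), k_max=4)[0]
        assert obs.counts.tolist() == [2, 1, 0, 1]  # bins 1, 2, 3, 4+

    def test_extinct_basal_clone_excluded(self):
        table = _clone_table({10: [1, 2]})
        table = pd.concat(
            [table, pd.DataFrame([{"mouse_id": "m1", "time_days": 10.0,
                                   "clone_id": "x", "n_basal": 0, "n_suprabasal": 3}])],
            ignore_index=True,
        )
        obs = bin_clone_sizes(table, k_max=4)[0]
        assert obs.n_clones == 2  # the suprabasal-only clone is not imaged

    def test_pooled_bin_can_be_empty(self):
        obs = bin_clone_sizes(_clone_table({10: [1, 2, 3]}), k_max=7)[0]
        assert obs.counts[-1] == 0

    def test_empty_table_errors(self):
        with pytest.raises(InvalidParameterError):
            bin_clone_sizes(_clone_table({}))


class TestLoglik:
    def _sim(self, counts, time=10.0, k_max=None):
        counts = np.asarray(counts)
        return CloneSizeDistribution(
            time=time, k_max=k_max or len(counts), counts=counts,
            n_clones_simulated=int(counts.sum()), surviving_fraction=1.0,
        )

    def test_two_bin_arithmetic(self):
        obs = ObservedCloneDistribution(10.0, 2, np.array([6, 4]))
        ll = clone_size_loglik(obs, self._sim([500, 500]))
        assert ll == pytest.approx(10 * np.log(0.5))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=3, max_size=7).filter(lambda c: sum(c) > 0))
    def test_matching_proportions_maximize(self, counts):
        """Multinomial likelihood is maximized when p equals the observed
        proportions (up to flooring)."""
        counts = np.asarray(counts)
        obs = ObservedCloneDistribution(10.0, len(counts), counts)
        matched = self._sim(counts * 1000 + 1)
        ll_match = clone_size_loglik(obs, matched, floor=1e-12)
        rng = np.random.default_rng(0)
        for _ in range(5):
            other = self._sim(rng.integers(1, 100, len(counts)))
            assert clone_size_loglik(obs, other, floor=1e-12) <= ll_match + 1e-6

    def test_zero_probability_bin_floored_with_warning(self):
        obs = ObservedCloneDistribution(10.0, 3, np.array([5, 0, 2]))
        sim = self._sim([100, 100, 0])
        with pytest.warns(UserWarning):
            ll = clone_size_loglik(obs, sim)
        assert np.isfinite(ll)

    def test_bin_mismatch_errors(self):
        obs = ObservedCloneDistribution(10.0, 3, np.array([5, 0, 2]))
        with pytest.raises(InvalidParameterError):
            clone_size_loglik(obs, self._sim([1, 1], time=10.0))


class TestProfileCI:
    def test_quadratic_surface_gives_normal_interval(self):
        """l = lmax - (theta - 3)^2 / (2 sigma^2) -> CI = 3 +/- 1.96 sigma."""
        sigma = 0.4
        theta = np.linspace(0, 6, 601)
        other = np.linspace(-1, 1, 41)
        surf = -((theta[:, None] - 3.0) ** 2) / (2 * sigma**2) - other[None, :] ** 2
        lo, hi = profile_ci(surf, theta, axis=0)
        assert lo == pytest.approx(3 - 1.96 * sigma, abs=0.01)
        assert hi == pytest.approx(3 + 1.96 * sigma, abs=0.01)

    def test_edge_maximum_gives_one_sided_interval(self):
        theta = np.linspace(0, 1, 11)
        surf = theta[:, None] * 10.0 + np.zeros((11, 3))
        lo, hi = profile_ci(surf, theta, axis=0)
        assert hi == 1.0 and lo < 1.0

    def test_single_point_grid_degenerates(self):
        surf = np.array([[0.0]])
        lo, hi = profile_ci(surf, np.array([0.3]), axis=0)
        assert lo == hi == 0.3

    def test_flat_surface_flagged(self):
        surf = np.zeros((5, 4))
        with pytest.warns(UserWarning, match="flat"):
            lo, hi = profile_ci(surf, np.arange(5.0), axis=0)
        assert (lo, hi) == (0.0, 4.0)


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        df, r2t, st_ = goodness_of_fit({10: [60, 40]}, {10: [60, 40]})
        assert r2t == 1.0 and st_ == 0.0

    def test_constant_prediction_gives_zero_r2(self):
        df, r2t, st_ = goodness_of_fit({10: [60.0, 40.0]}, {10: [50.0, 50.0]})
        assert r2t == pytest.approx(0.0)
        assert st_ == pytest.approx(10.0)  # sqrt(RSS/nbins) = sqrt(200/2)

    def test_zero_variance_observed_is_nan(self):
        df, r2t, _ = goodness_of_fit({10: [50.0, 50.0]}, {10: [40.0, 60.0]})
        assert np.isnan(r2t)


class TestCICoverage:
    def test_perfect_and_displaced(self):
        obs = ObservedCloneDistribution(10.0, 3, np.array([50, 30, 20]))
        exact = {10.0: obs.frequencies}
        assert ci_coverage([obs], exact) == {"n_covered": 3, "n_total": 3}
        p = obs.frequencies
        se = np.sqrt(p * (1 - p) / obs.n_clones)
        assert ci_coverage([obs], {10.0: p + 10 * se})["n_covered"] == 0

    def test_coverage_calibration_matches_binomial_oracle(self, rng):
        """Resampling data from the prediction: empirical coverage of the
        Wald interval matches exact binomial enumeration, near 95%."""
        p_true = np.array([0.45, 0.25, 0.15, 0.08, 0.04, 0.02, 0.01])
        n = 300

        # exact oracle: coverage per bin by enumerating Binomial(n, p) counts
        from scipy import stats as ss

        oracle = []
        for p in p_true:
            k = np.arange(0, n + 1)
            p_hat = k / n
            se = np.sqrt(p_hat * (1 - p_hat) / n)
            covered = np.abs(p - p_hat) <= 1.96 * se
            oracle.append(ss.binom.pmf(k, n, p)[covered].sum())
        oracle_mean = float(np.mean(oracle))

        n_rep = 500
        cov = 0
        tot = 0
        for _ in range(n_rep):
            counts = rng.multinomial(n, p_true)
            obs = ObservedCloneDistribution(10.0, len(p_true), counts)
            res = ci_coverage([obs], {10.0: p_true})
            cov += res["n_covered"]
            tot += res["n_total"]
        frac = cov / tot
        se_mc = np.sqrt(oracle_mean * (1 - oracle_mean) / (n_rep * len(p_true)))
        assert abs(frac - oracle_mean) < 4 * se_mc
        assert 0.90 <= frac <= 0.99  # "approximately 95%"

    def test_zero_clones_errors(self):
        obs = ObservedCloneDistribution(10.0, 2, np.array([0, 0]))
        with pytest.raises(InvalidParameterError):
            ci_coverage([obs], {10.0: np.array([0.5, 0.5])})


class TestGridSearch:
    def test_truth_inside_chi2_band_and_identity_holds(self, eso_params):
        """Small-scale coherence: the log-likelihood at the generating truth
        lies within the chi-square(2) 95% band of the surface maximum, and
        Gamma-hat satisfies the homeostatic identity exactly."""
        rng = np.random.default_rng(21)
        clones = ec.generate_lineage_experiment(
            eso_params,
            ec.LineageDesign(time_points=(10.0, 84.0), animals_per_time=(3, 3),
                             target_clones_per_time=(250, 250)),
            rng,
        )
        obs = bin_clone_sizes(clones)
        r_grid = np.arange(0.06, 0.151, 0.02)
        rho_grid = np.arange(0.45, 0.86, 0.10)
        fit = mle_grid_search(obs, 2.9, eso_params.cycle,
                              r_grid=r_grid, rho_grid=rho_grid, n_sim=4000, rng=22)
        i = int(np.argmin(np.abs(r_grid - 0.10)))
        j = int(np.argmin(np.abs(rho_grid - 0.65)))
        lmax = np.nanmax(fit.loglik)
        assert 2 * (lmax - fit.loglik[i, j]) < 3 * 5.99  # generous chi2_2 band
        g = fit.gamma_mle
        assert g == pytest.approx(fit.rho_mle * 2.9 / (1 - fit.rho_mle))
        assert fit.r_ci95[0] <= fit.r_mle <= fit.r_ci95[1]
        assert fit.rho_ci95[0] <= fit.rho_mle <= fit.rho_ci95[1]

    def test_boundary_truth_is_flagged(self, eso_params):
        rng = np.random.default_rng(23)
        clones = ec.generate_lineage_experiment(
            eso_params,
            ec.LineageDesign(time_points=(30.0,), animals_per_time=(2,),
                             target_clones_per_time=(150,)),
            rng,
        )
        obs = bin_clone_sizes(clones)
        with pytest.warns(UserWarning, match="boundary"):
            fit = mle_grid_search(obs, 2.9, eso_params.cycle,
                                  r_grid=[0.3, 0.4, 0.5], rho_grid=[0.6, 0.7],
                                  n_sim=2000, rng=24)
        assert fit.boundary_flag

    def test_invalid_grid_points_skipped(self, eso_params):
        obs = [ObservedCloneDistribution(10.0, 3, np.array([5, 3, 2]))]
        with pytest.warns(UserWarning, match="skipped"):
            fit = mle_grid_search(obs, 2.9, eso_params.cycle,
                                  r_grid=[0.1, 0.9], rho_grid=[0.5],
                                  n_sim=500, rng=25)
        assert np.isnan(fit.loglik[1, 0])
        with pytest.raises(InvalidParameterError):
            mle_grid_search(obs, 2.9, eso_params.cycle,
                            r_grid=[0.9], rho_grid=[0.5], n_sim=500, rng=26)


def test_gamma_cycles_narrow_early_distributions_then_converge(eso_params, eso_exp_params):
    """Realistic (gamma) cycle-time laws narrow the 10-day clone-size
    distribution relative to exponential cycles at the same division rate;
    by 180 days the scaled distributions coincide (variability in cycle
    times regresses toward the mean over many divisions)."""
    times = [10.0, 180.0]
    pg, dg, _ = ec.simulate_sp_counts(eso_params, 40_000, times, rng=27)
    pe, de, _ = ec.simulate_sp_counts(eso_exp_params, 40_000, times, rng=28)
    bg, be = pg + dg, pe + de

    g10 = bg[bg[:, 0] >= 1, 0].astype(float)
    e10 = be[be[:, 0] >= 1, 0].astype(float)
    assert g10.var() < e10.var()  # early-time narrowing

    from scipy import stats as ss

    def scaled_ks(col):
        g = bg[bg[:, col] >= 1, col] / bg[bg[:, col] >= 1, col].mean()
        e = be[be[:, col] >= 1, col] / be[be[:, col] >= 1, col].mean()
        return ss.ks_2samp(g, e).statistic

    ks10, ks180 = scaled_ks(0), scaled_ks(1)
    # by 180 d the two scaled laws agree down to the size-discreteness
    # granularity (single-size masses ~ 1/mean ~ 0.1), while at 10 d they
    # differ severalfold more
    assert ks180 < 0.1
    assert ks10 > 3 * ks180
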