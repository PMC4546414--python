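import warnings

import numpy as np
import pytest
from scipy.special import zeta

import semnetkit as sk
from semnetkit import degreefit as df
from semnetkit.degreefit import DegreeSample, FitError


def grid_search_alpha(values, k_min, step=0.001):
    """Independent brute-force likelihood oracle for the discrete power law."""
    grid = np.arange(1.01, 6.0, step)
    sum_logk = np.sum(np.log(values))
    ll = -len(values) * np.log(zeta(grid, k_min)) - grid * sum_logk
    return grid[np.argmax(ll)]


class TestDegreeSample:
    def test_rejects_zeros_and_empties(self):
        with pytest.raises(ValueError):
            DegreeSample(np.array([0, 1, 2]))
        with pytest.raises(ValueError):
            DegreeSample(np.array([], dtype=int))

    def test_from_in_degrees_excludes_and_counts_zeros(self):
        net = sk.SemanticNetwork.from_edges([(0, 1), (2, 1), (1, 3)],
                                            nodes=range(5), directed=True)
        sample = DegreeSample.from_in_degrees(net)
        assert sorted(sample.values) == [1, 2]
        assert sample.n_zeros == 3


class TestSampling:
    def test_powerlaw_pmf_at_kmin(self):
        s = df.sample_family("powerlaw", (2.5,), 1, 100_000, seed=0)
        assert np.mean(s.values == 1) == pytest.approx(1 / zeta(2.5, 1), abs=0.01)

    def test_exponential_geometric_ratio(self):
        lam = 0.4
        p = df.pmf(np.array([3, 4, 5]), "exponential", (lam,), 1)
        assert p[1] / p[0] == pytest.approx(np.exp(-lam), abs=1e-12)
        assert p[2] / p[1] == pytest.approx(np.exp(-lam), abs=1e-12)

    def test_deterministic_per_seed(self):
        a = df.sample_family("truncated", (2.0, 0.1), 3, 500, seed=9)
        b = df.sample_family("truncated", (2.0, 0.1), 3, 500, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            df.sample_family("powerlaw", (0.9,), 1, 10, seed=0)
        with pytest.raises(ValueError):
            df.sample_family("exponential", (-1.0,), 1, 10, seed=0)

    @pytest.mark.parametrize("family,params", [
        ("powerlaw", (2.5,)),
        ("truncated", (1.8, 0.05)),
        ("exponential", (0.3,)),
    ])
    def test_pmf_normalized(self, family, params):
        k = np.arange(2, 500_000)
        total = df.pmf(k, family, params, 2).sum()
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_finite_support_pmf_normalized(self):
        k = np.arange(1, 35)
        for family, params in [("powerlaw", (1.5,)), ("truncated", (0.5, 0.2)),
                               ("exponential", (0.12,))]:
            assert df.pmf(k, family, params, 1, k_max=34).sum() == pytest.approx(
                1.0, abs=1e-9)


class TestMLE:
    def test_powerlaw_matches_grid_oracle(self):
        s = df.sample_family("powerlaw", (2.5,), 5, 10_000, seed=3)
        fit = df.fit_family(s, "powerlaw", 5)
        oracle = grid_search_alpha(s.tail(5), 5)
        assert abs(fit.alpha - oracle) <= 0.0011
        assert abs(fit.alpha - 2.5) < 0.1

    @pytest.mark.parametrize("alpha,seed", [(1.8, 0), (2.2, 1), (3.5, 2)])
    def test_grid_oracle_parity_across_fixtures(self, alpha, seed):
        s = df.sample_family("powerlaw", (alpha,), 2, 4000, seed=seed)
        fit = df.fit_family(s, "powerlaw", 2)
        assert abs(fit.alpha - grid_search_alpha(s.tail(2), 2)) <= 0.0011

    def test_truncated_recovers_parameters(self):
        s = df.sample_family("truncated", (2.0, 0.05), 5, 20_000, seed=4)
        fit = df.fit_family(s, "truncated", 5)
        assert fit.alpha == pytest.approx(2.0, abs=0.25)
        assert fit.lam == pytest.approx(0.05, abs=0.03)

    def test_truncated_lambda_zero_reduces_to_powerlaw(self):
        k = np.array([5, 7, 20, 100, 1000])
        lp_t = df.logpmf(k, "truncated", (2.5, 0.0), 5)
        lp_p = df.logpmf(k, "powerlaw", (2.5,), 5)
        np.testing.assert_allclose(lp_t, lp_p, atol=1e-6)

    def test_exponential_closed_form(self):
        s = df.sample_family("exponential", (0.25,), 1, 20_000, seed=5)
        fit = df.fit_family(s, "exponential", 1)
        v = s.tail(1)
        expected = np.log1p(1.0 / (v.mean() - 1))
        assert fit.lam == pytest.approx(expected, abs=1e-9)
        assert fit.lam == pytest.approx(0.25, abs=0.02)

    def test_degenerate_sample_errors(self):
        with pytest.raises(FitError):
            df.fit_family(DegreeSample(np.full(50, 7)), "powerlaw", 7)

    def test_too_few_points_errors(self):
        with pytest.raises(FitError):
            df.fit_family(DegreeSample(np.array([2, 3, 4])), "powerlaw", 2)

    def test_ks_zero_for_identical_cdfs(self):
        # empirical distribution equal to the fitted one on a tiny support
        values = np.repeat([1, 2], [80, 20])
        lam = np.log(4.0)  # pmf on {1,2}: (0.8, 0.2)
        d = df.ks_distance(values, "exponential", (lam,), 1, k_max=2)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_truncated_normalization_accuracy_small_lambda(self):
        import mpmath
        for lam, alpha in [(1e-6, 1.8), (5e-5, 2.5), (1e-4, 0.5)]:
            z = df._truncated_Z(alpha, lam, 5, None)
            ref = float(mpmath.exp(-lam * 5)
                        * mpmath.lerchphi(mpmath.exp(-lam), alpha, 5))
            assert z == pytest.approx(ref, rel=1e-10)


class TestScanKmin:
    def test_pure_powerlaw_picks_low_kmin(self):
        picks = []
        for seed in range(10):
            s = df.sample_family("powerlaw", (2.5,), 1, 5000, seed=seed)
            picks.append(df.scan_kmin(s, kmin_max=50)[0])
        assert np.median(picks) <= 3

    def test_composite_picks_near_breakpoint(self):
        picks = []
        for seed in range(10):
            head = df.sample_family("exponential", (0.3,), 1, 6000,
                                    seed=seed, k_max=9).values
            tail = df.sample_family("powerlaw", (2.5,), 10, 4000,
                                    seed=seed + 100).values
            s = DegreeSample(np.concatenate([head, tail]))
            picks.append(df.scan_kmin(s, kmin_max=50)[0])
        assert abs(np.median(picks) - 10) <= 3

    def test_kmin_cap_respected(self):
        s = df.sample_family("powerlaw", (2.5,), 1, 5000, seed=1)
        k, _ = df.scan_kmin(s, kmin_max=5)
        assert k <= 5

    def test_no_usable_tail_errors(self):
        with pytest.raises(FitError):
            df.scan_kmin(DegreeSample(np.array([1] * 5 + [2] * 4)), kmin_max=50)


class TestGofBootstrap:
    def test_p_in_unit_interval(self):
        s = df.sample_family("powerlaw", (2.5,), 2, 500, seed=0)
        k, fit = df.scan_kmin(s, kmin_max=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = df.gof_bootstrap(s, fit, n_sets=30, seed=0, kmin_max=5)
        assert 0.0 <= p <= 1.0

    def test_null_data_not_rejected_on_average(self):
        ps = []
        for seed in range(20):
            s = df.sample_family("powerlaw", (2.5,), 3, 400, seed=seed)
            _, fit = df.scan_kmin(s, kmin_max=8)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ps.append(df.gof_bootstrap(s, fit, n_sets=40, seed=seed, kmin_max=8))
        assert 0.35 <= np.mean(ps) <= 0.65

    def test_exponential_data_rejected(self):
        s = df.sample_family("exponential", (0.4,), 1, 2000, seed=0)
        _, fit = df.scan_kmin(s, kmin_max=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = df.gof_bootstrap(s, fit, n_sets=60, seed=0, kmin_max=8)
        assert p < 0.1

    def test_small_n_sets_warns(self):
        s = df.sample_family("powerlaw", (2.5,), 2, 300, seed=2)
        _, fit = df.scan_kmin(s, kmin_max=4)
        with pytest.warns(UserWarning, match="n_sets"):
            df.gof_bootstrap(s, fit, n_sets=10, seed=0, kmin_max=4)


class TestCvSelect:
    def test_exponential_data_selects_exponential(self):
        wins = 0
        for seed in range(5):
            s = df.sample_family("exponential", (0.3,), 5, 10_000, seed=seed)
            sel, _ = df.cv_select(s, 5, folds=10, seed=seed)
            wins += sel == "exponential"
        assert wins >= 4

    def test_powerlaw_data_never_selects_exponential(self):
        for seed in range(3):
            s = df.sample_family("powerlaw", (2.5,), 5, 10_000, seed=seed)
            sel, means = df.cv_select(s, 5, folds=10, seed=seed)
            assert sel in ("powerlaw", "truncated")
            assert means["exponential"] < max(means["powerlaw"], means["truncated"])

    def test_truncated_beats_powerlaw_on_truncated_data(self):
        wins = 0
        for seed in range(5):
            s = df.sample_family("truncated", (2.0, 0.05), 5, 10_000, seed=seed)
            _, means = df.cv_select(s, 5, folds=10, seed=seed)
            wins += means["truncated"] > means["powerlaw"]
        assert wins >= 4

    def test_deterministic(self):
        s = df.sample_family("truncated", (2.0, 0.1), 3, 2000, seed=7)
        assert df.cv_select(s, 3, folds=5, seed=1) == df.cv_select(s, 3, folds=5, seed=1)


class TestFitBelowKmin:
    def test_geometric_head_recovery(self):
        s = df.sample_family("exponential", (0.12,), 1, 5000, seed=0, k_max=34)
        selected, fits, _ = df.fit_below_kmin(s, 35, seed=0)
        assert selected == "exponential"
        assert 0.10 <= fits["exponential"].lam <= 0.14

    def test_powerlaw_head_prefers_powerlaw(self):
        s = df.sample_family("powerlaw", (2.0,), 1, 8000, seed=1, k_max=34)
        selected, fits, means = df.fit_below_kmin(s, 35, seed=1)
        assert means["powerlaw"] >= means["exponential"]

    def test_head_cdf_mass_sums_to_one(self):
        s = df.sample_family("exponential", (0.12,), 1, 5000, seed=0, k_max=34)
        _, fits, _ = df.fit_below_kmin(s, 35, seed=0)
        k = np.arange(1, 35)
        for fam, fit in fits.items():
            assert df.pmf(k, fam, fit.params, 1, k_max=34).sum() == pytest.approx(
                1.0, abs=1e-9)

    def test_empty_head_errors(self):
        s = df.sample_family("powerlaw", (2.5,), 50, 200, seed=0)
        with pytest.raises(FitError):
            df.fit_below_kmin(s, 35)
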