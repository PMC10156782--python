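"""Power-law MLE, crossover fit, simple slopes, bootstrap, exponent relation."""

import numpy as np
import pytest

from avakit.avalanche import AvalancheTable
from avakit.scaling import (
    SizeDurationTable,
    bootstrap_scaling,
    chi_simple,
    detect_cutoff,
    exponent_relation,
    fit_powerlaw_exponent,
    fit_scaling_crossover,
    mean_size_vs_duration,
    select_fit_window,
)


def _draw_discrete_powerlaw(alpha, lo, hi, n, rng):
    support = np.arange(lo, hi + 1)
    p = support**-float(alpha)
    p /= p.sum()
    return rng.choice(support, size=n, p=p)


def _table(durations, sizes):
    return SizeDurationTable(
        durations=np.asarray(durations, dtype=float),
        mean_size=np.asarray(sizes, dtype=float),
        count=np.full(len(durations), 100),
        sd=np.zeros(len(durations)),
    )


def _crossover(d, C, sh, lg, Phi, gamma=4.0):
    return C * d**sh / (1 + (d / Phi) ** gamma) ** ((sh - lg) / gamma)


class TestPowerlawMLE:
    def test_known_exponent_recovered(self, rng):
        x = _draw_discrete_powerlaw(1.5, 1, 1000, 100_000, rng)
        fit = fit_powerlaw_exponent(x, x_min=1, x_max=1000)
        assert fit.exponent == pytest.approx(1.5, abs=0.03)
        assert fit.uncertainty < 0.01

    @pytest.mark.parametrize("alpha", [1.0, 2.5])
    def test_other_exponents(self, alpha, rng):
        x = _draw_discrete_powerlaw(alpha, 1, 500, 50_000, rng)
        fit = fit_powerlaw_exponent(x, x_min=1, x_max=500)
        assert fit.exponent == pytest.approx(alpha, abs=0.05)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_powerlaw_exponent(np.full(500, 7.0), x_min=1, x_max=100)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="need"):
            fit_powerlaw_exponent(rng.integers(1, 50, 30), x_min=1, x_max=50)

    def test_continuous_branch_on_wide_support(self, rng):
        # inverse-transform draws from a continuous power law on a wide range
        u = rng.random(100_000)
        lo, hi, alpha = 10.0, 1e7, 1.5
        a = 1 - alpha
        x = (lo**a + u * (hi**a - lo**a)) ** (1 / a)
        fit = fit_powerlaw_exponent(x, x_min=lo, x_max=hi)
        assert fit.estimator == "continuous-truncated-mle"
        assert fit.exponent == pytest.approx(1.5, abs=0.03)

    def test_cutoff_detector_on_planted_pileup(self, rng):
        """A hard pileup at the tail is located and the fit limit set well below it."""
        x = _draw_discrete_powerlaw(1.5, 1, 2000, 80_000, rng)
        pile = np.full(4000, 2000)  # finite-size pileup at x = 2000
        cut = detect_cutoff(np.concatenate([x, pile]), x_min=1)
        assert cut < 1000

    def test_ks_window_selection_on_clean_powerlaw(self, rng):
        x = _draw_discrete_powerlaw(1.5, 1, 3000, 100_000, rng)
        fit = select_fit_window(x)
        assert fit.exponent == pytest.approx(1.5, abs=0.08)


class TestMeanSizeVsDuration:
    def test_group_means(self):
        table = AvalancheTable(
            sizes=np.array([2, 4, 9.0]),
            durations=np.array([1, 1, 2]),
            k=1,
            offsets=0,
            start_bins=np.zeros(3, dtype=int),
        )
        sd = mean_size_vs_duration(table)
        assert np.array_equal(sd.durations, [1, 2])
        assert np.array_equal(sd.mean_size, [3, 9])
        assert np.array_equal(sd.count, [2, 1])

    def test_filter_count(self):
        sd = SizeDurationTable(
            durations=np.array([1.0, 2.0]),
            mean_size=np.array([1.0, 4.0]),
            count=np.array([50, 2]),
            sd=np.zeros(2),
        )
        assert np.array_equal(sd.filter_count(10).durations, [1.0])


class TestCrossoverFit:
    def test_noiseless_self_consistency(self):
        d = np.unique(np.round(np.geomspace(1, 1000, 60)))
        table = _table(d, _crossover(d, C=1.0, sh=2.0, lg=1.0, Phi=50.0))
        fit = fit_scaling_crossover(table)
        assert fit.chi_sh == pytest.approx(2.0, abs=1e-3)
        assert fit.chi_lg == pytest.approx(1.0, abs=1e-3)
        assert fit.Phi == pytest.approx(50.0, rel=1e-3)
        assert fit.C == pytest.approx(1.0, rel=1e-2)

    def test_single_powerlaw_limit(self):
        d = np.unique(np.round(np.geomspace(1, 100, 30)))
        table = _table(d, d**1.5)
        fit = fit_scaling_crossover(table)
        assert fit.chi_sh == pytest.approx(1.5, abs=0.02)

    @pytest.mark.parametrize("sh,lg,Phi", [(2.0, 1.0, 20.0), (1.5, 0.5, 50.0), (2.5, 1.2, 10.0)])
    def test_noisy_parameter_recovery_unbiased(self, sh, lg, Phi, rng):
        d = np.unique(np.round(np.geomspace(1, 500, 50)))
        estimates = []
        for _ in range(10):
            s = _crossover(d, 2.0, sh, lg, Phi) * np.exp(rng.normal(0, 0.03, d.size))
            fit = fit_scaling_crossover(_table(d, s))
            estimates.append((fit.chi_sh, fit.chi_lg))
        est = np.mean(estimates, axis=0)
        assert est[0] == pytest.approx(sh, abs=0.05)
        assert est[1] == pytest.approx(lg, abs=0.1)

    def test_size_rescaling_only_changes_C(self):
        d = np.unique(np.round(np.geomspace(1, 300, 40)))
        s = _crossover(d, 1.0, 2.0, 1.0, 30.0)
        f1 = fit_scaling_crossover(_table(d, s))
        f2 = fit_scaling_crossover(_table(d, 100.0 * s))
        assert f2.chi_sh == pytest.approx(f1.chi_sh, abs=1e-4)
        assert f2.chi_lg == pytest.approx(f1.chi_lg, abs=1e-4)
        assert f2.C == pytest.approx(100.0 * f1.C, rel=1e-3)


class TestChiSimple:
    def test_quadratic_table(self):
        d = np.arange(1, 21, dtype=float)
        assert chi_simple(_table(d, d**2)) == pytest.approx((2.0, 2.0))

    def test_long_range_only(self):
        d = np.arange(10, 40, dtype=float)
        sh, lg = chi_simple(_table(d, d))
        assert np.isnan(sh)
        assert lg == pytest.approx(1.0)

    def test_matches_crossover_on_sharp_piecewise(self):
        """Piecewise power law with a crossover at L = 7: both estimators agree."""
        d = np.arange(1, 60, dtype=float)
        s = np.where(d <= 7, d**2.0, 7.0**2 * (d / 7.0) ** 1.0)
        sh, lg = chi_simple(_table(d, s))
        assert sh == pytest.approx(2.0, abs=1e-6)
        assert lg == pytest.approx(1.0, abs=1e-6)
        fit = fit_scaling_crossover(_table(d, s), gamma=8.0)  # sharp transition
        assert fit.chi_sh == pytest.approx(2.0, abs=0.1)
        assert fit.chi_lg == pytest.approx(1.0, abs=0.1)


class TestBootstrap:
    def _pool(self, rng, n=400):
        durations = rng.integers(1, 30, n)
        sizes = durations**2.0 * np.exp(rng.normal(0, 0.2, n))
        return AvalancheTable(
            sizes=sizes, durations=durations, k=1, offsets=0,
            start_bins=np.zeros(n, dtype=int),
        )

    def test_identical_pool_zero_sd(self):
        table = AvalancheTable(
            sizes=np.full(200, 8.0), durations=np.full(200, 2), k=1, offsets=0,
            start_bins=np.zeros(200, dtype=int),
        )
        boot = bootstrap_scaling(table, n_reps=5, seed=0, method="simple")
        assert boot.sd_chi_sh == 0.0 or np.isnan(boot.sd_chi_sh)

    def test_replicate_count_and_sd_shrinks_with_pool_size(self, rng):
        small = bootstrap_scaling(self._pool(rng, 200), n_reps=10, seed=1, method="simple")
        large = bootstrap_scaling(self._pool(rng, 3200), n_reps=10, seed=1, method="simple")
        assert small.chi_sh_reps.size == 10
        assert large.sd_chi_sh < small.sd_chi_sh


class TestExponentRelation:
    def test_reference_values(self):
        assert exponent_relation(1.5, 2.0).ratio == pytest.approx(2.0)
        assert exponent_relation(2.0, 2.0).ratio == pytest.approx(1.0)

    def test_singularity_guard(self):
        with pytest.warns(UserWarning, match="singularity"):
            rel = exponent_relation(1.01, 2.0)
        assert rel.unstable
        with pytest.raises(ZeroDivisionError):
            exponent_relation(1.0, 2.0)
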