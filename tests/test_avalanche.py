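"""Thresholding, coarse-graining ensemble, epoch extraction, threshold selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import lognorm

from avalanche_series_oracle import scan_runs_oracle
from avakit.avalanche import (
    ThresholdPolicy,
    apply_threshold,
    coarse_grain,
    detect,
    extract_avalanches,
    fit_epoch_count_curve,
    select_threshold,
)


class TestApplyThreshold:
    def test_hard_and_soft_on_example(self):
        p = np.array([0, 3, 1, 0, 5.0])
        assert np.array_equal(apply_threshold(p, ThresholdPolicy("hard", 1)), [0, 3, 0, 0, 5])
        assert np.array_equal(apply_threshold(p, ThresholdPolicy("soft", 1)), [0, 2, 0, 0, 4])

    def test_integer_counts_theta_one_requires_two_spikes(self):
        counts = np.array([0, 1, 2, 3, 1.0])
        out = apply_threshold(counts, ThresholdPolicy("hard", 1))
        assert np.array_equal(out > 0, [False, False, True, True, False])

    def test_theta_zero_keeps_positive_bins(self, rng):
        p = rng.poisson(1.0, 100).astype(float)
        assert np.array_equal(apply_threshold(p, ThresholdPolicy("hard", 0)), p)

    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_soft_never_exceeds_hard(self, seed, theta):
        p = np.random.default_rng(seed).poisson(2.0, 50).astype(float)
        hard = apply_threshold(p, ThresholdPolicy("hard", theta))
        soft = apply_threshold(p, ThresholdPolicy("soft", theta))
        assert np.all(soft <= hard)
        if theta == 0:
            assert np.array_equal(soft, hard)


class TestCoarseGrain:
    def test_k1_identity(self, rng):
        p = rng.random(37)
        ens = coarse_grain(p, 1)
        assert len(ens.series) == 1
        assert np.array_equal(ens.series[0], p)

    def test_hand_example_with_truncation(self):
        ens = coarse_grain(np.array([1, 2, 3, 4.0]), 2)
        assert np.array_equal(ens.series[0], [3, 7])
        assert np.array_equal(ens.series[1], [5])  # trailing incomplete window dropped

    @given(st.integers(0, 2**32 - 1), st.integers(1, 10))
    @settings(max_examples=40, deadline=None)
    def test_mass_conservation_up_to_truncation(self, seed, k):
        p = np.random.default_rng(seed).poisson(2.0, 60).astype(float)
        total = p.sum()
        for j, series in enumerate(coarse_grain(p, k)):
            assert series.sum() <= total + 1e-9
            if (p.size - j) % k == 0:
                assert series.sum() == pytest.approx(p[j:].sum())

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            coarse_grain(np.ones(4), 5)


class TestExtractAvalanches:
    def test_duration_formula_on_example(self):
        table = extract_avalanches(np.array([0, 2, 3, 0.0]))
        assert len(table) == 1
        assert table.sizes[0] == 5 and table.durations[0] == 2

    def test_all_zero_series(self):
        assert len(extract_avalanches(np.zeros(10))) == 0

    def test_boundary_runs_discarded(self):
        table = extract_avalanches(np.array([1, 1, 0, 2, 0, 3.0]))
        assert len(table) == 1 and table.sizes[0] == 2

    def test_matches_independent_scan_oracle(self, rng):
        series = rng.poisson(0.5, 10_000).astype(float)
        table = extract_avalanches(series)
        expected = scan_runs_oracle(series)
        got = sorted(zip(table.sizes, table.durations))
        assert got == sorted(expected)

    def test_interior_mass_conserved(self, rng):
        """Sum of avalanche sizes equals the mass of all interior positive runs."""
        series = rng.poisson(0.7, 5000).astype(float)
        table = extract_avalanches(series)
        expected = sum(s for s, _ in scan_runs_oracle(series))
        assert table.sizes.sum() == pytest.approx(expected)


class TestThresholdSelection:
    def test_lognormal_curve_recovery(self, rng):
        """Self-consistency: counts generated from the model are refit within 5%."""
        grid = np.geomspace(0.5, 200, 120)
        mu, sigma, amp = 2.0, 0.5, 5000.0
        counts = amp * lognorm.pdf(grid, s=sigma, scale=np.exp(mu))
        counts *= 1 + rng.normal(0, 0.01, grid.size)
        _, mu_fit, sigma_fit, ok = fit_epoch_count_curve(grid, counts)
        assert ok
        assert mu_fit == pytest.approx(mu, rel=0.05)
        assert sigma_fit == pytest.approx(sigma, rel=0.05)

    def test_grid_endpoints_behavior(self, rng):
        p = rng.poisson(3.0, 4000).astype(float)
        sel = select_threshold(p, k=1)
        zero_thresh = len(extract_avalanches(p))
        assert sel.epoch_counts[0] == zero_thresh  # bottom of grid removes nothing
        assert sel.epoch_counts[-1] == 0  # top removes everything

    def test_scale_equivariance(self, rng):
        p = rng.lognormal(1.0, 1.0, 5000)
        p[rng.random(5000) < 0.3] = 0.0
        t1 = select_threshold(p, k=1).theta_star
        t2 = select_threshold(4.0 * p, k=1).theta_star
        assert t2 / t1 == pytest.approx(4.0, rel=0.15)


class TestDetect:
    def test_k1_pooling_noop(self, rng):
        p = rng.poisson(1.0, 500).astype(float)
        policy = ThresholdPolicy("hard", 1.0)
        pooled = detect(p, k=1, policy=policy)
        direct = extract_avalanches(apply_threshold(p, policy))
        assert np.array_equal(np.sort(pooled.sizes), np.sort(direct.sizes))

    def test_planted_epoch_across_offsets(self):
        """A 6-bin epoch at k=2 appears once per offset with identical total size.

        The epoch cannot align with both phase offsets simultaneously, so its coarse
        duration is 3 for the aligned offset and 4 for the misaligned one, while the
        summed size is identical (complete windows cover the epoch in both phases).
        """
        p = np.zeros(40)
        p[11:17] = [2, 3, 4, 4, 3, 2.0]  # start at an odd bin
        table = detect(p, k=2, policy=ThresholdPolicy("hard", 0.0))
        assert len(table) == 2
        assert set(table.durations) == {3, 4}
        assert np.allclose(table.sizes, 18.0)

    def test_epoch_merge_under_coarse_graining(self):
        """Two epochs split by one subthreshold bin merge at k = 2 for some offset."""
        p = np.zeros(20)
        p[5:8] = 3.0
        p[9:12] = 3.0  # single empty bin at index 8
        at_k1 = detect(p, k=1, policy=ThresholdPolicy("hard", 0.0))
        assert len(at_k1) == 2
        at_k2 = detect(p, k=2, policy=ThresholdPolicy("hard", 0.0))
        merged = at_k2.select(at_k2.sizes == 18.0)
        assert len(merged) >= 1

    def test_count_decreases_with_theta(self, critical_subsampled):
        p = critical_subsampled.sampled_counts.astype(float)[:200_000]
        counts = [
            len(detect(p, k=3, policy=ThresholdPolicy("hard", th))) for th in (1.0, 2.0, 4.0)
        ]
        assert counts[0] > counts[1] > counts[2]

    def test_deterministic(self, rng):
        p = rng.poisson(1.0, 1000).astype(float)
        a = detect(p, k=3, policy=ThresholdPolicy("hard", 1.0)).to_frame()
        b = detect(p, k=3, policy=ThresholdPolicy("hard", 1.0)).to_frame()
        assert a.equals(b)
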