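"""Raster data model, population activity, correlation-based cell removal, toy generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avakit.raster import (
    PlantedEpoch,
    SpikeRaster,
    TrialTable,
    make_toy_raster,
    parabolic_envelope,
    population_activity,
    population_correlation_z,
    remove_uncorrelated,
)
from avakit.raster import _pearson_all_circular_shifts


def _raster(values, dt=0.022):
    return SpikeRaster(values=np.asarray(values, dtype=float), dt=dt)


class TestPopulationActivity:
    @pytest.mark.parametrize(
        "values, expected",
        [
            (np.zeros((3, 4)), [0, 0, 0, 0]),
            ([[1, 0], [2, 3]], [3, 3]),
        ],
    )
    def test_column_sums(self, values, expected):
        assert np.array_equal(population_activity(_raster(values)).p, expected)

    def test_matches_per_bin_summation_oracle(self, rng):
        values = rng.random((50, 1000))
        p = population_activity(_raster(values)).p
        brute = np.array([sum(values[i, t] for i in range(50)) for t in range(1000)])
        assert np.allclose(p, brute, rtol=0, atol=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.random((4, 30)), r.random((4, 30))
        pa = population_activity(_raster(a)).p
        pb = population_activity(_raster(b)).p
        pab = population_activity(_raster(a + b)).p
        assert np.allclose(pab, pa + pb)

    def test_invalid_raster_rejected(self):
        with pytest.raises(ValueError):
            SpikeRaster(values=np.zeros((0, 5)), dt=0.022)
        with pytest.raises(ValueError):
            SpikeRaster(values=-np.ones((2, 2)), dt=0.022)
        with pytest.raises(ValueError):
            SpikeRaster(values=np.ones((2, 2)), dt=0.0)


class TestCircularShiftPearson:
    def test_fft_matches_direct_roll(self, rng):
        r = rng.poisson(2.0, 400).astype(float)
        q = rng.poisson(3.0, 400).astype(float) + 0.3 * r
        rho = _pearson_all_circular_shifts(r, q)
        for tau in (-100, -3, 0, 1, 57):
            direct = np.corrcoef(np.roll(r, tau), q)[0, 1]
            assert rho[tau % 400] == pytest.approx(direct, abs=1e-10)


class TestPopulationCorrelationZ:
    def test_coupled_pair_retained(self, rng):
        drive = rng.poisson(5.0, 1000).astype(float)
        cells = [drive, drive.copy()]
        cells += [rng.poisson(5.0, 1000) * 0.01 + 5.0 for _ in range(20)]
        raster = _raster(np.array(cells))
        report = population_correlation_z(raster, max_shift=100)
        assert report.z[0] > 1.0 and report.z[1] > 1.0
        assert not report.removed[0] and not report.removed[1]

    def test_independent_cell_z_near_zero(self, rng):
        """An independent Poisson train has z statistically indistinguishable from 0."""
        zs = []
        for _ in range(40):
            shared = rng.poisson(4.0, 600).astype(float)
            cells = np.vstack(
                [shared + rng.poisson(1.0, 600) for _ in range(8)]
                + [rng.poisson(5.0, 600).astype(float)]  # the independent cell
            )
            report = population_correlation_z(_raster(cells), max_shift=50)
            zs.append(report.z[-1])
        zs = np.asarray(zs)
        assert abs(np.mean(zs)) < 0.5  # mean |z| small
        below = np.mean(zs < 0.01)
        assert 0.2 < below < 0.8  # about half of repeats fall below the removal cut

    def test_constant_cell_flagged_with_warning(self, rng):
        cells = np.vstack([rng.poisson(3.0, 300) for _ in range(3)] + [np.full(300, 2.0)])
        with pytest.warns(UserWarning, match="zero variance"):
            report = population_correlation_z(_raster(cells), max_shift=50)
        assert report.removed[-1]
        assert np.isnan(report.z[-1])

    def test_permutation_equivariance(self, rng):
        values = rng.poisson(3.0, (6, 500)).astype(float)
        perm = rng.permutation(6)
        z0 = population_correlation_z(_raster(values), max_shift=40).z
        z1 = population_correlation_z(_raster(values[perm]), max_shift=40).z
        assert np.allclose(z1, z0[perm], equal_nan=True)


class TestRemoveUncorrelated:
    def test_identity_and_selection(self, rng):
        values = rng.poisson(2.0, (4, 200)).astype(float)
        raster = _raster(values)
        report = population_correlation_z(raster, max_shift=30)
        report.removed[:] = False
        assert np.array_equal(remove_uncorrelated(raster, report).values, values)
        report.removed[:] = [True, False, True, False]
        kept = remove_uncorrelated(raster, report)
        assert np.array_equal(kept.values, values[[1, 3]])
        report.removed[:] = True
        with pytest.raises(ValueError, match="all cells"):
            remove_uncorrelated(raster, report)

    def test_planted_independent_cells_recovered(self):
        """Planted fraction of independent cells is removed, within the planted range."""
        rng = np.random.default_rng(5)
        n_corr, n_indep = 40, 12  # 23% independent
        shared = rng.poisson(3.0, 3000).astype(float)
        cells = [shared + rng.poisson(0.5, 3000) for _ in range(n_corr)]
        cells += [rng.poisson(3.5, 3000).astype(float) for _ in range(n_indep)]
        report = population_correlation_z(_raster(np.vstack(cells)), max_shift=100)
        removed_frac = report.removed.mean()
        assert 0.10 <= removed_frac <= 0.35
        # the removals concentrate on the planted independent cells
        assert report.removed[n_corr:].mean() > report.removed[:n_corr].mean()


class TestToyRaster:
    def test_planted_epoch_only_activity(self):
        epoch = PlantedEpoch(start=10, envelope=parabolic_envelope(6, 12.0))
        raster = make_toy_raster(5, 50, background_rate=0.0, planted_epochs=[epoch], seed=0)
        p = population_activity(raster).p
        assert np.all(p[:10] == 0) and np.all(p[16:] == 0)
        assert p[10:16].sum() == pytest.approx(np.round(epoch.envelope).sum())

    def test_zero_correlation_knob(self):
        rng = np.random.default_rng(2)
        cors = []
        for seed in range(5):
            raster = make_toy_raster(20, 2000, background_rate=1.0, correlation=0.0, seed=seed)
            c = np.corrcoef(raster.values)
            cors.append(c[np.triu_indices(20, 1)].mean())
        assert abs(np.mean(cors)) < 0.01

    def test_correlation_knob_sets_pairwise_correlation(self):
        raster = make_toy_raster(30, 20000, background_rate=2.0, correlation=0.4, seed=3)
        c = np.corrcoef(raster.values)
        mean_c = c[np.triu_indices(30, 1)].mean()
        assert mean_c == pytest.approx(0.4, abs=0.05)

    def test_out_of_bounds_epoch_rejected(self):
        with pytest.raises(ValueError):
            make_toy_raster(3, 10, planted_epochs=[PlantedEpoch(8, np.ones(5))])


class TestTrialTable:
    def test_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            TrialTable(conditions=["a", "a"], starts=[0, 5], ends=[6, 10])
        table = TrialTable(conditions=["a", "b"], starts=[0, 10], ends=[5, 15])
        with pytest.raises(ValueError, match="beyond"):
            table.validate_bounds(12)
        table.validate_bounds(15)
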