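"""Spike-density raster data model, population activity, and correlation-based cell selection.

The raster is the common currency of the package: an ``n_cells x n_bins`` matrix of
nonnegative spike densities (deconvolved spike counts or spike-probability mass per
imaging frame) with a known bin width ``dt``.  Population activity is the per-bin sum
over cells and is the series on which avalanches are defined.

Weakly population-coupled cells can be identified and removed by z-scoring each
cell's Pearson correlation with the rest of the population against a circular-shift
null, a standard control for spurious coupling in calcium-imaging rasters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeRaster",
    "PopulationActivity",
    "CellCorrelationReport",
    "TrialTable",
    "PlantedEpoch",
    "population_activity",
    "population_correlation_z",
    "remove_uncorrelated",
    "make_toy_raster",
    "parabolic_envelope",
]


@dataclass
class SpikeRaster:
    """A neurons-by-time matrix of nonnegative spike densities.

    Parameters
    ----------
    values
        Array of shape ``(n_cells, n_bins)``; entries are spikes (or spike-probability
        mass) per bin and must be nonnegative.
    dt
        Seconds per time bin (e.g. 0.022 for a 45.5 Hz frame rate).
    cell_ids
        Opaque per-cell labels; generated as ``c0000 ...`` when omitted.
    cell_type
        Optional per-cell ``"E"``/``"I"`` tag (populated by the network simulator).
    """

    values: np.ndarray
    dt: float
    cell_ids: list[str] = field(default=None)  # type: ignore[assignment]
    cell_type: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D (n_cells, n_bins) array")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("raster must contain at least one cell and one bin")
        if np.any(self.values < 0):
            raise ValueError("spike densities must be nonnegative")
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ValueError("dt must be a positive number of seconds")
        if self.cell_ids is None:
            self.cell_ids = [f"c{i:04d}" for i in range(self.n_cells)]
        if len(self.cell_ids) != self.n_cells:
            raise ValueError("cell_ids length must match the number of cells")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type)
            if self.cell_type.shape != (self.n_cells,):
                raise ValueError("cell_type must have one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def select_cells(self, index: np.ndarray | Sequence[int]) -> "SpikeRaster":
        """Return a raster restricted to the given cell indices (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        if index.size == 0:
            raise ValueError("cell selection is empty")
        return SpikeRaster(
            values=self.values[index].copy(),
            dt=self.dt,
            cell_ids=[self.cell_ids[i] for i in index],
            cell_type=None if self.cell_type is None else self.cell_type[index],
        )

    def with_values(self, values: np.ndarray) -> "SpikeRaster":
        """Return a copy of this raster with ``values`` replaced (same metadata)."""
        return replace(self, values=values)


@dataclass
class PopulationActivity:
    """Per-bin sum of spike densities over all cells of a raster."""

    p: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).ravel()
        if self.p.size < 1:
            raise ValueError("population activity must have at least one bin")
        if np.any(self.p < 0):
            raise ValueError("population activity must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.p.size


def population_activity(raster: SpikeRaster) -> PopulationActivity:
    """Sum spike densities over cells: ``p(t) = sum_i r_i(t)``."""
    return PopulationActivity(p=raster.values.sum(axis=0), dt=raster.dt)


@dataclass
class CellCorrelationReport:
    """Per-cell population coupling and its z-score against a circular-shift null.

    ``removed`` marks cells whose z-scored coupling falls below ``z_threshold``
    (cells with zero variance are always marked removed).
    """

    c: np.ndarray
    z: np.ndarray
    removed: np.ndarray
    null_shift_range: tuple[int, int]
    z_threshold: float


def _pearson_all_circular_shifts(r: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Pearson correlation of ``np.roll(r, tau)`` with ``q`` for every tau in one FFT.

    Returns an array ``rho`` of length ``len(r)`` with ``rho[tau % T]`` the correlation
    at forward circular shift ``tau``.  Means and standard deviations are invariant
    under rotation, so only the cross term depends on tau.
    """
    T = r.size
    rc = r - r.mean()
    qc = q - q.mean()
    denom = np.sqrt((rc @ rc) * (qc @ qc))
    if denom == 0:
        return np.full(T, np.nan)
    # sum_t roll(r, tau)[t] * q[t] = sum_u r[u] * q[(u + tau) % T]
    cross = np.fft.irfft(np.conj(np.fft.rfft(rc)) * np.fft.rfft(qc), n=T)
    return cross / denom


def population_correlation_z(
    raster: SpikeRaster,
    max_shift: int = 100,
    z_threshold: float = 0.01,
    include_zero_shift: bool = False,
    variance_denominator: bool = False,
) -> CellCorrelationReport:
    """z-score each cell's population coupling against a circular-shift null.

    For cell *i*, the coupling ``c_i`` is the Pearson correlation between ``r_i(t)``
    and the all-except-*i* population activity.  Null correlations are obtained by
    circularly shifting ``r_i`` by every ``tau`` in ``[-max_shift, max_shift]``;
    ``z_i`` standardizes ``c_i`` against this null distribution.

    Parameters
    ----------
    include_zero_shift
        Whether ``tau = 0`` enters the null.  Off by default: the unshifted
        correlation equals ``c_i`` itself and would bias the null upward.
    variance_denominator
        Divide by the null variance instead of its standard deviation.  The standard
        z-score (SD denominator) is the default.
    """
    T = raster.n_bins
    if T <= 2 * max_shift:
        raise ValueError("need n_bins > 2 * max_shift for a meaningful null")
    total = raster.values.sum(axis=0)
    taus = np.arange(-max_shift, max_shift + 1)
    if not include_zero_shift:
        taus = taus[taus != 0]

    n = raster.n_cells
    c = np.full(n, np.nan)
    z = np.full(n, np.nan)
    removed = np.zeros(n, dtype=bool)
    for i in range(n):
        r = raster.values[i]
        q = total - r  # all-except-i population activity
        if np.ptp(r) == 0 or np.ptp(q) == 0:
            warnings.warn(
                f"cell {raster.cell_ids[i]!r} has zero variance; correlation "
                "undefined, marking as removed",
                stacklevel=2,
            )
            removed[i] = True
            continue
        rho = _pearson_all_circular_shifts(r, q)
        c[i] = rho[0]
        null = rho[taus % T]
        spread = null.std()
        if variance_denominator:
            spread = spread**2
        z[i] = (c[i] - null.mean()) / spread
        removed[i] = z[i] < z_threshold
    return CellCorrelationReport(
        c=c,
        z=z,
        removed=removed,
        null_shift_range=(-max_shift, max_shift),
        z_threshold=z_threshold,
    )


def remove_uncorrelated(raster: SpikeRaster, report: CellCorrelationReport) -> SpikeRaster:
    """Drop the cells flagged by ``report``; cell order is preserved."""
    if report.removed.shape != (raster.n_cells,):
        raise ValueError("report does not match this raster")
    keep = np.flatnonzero(~report.removed)
    if keep.size == 0:
        raise ValueError("all cells were flagged as uncorrelated; nothing left")
    return raster.select_cells(keep)


@dataclass
class TrialTable:
    """Per-trial condition labels and half-open ``[start_bin, end_bin)`` intervals."""

    conditions: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.conditions = np.asarray(self.conditions)
        self.starts = np.asarray(self.starts, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        if not (self.conditions.size == self.starts.size == self.ends.size):
            raise ValueError("condition/start/end columns must have equal length")
        if np.any(self.ends <= self.starts) or np.any(self.starts < 0):
            raise ValueError("trial intervals must be nonempty with start_bin >= 0")
        order = np.argsort(self.starts, kind="stable")
        s, e = self.starts[order], self.ends[order]
        if np.any(s[1:] < e[:-1]):
            raise ValueError("trial intervals must not overlap")

    def __len__(self) -> int:
        return self.starts.size

    def validate_bounds(self, n_bins: int) -> None:
        if np.any(self.ends > n_bins):
            raise ValueError("trial intervals extend beyond the raster")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"condition": self.conditions, "start_bin": self.starts, "end_bin": self.ends}
        )


@dataclass
class PlantedEpoch:
    """A coincident-firing epoch to plant into a toy raster.

    ``envelope`` gives the target summed population activity for each bin of the
    epoch, starting at bin ``start``.
    """

    start: int
    envelope: np.ndarray

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float).ravel()
        if self.start < 0 or np.any(self.envelope < 0):
            raise ValueError("epoch start and envelope must be nonnegative")


def parabolic_envelope(duration: int, amplitude: float) -> np.ndarray:
    """Inverted parabola ``amplitude * 4 x (1 - x)`` sampled at bin centers."""
    x = (np.arange(duration) + 0.5) / duration
    return amplitude * 4.0 * x * (1.0 - x)


def make_toy_raster(
    n_cells: int,
    n_bins: int,
    background_rate: float = 0.01,
    planted_epochs: Sequence[PlantedEpoch] = (),
    correlation: float = 0.0,
    seed: int | None = None,
    dt: float = 0.022,
) -> SpikeRaster:
    """Poisson background plus planted coincident-firing epochs.

    The background is a correlated Poisson construction: a shared source of rate
    ``correlation * background_rate`` is added to every cell on top of independent
    Poisson counts of rate ``(1 - correlation) * background_rate``, which yields a
    pairwise zero-lag correlation of ``correlation`` exactly.  Planted epochs
    distribute ``round(envelope(t))`` unit spikes uniformly over cells, so the
    population activity inside an epoch follows the requested envelope.
    """
    if background_rate < 0:
        raise ValueError("background_rate must be nonnegative")
    if not 0.0 <= correlation <= 1.0:
        raise ValueError("correlation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    values = rng.poisson((1.0 - correlation) * background_rate, size=(n_cells, n_bins)).astype(
        float
    )
    if correlation > 0:
        shared = rng.poisson(correlation * background_rate, size=n_bins)
        values += shared[None, :]
    for epoch in planted_epochs:
        stop = epoch.start + epoch.envelope.size
        if stop > n_bins:
            raise ValueError("planted epoch extends beyond the raster")
        for t, amp in enumerate(epoch.envelope):
            count = int(round(amp))
            if count > 0:
                cells = rng.integers(0, n_cells, size=count)
                np.add.at(values[:, epoch.start + t], cells, 1.0)
    return SpikeRaster(values=values, dt=dt)
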