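"""Thresholding, temporal coarse-graining, and avalanche (epoch) extraction.

An avalanche is a maximal run of strictly suprathreshold population activity.  The
population activity is first thresholded at the original resolution:

* hard threshold: bins with ``p <= theta`` are zeroed, suprathreshold bins kept;
* soft threshold: suprathreshold bins are additionally reduced by ``theta``.

The thresholded series is then temporally coarse-grained with factor ``k``: for each
phase offset ``j in {0, ..., k-1}`` consecutive groups of ``k`` bins are summed,
giving an ensemble of ``k`` coarse series.  Coarse-graining compensates for spatial
subsampling: epochs that subsampling fragmented at the native resolution merge back
into single avalanches.  Epochs are extracted from every ensemble member and pooled.

The threshold itself can be selected per coarse-graining factor from the epoch-count
curve ``N(theta)``, which is typically well approximated by a lognormal shape; the
working threshold is ``exp(mu - 2*sigma)`` of the fitted log-location/scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .raster import PopulationActivity, SpikeRaster, population_activity

__all__ = [
    "ThresholdPolicy",
    "ThresholdSelection",
    "Avalanche",
    "AvalancheTable",
    "CoarseEnsemble",
    "apply_threshold",
    "coarse_grain",
    "extract_avalanches",
    "fit_epoch_count_curve",
    "select_threshold",
    "detect",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """How to threshold population activity: ``mode`` is ``"hard"`` or ``"soft"``."""

    mode: str = "hard"
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise ValueError("mode must be 'hard' or 'soft'")
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")


def _threshold_array(p: np.ndarray, policy: ThresholdPolicy) -> np.ndarray:
    out = np.where(p > policy.theta, p, 0.0)
    if policy.mode == "soft":
        out = np.where(out > 0, out - policy.theta, 0.0)
    return out


def apply_threshold(
    p: PopulationActivity | np.ndarray, policy: ThresholdPolicy
) -> PopulationActivity | np.ndarray:
    """Zero subthreshold bins; in soft mode also subtract theta from the survivors.

    Suprathreshold means strictly ``p > theta``.
    """
    if isinstance(p, PopulationActivity):
        return PopulationActivity(p=_threshold_array(p.p, policy), dt=p.dt)
    return _threshold_array(np.asarray(p, dtype=float), policy)


@dataclass
class CoarseEnsemble:
    """All ``k`` phase-offset coarse-grainings of one thresholded series."""

    k: int
    series: list[np.ndarray]

    def __iter__(self):
        return iter(self.series)


def coarse_grain(p_thr: PopulationActivity | np.ndarray, k: int) -> CoarseEnsemble:
    """Sum consecutive groups of ``k`` bins for every phase offset ``j``.

    Only complete windows are kept (a trailing partial window would bias its sum
    low).  ``k = 1`` returns the input as the sole ensemble member.
    """
    arr = p_thr.p if isinstance(p_thr, PopulationActivity) else np.asarray(p_thr, dtype=float)
    if k < 1:
        raise ValueError("coarse-graining factor k must be >= 1")
    if k > arr.size:
        raise ValueError("k exceeds the number of bins")
    series = []
    for j in range(k):
        n_win = (arr.size - j) // k
        series.append(arr[j : j + n_win * k].reshape(n_win, k).sum(axis=1))
    return CoarseEnsemble(k=k, series=series)


@dataclass(frozen=True)
class Avalanche:
    """One suprathreshold epoch at coarse resolution ``k * dt``."""

    size: float
    duration: int  # bins at resolution k*dt
    k: int
    offset: int
    start_bin: int  # 0-based start in the coarse series of this offset
    dt: float  # original (k = 1) bin width in seconds

    @property
    def duration_seconds(self) -> float:
        return self.duration * self.k * self.dt


class AvalancheTable:
    """Column-oriented collection of avalanches (sizes, durations, provenance).

    Backed by numpy arrays so that millions of epochs remain cheap; iterate to get
    :class:`Avalanche` records, or use :meth:`to_frame` for a DataFrame.
    """

    def __init__(
        self,
        sizes: np.ndarray,
        durations: np.ndarray,
        k: np.ndarray | int,
        offsets: np.ndarray | int,
        start_bins: np.ndarray,
        dt: float = 1.0,
    ):
        self.sizes = np.asarray(sizes, dtype=float)
        self.durations = np.asarray(durations, dtype=np.int64)
        n = self.sizes.size
        self.k = np.broadcast_to(np.asarray(k, dtype=np.int64), (n,)).copy()
        self.offsets = np.broadcast_to(np.asarray(offsets, dtype=np.int64), (n,)).copy()
        self.start_bins = np.asarray(start_bins, dtype=np.int64)
        self.dt = float(dt)
        if not (self.durations.size == self.start_bins.size == n):
            raise ValueError("column lengths differ")

    def __len__(self) -> int:
        return self.sizes.size

    def __iter__(self):
        for i in range(len(self)):
            yield Avalanche(
                size=float(self.sizes[i]),
                duration=int(self.durations[i]),
                k=int(self.k[i]),
                offset=int(self.offsets[i]),
                start_bin=int(self.start_bins[i]),
                dt=self.dt,
            )

    @property
    def duration_seconds(self) -> np.ndarray:
        return self.durations * self.k * self.dt

    def select(self, mask: np.ndarray) -> "AvalancheTable":
        return AvalancheTable(
            self.sizes[mask],
            self.durations[mask],
            self.k[mask],
            self.offsets[mask],
            self.start_bins[mask],
            dt=self.dt,
        )

    @classmethod
    def concat(cls, tables: list["AvalancheTable"]) -> "AvalancheTable":
        if not tables:
            return cls(np.array([]), np.array([], int), 1, 0, np.array([], int))
        dt = tables[0].dt
        return cls(
            np.concatenate([t.sizes for t in tables]),
            np.concatenate([t.durations for t in tables]),
            np.concatenate([t.k for t in tables]),
            np.concatenate([t.offsets for t in tables]),
            np.concatenate([t.start_bins for t in tables]),
            dt=dt,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "offset": self.offsets,
                "start_bin": self.start_bins,
                "duration_bins": self.durations,
                "size": self.sizes,
                "duration_seconds": self.duration_seconds,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dt: float = 1.0) -> "AvalancheTable":
        return cls(
            frame["size"].to_numpy(),
            frame["duration_bins"].to_numpy(),
            frame["k"].to_numpy(),
            frame["offset"].to_numpy(),
            frame["start_bin"].to_numpy(),
            dt=dt,
        )


def extract_avalanches(
    series: np.ndarray, k: int = 1, offset: int = 0, dt: float = 1.0
) -> AvalancheTable:
    """Maximal runs of strictly positive bins bounded by zero bins.

    Size is the summed activity over the run, duration the run length.  Runs touching
    either end of the series are discarded: their bounding zero is unobserved, so
    their true extent is unknown.
    """
    arr = np.asarray(series, dtype=float)
    if np.any(arr < 0):
        raise ValueError("series must be nonnegative")
    pos = arr > 0
    if arr.size == 0 or not pos.any():
        return AvalancheTable(np.array([]), np.array([], int), k, offset, np.array([], int), dt)
    edges = np.diff(pos.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if pos[0]:
        ends = ends[1:]  # run touching the left boundary
    if pos[-1]:
        starts = starts[:-1]  # run touching the right boundary
    if starts.size == 0:
        return AvalancheTable(np.array([]), np.array([], int), k, offset, np.array([], int), dt)
    cumsum = np.concatenate([[0.0], np.cumsum(arr)])
    sizes = cumsum[ends] - cumsum[starts]
    durations = ends - starts
    return AvalancheTable(sizes, durations, k, offset, starts, dt=dt)


@dataclass
class ThresholdSelection:
    """Epoch-count curve ``N(theta)`` and the lognormal-shaped fit used to pick theta."""

    theta_grid: np.ndarray
    epoch_counts: np.ndarray
    mu: float
    sigma: float
    theta_star: float
    converged: bool
    rule: str = "log"
    amplitude: float = np.nan


def _count_epochs(p_thr: np.ndarray, k: int) -> int:
    total = 0
    for series in coarse_grain(p_thr, k):
        pos = series > 0
        if not pos.any():
            continue
        edges = np.diff(pos.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if pos[0]:
            ends = ends[1:]
        if pos[-1]:
            starts = starts[:-1]
        total += starts.size
    return total


def fit_epoch_count_curve(
    theta_grid: np.ndarray, counts: np.ndarray
) -> tuple[float, float, float, bool]:
    """Fit ``A * lognormal_pdf(theta; mu, sigma)`` to an epoch-count curve N(theta).

    Returns ``(amplitude, mu, sigma, converged)``; on optimizer failure falls back to
    count-weighted log-moments with a warning.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    counts = np.asarray(counts, dtype=float)
    w = counts.clip(min=0)
    log_theta = np.log(theta_grid)
    if w.sum() > 0:
        mu0 = float(np.average(log_theta, weights=w))
        sigma0 = float(np.sqrt(np.average((log_theta - mu0) ** 2, weights=w)))
    else:
        mu0, sigma0 = float(log_theta.mean()), float(log_theta.std())
    sigma0 = max(sigma0, 1e-3)

    def lognormal_shape(theta, amplitude, mu, sigma):
        return (
            amplitude
            / (theta * sigma * np.sqrt(2 * np.pi))
            * np.exp(-((np.log(theta) - mu) ** 2) / (2 * sigma**2))
        )

    try:
        popt, _ = curve_fit(
            lognormal_shape,
            theta_grid,
            counts,
            p0=[counts.max() * sigma0 * np.exp(mu0), mu0, sigma0],
            bounds=([0, log_theta.min() - 5, 1e-4], [np.inf, log_theta.max() + 5, 10.0]),
            maxfev=20_000,
        )
        amplitude, mu, sigma = (float(v) for v in popt)
        return amplitude, mu, sigma, True
    except (RuntimeError, ValueError):
        warnings.warn(
            "lognormal fit of N(theta) failed; falling back to weighted log-moments",
            stacklevel=2,
        )
        return np.nan, mu0, sigma0, False


def select_threshold(
    p: PopulationActivity | np.ndarray,
    k: int = 1,
    theta_grid: np.ndarray | None = None,
    n_grid: int = 100,
    mode: str = "hard",
    rule: str = "log",
) -> ThresholdSelection:
    """Pick a threshold from the epoch-count curve ``N(theta)``.

    Counts epochs (after thresholding at native resolution and coarse-graining at
    ``k``) for each theta on a grid spanning "removes nothing" to "removes
    everything", fits a scaled lognormal-shaped curve to ``N(theta)``, and returns
    ``theta* = exp(mu - 2 sigma)`` (``rule="log"``: mu/sigma are log-location and
    log-scale of the fitted curve).  ``rule="linear"`` instead uses the fitted
    lognormal's linear-space mean and SD.  If the fit does not converge, falls back
    to count-weighted log-moments with a warning.
    """
    arr = p.p if isinstance(p, PopulationActivity) else np.asarray(p, dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("population activity is identically zero")
    if theta_grid is None:
        lo = 0.5 * positive.min()
        hi = arr.max()
        theta_grid = np.geomspace(lo, hi, n_grid)
    theta_grid = np.asarray(theta_grid, dtype=float)

    counts = np.empty(theta_grid.size)
    for i, theta in enumerate(theta_grid):
        p_thr = _threshold_array(arr, ThresholdPolicy(mode=mode, theta=theta))
        counts[i] = _count_epochs(p_thr, k)

    amplitude, mu, sigma, converged = fit_epoch_count_curve(theta_grid, counts)

    if rule == "log":
        theta_star = float(np.exp(mu - 2.0 * sigma))
    elif rule == "linear":
        mean_lin = np.exp(mu + sigma**2 / 2.0)
        sd_lin = mean_lin * np.sqrt(np.expm1(sigma**2))
        theta_star = float(max(mean_lin - 2.0 * sd_lin, theta_grid.min()))
    else:
        raise ValueError("rule must be 'log' or 'linear'")
    return ThresholdSelection(
        theta_grid=theta_grid,
        epoch_counts=counts,
        mu=mu,
        sigma=sigma,
        theta_star=theta_star,
        converged=converged,
        rule=rule,
        amplitude=amplitude,
    )


def detect(
    source: SpikeRaster | PopulationActivity | np.ndarray,
    k: int = 1,
    policy: ThresholdPolicy | None = None,
    auto_theta: bool = False,
    mode: str = "hard",
) -> AvalancheTable:
    """Threshold, coarse-grain at ``k``, extract epochs from all offsets, and pool.

    Either give an explicit ``policy`` or set ``auto_theta=True`` to select the
    threshold per ``k`` from the epoch-count curve.  Epochs from all ``k`` phase
    offsets are pooled into one table tagged with ``(k, offset)``.
    """
    if isinstance(source, SpikeRaster):
        pa = population_activity(source)
    elif isinstance(source, PopulationActivity):
        pa = source
    else:
        pa = PopulationActivity(p=np.asarray(source, dtype=float), dt=1.0)
    if policy is None:
        if auto_theta:
            selection = select_threshold(pa, k=k, mode=mode)
            policy = ThresholdPolicy(mode=mode, theta=selection.theta_star)
        else:
            raise ValueError("provide a ThresholdPolicy or set auto_theta=True")
    p_thr = _threshold_array(pa.p, policy)
    tables = [
        extract_avalanches(series, k=k, offset=j, dt=pa.dt)
        for j, series in enumerate(coarse_grain(p_thr, k))
    ]
    return AvalancheTable.concat(tables)
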