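"""Surrogate rasters that destroy specific statistical structure while conserving the rest.

Each generator targets one ingredient of avalanche scaling:

* circular temporal shifts remove inter-neuronal (zero-lag) correlations while
  preserving each cell's spike count and rotation-invariant inter-spike-interval
  structure exactly;
* random spike addition mimics uncorrelated background activity (100% addition
  doubles the firing rate);
* random cell removal emulates a reduced spatial sampling fraction;
* trial shuffling destroys within-trial spatial correlations in evoked data while
  preserving each cell's trial-averaged response per stimulus condition.

Every generator takes an explicit seed; drivers that need repeated surrogates should
derive per-repeat seeds from a master ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np

from .raster import SpikeRaster, TrialTable

__all__ = [
    "circular_shift_surrogate",
    "add_random_spikes",
    "remove_cells",
    "trial_shuffle",
]


def circular_shift_surrogate(raster: SpikeRaster, seed: int | None = None) -> SpikeRaster:
    """Rotate each cell's time series by an independent uniform random offset.

    Offsets are drawn from ``[1, n_bins - 1]`` so that no cell is left unshifted.
    Per-cell totals are conserved exactly.
    """
    rng = np.random.default_rng(seed)
    out = raster.values.copy()
    if raster.n_bins > 1:
        offsets = rng.integers(1, raster.n_bins, size=raster.n_cells)
        for i, off in enumerate(offsets):
            out[i] = np.roll(out[i], off)
    return raster.with_values(out)


def add_random_spikes(raster: SpikeRaster, pct: float, seed: int | None = None) -> SpikeRaster:
    """Add unit spikes at uniformly random (cell, bin) positions.

    The number of added spikes is ``round(pct / 100 * total)`` where ``total`` is the
    summed spike-density mass of the raster, so ``pct = 100`` exactly doubles the
    total count.
    """
    if pct < 0:
        raise ValueError("noise percentage must be nonnegative")
    rng = np.random.default_rng(seed)
    out = raster.values.copy()
    n_add = int(round(pct / 100.0 * out.sum()))
    if n_add > 0:
        flat = rng.integers(0, out.size, size=n_add)
        np.add.at(out.reshape(-1), flat, 1.0)
    return raster.with_values(out)


def remove_cells(raster: SpikeRaster, pct: float, seed: int | None = None) -> SpikeRaster:
    """Retain a uniformly random subset of ``round((1 - pct/100) * n_cells)`` cells.

    Emulates a reduction of the neuronal sampling fraction.  Callers probing
    robustness should repeat with several seeds and average downstream statistics.
    """
    if not 0 <= pct < 100:
        raise ValueError("removal percentage must lie in [0, 100)")
    rng = np.random.default_rng(seed)
    n_keep = int(round((1.0 - pct / 100.0) * raster.n_cells))
    if n_keep < 1:
        raise ValueError("cell removal would leave an empty raster")
    keep = np.sort(rng.choice(raster.n_cells, size=n_keep, replace=False))
    return raster.select_cells(keep)


def trial_shuffle(
    raster: SpikeRaster, trials: TrialTable, seed: int | None = None
) -> SpikeRaster:
    """Permute each cell's responses across same-condition trials, independently per cell.

    Activity outside the listed trial intervals is untouched.  Trials belonging to one
    condition must have equal length (bins), otherwise segments are not exchangeable.
    """
    trials.validate_bounds(raster.n_bins)
    rng = np.random.default_rng(seed)
    out = raster.values.copy()
    for cond in np.unique(trials.conditions):
        sel = np.flatnonzero(trials.conditions == cond)
        lengths = trials.ends[sel] - trials.starts[sel]
        if np.unique(lengths).size > 1:
            raise ValueError(f"trials of condition {cond!r} have unequal lengths")
        starts = trials.starts[sel]
        L = int(lengths[0])
        for i in range(raster.n_cells):
            perm = rng.permutation(sel.size)
            segments = [raster.values[i, s : s + L] for s in starts]
            for j, s in enumerate(starts):
                out[i, s : s + L] = segments[perm[j]]
    return raster.with_values(out)
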