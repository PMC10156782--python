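"""Mean temporal profiles of avalanches, shape collapse, and remapping to native resolution.

At criticality, avalanches of different durations share one universal shape: the mean
activity profile of duration-``L`` avalanches is ``s_L(t) = L^(chi-1) * g(t/L)`` with
``g`` an inverted parabola when ``chi = 2``.  The collapse exponent ``chi_coll`` is
found by x-rescaling each per-duration mean profile to [0, 1], interpolating to a
common support of 500 points, y-rescaling by ``L^(chi-1)``, and minimizing the RMS
spread between the rescaled shapes over ``chi``.

Epochs detected at coarse resolution ``k`` can be mapped back to the native bin width
to recover the underlying profile at the original frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .avalanche import AvalancheTable, CoarseEnsemble, coarse_grain

__all__ = [
    "MeanProfile",
    "CollapseResult",
    "avalanche_segments",
    "temporal_profile",
    "collapse_exponent",
    "parabola_quality",
    "remap_to_original_dt",
]

N_INTERP = 500


@dataclass
class MeanProfile:
    """Element-wise mean (and SD) activity time course of same-duration avalanches."""

    duration: int
    k: int
    mean: np.ndarray
    sd: np.ndarray
    n_avalanches: int


def avalanche_segments(
    p_thr: np.ndarray, table: AvalancheTable, k: int, durations: tuple[int, int] | None = None
) -> dict[int, list[np.ndarray]]:
    """Suprathreshold activity time courses of the table's epochs, grouped by duration.

    ``p_thr`` is the thresholded series at native resolution from which ``table`` was
    detected; the coarse ensemble is rebuilt to slice out each epoch's bins.
    """
    ensemble: CoarseEnsemble = coarse_grain(np.asarray(p_thr, dtype=float), k)
    out: dict[int, list[np.ndarray]] = {}
    mask = table.k == k
    for size, dur, off, start in zip(
        table.sizes[mask], table.durations[mask], table.offsets[mask], table.start_bins[mask]
    ):
        dur = int(dur)
        if durations is not None and not durations[0] <= dur <= durations[1]:
            continue
        series = ensemble.series[int(off)]
        seg = series[int(start) : int(start) + dur]
        out.setdefault(dur, []).append(seg)
    return out


def temporal_profile(
    segments: list[np.ndarray], min_count: int = 5
) -> MeanProfile:
    """Element-wise mean and SD over same-duration avalanche time courses."""
    if len(segments) < min_count:
        raise ValueError(f"only {len(segments)} avalanches; need at least {min_count}")
    lengths = {len(s) for s in segments}
    if len(lengths) != 1:
        raise ValueError("segments must all share one duration")
    stack = np.vstack(segments)
    return MeanProfile(
        duration=stack.shape[1],
        k=1,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0),
        n_avalanches=stack.shape[0],
    )


@dataclass
class CollapseResult:
    chi_coll: float
    residual: float
    durations: tuple[int, ...]


def _rescaled_shapes(curves: dict[int, np.ndarray], chi: float) -> np.ndarray:
    grid = np.linspace(0.0, 1.0, N_INTERP)
    shapes = []
    for L, curve in sorted(curves.items()):
        x = np.linspace(0.0, 1.0, curve.size)
        shapes.append(np.interp(grid, x, curve) / float(L) ** (chi - 1.0))
    return np.vstack(shapes)


def _pairwise_rms(shapes: np.ndarray) -> float:
    n = shapes.shape[0]
    total, count = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            total += float(np.mean((shapes[i] - shapes[j]) ** 2))
            count += 1
    return np.sqrt(total / count)


def _collapse_cost(shapes: np.ndarray, objective: str) -> float:
    """Spread between rescaled shapes, normalized by their common amplitude.

    The normalization (RMS of the grand mean shape) makes the objective invariant
    under a global rescaling of all curves; without it, ever larger collapse
    exponents would trivially shrink the absolute spread toward zero.
    """
    amplitude = float(np.sqrt(np.mean(shapes.mean(axis=0) ** 2)))
    if amplitude == 0:
        return np.inf
    if objective == "pairwise":
        return _pairwise_rms(shapes) / amplitude
    return float(np.sqrt(np.mean((shapes - shapes.mean(axis=0)) ** 2))) / amplitude


def collapse_exponent(
    profiles: list[MeanProfile] | dict[int, np.ndarray],
    chi_range: tuple[float, float] = (0.5, 4.0),
    objective: str = "pairwise",
    tol: float = 1e-4,
) -> CollapseResult:
    """Shape-collapse exponent: minimize the RMS spread between rescaled profiles.

    Each per-duration mean profile is x-rescaled to [0, 1], linearly interpolated to
    500 points (endpoints pinned to the first/last bin values) and y-rescaled by
    ``L^(chi - 1)``; ``chi_coll`` minimizes the mean pairwise RMS between the
    rescaled shapes (``objective="mean"`` instead uses deviation from the mean
    shape — the two agree on exact scaling families).
    """
    if isinstance(profiles, dict):
        curves = {int(L): np.asarray(c, dtype=float) for L, c in profiles.items()}
    else:
        curves = {int(pr.duration): np.asarray(pr.mean, dtype=float) for pr in profiles}
    curves = {L: c for L, c in curves.items() if L >= 2}
    if len(curves) < 3:
        raise ValueError("need at least 3 duration classes (L >= 2) for a collapse")

    def cost(chi: float) -> float:
        return _collapse_cost(_rescaled_shapes(curves, chi), objective)

    res = minimize_scalar(cost, bounds=chi_range, method="bounded", options={"xatol": tol})
    if not res.success:
        raise RuntimeError("collapse optimization failed")
    return CollapseResult(
        chi_coll=float(res.x), residual=float(res.fun), durations=tuple(sorted(curves))
    )


def parabola_quality(profile: np.ndarray | MeanProfile) -> float:
    """Goodness of the best inverted-parabola fit ``a * x(1-x) + b`` with ``a >= 0``.

    Returns ``1 - RMS(residual) / RMS(profile - mean)``; 1 for an exact parabola, ~0
    for a shape the parabola explains no better than a constant (a flat profile
    yields 0 by convention).
    """
    y = np.asarray(profile.mean if isinstance(profile, MeanProfile) else profile, dtype=float)
    if y.size < 3:
        raise ValueError("profile too short")
    spread = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
    if spread == 0:
        return 0.0
    x = np.linspace(0.0, 1.0, y.size)
    basis = x * (1.0 - x)
    design = np.column_stack([basis, np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    if a < 0:  # upright parabolas are not admissible; degenerate to a constant
        a, b = 0.0, float(y.mean())
    resid = y - (a * basis + b)
    return float(1.0 - np.sqrt(np.mean(resid**2)) / spread)


def remap_to_original_dt(
    table: AvalancheTable, p_original: np.ndarray, k: int
) -> dict[int, list[np.ndarray]]:
    """Map coarse epochs back to native-resolution windows and return their segments.

    A coarse epoch at ``(k, offset, start, L)`` covers native bins
    ``[start*k + offset, (start + L)*k + offset)``; for ``k = 1`` this is the
    identity.  Segments are grouped by coarse duration ``L`` (each has ``L * k``
    native bins), ready for :func:`temporal_profile`.
    """
    arr = np.asarray(p_original, dtype=float)
    out: dict[int, list[np.ndarray]] = {}
    mask = table.k == k
    for dur, off, start in zip(
        table.durations[mask], table.offsets[mask], table.start_bins[mask]
    ):
        lo = int(start) * k + int(off)
        hi = (int(start) + int(dur)) * k + int(off)
        if hi > arr.size:
            raise ValueError("remapped epoch extends beyond the native series")
        out.setdefault(int(dur), []).append(arr[lo:hi])
    return out
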