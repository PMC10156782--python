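"""Ordinal-pattern statistical complexity and lag-1 autocorrelation of population activity.

Sliding windows of ``D`` consecutive bins are mapped to their rank-order (ordinal)
pattern — e.g. a monotonically increasing window of depth 4 is pattern ``0123`` — and
the distribution ``P`` over the ``D!`` possible patterns is formed.  The normalized
permutation entropy is ``H = S[P] / ln(D!)`` and the statistical complexity

    C = Q_J * H,    Q_J = Q_0 * ( S[(P + P_e)/2] - S[P]/2 - S[P_e]/2 )

where ``P_e`` is uniform, the bracket is the (unnormalized) Jensen-Shannon divergence
between ``P`` and ``P_e``, and ``Q_0`` normalizes it by its maximum over the simplex
(attained by a point mass).  ``C`` is zero both for fully random (uniform ``P``) and
fully ordered (single-pattern) series and peaks for structured-but-diverse dynamics.

By default only windows lying fully inside suprathreshold epochs are evaluated, so
the statistic describes the temporal order *within* avalanches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .avalanche import ThresholdPolicy, apply_threshold, coarse_grain

__all__ = [
    "PatternDistribution",
    "ComplexityResult",
    "ordinal_patterns",
    "pattern_counts",
    "shannon_entropy",
    "shannon_H",
    "jensen_shannon_Q0",
    "complexity_C",
    "complexity_vs_k",
    "ac1",
]


@dataclass
class PatternDistribution:
    """Probabilities over the D! ordinal patterns of depth D."""

    D: int
    probabilities: np.ndarray  # length D!, canonical lexicographic pattern order
    n_windows: int

    def __post_init__(self) -> None:
        n = math.factorial(self.D)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.size != n:
            raise ValueError(f"expected {n} pattern probabilities for depth {self.D}")
        if self.n_windows > 0 and abs(self.probabilities.sum() - 1.0) > 1e-8:
            raise ValueError("probabilities must sum to 1")


def _pattern_code_lookup(D: int) -> dict[int, int]:
    """Map base-D encoded rank words to lexicographic pattern indices."""
    lookup: dict[int, int] = {}
    base = D ** np.arange(D)
    for idx, perm in enumerate(permutations(range(D))):
        code = int(np.dot(np.asarray(perm), base))
        lookup[code] = idx
    return lookup


def pattern_counts(
    series: np.ndarray, D: int, within_epochs: bool = True, jitter_seed: int | None = None
) -> tuple[np.ndarray, int]:
    """Raw ordinal-pattern counts (length D!) for one series.

    Ranks are assigned by value with ties broken by temporal order (the earlier bin
    gets the lower rank), which matters for thresholded count data; pass
    ``jitter_seed`` to instead break ties with an infinitesimal random perturbation
    (sensitivity check).  With ``within_epochs`` only windows whose ``D`` bins are all
    suprathreshold (positive) are counted.
    """
    if not 3 <= D <= 7:
        raise ValueError("pattern depth D must be between 3 and 7")
    arr = np.asarray(series, dtype=float)
    if arr.size < D:
        raise ValueError("series shorter than the pattern depth")
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        scale = max(arr.std(), 1.0)
        arr = arr + rng.uniform(0, 1e-9 * scale, size=arr.size)
    windows = np.lib.stride_tricks.sliding_window_view(arr, D)
    if within_epochs:
        valid = np.all(windows > 0, axis=1)
        windows = windows[valid]
    n = windows.shape[0]
    counts = np.zeros(math.factorial(D))
    if n == 0:
        return counts, 0
    order = np.argsort(windows, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(D)[None, :]
    codes = ranks @ (D ** np.arange(D))
    lookup = _pattern_code_lookup(D)
    code_counts = np.bincount(codes, minlength=D**D)
    for code, idx in lookup.items():
        counts[idx] = code_counts[code]
    return counts, n


def ordinal_patterns(
    series: np.ndarray, D: int, within_epochs: bool = True, jitter_seed: int | None = None
) -> PatternDistribution:
    """Distribution over rank-order patterns of depth D (stride-1 sliding windows)."""
    counts, n = pattern_counts(series, D, within_epochs=within_epochs, jitter_seed=jitter_seed)
    if n == 0:
        raise ValueError("no valid windows (is the series entirely subthreshold?)")
    return PatternDistribution(D=D, probabilities=counts / n, n_windows=n)


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0 * ln 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def shannon_H(P: PatternDistribution) -> float:
    """Normalized permutation entropy H = S[P] / ln(D!) in [0, 1]."""
    return shannon_entropy(P.probabilities) / math.log(math.factorial(P.D))


def jensen_shannon_Q0(n_states: int) -> float:
    """Normalization constant: inverse of the maximal JS term over the simplex.

    The bracket ``S[(P+P_e)/2] - S[P]/2 - S[P_e]/2`` is maximized by a point mass;
    evaluating it there gives the closed form used here.
    """
    n = n_states
    delta = np.zeros(n)
    delta[0] = 1.0
    pe = np.full(n, 1.0 / n)
    max_term = shannon_entropy((delta + pe) / 2) - 0.0 / 2 - shannon_entropy(pe) / 2
    return 1.0 / max_term


@dataclass
class ComplexityResult:
    H: float
    Q_J: float
    C: float
    Q_0: float
    D: int
    n_windows: int


def complexity_C(P: PatternDistribution) -> ComplexityResult:
    """Statistical complexity C = Q_J * H of a pattern distribution."""
    n = math.factorial(P.D)
    pe = np.full(n, 1.0 / n)
    H = shannon_H(P)
    Q0 = jensen_shannon_Q0(n)
    term = (
        shannon_entropy((P.probabilities + pe) / 2)
        - shannon_entropy(P.probabilities) / 2
        - shannon_entropy(pe) / 2
    )
    QJ = Q0 * term
    return ComplexityResult(H=H, Q_J=QJ, C=QJ * H, Q_0=Q0, D=P.D, n_windows=P.n_windows)


def _pooled_complexity(p_thr: np.ndarray, k: int, D: int) -> ComplexityResult | None:
    """Complexity of one thresholded series: pattern counts pooled over the k offsets."""
    counts = np.zeros(math.factorial(D))
    total = 0
    for series in coarse_grain(p_thr, k):
        if series.size < D:
            continue
        c, n = pattern_counts(series, D, within_epochs=True)
        counts += c
        total += n
    if total == 0:
        return None
    return complexity_C(PatternDistribution(D=D, probabilities=counts / total, n_windows=total))


def complexity_vs_k(
    p: np.ndarray,
    D: int = 5,
    k_values: range | list[int] = range(1, 21),
    theta: float = 0.0,
    mode: str = "hard",
    n_sections: int = 10,
) -> pd.DataFrame:
    """Complexity of thresholded, coarse-grained activity as a function of k.

    For each k the native-resolution series is thresholded, coarse-grained, and the
    pattern statistics are pooled over all k offsets.  The quoted SD is the spread of
    C over ``n_sections`` equal contiguous sections of the recording.  A fixed
    ``theta`` is used for every k (pass the per-k selected threshold explicitly to
    follow the adaptive rule).
    """
    arr = np.asarray(p, dtype=float)
    p_thr = apply_threshold(arr, ThresholdPolicy(mode=mode, theta=theta))
    bounds = np.linspace(0, arr.size, n_sections + 1).astype(int)
    rows = []
    for k in k_values:
        res = _pooled_complexity(p_thr, k, D)
        if res is None:
            rows.append({"k": k, "D": D, "H": np.nan, "QJ": np.nan, "C": np.nan, "sd": np.nan})
            continue
        section_C = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi - lo <= D * k:
                continue
            sec = _pooled_complexity(p_thr[lo:hi], k, D)
            if sec is not None:
                section_C.append(sec.C)
        sd = float(np.std(section_C)) if len(section_C) >= 2 else np.nan
        rows.append({"k": k, "D": D, "H": res.H, "QJ": res.Q_J, "C": res.C, "sd": sd})
    return pd.DataFrame(rows)


def ac1(segments: list[np.ndarray]) -> float:
    """Lag-1 Pearson autocorrelation using only lag pairs fully inside epochs.

    ``segments`` are the suprathreshold activity time courses (typically of one
    duration class, from :func:`avakit.profiles.avalanche_segments`).
    """
    xs, ys = [], []
    for seg in segments:
        if len(seg) >= 2:
            xs.append(np.asarray(seg[:-1], dtype=float))
            ys.append(np.asarray(seg[1:], dtype=float))
    if not xs:
        raise ValueError("need at least 2 valid lag pairs")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        raise ValueError("insufficient variance for a lag-1 correlation")
    return float(np.corrcoef(x, y)[0, 1])
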