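"""Balanced E/I probabilistic integrate-and-fire network with subsampled observation.

The network is the package's ground truth for critical vs subcritical cascading
dynamics: ``N`` binary, non-leaky, probabilistic integrate-and-fire neurons (80%
excitatory by default) with all-to-all uniform coupling.  Excitatory synapses have
weight ``J`` and inhibitory synapses ``-g*J``; ``g`` is the E/I balance parameter.
Membrane potentials evolve as

    V_i(t+1) = (mu * V_i(t) + sum_j W_ij X_j(t)) * (1 - X_i(t))

so a spike (``X_i(t) = 1``) resets the potential — an absolute refractory period of
one step.  A quiescent neuron fires with probability ``clip(Gamma * V, 0, 1)`` and is
additionally activated by an external Poisson drive with per-step probability
``lam``.  With ``Gamma = 1`` and ``mu = 0`` the mean-field branching ratio is
``N * J * (frac_E - (1 - frac_E) * g)``; the default ``J = 10/N`` places the critical
balance at ``g_c = 3.5``.

Two engines are provided.  The *naive* engine tracks every neuron and serves as the
reference oracle at small ``N``.  The *cohort* engine exploits the uniform-weight
mean-field structure: with ``mu = 0`` every non-refractory neuron carries the same
membrane potential ``h(t) = J * (n_E(t) - g * n_I(t))``, so the unobserved population
reduces to four counts (E/I crossed with refractory-or-not) and per-step firing is
binomial.  Its cost is independent of ``N``, which makes ``N = 10^6`` desk-scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .raster import SpikeRaster, PopulationActivity

__all__ = [
    "NetworkParams",
    "SimOutput",
    "naive_simulate",
    "cohort_simulate",
    "simulate",
    "branching_ratio",
    "drive_threshold",
]


@dataclass
class NetworkParams:
    """Parameters of the balanced E/I network.

    ``J`` and ``lam`` default to ``10/N`` and ``20/N`` respectively: the former puts
    the critical balance at ``g_c = 3.5``, the latter makes the external drive
    activate ~20 neurons per step network-wide.
    """

    N: int = 1_000_000
    frac_E: float = 0.8
    J: float | None = None
    g: float = 3.5
    Gamma: float = 1.0
    mu: float = 0.0
    lam: float | None = None
    T: int = 100_000
    burn_in: int = 10_000
    seed: int = 0
    drive_mode: str = "activate"  # "activate": drive sets X=1; "voltage": drive adds J to V

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("need at least 2 neurons")
        if not 0.0 < self.frac_E < 1.0:
            raise ValueError("frac_E must lie strictly between 0 and 1")
        if self.J is None:
            self.J = 10.0 / self.N
        if self.lam is None:
            self.lam = 20.0 / self.N
        if self.J <= 0 or self.g < 0 or not 0.0 <= self.lam <= 1.0:
            raise ValueError("require J > 0, g >= 0 and lam in [0, 1]")
        if self.T < 1 or self.burn_in < 0:
            raise ValueError("T must be positive and burn_in nonnegative")
        if self.drive_mode not in ("activate", "voltage"):
            raise ValueError("drive_mode must be 'activate' or 'voltage'")

    @property
    def n_E(self) -> int:
        return int(round(self.frac_E * self.N))

    @property
    def n_I(self) -> int:
        return self.N - self.n_E

    @property
    def branching_ratio_mean_field(self) -> float:
        """Expected descendants per spike from the uniform-coupling mean field."""
        return self.N * self.J * self.Gamma * (self.frac_E - (1.0 - self.frac_E) * self.g)


@dataclass
class SimOutput:
    """Per-step spike counts of the whole network plus a subsampled observation.

    ``e_counts``/``i_counts`` cover the full network after burn-in; ``sampled_counts``
    is the per-step spike count within the random fraction ``f`` of observed neurons.
    ``sampled_raster`` (optional) holds the observed neurons' binary spike trains.
    """

    params: NetworkParams
    f: float
    n_sampled: int
    e_counts: np.ndarray
    i_counts: np.ndarray
    sampled_counts: np.ndarray
    sampled_raster: SpikeRaster | None = None
    engine: str = "cohort"

    @property
    def pop_counts(self) -> np.ndarray:
        return self.e_counts + self.i_counts

    @property
    def drive_expectation(self) -> float:
        """Expected external-drive spikes per step within the observed population."""
        return self.params.lam * self.n_sampled

    @property
    def firing_rate_per_1000(self) -> float:
        """Network-average firing rate in spikes per neuron per 1000 steps."""
        return float(self.pop_counts.mean()) / self.params.N * 1000.0

    def sampled_activity(self) -> PopulationActivity:
        """Observed population activity (1 simulated step per bin, dt = 1)."""
        return PopulationActivity(p=self.sampled_counts.astype(float), dt=1.0)


def _fire_probability(h: float, params: NetworkParams) -> float:
    """Per-step firing probability of a quiescent neuron given recurrent input h."""
    pv = params.Gamma * h
    pv = 0.0 if pv < 0.0 else (1.0 if pv > 1.0 else pv)
    if params.drive_mode == "activate":
        return params.lam + (1.0 - params.lam) * pv
    pvd = params.Gamma * (h + params.J)
    pvd = 0.0 if pvd < 0.0 else (1.0 if pvd > 1.0 else pvd)
    return params.lam * pvd + (1.0 - params.lam) * pv


def cohort_simulate(
    params: NetworkParams, f: float = 1.0, store_raster: bool = False
) -> SimOutput:
    """Aggregated engine: distributionally identical to ``naive_simulate`` at mu = 0.

    The unobserved population is held as E/I refractory counts and updated with
    binomial draws; observed neurons are either aggregated the same way (default) or
    simulated individually when ``store_raster`` is requested.
    """
    if params.mu != 0.0:
        raise ValueError("the cohort engine requires mu = 0 (use naive_simulate)")
    if not 0.0 <= f <= 1.0:
        raise ValueError("sampling fraction f must lie in [0, 1]")
    rng = np.random.default_rng(params.seed)
    NE, NI = params.n_E, params.n_I
    n_s = int(round(f * params.N))
    n_sE = min(int(round(params.frac_E * n_s)), NE)
    n_sI = min(n_s - n_sE, NI)
    n_s = n_sE + n_sI
    NE_u, NI_u = NE - n_sE, NI - n_sI
    if store_raster and n_s * params.T > 2 * 10**9:
        raise MemoryError("requested raster is too large; use store_raster=False")

    J, g = params.J, params.g
    lam = params.lam
    T, burn = params.T, params.burn_in
    e_counts = np.zeros(T, dtype=np.int64)
    i_counts = np.zeros(T, dtype=np.int64)
    s_counts = np.zeros(T, dtype=np.int64)
    raster = np.zeros((n_s, T), dtype=np.uint8) if store_raster else None

    binom = rng.binomial
    fE_u = fI_u = fE_s = fI_s = 0
    X_s = np.zeros(n_s, dtype=bool) if store_raster else None
    for t in range(burn + T):
        nE = fE_u + fE_s
        nI = fI_u + fI_s
        h = J * (nE - g * nI)
        p = _fire_probability(h, params)
        fE_u = int(binom(NE_u - fE_u, p)) if NE_u else 0
        fI_u = int(binom(NI_u - fI_u, p)) if NI_u else 0
        if store_raster:
            fire = ~X_s & (rng.random(n_s) < p)
            fE_s = int(np.count_nonzero(fire[:n_sE]))
            fI_s = int(np.count_nonzero(fire[n_sE:]))
            X_s = fire
            if t >= burn:
                raster[:, t - burn] = fire
        else:
            fE_s = int(binom(n_sE - fE_s, p)) if n_sE else 0
            fI_s = int(binom(n_sI - fI_s, p)) if n_sI else 0
        if t >= burn:
            idx = t - burn
            e_counts[idx] = fE_u + fE_s
            i_counts[idx] = fI_u + fI_s
            s_counts[idx] = fE_s + fI_s

    sampled_raster = None
    if store_raster:
        cell_type = np.array(["E"] * n_sE + ["I"] * n_sI)
        sampled_raster = SpikeRaster(
            values=raster.astype(float), dt=1.0, cell_type=cell_type
        )
    return SimOutput(
        params=params,
        f=f,
        n_sampled=n_s,
        e_counts=e_counts,
        i_counts=i_counts,
        sampled_counts=s_counts,
        sampled_raster=sampled_raster,
        engine="cohort",
    )


def naive_simulate(
    params: NetworkParams, f: float = 1.0, store_raster: bool = True
) -> SimOutput:
    """Reference engine holding per-neuron state; intended for N up to ~10^4."""
    if params.N > 100_000:
        raise ValueError("naive engine is limited to N <= 1e5; use cohort_simulate")
    if not 0.0 <= f <= 1.0:
        raise ValueError("sampling fraction f must lie in [0, 1]")
    rng = np.random.default_rng(params.seed)
    N, NE = params.N, params.n_E
    n_s = int(round(f * N))
    sampled = np.sort(rng.choice(N, size=n_s, replace=False)) if n_s else np.array([], int)
    J, g, lam, Gamma, mu = params.J, params.g, params.lam, params.Gamma, params.mu
    T, burn = params.T, params.burn_in

    V = np.zeros(N)
    X = np.zeros(N, dtype=bool)
    e_counts = np.zeros(T, dtype=np.int64)
    i_counts = np.zeros(T, dtype=np.int64)
    s_counts = np.zeros(T, dtype=np.int64)
    raster = np.zeros((n_s, T), dtype=np.uint8) if (store_raster and n_s) else None
    is_E = np.zeros(N, dtype=bool)
    is_E[:NE] = True

    for t in range(burn + T):
        nE = int(np.count_nonzero(X[:NE]))
        nI = int(np.count_nonzero(X[NE:]))
        h = J * (nE - g * nI)
        V = (mu * V + h) * (1.0 - X)
        pv = np.clip(Gamma * V, 0.0, 1.0)
        if params.drive_mode == "activate":
            p = lam + (1.0 - lam) * pv
        else:
            pvd = np.clip(Gamma * (V + J), 0.0, 1.0)
            p = lam * pvd + (1.0 - lam) * pv
        p[X] = 0.0  # absolute refractory period: no recurrent firing, no drive
        X = rng.random(N) < p
        if t >= burn:
            idx = t - burn
            e_counts[idx] = np.count_nonzero(X[:NE])
            i_counts[idx] = np.count_nonzero(X[NE:])
            if n_s:
                fired = X[sampled]
                s_counts[idx] = np.count_nonzero(fired)
                if raster is not None:
                    raster[:, idx] = fired

    sampled_raster = None
    if raster is not None:
        cell_type = np.where(is_E[sampled], "E", "I")
        sampled_raster = SpikeRaster(values=raster.astype(float), dt=1.0, cell_type=cell_type)
    return SimOutput(
        params=params,
        f=f,
        n_sampled=n_s,
        e_counts=e_counts,
        i_counts=i_counts,
        sampled_counts=s_counts,
        sampled_raster=sampled_raster,
        engine="naive",
    )


def simulate(
    params: NetworkParams, f: float = 1.0, engine: str = "cohort", store_raster: bool = False
) -> SimOutput:
    """Dispatch to the requested engine."""
    if engine == "cohort":
        return cohort_simulate(params, f=f, store_raster=store_raster)
    if engine == "naive":
        return naive_simulate(params, f=f, store_raster=store_raster)
    raise ValueError("engine must be 'cohort' or 'naive'")


def branching_ratio(output: SimOutput, max_fraction: float = 0.05) -> float:
    """Estimate the expected number of descendant spikes per spike.

    Regression slope (with intercept, which absorbs the external drive) of
    ``pop_count(t+1) - lam * N`` on ``pop_count(t)`` over active steps.  Close to 1
    at the critical balance, below 1 for inhibition-dominated (subcritical)
    networks, above 1 for excitation-dominated ones.  Steps with more than
    ``max_fraction`` of the network active are excluded: there refractoriness and
    probability saturation curb the offspring count, which would mask supercritical
    growth.
    """
    n = output.pop_counts.astype(float)
    x = n[:-1]
    y = n[1:] - output.params.lam * output.params.N
    active = (x > 0) & (x <= max_fraction * output.params.N)
    n_active = int(np.count_nonzero(active))
    if n_active == 0:
        raise ValueError("no active steps; cannot estimate a branching ratio")
    if n_active < 1000:
        warnings.warn(
            f"only {n_active} active steps; branching-ratio estimate will be noisy",
            stacklevel=2,
        )
    slope, _ = np.polyfit(x[active], y[active], 1)
    return float(slope)


def drive_threshold(output: SimOutput) -> float:
    """Baseline population threshold: expected drive spikes per step in the sample.

    Thresholding the observed activity above this baseline focuses the avalanche
    analysis on recurrent (cascading) activity rather than the external drive.
    Analyses may use any theta >= this value.
    """
    return output.drive_expectation
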