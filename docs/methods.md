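# Methods

This note documents the models, estimators and numerical conventions behind
`avakit`. It is written for users who want to know exactly what each number the
package prints means, and what a green test does and does not establish.

## 1. The analysis problem

Two-photon calcium imaging yields a spike-density raster: `n_cells × n_bins`
nonnegative activities at bin width `Δt` (≈22 ms at a 45.5 Hz frame rate). Summing
over cells gives the population activity `p(t)`. Epochs in which `p(t)` stays above
a threshold `Θ` are *neuronal avalanches*, characterized by size `S` (summed
suprathreshold activity) and duration `L` (bins). At a critical branching point the
avalanche statistics follow

- `P(S) ∝ S^−α` with `α = 3/2`,
- `P(L) ∝ L^−β` with `β = 2`,
- `⟨S⟩(L) ∝ L^χ` with `χ = 2`, and mean temporal profiles that are inverted
  parabolas collapsing under `L^(χ−1)` rescaling.

An imaging experiment observes only a spatial fraction `f` of the circuit.
Subsampling fragments avalanches, biasing `χ` toward 1. The package's central
operation is *temporal coarse-graining*: after thresholding at native resolution,
sum every `k` consecutive bins at each of the `k` phase offsets and pool the epochs
extracted from all offsets. For critical dynamics this recovers `χ_sh ≈ 2` for
short-duration avalanches at some optimal `k`; for subcritical dynamics no `k`
does. That contrast is the diagnostic.

## 2. Avalanche definition and conventions

- **Thresholding** (`avakit.avalanche.apply_threshold`): hard mode zeroes bins with
  `p ≤ Θ` (strict inequality for survival); soft mode additionally subtracts `Θ`
  from the survivors. Hard is the default everywhere.
- **Coarse-graining** (`coarse_grain`): for offset `j ∈ {0..k−1}`, complete windows
  of `k` bins are summed; a trailing partial window is dropped (a partial sum would
  be biased low).
- **Epoch extraction** (`extract_avalanches`): maximal runs of strictly positive
  bins bounded by zeros. Runs touching either end of the series are discarded —
  their bounding zero is unobserved, so their true extent is unknown. Durations are
  run lengths in coarse bins; the absolute duration is `L·k·Δt` seconds.
- **Pooling**: epochs from all `k` offsets are pooled without deduplication. A
  consequence used below: a long epoch appears once per offset, so very sparse
  duration classes can be a single epoch counted `k` times.
- **Threshold selection** (`select_threshold`): the epoch count `N(Θ)` over a
  100-point log grid spanning "removes nothing" to "removes everything" is fitted
  with a scaled lognormal shape; the working threshold is `exp(μ − 2σ)` with
  `(μ, σ)` the log-location/scale of the fit (shape parameters of a lognormal live
  in log space; a linear-space reading `mean − 2·SD` is available via
  `rule="linear"`). `τ = 0` style edge cases: if the optimizer fails, the
  count-weighted log-moments are used with a warning. For simulated data a fixed
  `Θ` (one spike above the expected drive) replaces the rule.

## 3. Scaling estimators

- **Exponents** (`fit_powerlaw_exponent`): discrete truncated maximum likelihood on
  `[x_min, x_max]`, normalization by explicit sum (continuous-integral
  approximation for supports wider than 2·10^5, accurate for `x_min ≳ 10`). Any
  real exponent is admissible — under heavy coarse-graining slopes cross below 1.
  Uncertainty is the observed-information standard error.
- **Fit ranges**: two automated conventions are provided. `detect_cutoff`
  implements a CCDF-departure rule (fit the full range, find where the empirical
  CCDF departs from the fit by >3 binomial SDs, set `x_max` to a quarter of that
  point) — adequate for clean distributions with a hard cutoff.
  `select_fit_window` generalizes Clauset-style `x_min` selection to a truncated
  fit by KS minimization over candidate windows. Neither is reliable when the
  approach to the asymptote is slow (see §5), which is why the simulation protocol
  below anchors its windows at the finite-size cutoff instead.
- **Mean size vs duration** (`mean_size_vs_duration`): group by duration; mean,
  count and SD per class.
- **Crossover fit** (`fit_scaling_crossover`): the double power law

      S(d) = C·d^χ_sh / (1 + (d/Φ)^γ)^((χ_sh − χ_lg)/γ)

  fitted to `log⟨S⟩` vs `log d`, unweighted (each populated duration counts once),
  with `γ = 4` fixed, bounds `χ ∈ [0, 4]`, `Φ ∈ [min L, 10·max L]`, and
  multi-start over crossover initializations (the objective has local minima when
  the empirical transition is sharper than `γ` allows). The denominator exponent is
  `χ_sh − χ_lg` so that the asymptotic slope beyond `Φ` is `+χ_lg`, which is what
  the long-duration exponent means; the widely quoted variant with `χ_sh + χ_lg`
  has asymptotic slope `−χ_lg` and, under the `χ_lg ≥ 0` bound, degenerates to a
  flat tail and biases `χ_sh` low by ~0.2 on simulated data.
- **k-scan** (`avakit.pipeline.chi_vs_k`): per `k`, detect → table → crossover fit
  plus two-range OLS slopes (`L = 1–4` and `L ≥ 10`). Duration classes with fewer
  than 10 avalanches are excluded from the fits: with offsets pooled these are
  single epochs repeated per offset, the automated analogue of excluding the
  finite-size cutoff region by eye.
- **Bootstrap** (`bootstrap_scaling`): resample the avalanche pool to its original
  cardinality with replacement (10 replicates by default), refit, report
  across-replicate SDs.
- **Exponent relation** (`exponent_relation`): `(β−1)/(α−1)`, flagged as unstable
  within `|α−1| < 0.05` (subsampling plus coarse-graining drives `α` through 1,
  where the ratio is singular).

## 4. The balanced E/I network (synthetic ground truth)

`avakit.model` implements `N` binary, non-leaky, probabilistic integrate-and-fire
neurons (fraction `frac_E = 0.8` excitatory), all-to-all with uniform weights:
excitatory synapses `J`, inhibitory `−gJ`. Membrane potential:
`V(t+1) = (μV(t) + Σ_j W_ij X_j(t))·(1 − X(t))` with `μ = 0`; the `(1 − X)` factor
is a one-step absolute refractory period. A quiescent neuron fires with probability
`clip(ΓV, 0, 1)` (`Γ = 1`) and is externally activated with probability `lam` per
step (default `20/N`, ~20 drive spikes/step network-wide; refractory neurons are
not drivable). The mean-field branching ratio is `m = NJΓ(frac_E − (1−frac_E)g)`;
`J = 10/N` (not stated in the source description; derived from `m = 1` at the
stated critical balance `g_c = 3.5` and verified by the `branching_ratio`
estimator, which measures ≈0.98 at `g = 3.5` and ≈0.56 at `g = 3.75`).

**Engines.** The naive engine holds per-neuron state (reference, `N ≤ 1e5`,
supports `μ ≠ 0` and a voltage-kick drive variant). The cohort engine exploits the
uniform-weight structure: with `μ = 0` every non-refractory neuron carries the same
potential `h(t) = J(n_E(t) − g·n_I(t))`, so the unobserved population reduces to
E/I refractory counts updated by binomial draws, and per-step cost is independent
of `N`. Observed neurons are either aggregated the same way or simulated
individually when a raster is requested. The two engines agree in distribution
(two-sample KS on epoch sizes/durations, rate comparison) — this is tested, not
assumed. E and I spikes count equally in population activity.

**Dynamics worth knowing about.** The E/I composition of who fired feeds back with
weights `+J` / `−gJ`, amplifying the per-step variance by a factor
`(NJΓ)²(frac_E + g²(1−frac_E)) ≈ 325` over Poisson. Two consequences: (i) the
driven critical network is strongly intermittent (that is what makes drive-level
thresholding meaningful), and (ii) the effective offspring variance per spike is
~326, so Galton–Watson asymptotics only emerge above sizes of a few hundred spikes
— a microscopic transient that any exponent fit must stay clear of.

**Burn-in** is 10^4 steps by default, discarded before any statistic.

## 5. Simulation protocols

Two distinct observation protocols, matched to what each quantity means:

1. **Driven, (sub)sampled** (`lam = 20/N`): the operating condition of the
   recovery experiment. Observed population activity is thresholded at `Θ = 1`
   spike (one above nothing — the minimum requirement of 2 coincident spikes),
   which exceeds the expected drive within a 0.1% sample (`f·N·lam = 0.02`),
   then scanned over `k = 1..20`. Desk scale: `T = 2–3·10^6` steps for the
   critical arm; the subcritical arm runs longer (`T = 6–8·10^6`) because its
   firing rate is ~25× lower. Measured at desk scale: max_k `χ_sh` ≈ 2.00–2.05
   near `k ≈ 13` with `χ_lg ≈ 1.1–1.2` (critical); `χ_sh(k≥10)` ≈ 1.0–1.1
   (subcritical).

2. **Fully sampled, sparse seeding** (`lam·N = 0.02/step`,
   `avakit.pipeline.fully_sampled_exponents`): the protocol under which the
   critical exponents `α, β, χ` are defined. With the full 20 spikes/step drive
   the fully sampled population never goes quiescent (its activity floor is far
   above the drive-level threshold), and epochs become level-crossing excursions
   with diffusive exponents at any threshold — not the cascade statistics the
   exponents describe. Reducing the drive separates time scales: cascades are
   bounded by genuine quiescence and `Θ = 0` applies. Fit windows are anchored at
   the finite-size cutoff, clear of the §4 microscopic transient: sizes over the
   two decades below the 99.5th percentile; durations (and the `⟨S⟩` vs `L` slope)
   over the decade below the largest duration class still holding ≥4 avalanches.
   Measured at desk scale (`T = 3–6·10^6`): `α ≈ 1.44–1.50`, `β ≈ 1.93–1.98`,
   slope ≈ 2.10–2.17, `(β−1)/(α−1) ≈ 2.0–2.1`.

## 6. Temporal profiles and shape collapse

Per-duration mean profiles are element-wise means of the suprathreshold activity
courses (bounding zeros excluded; SD is avalanche-level). For the collapse, each
profile is x-rescaled to `[0, 1]` (endpoints pinned to the first/last bin values),
linearly interpolated to 500 points, y-rescaled by `L^(χ−1)`, and `χ_coll`
minimizes the mean pairwise RMS between the rescaled shapes, *normalized by the RMS
of their grand mean* — without that normalization larger `χ` trivially shrinks the
absolute spread and the optimizer runs to its upper bound. Golden-section
minimization on `χ ∈ [0.5, 4]`, tolerance 10⁻⁴; a deviation-from-mean-shape
objective is available and agrees on exact scaling families.

Parabola quality is `1 − RMS(residual)/RMS(profile − mean)` for the best
least-squares inverted parabola `a·x(1−x) + b` with `a ≥ 0`; 1 for an exact
parabola, 0 when the parabola explains nothing beyond a constant.

Coarse epochs are remapped to native resolution via
`[start·k + j, (start+L)·k + j)` (`remap_to_original_dt`), recovering the
underlying profile at the original frame rate.

"Few-generation" avalanches are `L = 3–6` at the `χ_sh`-maximizing `k`. The
contrasting "flat" class is defined *relative to the fitted crossover*: durations
in `[1.5Φ, 3Φ]`. At desk scale the model's `Φ ≈ 18` coarse bins at `k* ≈ 13`, so a
fixed `L = 10–20` window (appropriate for recordings whose `Φ` is ~5 coarse bins)
would still lie inside the parabolic regime.

## 7. Ordinal-pattern complexity

Sliding windows of `D` consecutive bins (depth 3–7, default 5) are ranked — ties
broken by temporal order, earlier bin lower; an infinitesimal-jitter mode exists
for sensitivity checks — giving a distribution `P` over the `D!` patterns.
`H = S[P]/ln D!` is the normalized permutation entropy;
`Q_J = Q_0·(S[(P+P_e)/2] − S[P]/2 − S[P_e]/2)` the Jensen–Shannon disequilibrium
against the uniform `P_e`, with `Q_0` the inverse of the point-mass maximum
(closed form, cross-checked numerically); `C = Q_J·H`. Only windows fully inside
suprathreshold epochs are counted by default (whole-series mode available).
`complexity_vs_k` pools pattern counts over all `k` offsets and quotes the SD of
`C` across 10 equal sections of the recording. AC(1) is the lag-1 Pearson
correlation restricted to lag pairs inside epochs of a chosen duration class — one
of several defensible conditionings; it is the package's convention.

## 8. Surrogates and cell selection

- Circular shift: each cell rotated by an independent uniform offset in
  `[1, n_bins−1]` (never the identity); conserves per-cell totals and
  rotation-invariant inter-spike structure exactly; destroys zero-lag correlations.
- Random spike addition: `round(pct/100 × total mass)` unit spikes at uniform
  (cell, bin) positions; 100% doubles the total.
- Cell removal: uniform random subset retained; repeat-and-average is the caller's
  responsibility (5 repeats typical).
- Trial shuffle: per cell and per stimulus condition, responses permuted across
  same-length trials; everything outside trials untouched.
- Uncorrelated-cell removal: `c_i` is the Pearson correlation of cell `i` with the
  all-except-`i` population; the null shifts `r_i` circularly by every
  `τ ∈ [−100, 100]` excluding `τ = 0` (the unshifted value is `c_i` itself and
  would bias the null; configurable). `z_i` standardizes against the null SD (a
  variance-denominator variant is selectable for compatibility); cells with
  `z_i < 0.01` are removed. All 201 shifted correlations come from one FFT-based
  circular cross-correlation.

## 9. What the synthetic data does and does not establish

The toy generator (`make_toy_raster`) plants exact coincident-firing envelopes on
correlated Poisson background — ground truth for detection, remapping and `S ∝ L²`
plumbing, but with none of real calcium imaging's indicator dynamics, soft
nonnegativity violations, or slow drifts. The E/I network provides real cascade
dynamics but with all-to-all uniform topology, binary spikes and discrete time; a
green recovery test establishes that the *analysis* recovers `χ = 2` from
subsampled critical dynamics of this model class, not that any particular
recording is critical. Desk-scale runs (`T ≤ 10^7` vs 10^8 in a full study) leave
the far tail of the duration distribution sparse; quantities defined below the
cutoff are stable at desk scale, while the plateau value of the scaling range `Φ`
itself (≈400 native steps) is only fully expressed in overnight-scale runs.

## 10. Known limitations

- The cohort engine requires `μ = 0`; leaky dynamics are naive-engine only.
- `select_threshold` assumes a unimodal (lognormal-shaped) `N(Θ)`; bimodal count
  curves (e.g. strong oscillations) will mislead it.
- `select_fit_window`/`detect_cutoff` assume the scaling regime is the
  best-sampled power-law-like stretch; for distributions with a large microscopic
  transient use the cutoff-anchored protocol of §5.
- AC(1) and the within-epoch complexity are undefined on series whose epochs are
  all shorter than the window depth; callers see explicit errors, not NaNs.
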