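# Methods

This note documents the statistical model behind `interbrain`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Design and model

Two speakers each narrate a story; their superimposed recordings are played
to listeners who attend to exactly one speaker. Sensory input is identical
across listeners; the attended-speaker label is the only manipulated
variable. Writing `x_l(t, c)` for listener `l`'s voltage at time `t` and
channel `c`, the working decomposition is

```
x_l = content_{g(l)} + sensory + noise_l
```

where `g(l)` is the attended speaker, `sensory` is common to all listeners,
and `noise_l` is listener-specific background activity that dominates the
variance. No distributional assumptions are made anywhere in the inference
chain: all p-values come from the exact group-exchange permutation
distribution, which only requires exchangeability of listeners under the
null that the attended-speaker label is irrelevant.

### Listener statistic

The content component of group `g` is estimated as `mean_g − grand mean`
(per time sample and channel), which cancels `sensory` exactly for equal
group sizes and in expectation otherwise. `R²_L = SS_between / SS_total`
pools squared deviations over time and channels (a one-way MANOVA ratio
flattened over the time×channel grid) and is averaged across stimuli.
Because even exchangeable listeners produce a positive sample `R²_L`
(expectation `(g−1)/(n−1)` per channel for white data), the reported effect
is the bias-corrected `ΔR²_L = observed − mean of the permutation
distribution`.

Decompositions: per channel, the *local* ratio `SS_between(c)/SS_total(c)`
is reported (each channel's own explained-variance share); per frequency,
*global* contributions `SS_between(b)/SS_total` are computed from
Parseval-weighted rFFT cross-products, so they sum to the pooled `R²_L`
to within 1e-12 relative — an identity the tests assert. Both families are
corrected by the max-statistic over their own permutation distribution.

### Coupling statistic

For each lag ℓ the listener content component at time `t` is paired with
the speaker's EEG at `t − ℓ` on the trimmed overlap (positive lag =
listener follows). Canonical correlation analysis between the two
channel sets yields correlations `r_1 ≥ r_2 ≥ …`, summarized by Cohen's
set correlation `R²_SL = 1 − Π(1 − r_i²)` — the complement of Wilks' Λ,
i.e. the proportion of generalized variance shared. This choice (over,
say, the mean squared canonical correlation) is deliberate: it is the
quantity whose complement factorizes over variates, reduces to the squared
Pearson correlation in the univariate case, and matches the
"generalized variance" reading. The one-to-one variant applies the same
product formula to the Pearson correlations of homologous channel pairs
only; it is blind to coupling routed through non-homologous patterns,
which is exactly what makes the contrast informative.

Per-lag values are averaged across stimuli and speakers *inside every
permutation replicate*, so the permutation distribution applies to the
averaged statistic. Canonical-variate counting uses Bartlett's sequential
chi-square approximation with the statistic
`−(n − (p+q+3)/2)·ln Π_{i>k}(1 − r_i²)` on `(p−k)(q−k)` degrees of
freedom, stopping at the first non-rejection.

### Permutation framework

Group exchanges keep group sizes fixed; for 12 listeners in 6/6 groups the
exhaustive grid has C(12,6) = 924 assignments including the identity. One
exchange relabels listeners jointly in every stimulus. P-values count ties
as exceedances (conservative) and include the identity, so `p ∈ [1/N, 1]`.
Family-wise correction compares each observed value with the permutation
distribution of the family-wide maximum. The bias-correction mean includes
the identity assignment, matching the p-value convention (configurable).

A structural fact worth knowing: with equal group sizes the two content
components are exact negatives of each other, and both `R²_L` and the
speaker-averaged `R²_SL` are invariant under the *full* group swap
(quadratic forms and CCA are sign-invariant). The minimum attainable
p-value for these statistics on the 924 grid is therefore 2/924 ≈ 0.00216,
while an asymmetric statistic (e.g. with unequal groups after a lost
recording) can attain 1/924 ≈ 0.00108. A Monte-Carlo fallback with a
stored seed replaces enumeration when C(n,k) exceeds a configurable cap.

## Synthetic ensembles

The generator plants exactly the structure the analyses target. Latent
story signals (default dimensionality d = 5 per speaker, reflecting the
multi-dimensional shared components such designs exhibit) are 1/f-shaped
("pink") standardized noise. The listener copy of the attended latent is
delayed by an integer number of samples (fractional lags round to the
nearest sample) and mixed through a group-level spatial pattern: the
speaker's own pattern under `homologous` mixing, an unrelated random one
under `random`. The sensory component mixes both latents (zero lag,
identical for all listeners). Background noise is spatially correlated —
independent 1/f sources through a random full-rank mixing — so covariance
matrices are realistic and CCA is not trivially easy.

Variance fractions are enforced by post-hoc scaling of the content and
sensory components against the realized mean noise power, which makes
`effect_fraction` directly interpretable as the planted share of listener
variance (realized per-listener fractions land within a few percent
relative). The generated ensemble stores the manifest and the ground-truth
component arrays for recovery tests.

What the generator does **not** emulate: eye/muscle artifacts, line noise,
nonstationarity, inter-listener latency jitter, volume-conduction
geometry, or any realistic cortical dynamics — the latent process is a
stand-in, not a model of narrative processing. Passing tests therefore
demonstrate that the *inference machinery* is correct and calibrated (the
permutation test is exact for any exchangeable noise, so calibration
transfers), not that real EEG carries effects of any particular size.

## Numerical choices

* CCA is computed by QR + SVD when unregularized; rank-deficient inputs
  raise an error unless ridge regularization is enabled. A relative ridge
  of 1e-3 on the within-set covariances is auto-enabled (with a warning)
  when samples < 5·(p+q). The permutation engine adds a relative 1e-12
  diagonal jitter before Cholesky factorization for numerical stability.
* The lag-scan permutation engine precomputes, per lag, all listener-pair
  and speaker–listener cross-product matrices; every relabeled statistic
  is then a quadratic form plus a channels-square SVD, which is what makes
  exhaustive 924-assignment inference over a lag grid feasible in seconds
  to minutes. A direct (slow) route exists for every statistic and the
  tests assert agreement between the two.
* Sample set correlation saturates when channel counts are large relative
  to the effective sample size (1/f autocorrelation shrinks effective
  degrees of freedom substantially). The reported `ΔR²` and the exact
  permutation p remain meaningful in this regime — the tests recover a
  planted 5 s lag at 63 channels precisely — but raw `R²_SL` values should
  never be interpreted without their permutation baseline.
* Frequency bins are `[k·Δf, (k+1)·Δf)` over the rFFT grid with Parseval
  weights (DC and Nyquist counted once); channels are mean-centered per
  listener and segment, so the DC bin is empty.
* Notch filtering uses second-order IIR notches (Q = 35) applied
  forward-backward (zero phase); audio-offset estimation maximizes the
  absolute cross-correlation at one-sample resolution, with the audio
  downsampled to the EEG analysis rate (default 100 Hz) beforehand.
* ICC form is ICC(2,1) — two-way random effects, absolute agreement,
  single rater — computed from the ANOVA mean squares.
* Transcript arithmetic rounds words to the nearest integer and semantic
  units to one decimal; unit durations are quantile word counts times the
  mean word duration.

## Validation problem sizes

The test suite and `scripts/acceptance.py` exercise, as this package's
chosen validation conditions: planted-lag recovery at 12 listeners ×
63 channels × 120 s × 100 Hz (effect fraction 0.05, lag 5.0 s, random
mixing, exhaustive 924 permutations over a −2…8 s × 0.5 s grid); type-I
error calibration over 200 null ensembles (effect 0, sensory 0.2;
12 listeners × 16 channels × 40 s × 50 Hz), asserting a rejection rate in
the exact-test binomial band at α = 0.05 and a mean `ΔR²_L` within ±0.005
of zero; and the set-vs-one-to-one contrast over 10 seeds at 24 channels ×
90 s × 50 Hz.

## Known limitations

* Group sizes must currently be equal within an ensemble, and the observed
  grouping must be positionally identical across stimuli for joint
  permutation.
* The frequency decomposition of the *coupling* effect (as opposed to the
  listener effect) would require band-filtering both sets and repeating
  the CCA per band, since Parseval does not commute with CCA; the listener
  frequency decomposition is exact, the coupling one is not built in.
* The default 7×9 ROI layout over generic channel names is consecutive
  blocks — a documented stand-in adequate for planted-structure recovery;
  real montages should supply a YAML ROI spec with 10/20 names.
* ICA estimation itself is delegated to external tooling; only the
  ratings-driven removal harness and its file contract live here.
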