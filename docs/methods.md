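# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `kseqland`.

## Kinetic model and fitting

Each sequence–substrate pair is described by the pseudo-first-order law
`F = A(1 − exp(−k·α·[S]·t))`, where `F` is the fraction of RNA
aminoacylated after the reaction, `A ∈ [0, 1]` the maximum amplitude,
`k` (M⁻¹min⁻¹) the rate constant, `[S]` the initial substrate
concentration (stored in μM, converted to molar inside the kinetic law),
`t = 90` min, and `α = 0.479` a fixed coefficient accounting for substrate
hydrolysis during the reaction, applied uniformly to all substrates.
Because `α` rescales every fitted `k` identically, it cancels in catalytic
enhancement ratios; this is asserted by test.

**Fractions reacted.**  A sequence's absolute amount (ng) in a sample is
its read fraction times the sample's mean qPCR total-RNA measurement; its
input amount is the median of those amounts over the (six) unreacted-pool
replicates; `F` is reacted over input amount.  Sequences absent from the
input pool are dropped with a logged record (their `F` is undefined).
Samples with zero total reads are excluded with an error record.  `F`
values above 1 (possible through quantitation noise) are retained in
fitting and flagged, not clipped — clipping would bias amplitudes;
the bounded amplitude regularises the fit instead.

**Filtering.**  Before fitting, sequences are kept only if they are
unambiguous (ACGT), exactly 21 nt, and within two substitutions of a
family center.  A sequence within range of several centers is assigned to
the nearest; exact ties go to the center configured first (the choice is
deterministic and flagged in output; which center such a sequence
"belongs" to is not decidable from the data).

**Fitting.**  All replicate points are fit jointly by unweighted least
squares (no pre-averaging), with bounds `A ∈ [0, 1]`,
`k ∈ [1e−4, 1e8]` M⁻¹min⁻¹.  The solver uses variable projection: for
fixed `k` the optimal amplitude has the closed form
`Â(k) = clip(ΣFg / Σg², 0, 1)` with `g = 1 − exp(−kα[S]t)`, reducing the
problem to one dimension in `log k`.  A 241-point log-spaced grid scan
locates the basin (the grid loss is computed as an explicit residual sum;
the expanded quadratic form loses all significance when the loss is
~1e−20 on noiseless data), and Brent root-finding on the profiled
envelope gradient polishes the optimum to near machine precision.  This
is substantially more robust than a generic two-parameter optimiser on a
model whose loss surface has long plateaus in `k`.

Fits are flagged non-converged when fewer than two distinct concentrations
are available, when the optimum sits at the rate bounds, when the
amplitude collapses to zero (no signal), or when the reaction is saturated
even at the lowest concentration (`kα[S]min·t > 20`), in which case the
data pin the amplitude but carry essentially no rate information.  Flagged
fits still report their parameter values.

One practical precision limit is worth recording: for noiseless data with
`k ≳ 3×10⁵` M⁻¹min⁻¹, the 2 μM points differ from `A` by less than
~1e−11, and the float64 rounding of the stored fractions itself perturbs
the implied rate by ~1e−6 — no solver can do better from those numbers.

**Bootstrap.**  Uncertainty comes from resampling the individual
(concentration, replicate) fraction-reacted points with replacement to
the original size, 1000 times, refitting each resample, and reporting the
median, SD, and 2.5/97.5 percentiles of `k`, `A`, and `k·A`; the
bootstrap median of `k·A` is the sequence's reported activity.  The
resampled refits are vectorised over replicates on a 201-point local grid
centred ±2.5 decades around the point estimate with parabolic sub-grid
refinement (quantisation ≪ 0.1%).  Bootstrap seeds are spawned per
(sequence, substrate) from a CRC32 of the pair's identity, so results are
independent of iteration order and of which other groups are fit.

A structural caveat: the per-sequence input amount is *shared* by all 15
points of a fit, so input-side noise (input-pool counting and qPCR error)
shifts all fractions together.  Resampling the reacted points cannot see
this component, and with ~500 input reads per sequence the resulting 95%
bootstrap intervals cover the true `k·A` at roughly 82–90% rather than
95% in our simulations.  This is a property of the interval construction
under count-limited input quantitation, not of the point estimate (which
stays accurate to a few percent, see below).

## Background estimation and catalytic enhancement

For each substrate, log₁₀(kA) values pooled over all families are
histogrammed into 100 equal-width bins spanning [min, max] and the bin
densities are least-squares fit to a two-component Gaussian curve
(`scipy.optimize.curve_fit`; initial means at the 25th/85th percentiles;
components reordered so μ₁ ≤ μ₂).  The low-peak mean gives the
uncatalysed rate `k₀A₀ = 10^μ₁`, and `r = kA/k₀A₀`.  Non-positive kA
values are excluded before the log; values at the fit lower bound are
retained (they populate the background peak, and excluding them would
bias μ₁ upward).  If the mixture fit fails or collapses onto one
component, a single Gaussian is fit instead and flagged.  An EM fit on
the raw (unbinned) values via `sklearn.mixture.GaussianMixture` is
provided as a cross-check; the two routes agree within 0.1 log-units on
simulated data.

The 95% background band on the enhancement scale is
`[10^(−1.96σ₁), 10^(+1.96σ₁)]` around `r = 1`.  The statement that the
activity threshold `r_t = 5` is "two-fold more than the 95% range" admits
two readings — threshold over the band's upper edge, or over the band's
full fold-ratio (upper/lower) — and `background_band` reports both rather
than deciding.

## Specificity metrics

The promiscuity index is the Shannon entropy of the enhancement
proportions normalised by `log N` (natural log internally; the base
cancels, asserted by computing in two bases).  `0·log 0 := 0`.  Aromatic
preference is the summed enhancement on {BWO, BFO} over the total.  Both
are undefined (NaN with an error record) when the total enhancement is
zero.  Pairwise substrate regressions are OLS with intercept by default;
since the intercept treatment of such comparisons is a free choice, the
through-origin slope is always reported alongside.  Total activity is
`Σ_X r^BXO`; per-family activity–specificity association is reported as
Pearson's R and Spearman's ρ with two-sided p-values.

## Co-option census and landscape connectivity

"Active on a substrate" means `r > r_t` strictly (default `r_t = 5`);
sequences active on ≥ 2 substrates are counted as co-optable.  Results
change only for `r` exactly equal to `r_t` under a non-strict reading.

The landscape graph of a family contains the wild type, the six
highest-enhancement sequences per substrate (ties broken by higher total
activity, then lexicographically), and connector sequences: for every
seed pair at Hamming distance 2, the two single-substitution hybrids are
looked up in the family table and added when their total enhancement
exceeds the activity floor (default `30 = r_t × 6` substrates).  The scan
is a single pass over seed pairs; connectors found are not themselves
re-scanned for further pairs.  Edges join nodes at Hamming distance 1.
Connectivity is reported as components plus whether all per-substrate
peaks share one component, with pairwise peak path lengths.  Neighborhood
reasoning is substitution-only, consistent with a fixed-length design
space.

## Clustering

Selection pools are clustered greedily: sequences sorted by count
(descending; ties broken lexicographically for determinism), the most
abundant unassigned sequence with count ≥ c_min (10) seeds a family, and
all unassigned sequences with count ≥ a_min (1) at Levenshtein distance
strictly less than d_cutoff (3) join it permanently; families smaller
than n_min (1) dissolve back.  Sequences below a_min are skipped for the
current family but remain available later (with the default a_min = 1 the
distinction never triggers).  Levenshtein distances are computed with
`edlib`; the test suite checks the clusterer against an independent
dynamic-programming reference on random pools.

## Synthetic-data generator

The generator emulates the structure of the assayed pools so that every
stage can be validated against known truth.  What it models:

- **Pools**: five families, each a seeded random 21-mer center plus all
  single/double mutants (1954 sequences; overlapping neighborhoods are
  resolved by the nearest-center rule).  Input abundances follow the
  doped synthesis profile (91% wild-type base, 3% per substitution), so
  double mutants are ~900-fold rarer than the wild type — as in the real
  library, most of the read budget sits on a few sequences.
- **Activities**: a sequence is inactive with family-specific probability
  (its kA scatters log-normally, SD 0.25 log-units, around the background
  rate 0.55 M⁻¹min⁻¹); otherwise log₁₀(kA) is drawn from a family
  distribution (mean 1.3, SD 0.8 — enhancements centred near 40 with a
  long tail) shifted by per-substrate preference multipliers, plus
  equicorrelated log-normal noise (SD 0.3).  The active tail is
  log-normal as the simplest heavy-tailed positive model consistent with
  bimodal log-histograms.  Amplitudes are uniform (0.5–1 active, 0.2–1
  inactive) and `k = kA/A`.
- **Activity–specificity coupling**: the preference profile of an active
  sequence is raised to the power `max(0.2, 1 + γz)`, where `z` is the
  sequence's activity z-score and `γ` the coupling strength (default
  0.5).  More active sequences therefore have sharper substrate profiles
  — lower promiscuity, higher aromatic preference — reproducing the
  characteristic sign pattern of per-family correlations.  The five
  default family specs differ in inactive fraction, preference order
  (aromatic-favouring motifs vs. a broadly active, F-preferring pair of
  families), and cross-substrate correlation.
- **Readout**: reacted reads are multinomial with probabilities
  ∝ abundance × F at 10⁶ reads per sample (triplicates at 1250, 250, 50,
  10, 2 μM; six input-pool replicates); total reacted RNA is the true
  reacted mass under multiplicative log-normal qPCR noise (CV 0.05 per
  measurement, triplicate measurements per sample — typical intra-assay
  quantitation variability, and consistent with the recovery accuracy the
  k-Seq estimator is expected to deliver at this depth).  A noiseless
  mode (infinite depth, zero qPCR CV) yields exact expected fractions for
  round-trip tests.

What it does **not** model: sequencing error, PCR amplification bias,
paired-end joining artifacts, substrate depletion beyond the fixed α, or
any sequence–structure relationship (activities are drawn independently
of the mutation positions).  Passing tests therefore demonstrate that the
estimators recover the truth under the assumed noise model, not that the
noise model captures every feature of real experiments.

Under these defaults, the bootstrap-median `k·A` of sequences with true
enhancement in [10, 1000] is recovered with a median relative error just
under 5% (dominated by input-pool counting noise on low-abundance double
mutants), and the estimated background normalises truly inactive
sequences to a median enhancement within [0.8, 1.25].

One statistical artifact deserves note: even in a fully exchangeable null
landscape (no coupling, equal preferences, independent per-substrate
noise), the activity–promiscuity *rank* correlation is slightly negative
(ρ ≈ −0.1 to −0.2).  The enhancement sum and its evenness share the same
per-substrate noise: a lucky high draw on one substrate raises the total
and lowers the entropy simultaneously.  Product-moment correlations stay
within ±0.1.  Interpreting small negative rank correlations in real data
therefore requires this baseline.

## Determinism and problem sizes

All randomness descends from explicit integer seeds; identically seeded
runs produce byte-identical outputs (asserted by test).  The test suite
exercises the full analysis at the scale of one complete family
(1954 sequences × 6 substrates, 10⁶ reads per sample, 1000 bootstrap
resamples for every pair in the recovery window) and uses reduced pools
(shorter variable regions, fewer families) for pipeline smoke tests;
these sizes keep the whole suite to a few minutes on one CPU while
preserving every structural feature of the full design.
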