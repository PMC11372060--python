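# Methods

## Signal model

A backscatter trace from one well is modelled as the sum of a smooth growth
trend, an oscillatory clock output, a start-up transient, and noise:

    y(t) = g(t) + c·e^{−t/τ} + A₀·e^{−λt}·cos(2πt/P + φ₀) + ε,   ε ~ N(0, σ²) i.i.d.

- `g(t)`: polynomial of degree ≤ 4 (coefficients in backscatter units per
  hourᵏ) or a logistic curve; represents culture growth, which dominates the
  raw signal.
- `c·e^{−t/τ}`: instrument/culture settling transient after the plate is
  loaded; with the default τ = 1 h it decays to < 5 % within 3 h, which is
  why the first 3 h are excluded from trend fitting.
- `A₀` (backscatter units), `P` (hours), `φ₀` (radians): oscillation
  amplitude, period, and phase.
- `λ` (h⁻¹): exponential damping; 0 for a self-sustained rhythm.
- `σ`: i.i.d. Gaussian measurement noise. The noise spectrum of the real
  instrument is not characterized; white Gaussian noise is an explicit
  modelling assumption, not a measured property.

The synthetic generator (`cyanorhythm.synthetic`) draws exactly from this
model. Per-well seeds derive from `SeedSequence((experiment_seed, well_index))`,
so plates are bit-reproducible. Default study-like conditions: 84 h duration,
5-min sampling (1009 points), 5 replicate wells per strain, noise SD 8 on an
oscillation of amplitude 80 (signal-to-noise ≈ 10), a monotone quartic trend
rising from ~200 to ~3200 a.u. What the generator does **not** emulate:
autocorrelated instrument noise, well-to-well trend heterogeneity, growth
arrest, evaporation drift, or period drift over the run. Tests passing on
synthetic plates therefore certify the *procedure*, not the behaviour of any
particular instrument.

## Signal isolation (preprocess)

1. **Trend fit**: OLS polynomial of degree 4 on all samples with
   t ≥ 3 h. Internally the fit uses a rescaled time basis (a quartic design
   on t ∈ [0, 84] is ill-conditioned in raw monomials); coefficients are
   reported in the monomial basis, lowest order first.
2. **Detrend**: the fitted polynomial is evaluated and subtracted at *all*
   time points, including the excluded first 3 h.
3. **Normalize**: subtract the residual's arithmetic mean (over all
   samples).
4. **Smooth**: convolve with a uniform kernel of 40 samples (3 h 20 min at
   5-min sampling), weight 1/40, zero-padded "same" alignment. The edge
   bias of zero padding (first/last ~20 samples pulled toward zero) is
   reproduced deliberately; `PeakParams.edge_exclude` can drop those samples
   from peak search (off by default).

Normalization precedes smoothing; for a uniform kernel the order matters
only at the edges.

### Known distortion of sequential detrending

Fitting a quartic to trend + cosine absorbs the projection of the cosine
onto the polynomial space. Over 84 h a 26 h cosine completes only ~3.2
cycles, and a quartic absorbs ≈ 14 % of its variance (the degree-4
component resonates with so few cycles; confirmed numerically and by a
Legendre/spherical-Bessel expansion). Consequences, all verified by the
test suite against independent closed-form oracles:

- the processed signal equals `cosine − OLS-projection − mean` exactly, but
  its correlation with the true cosine on t ∈ [3, 81] h is ≈ 0.93, not ~1;
- the best-fitting single cosine of that residual has period ≈ 25.1 h for a
  26.0 h input (−0.9 h systematic bias) and amplitude ≈ 75 for an input of
  80 (−6 %);
- extrapolating the polynomial into the excluded first 3 h produces a large
  artifact there (order +150 units at t = 0 for an amplitude-80 cosine), so
  rhythm features that fall in the first ~3 h (e.g. the first trough of a
  strongly phase-advanced strain) are unreliable.

This bias is a property of the sequential detrend-then-fit procedure, which
the package reproduces faithfully; it cancels to first order in
*between-strain comparisons* (phase shift, relative amplitude), which is
the setting the metrics are designed for. Joint trend+cosine fitting would
remove the bias but is a different method and is out of scope.

## Period estimation (harmonic)

The cosinor model `A·cos(ωt + φ)` is fitted by bounded least squares
(trust-region reflective) under `0 ≤ A ≤ max(y) − mean(y)`,
`2π/P_max ≤ ω ≤ 2π/P_min` with the widest default period envelope
[18 h, 45 h] (narrower per-strain envelopes are config), and
`2π/12 ≤ φ ≤ 2π`. The objective is multimodal in ω, so the fit multi-starts
from 8 equally spaced periods across the envelope, with A at half its upper
bound and φ at the midpoint of its box. The best start wins by smallest
residual sum of squares, ties broken by smaller period (determinism).
Convergence uses the solver's xtol/ftol/gtol at 1e-10. A fit with A pinned
at 0 (or a constant input, A_max = 0) is flagged `degenerate` and not
`converged`; `relative_rss` (rss over total sum of squares) is reported so
callers can decide that a strain is not cosine-like — no threshold is
imposed.

By default the pipeline fits the replicate-averaged *normalized* signal per
strain (averaging suppresses noise; the unsmoothed signal avoids the
moving-average amplitude attenuation, which is ≈ 2.7 % for a 26 h cosine
under the 40-sample kernel). Per-well fitting and fitting the smoothed
signal are both available (`fit_averaged`, `fit_signal`).

Two practical caveats, both consequences of the stated model and bounds
rather than implementation choices: the model has no intercept, so a
residual constant offset (a window that is not an integer number of
periods has nonzero cosine mean) slightly biases ω; and the data-driven
amplitude bound `max − mean` can sit *below* the true amplitude when the
window mean of the oscillation is positive, clipping A at the bound.

## Dampened-oscillation metrics (rhythm_features)

Peak detection is prominence-based with the conventions of
`scipy.signal.find_peaks` (the brute-force enumerator in the test suite
pins them down independently): strict local maxima with plateaus collapsed
to the floor-midpoint sample; height filter; distance thinning that keeps
the highest remaining peak first; optional filter on the full width at half
prominence (linearly interpolated). Defaults follow the original analysis
and are quoted in samples at 5-min sampling, rescaled by Δt for other
grids:

- first-cycle period: distance 150 (12.5 h), height 50 (normalized
  backscatter units — configurable, since synthetic scales differ; the
  acceptance runs use 10 for amplitude-80 signals, safely above the
  smoothed noise floor of ≈ 1.3 units and below the smallest true extremum
  of ≈ 20);
- first-peak features: distance 150, width 65 (≈ 5.4 h), height
  mean + 0.2·max of the signal.

The first-cycle period is `2·|t(first peak) − t(first trough)|`; the
absolute value makes it order-independent. For a damped cosine the
`atan(λ/ω)` extremum shift affects trough and peak equally, so the
trough-to-peak distance remains exactly half the period.

Strain summaries use the arithmetic mean and the sample SD (n−1; SD = 0 for
a single well). Phase shift and relative amplitude compare a mutant's
first-peak summary to a reference strain's; their error boundaries are the
plain sum of SDs and the sum of relative SDs, implemented literally (a
propagated-error variant that scales by the ratio is available behind a
flag, off by default). Wells whose features cannot be detected raise
`FeatureError`; the pipeline logs and skips them rather than guessing — a
deliberately conservative choice for very low-amplitude strains.

## Strain statistics (group_stats)

Classic mean-centred Levene (W against F(1, n₁+n₂−2); median centring is a
config option) gates the mean test: Welch's t when Levene's p < 0.05,
pooled-variance Student's t otherwise. Both two-sided; significance at
p < 0.05. No multiple-testing correction is applied across the pairwise
strain grid by default. The suite verifies the cascade's empirical type-I
error at n = 5 per group is within [0.04, 0.06] over 10⁴ null replicates,
and all p-values against textbook-formula oracles at 1e-9.

## Co-occurrence (cooccurrence)

Within the universe of genomes carrying the anchor protein, each unordered
protein pair gets a 2×2 table (rows: protein 1 present/absent; columns:
protein 2) and a right-sided Fisher's exact p = P(X ≥ a) — enrichment of
joint presence — computed through the hypergeometric survival function
(log-space internally). A zero row or column margin gives p = 1. BH
step-up adjustment runs over all tested pairs as one family; edges keep
adjusted p ≤ 0.01 by default (a flag thresholds raw p instead, since the
original figure's wording is ambiguous on this point). Degrees count
retained incident edges. Phylogenetic non-independence of genomes is a
known limitation and is not modelled.

## Stoichiometry

Complex mass = Σ copies × monomer mass, with tag-inclusive nominal monomer
masses (KaiC3 58, KaiA3 35, KaiB3 12 kDa) as the default table; a
sequence-derived table can be supplied instead. Molar ratios are
`conc_b/conc_a`, rounded half-even.

## Problem sizes and determinism

Default test and acceptance runs use 84 h × 5-min plates (1009 samples),
5 wells per strain, 10⁴ replicates for the type-I simulation, 500 random
signals for the peak-detector/enumerator equivalence, and exact Fisher
checks across all margins N ≤ 60 — sizes chosen so the whole suite runs in
about a minute on one core while keeping every estimate's Monte-Carlo error
well inside its asserted tolerance. All randomness is seeded; pipelines
re-run byte-identically from the same config and seed.
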