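# Methods

## Quantification model

The qPCR calibration assumes log-linear amplification over the standard
range: `C_T = b₀ + b₁·log₁₀ q`, with `q` in spore equivalents per reaction.
The slope must be negative; amplification efficiency is reported as
`10^(−1/b₁) − 1` (1.0 at a slope of −3.32). The curve is re-fitted per
plate from the standard wells by ordinary least squares; standards that
fail to amplify are omitted from the fit rather than imputed, and a span of
fewer than two decades or fewer than three points is a calibration error.

Replicate QC follows the drop-one rule: triplicates with sample SD
(ddof = 1) ≥ 0.2 cycles retain the leave-one-out pair with the smallest SD.
When two candidate drops tie exactly (a symmetric triplicate), the replicate
with the highest C_T is dropped — late amplification is the common failure
mode — making the rule deterministic. Pairs pass through unchanged; fewer
than two finite replicates is a QC failure for that sample, flagged rather
than silently imputed.

Back-calculation scales the per-reaction quantity by elution/template
volume (defaults 50 µL and 2 µL). Samples quantifying below the lowest
standard (10⁰ per reaction) keep their extrapolated value but carry a
`below_loq` flag: unexposed field blanks are expected to sit in this
regime, and dropping them would silently hide contamination signals.

## Spore-equivalent integerization

Relative abundances are computed after all taxonomic filtering (non-fungal
kingdoms and missing genus assignments removed, genera aggregated), over
the genera present in the sample; `S` counts present genera only. The qPCR
total `A` stays real-valued throughout — only the final per-genus values
are integers. The adjusted total is

    A_adj = A − (Σᵢ ⌈Rᵢ·A⌉ − A),

and per-genus counts are `⌈Rᵢ·A_adj⌉`. Two guarantees follow and are
enforced by tests: every present genus keeps at least one spore
equivalent, and the adjusted count total never exceeds the unadjusted one.
`A_adj ≤ 0` (possible only when `A < S`) is a degenerate-sample error that
names the sample; it indicates a spore load too small to carry the
observed richness and has no meaningful integerization.

Repeated active samples are each integerized with their own qPCR total and
then summed over the union of genera. The alternative — pooling raw reads
and applying a summed total — is a mathematically different quantity
(it re-weights the two days by read depth rather than by spore load) and
is deliberately not offered.

## Coverage and rarefaction

Reference-sample coverage uses the singleton/doubleton estimator
`Ĉ = 1 − (f₁/n)·(n−1)f₁/((n−1)f₁ + 2f₂)`; interpolated coverage and
richness use the hypergeometric forms
`Ĉ(m) = 1 − Σᵢ (Xᵢ/n)·C(n−Xᵢ, m)/C(n−1, m)` and
`S(m) = S_obs − Σᵢ C(n−Xᵢ, m)/C(n, m)`. All binomial-coefficient ratios are
evaluated as differences of log-gamma functions, so totals of several
hundred thousand spore equivalents are handled without overflow; tests
confirm agreement with exact rational arithmetic at small n (1e-10) and
with exhaustive subsample enumeration for every abundance vector with
n ≤ 12.

The subsample size at a target coverage is defined as the *smallest
integer* m with `Ĉ(m) ≥ target` (integer because the value has subsampling
semantics), found by binary search over the nondecreasing coverage curve
and cross-checked against a linear scan in tests; `m = n` maps to the
reference-sample estimator. Samples whose reference coverage is below the
target raise an exclusion signal — extrapolation beyond the reference
sample is out of scope because it relies on the singleton/doubleton tail
that integerized spore-equivalent data often lacks. The exclusion operates
at residence level: one low-coverage sample removes the whole residence
from the paired analysis.

Rarefied per-genus abundance is `Rᵢ·m`, unrounded, with `Rᵢ` taken from
the integer spore-equivalent vector (the vector the rarefaction actually
operates on); its deviation from read-based `Rᵢ` is bounded by the ceiling
inflation, which the adjustment keeps near zero.

## Statistical comparison

The test-selection gate interprets "normal and homoscedastic" as:
Shapiro–Wilk on the paired differences and a two-sided F-ratio test of the
two series' variances, both at α = 0.05; the paired t-test is used only
when both pass, otherwise the exact Wilcoxon signed-rank test. The exact
Wilcoxon drops zero differences, assigns mid-ranks to tied |d|, and builds
the null distribution of W⁺ by dynamic programming over the realized
(doubled, hence integer) rank multiset — equivalent to full 2ⁿ sign
enumeration, which the tests verify directly. Two-sided p values are
`min(1, 2·min(P(W ≤ w), P(W ≥ w)))`.

Holm families are one per metric × location (the three pairwise group
comparisons adjusted together); families are not pooled across locations
or metrics. This is the narrowest family consistent with
location-stratified reporting; the choice is configurable in the sense
that `holm_adjust` is exposed and the comparison layer can be re-driven
over any grouping.

Indoor/outdoor ratios use untransformed values; indoor = 0 is excluded as
"zero", outdoor = 0 as "undefined". Group comparisons of ratios use
Mann–Whitney U, exact by rank-split enumeration up to combined n = 20,
otherwise a normal approximation with tie correction and continuity
correction (verified against the exact method to < 0.01 absolute at
n = 10 + 10).

## Synthetic studies

The generator emulates the paired design: 12 residences × {indoor,
outdoor} × {active day 6, active day 7, passive 1-day, passive 7-day} = 96
physical samples. Defaults are the study's operating magnitudes: a
1500-genus regional pool with lognormal rank abundances (meanlog 0, sdlog
2.5), amplicon depths uniform on [7432, 35338], expected spore loads of
21,080 (per active day), 41,072 (1-day passive) and 115,392 (7-day
passive) spore equivalents, C_T noise σ = 0.05 cycles, and a 10% chance
per sample of one +1.5-cycle outlier replicate (exercising the drop-one
rule). Communities: outdoor = Dirichlet(regional mean × 5000); indoor =
overlap-weighted mix (default 0.7) of outdoor and an independent
indoor-specific draw, with multiplicative indoor effects on designated
allergenic genera (defaults: Aspergillus ×2, Schizophyllum ×1.5, the two
genera whose indoor/outdoor ratios exceed one in field data). The eight
allergenic genera are seeded into the pool at boosted abundance so a
realistic study detects them in most samples. Spore capture is Poisson
around the expected load; read depth and spore load are drawn
independently — amplicon depth is instrument-driven, which is precisely
why absolute calibration is needed, and the simulator preserves that
decoupling. Randomness flows from a single master seed through named
substreams (community, sampling, qPCR) keyed additionally by residence,
location and sample kind, so any stage regenerates identically regardless
of call order.

Residences listed as *shallow* have all loads scaled by 0.03. That factor
is set by the coverage model, once: it pushes totals to the few-hundred to
few-thousand spore-equivalent range where the integerized profile is
singleton-rich (coverage far below 97.5%) while keeping `A > S` so the
integerization stays non-degenerate — mirroring field samples that are
excluded for low coverage but still quantifiable.

What the generator does **not** emulate: sequence-level artifacts (primer
bias, chimeras, length variation), rDNA copy-number variation across taxa,
aerosol physics (settling velocity, particle size), meteorological
covariates, and insect or debris contamination of passive traps. Passing
recovery tests therefore demonstrate that the *computational* chain —
calibration, integerization, standardization, testing — is unbiased and
rank-faithful under the design's noise structure, not that field samples
are free of the above processes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the complete 12-residence
design (96 physical samples, 1500-genus pool) once and share it across
checks; unit oracles (exhaustive enumeration, Monte-Carlo subsampling,
exact rational arithmetic) run on vectors small enough to enumerate. Exact
Wilcoxon enumeration is exercised to n = 10 pairs and Mann–Whitney to
combined n = 12 against test-local brute-force oracles. Tolerances: 1e-10
for enumeration equivalence, 1e-9 relative for calibration round-trips,
3 standard errors for Monte-Carlo agreement, 2% log-scale bias and
Spearman ≥ 0.95 (genera at true relative abundance ≥ 0.005) for recovery
at the fixed test seed.

## Known limitations

- Spore equivalents inherit the calibration species' rDNA copy number;
  cross-taxon copy-number variation is not corrected, so between-genus
  abundance contrasts carry that systematic uncertainty.
- The assumption gate (Shapiro–Wilk + F-ratio) is one defensible reading
  of "normal and homoscedastic"; other gates (e.g. Levene) would
  occasionally select the other test near the α boundary.
- Coverage below target excludes a whole residence; with many shallow
  residences the paired design loses power quickly, and the pipeline
  reports but does not remedy this.
- Sub-LOQ samples are flagged, not dropped; downstream users must decide
  how to treat them (field blanks typically live here).
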