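# Methods

## Model

Two-sample summary-data Mendelian randomization. Each instrument i carries a
true effect γᵢ on the exposure; the outcome-side effect is
β_true·γᵢ + αᵢ, where αᵢ is a direct (horizontally pleiotropic) effect that
bypasses the exposure and is zero for valid instruments. Observed summary
statistics add independent Gaussian sampling noise with the per-variant
standard errors reported by the GWAS. All estimators consume the harmonized
quadruples (β̂_GX, σ_GX, β̂_GY, σ_GY).

### Estimators

- **Wald ratio**: β̂_GY/β̂_GX with SE σ_GY/|β̂_GX|. Only the first-order
  delta term is used; the σ_GX contribution is omitted, which is accurate
  when instruments are strong (|β_GX|/σ_GX ≫ 1), the regime instrument
  selection enforces.
- **IVW**: weighted mean of ratios with weights wᵢ = β̂_GXᵢ²/σ_GYᵢ²,
  identical to weighted least squares of β̂_GY on β̂_GX through the origin
  with weights 1/σ_GY². Fixed-effect SE (Σw)^(−1/2); the
  multiplicative-random-effects variant (default for N ≥ 2) inflates it by
  φ = max(1, √(Q/(N−1))) with Q the Cochran heterogeneity of the ratios, so
  the SE never deflates below fixed-effect under homogeneity.
- **Weighted median**: ratios sorted ascending; standardized cumulative
  weight pᵢ = (Σ_{k≤i} w_k − wᵢ/2)/Σw; the estimate interpolates linearly
  between the two ratios bracketing p = 0.5 (clamped to the extreme ratio
  when 0.5 falls outside the grid). SE is the standard deviation over a
  seeded parametric bootstrap (default 1000 replicates) drawing
  β̂*_GX ~ N(β̂_GX, σ_GX), β̂*_GY ~ N(β̂_GY, σ_GY); bootstrap draws with
  β̂*_GX = 0 are excluded from that replicate.
- **MR-Egger**: instruments oriented so β̂_GX ≥ 0 (negating the paired
  β̂_GY), then weighted linear regression with intercept (weights 1/σ_GY²,
  fitted via statsmodels WLS). The slope estimates the causal effect, the
  intercept the mean directional pleiotropy under InSIDE; both SEs are
  inflated by max(1, √(RSS_w/(N−2))).

Inference is normal-theory throughout: two-sided p from z = β̂/SE, 95%
intervals with multiplier 1.959964. Normal rather than t quantiles match
z-scored GWAS pipelines that report p-values at extreme magnitudes (10⁻³³);
at the instrument counts involved (≥150) the difference is negligible.

### Sensitivity battery

- **Leave-one-out**: IVW recomputed omitting each instrument; the summary is
  the maximum absolute deviation from the full-set estimate.
- **Steiger directionality**: per-instrument variance explained via the
  t-statistic transform r²ᵢ = tᵢ²/(tᵢ² + nᵢ − 2) (needs only β̂, SE, n — no
  allele frequencies), summed over instruments per trait (valid because
  clumped instruments are approximately independent). Direction is
  "correct" when Σr²_exposure > Σr²_outcome; the p-value is a two-sided
  z-test on the difference of Fisher-transformed √r² with variances
  1/(n−3), using the mean per-instrument sample size per trait. The
  aggregate (trait-level) formulation is deliberate; a per-instrument
  variant would need a multiplicity rule the aggregate avoids.
- **MR-PRESSO**: residuals rᵢ = β̂_GYᵢ − β̂₍₋ᵢ₎·β̂_GXᵢ from leave-one-out
  through-origin slopes; RSS = Σrᵢ²/σ_GYᵢ². The null distribution comes
  from parametric simulation (β̂*_GX ~ N(β̂_GX, σ_GX),
  β̂*_GY ~ N(β̂₍₋ᵢ₎β̂_GX, σ_GY)) with leave-one-out slopes *recomputed on
  each simulated dataset*. Monte-Carlo p-values take the (1+k)/(1+n_sim)
  form and are never exactly 0. Outliers: per-instrument residual p below
  0.05/N (Bonferroni). The corrected estimate is IVW without flagged
  outliers (identical object to the raw estimate when nothing is flagged);
  the distortion p compares the raw-minus-corrected difference against
  differences from removing random subsets of the same size (two-sided).

### Instrument selection

Genome-wide filter keeps p strictly below 5×10⁻⁸, then greedy clumping:
sort by ascending p (ties by chromosome, then position, making the output
independent of input order), take the best remaining variant as an index,
and remove same-chromosome variants within the window whose r² with it
meets the threshold. Defaults: r² < 0.01 and a 10 Mb window — the window is
the conservative two-sample-MR convention since the matching PLINK setting
is rarely reported; both are configurable. r² is the squared Pearson
correlation of unphased dosages (composite LD), adequate for clumping.
Variants unknown to the LD provider are treated as independent and logged
(policy `drop` discards them instead): with a sparse toy panel, silently
discarding instruments would be the worse failure mode.

### Harmonization

Non-palindromic variants are aligned by literal allele match, label swap
(negate β̂_GY, complement EAF), strand complement, or both; anything else is
dropped as a mismatch. Palindromic variants (A/T, C/G) are label-aligned
first, then oriented by allele frequency: kept only when both frequencies
lie outside 0.5 ± 0.08 *and* agree in orientation; discordant frequencies
are dropped rather than flipped (a strand flip cannot be distinguished from
a genuine frequency discrepancy, and with ~10⁶ candidate variants the cost
of dropping is small). Missing frequency on either side drops a palindromic
variant; non-palindromic variants never need frequencies. Harmonizing an
already-harmonized pair is a no-op, and consistently swapping any
instrument's allele labels leaves every downstream estimate unchanged to
machine precision (tested to 12 significant digits).

## Synthetic data generator

`simulate_sumstats` draws, per instrument: maf ~ U(0.05, 0.45);
γ = |N(0, gamma_sd²)| — instruments are coded to the exposure-increasing
allele, the standard convention in MR simulation designs; with sign-symmetric
γ a fixed-sign α would *not* be directional on the ratio scale (α/γ takes
both signs) and directional pleiotropy would not bias IVW, defeating the
robustness comparisons the generator exists to support (`orient_gamma=False`
restores symmetric γ). Standard errors use the standardized-trait
approximation SE = 1/√(2·n·maf(1−maf)), which ignores residual-variance and
covariate terms but gives the correct n^(−1/2) and allele-frequency scaling;
an `se_floor` (10⁻¹²) makes n = ∞ a usable noise-free limit. Observed
effects are β̂_GX ~ N(γ, SE_x) and β̂_GY ~ N(β_true·γ + α, SE_y), with an
optional `overlap_rho` correlating the two noise terms to mimic one-sample
(overlapping-cohort) designs; the default 0 reflects the standard
non-overlapping two-sample setting, and the knob exists because sample
overlap biases MR-Egger before it biases IVW or the weighted median.

Default study conditions — 170 instruments, β_true = −0.24, GWAS sizes
166k/194k, gamma_sd = 0.05 — mirror a whole-body-fat-mass-on-total-
testosterone style analysis: ~170 retained SNVs, an effect of −0.24 on the
standardized outcome, and instrument strengths that put the large majority
past genome-wide significance at n = 166k. Pleiotropy defaults
(`pleio_fraction` 0.3, `pleio_mean` 0.02, `pleio_sd` 0.01) encode a
moderate directional scenario: 30% invalid instruments whose mean direct
effect is ~40% of the typical instrument effect.

What the generator does *not* emulate: LD between instruments (summary pairs
are drawn independently; LD lives only in the separate reference-panel
generator), winner's-curse from selecting instruments in the same sample,
MAF–effect-size coupling, population stratification, and non-Gaussian
effect-size distributions. Passing recovery/calibration tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to those real-data phenomena.

`simulate_ld_panel` builds dosages by thresholding a block-equicorrelated
latent Gaussian at Hardy–Weinberg genotype quantiles (503 samples by
default, the size of a European-ancestry 1000 Genomes panel). Blocks span
~5 kb internally but successive blocks sit 20 Mb apart — beyond the default
clump window — so that cross-block r² sampling noise (≈ χ²₁/n, above 0.01
with probability ≈2.5% per pair at n = 503) cannot evict variants from
other blocks; one-retained-variant-per-block is then a property of the LD
structure rather than of lucky draws.

`simulate_grid` gives each exposure its own disjoint instrument set and
writes every outcome as the union of all instruments, each driven by its
owning exposure's true effect on that outcome — enough structure for grid
accounting and recovery checks without modelling genetic correlation
between exposures.

## Pipeline

The grid runs filter → clump → harmonize → estimate → sensitivity per
(exposure, outcome) pair. A failing pair (e.g. no shared instruments)
produces NA rows with the reason attached, never an abort, so an E×O grid
always accounts for E·O·|methods| rows. Significance uses Bonferroni
alpha/(E·O) — 0.05/39 ≈ 0.0013 for 13×3 — kept at full precision
internally and displayed at 4 decimals. Every stochastic stage derives its
seed as SHA-256(master seed | exposure | outcome | stage) mod 2³¹, so rerunning
one pair in isolation reproduces its grid rows exactly and identical
configs give byte-identical outputs.

## Numerical choices and degenerate inputs

- Input p-values of exactly 0 are clamped to the smallest positive double
  and counted in the read audit (Steiger needs finite statistics).
- Wald/IVW reject β̂_GX = 0 explicitly (degenerate instrument) rather than
  returning ±inf.
- MR-Egger requires variation in |β̂_GX| after orientation; an all-equal
  design raises a collinearity error.
- Weighted-median interpolation clamps at the extreme ratios; the estimate
  always lies within [min ratio, max ratio].
- Sums of per-instrument Steiger r² are capped just below 1.
- MR-PRESSO refuses to "correct" when fewer than two instruments survive
  outlier removal.
- Estimator SEs are validated positive at construction; harmonized sets
  refuse zero or negative SEs and duplicate variants.

## Test scale

The study-level suite uses the replicate counts the analyses were designed
at: 2000 null replicates for type-I error, 200 seeds for effect recovery
and the weighted-median robustness comparison, 100 runs for MR-PRESSO
outlier recovery and Steiger directionality. The full suite and the
acceptance script each complete in well under a minute on one CPU, so no
scaling-down was needed.

## Known limitations

- No LD-proxy lookup for instruments missing from the outcome GWAS; they
  are dropped and audited.
- No multivariable MR, mode-based or penalized estimators, and no
  contamination-mixture models.
- The Steiger p-value treats trait-level √r² as if estimated from
  independent samples of the mean per-instrument size; it is a screening
  statistic, not an exact test.
- Clumping instrument counts from published analyses are only approximately
  reproducible when the original clump window and palindrome policy are
  unreported.
- The weighted-median bootstrap SE ignores uncertainty in the weights'
  normalization (standard practice).
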