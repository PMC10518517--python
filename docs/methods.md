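# Methods

## Model

Two-sample Mendelian randomization treats each instrument SNP *j* as a
natural experiment. With per-allele SNP-exposure effect γⱼ and SNP-outcome
effect Γⱼ estimated in non-overlapping cohorts, the structural model is

    Γⱼ = θ·γⱼ + αⱼ,

where θ is the causal effect of the exposure on the outcome and αⱼ is a
horizontal-pleiotropy term, zero for a valid instrument. The estimators
make progressively weaker assumptions about α:

- **Wald ratio** (single SNP): θ̂ = Γ̂/γ̂, first-order delta SE σ_Γ/|γ̂|
  (a second-order option adds Γ̂²σ_γ²/γ̂⁴; off by default since the
  first-order form is the field's convention and the instruments are
  filtered for strength).
- **IVW**: inverse-variance-weighted mean of Wald ratios, algebraically a
  zero-intercept weighted regression of Γ̂ on γ̂ with weights 1/σ_Γ².
  The multiplicative-random-effects variant scales the fixed-effect SE by
  √max(1, Q/(J−1)) — overdispersion inflates uncertainty but the SE never
  drops below the fixed-effect SE. Normal inference.
- **MR-Egger**: the same regression with a free intercept, after orienting
  every γ̂ positive (results are invariant to the input orientation; the
  test suite asserts this). The slope estimates θ under InSIDE
  (pleiotropy independent of instrument strength); the intercept estimates
  the mean directional pleiotropy. SEs carry the dispersion floor
  √max(1, σ̂²) and inference uses t(J−2).
- **Weighted median**: order the ratios, interpolate the standardized
  cumulative weight function sⱼ = (Σₖ≤ⱼ wₖ − wⱼ/2)/Σw at s = 0.5, with
  wⱼ the inverse first-order ratio variances. Consistent while valid
  instruments hold >50% of the weight. SE by parametric bootstrap
  (γ̂*, Γ̂* redrawn from their estimation normals; default 1000
  replicates, explicit seed).
- **Weighted mode**: argmax over a 512-point grid of a normal-kernel
  weighted density of the ratios, bandwidth
  h = φ·0.9·min(weighted SD, weighted MAD/0.6745)·J^(−1/5) (modified
  Silverman rule; φ defaults to 1). All ratios identical degenerates to the
  common ratio. SE by the same bootstrap.

Heterogeneity: Cochran's Q = Σwⱼ(θ̂ⱼ − θ̂_IVW)² over first-order ratio
weights (identical to the IVW weighted residual sum), df = J−1,
I² = max(0, (Q−df)/Q).

**MR-PRESSO.** The global test measures RSS = Σwⱼ(Γ̂ⱼ − θ̂₍₋ⱼ₎γ̂ⱼ)² with
leave-one-out IVW slopes, and compares it with K parametric simulations
(Γⱼ* ~ N(θ̂₍₋ⱼ₎γ̂ⱼ, σ_Γⱼ²), γⱼ* ~ N(γ̂ⱼ, σ_γⱼ²)); empirical p-values use
the +1 correction and so live in [1/(K+1), 1]. Per-SNP residual p-values
are Bonferroni-adjusted across J (the same convention the selection screens
use); flagged outliers trigger an outlier-corrected IVW estimate and the
distortion test, whose null removes equally many random SNPs. K defaults to
1000. A minimum of J = 4 instruments guarantees every leave-one-out slope
rests on ≥3 SNPs. The plug-in null makes the global test mildly
conservative at small J (empirical type-I ≈ 3% at α = 5%, J = 10), matching
the behaviour of the simulation-based method it implements.

## Pipeline defaults

| parameter | default | meaning |
|---|---|---|
| strict / relaxed p | 5e-8 / 1e-5 | genome-wide threshold; relaxed used when <3 SNPs reach it |
| clump r² / window | 0.001 / 10 Mb | greedy LD independence rule (window is a standard clumping default; the LD source is a local table, not a web service) |
| screen α | 0.05 / n testable | Bonferroni confounder & outcome screens (BMI-like, age-at-recruitment-like); the divisor counts instruments present in the screen table, since a p threshold only applies to testable SNPs |
| F minimum | 10 | weak instruments excluded via F = R²(N−2)/(1−R²), R² = 2·EAF(1−EAF)β²; F exactly 10 is retained (the rule excludes F < 10) |
| proxy r² | 0.9 | minimum LD for outcome proxies; ties broken by smaller outcome p |
| bootstrap / PRESSO K | 1000 / 1000 | all stochastic steps take explicit seeds |

Harmonization aligns outcome rows to the exposure's effect allele: direct
match, allele swap (negate Γ̂, EAF → 1−EAF), then strand complementation
(A↔T, C↔G) retried with both; palindromic (A/T, C/G) variants are excluded
unconditionally, with no allele-frequency rescue — orientation for them is
ambiguous by construction. Palindrome checks re-apply to substituted
proxies. An EAF discordance >0.2 after alignment warns but does not
exclude. |Γ̂| and σ_Γ are never modified, only Γ̂'s sign.

Binary traits reported on the BOLT-LMM linear scale convert to log odds by
dividing β and SE by μ(1−μ), μ the case fraction (≈0.00217 for a
470-case / 216 099-control biobank GWAS, divisor ≈ 0.0021655). The
conversion is exactly invertible and preserves z-scores.

Significance across a factor panel is flagged at raw p < 0.05 with the
Bonferroni-adjusted p (m = factors per direction) reported alongside; both
columns appear in `results.tsv` so the reader can apply either gate. The
reverse direction selects disease instruments once and reuses them against
every factor outcome; failures are reported per pair and never abort the
batch.

## Synthetic-data generator

The generator realises the instrumental-variable diagram directly: true
γⱼ ~ N(mean, sd); Γⱼ = θγⱼ + αⱼ; observed effects add estimation noise with
SE ≈ 1/√(2·EAF(1−EAF)·n) for standardized continuous traits and
1/√(2·EAF(1−EAF)·n·μ(1−μ)) on the log-odds scale for binary traits — the
effective-sample-size form that yields the large log-odds SEs real rare-
disease GWAS show. EAFs are Uniform(0.05, 0.95) to avoid degenerate R².
Binary outcomes are emitted on the BOLT-LMM linear scale so the conversion
path is always exercised.

Pleiotropy modes: `none`; `balanced` (mean-zero α on all SNPs);
`directional` (a fraction `pleiotropy_frac`, default 0.3, of instruments
receive α ~ N(mean, sd) oriented by the exposure-raising allele — keeping
fewer than half the instruments invalid so median-type estimators retain
their guarantee, while InSIDE still holds in the oriented frame);
`inside_violated` (α = ρ·γ + noise, the minimal construction that breaks
the Egger assumption). Allele quirks — palindromic assignment,
strand-flipped and allele-swapped outcome rows, outcome missingness — are
injected at configurable rates (0 by default; tests and scenarios opt in).
LD blocks are emitted as a local symmetric r² table.

Scenario defaults mirror the emulated study: ~30 candidate instruments for
a rank-normalised exposure measured in 8 293 individuals against a binary
outcome from a 216 569-person biobank GWAS with 470 cases. The panel
generator produces 41 rank-normalised cytokine-like factors, two log-scale
acute-phase proteins (n = 206 158 and 3 301) and one disease, with all
causal effects zero except a designated signal factor (θ = 0.35, OR ≈ 1.42)
and 18 disease instruments sized to pass the relaxed threshold.

What the generator does **not** emulate: LD-induced correlation between
instrument *estimates* (effects are drawn independently given the truth),
sample overlap between cohorts, population stratification, allele-frequency
differences between cohorts, and winner's-curse beyond what the explicit
significance threshold induces. Passing calibration on this generator
therefore validates the statistical machinery under the stated model, not
robustness to those real-data pathologies.

## Validation design

- IVW and MR-Egger are checked to 1e-10 against a generic weighted-least-
  squares oracle (statsmodels) on random small instances — the
  implementation itself is closed-form numpy, so the check is a genuine
  dual route.
- Exact hand-derived fixtures: a collinear Egger set (slope 2, intercept
  0.05), equal-weight median ratios, a two-ratio Q/I² case, the rare-
  disease conversion divisor.
- Calibration: IVW 95% CI coverage over 500 no-pleiotropy replicates must
  lie in [0.93, 0.97]; MR-PRESSO global type-I error over 200 replicates at
  K = 500 in [0.02, 0.09].
- Recovery: with θ = 0.35 and no pleiotropy every estimator's CI covers θ;
  under directional pleiotropy the Egger intercept flags it while the
  weighted median stays on target. Because a single replicate of the
  pleiotropy scenario has limited power for the intercept test and a
  quantile-shift bias for the median, this check aggregates 20 fixed-seed
  replicates (mean |z| > 2; median CI coverage ≥ 50%); the scenario
  (J = 100, 30% invalid, pleiotropic effect ≈ 10 outcome SEs) was sized by
  a power calculation, not fitted to outcomes.
- Harmonization invariances: a 100% strand-flipped outcome yields a
  byte-identical harmonized set; palindrome exclusions match the configured
  rate within the binomial 95% band.

Simulation sizes in tests and in `scripts/acceptance.py` (500/200/20/10
replicates) were chosen so Monte-Carlo error is small relative to the
widths of the assertion bands while the whole suite stays quick to run.

## Known limitations

- Ratio SEs are first-order by default; very weak instruments (F near the
  cutoff) make both the delta method and IVW's NOME assumption strained.
- The weighted median keeps a finite-sample quantile-shift bias under
  directional pleiotropy even when <50% of weight is invalid; its CI
  coverage there is below nominal, as the acceptance study quantifies.
- MR-PRESSO p-values are Monte-Carlo quantities; two runs agree only when
  (seed, K) match. The global test is conservative at small J.
- No support for multi-allelic variants, VCF input, genome-build liftover,
  sample-overlap correction, MR-RAPS/multivariable MR, or Steiger
  filtering.
- CRP/PCT-style effects are reported per unit of the log-transformed
  exposure; any percent-change rescaling is presentation metadata left to
  the caller.
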