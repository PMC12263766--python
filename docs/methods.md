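# Methods

This note records the statistical model behind `ketomr`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## The screening procedure

Candidate gene regions are discovered from an acetone GWAS at p < 5×10⁻⁶ —
deliberately below genome-wide significance, so that biologically relevant
but sub-threshold regions are not overlooked.  Each candidate region (gene
interval ± 200 kb, inclusive 1-based coordinates) is then assessed against
four premises in order:

| premise | check | default threshold |
|---|---|---|
| 1 biological relevance | gene symbol in the ketone-metabolism list | — |
| 2 ketone-body consistency | lead variant associated with acetone, acetoacetate and beta-hydroxybutyrate | p < 10⁻⁴ each |
| 3 no horizontal pleiotropy | catalogue traits for the region all whitelisted | flagged at p < 5×10⁻⁸ |
| 4 positive-control association | IVW/ratio estimate on ≥1 control significant | α = 0.05, two-sided |

Stepwise semantics: a failure at premise 1 or 2 marks later premises "not
investigated".  Premises 3 and 4 are evaluated *independently* once 1–2
pass: a pleiotropy failure is informative alongside the positive-control
outcome, and reporting both mirrors how the screen is read in practice.
Overall validity still requires all four passes.  Instruments for premise 4
are the genome-wide-significant (p < 5×10⁻⁸) variants in the window after
greedy LD clumping at r² < 0.1; the clump comparison is "remove at r² ≥
threshold", so retained pairs are strictly below it.  Whether "one variant
per gene region" in the agnostic analysis means the lead variant is an
assumption; the package uses the lead (smallest p, ties to smaller
position, then lexicographic id, so every selection is deterministic).

The vertical-versus-horizontal pleiotropy judgement is inherently a human
call; the package reduces it to a whitelist of trait names treated as
vertical.  The default whitelist is empty, the most conservative choice.
Premise-2 sign concordance across the three ketone bodies is available but
off by default (only the p-threshold is part of the core rule).

## Estimators

All estimators operate on harmonized per-variant quadruples
(γ̂ⱼ, σ_Xⱼ, Γ̂ⱼ, σ_Yⱼ) and are coded directly from their defining formulas;
`statsmodels` appears only in the test suite as an independent
weighted-least-squares oracle.

* **IVW** is computed in the regression form
  β̂ = Σγ̂ⱼΓ̂ⱼ/σ_Yⱼ² ÷ Σγ̂ⱼ²/σ_Yⱼ², which tolerates γ̂ⱼ = 0.  The default
  standard error is multiplicative random effects — the fixed-effect SE
  inflated by √(Q/(J−1)) with the scale floored at 1 — because real summary
  data are rarely homogeneous; the fixed-effect SE is available by flag.
  A single-variant set reduces exactly to the ratio estimate.
* **MR-Egger** requires an orientation convention for the intercept to be
  identified; the package flips each variant so γ̂ⱼ > 0.  Coefficient
  covariance uses the classical WLS form times the weighted residual scale
  floored at 1 (the usual MR-Egger overdispersion treatment).  At least
  three instruments are required.
* **Weighted median**: θ̂ⱼ sorted ascending with weights wⱼ = γ̂ⱼ²/σ_Yⱼ²,
  standardized cumulative midpoints sⱼ = (Σ_{k≤j}w_k − wⱼ/2)/Σw, linear
  interpolation at 0.5.  The SE is a parametric bootstrap (γ̂ⱼ, Γ̂ⱼ resampled
  from normals at their observed values and SEs); the seed is a required
  argument — reproducibility is prioritised over an exact closed form.
* **Ratio** SE is first-order delta method (σ_Y/|γ̂|); the second-order term
  is deliberately not implemented — a known limitation that understates
  uncertainty for weak instruments.
* Confidence intervals are normal-approximation 95% throughout; no
  t-correction for small instrument counts.

## Harmonization

Outcome records are rewritten onto the exposure's effect-allele frame:
literal match, swapped alleles (sign flip, EAF mirrored), strand complement
for non-palindromic pairs, and EAF-guided orientation for palindromic (A/T,
C/G) variants.  Palindromes are kept only when both studies report an EAF
and both fall outside the ambiguity window [0.42, 0.58] (a common
conservative default, configurable); with a missing EAF they are dropped,
since silence would risk sign errors.  Indel alleles are compared literally
with no strand logic.  Standard errors are never modified.  Proxy-variant
substitution for instruments missing from the outcome is out of scope; such
variants are dropped with a logged reason.

## The synthetic generator

`generate_bundle` emulates the statistical structure of the screening
problem, not any particular cohort:

* true per-allele exposure effects γⱼ ~ N(0, τ²) at causal variants, τ =
  0.05 SD by default — the scale of lead cis variants in NMR-metabolite
  GWAS, where per-allele effects of 0.05–0.2 SD are routine;
* ketone body k inherits λ_k·γⱼ (defaults 1.0, 0.9, 0.8), so the three
  traits share regional genetics; the *inconsistent* archetype zeroes the
  two non-acetone loadings (an acetone-only signal);
* positive-control effects Γⱼ = β_c·γⱼ (defaults ±0.1 — the magnitude of
  the modest causal signals such screens target) plus, in the *pleiotropic*
  archetype, directional pleiotropy defined on the exposure-raising allele:
  sign(γⱼ)·αⱼ with αⱼ ~ N(0.02, 0.005²).  σ_α is kept small relative to μ_α
  because the archetype's ground truth asserts both a detectable control
  association and flagged pleiotropy; strongly heterogeneous αⱼ would
  silently falsify the first at these sample sizes;
* `n_causal` means that many *independent* signals: causal variants are
  placed jittered-but-evenly across the region so the AR(1) LD (ρ = 0.6)
  cannot merge them during clumping.  Fully random placement would collapse
  a 5-signal region to 1–2 clumped instruments in many replicates, turning
  the truth table false by construction rather than by sampling;
* observed estimates are multivariate normal around the truth with
  per-variant SE 1/√(2fⱼ(1−fⱼ)n) and cross-variant noise correlation equal
  to the LD correlation r — the sampling correlation of standardized
  effect estimates from a shared sample.  Exposure and outcome samples are
  non-overlapping (independent noise), the two-sample MR design.  Default
  sample sizes are 500,000 on both sides, the regime in which the archetype
  truths are near-deterministically recoverable;
* allele encodings are churned between "studies" (20% swapped, 10% strand
  flipped, 10% palindromic pairs) to exercise harmonization; two acetone
  studies with independent noise emulate a replication pair.

What the generator does **not** emulate: genotype-level data, population
structure and its confounding, case-control traits, sample overlap between
exposure and outcome, winner's-curse selection of instruments, and
cross-trait correlation of estimation noise beyond the shared true effects.
Passing tests therefore demonstrate the correctness and calibration of the
estimators and pipeline logic under a faithful summary-statistic sampling
model — not robustness to those real-data pathologies.

## Numerical conventions and degenerate inputs

* p-values derived from β/se are clipped at the smallest positive double,
  never 0; stored p-values are kept as given, recomputed only when absent.
* LD matrices are symmetrized by averaging within 10⁻⁸, the diagonal forced
  to 1; entries beyond |r| = 1 + 10⁻⁸ are data errors.
* Malformed summary rows are rejected with row-numbered diagnostics rather
  than aborting the read (strict mode escalates); duplicate variant ids are
  always an error naming the id.
* γ̂ = 0 is a domain error for the ratio estimator, tolerated by the IVW
  regression form; empty regions, empty instrument lists and fewer than
  3 instruments for Egger/weighted-median raise usage errors.
* BED input (0-based half-open) is converted once at read time to the
  internal 1-based inclusive convention; genome builds are treated as
  opaque and all inputs must share one.

## Simulation sizes

The reproduction script (`scripts/acceptance.py`) and the statistical test
suite use: 1,000 random instrument sets for the
IVW-vs-WLS oracle check; 500 replicates for IVW bias/coverage (J = 10,
n = 100,000, β = 0.1); 10,000 replicates for the null rejection rate of the
positive-control check (the rate is ~4%, and this count keeps its
Monte-Carlo error near 0.2 percentage points); 2,000 replicates for Egger
intercept recovery; 500 for weighted-median robustness (3 of 10 instruments
contaminated); 1,000 random instances for the clumping oracle; 100
replicates of the full five-archetype screen; and 200 replicates of the
biobank-scale seven-instrument design (true effect 0.08 SD/SD).  Each was
chosen so the Monte-Carlo error of the reported quantity is small relative
to the band it is judged against.
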