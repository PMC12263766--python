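# ketomr

Instrument-validity screening and two-sample Mendelian randomization (MR)
for ketone metabolism.

## The problem

MR uses genetic variants as instrumental variables to estimate the causal
effect of an exposure — here circulating ketone bodies (acetone,
acetoacetate, beta-hydroxybutyrate) — on an outcome, from GWAS summary
statistics alone.  The inference is only as good as the instruments: a valid
instrument must associate with the exposure (relevance), share no
confounding path with the outcome (independence), and affect the outcome
only through the exposure (exclusion restriction).  For a complex metabolic
exposure, picking variants purely by p-value invites violations of all
three.

`ketomr` implements a stepwise, biologically motivated screen in which a
candidate gene region must satisfy four premises before its variants are
treated as plausible instruments:

1. **Biological relevance** — the region encodes a protein directly involved
   in ketone production or utilisation (defaults: *ACAT1*, *ACAT2*,
   *HMGCS2*, *HMGCL*, *BDH1*, *SLC2A4*, *AACS*, *OXCT1*, *CYP2E1*);
2. **Ketone-body consistency** — the regional lead variant associates with
   all three primary ketone bodies (p < 10⁻⁴ in each);
3. **No horizontal pleiotropy** — catalogue-reported trait associations for
   the region at p < 5×10⁻⁸ are limited to a configurable whitelist of
   traits on the exposure's own pathway;
4. **Positive-control association** — genome-wide-significant variants in
   the region (±200 kb window, LD-pruned at r² < 0.1) recover an effect on
   at least one trait with trial-established response to ketone
   supplementation (cognitive performance, two-hour glucose, insulin fold
   change), at α = 0.05.

A failure at premise 1 or 2 short-circuits the rest ("not investigated");
premises 3 and 4 are evaluated independently once 1–2 pass.  A complementary
*agnostic* pipeline skips the biology and runs one lead variant per gene
region through IVW, weighted-median and MR-Egger.

## The estimators

For harmonized per-variant associations (γ̂ⱼ, σ_Xⱼ) with the exposure and
(Γ̂ⱼ, σ_Yⱼ) with the outcome, with θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ and wⱼ = γ̂ⱼ²/σ_Yⱼ²:

* **ratio** (single variant): θ̂ = Γ̂/γ̂, se = σ_Y/|γ̂|;
* **IVW**: θ̂ = Σwⱼθ̂ⱼ / Σwⱼ — equivalently weighted least squares of Γ̂ on γ̂
  through the origin with weights σ_Yⱼ⁻²; fixed-effect se = (Σwⱼ)^(−1/2), or
  (default) multiplicative random effects, inflating by √(Q/(J−1)) floored
  at 1, where Q is Cochran's heterogeneity statistic;
* **MR-Egger**: the same weighted regression with an intercept after
  orienting every variant so γ̂ⱼ > 0; a non-zero intercept estimates
  directional horizontal pleiotropy;
* **weighted median**: the 50% weighted quantile of the θ̂ⱼ, consistent when
  valid instruments carry ≥ 50% of the weight; SE by seeded parametric
  bootstrap.

All estimators are implemented from their defining formulas.  Because the
real summary statistics the screen was designed around are external
downloads, the package ships a synthetic GWAS generator
(`ketomr.simulate`) producing bundles with known ground truth — correlated
ketone traits, AR(1) LD, allele-encoding churn between studies, and region
archetypes that each violate exactly one premise — so the entire pipeline is
testable offline.

## Worked example

```sh
ketomr simulate --out demo --seed 7
ketomr biological --bundle demo/manifest.yaml --seed 7
```

```
source               gene    lead_variant  secondary_variants                   biological_relevance  ketone_consistency  no_horizontal_pleiotropy  positive_control
borges_acetone       OXCT1   rs100017      rs100013,rs100006                    ✓                     ✓                   ✓                         ✓
borges_acetone       LPL     rs200001      -                                    ×                     -                   -                         -
borges_acetone       CYP2E1  rs300010      -                                    ✓                     ×                   -                         -
borges_acetone       SLC2A4  rs400006      rs400009,rs400014,rs400001,rs400018  ✓                     ✓                   ×                         ✓
karjalainen_acetone  OXCT1   rs100017      rs100013,rs100006                    ✓                     ✓                   ✓                         ✓
...
```

Reading the rows: *OXCT1* (the valid archetype) passes all four premises —
its clumped variants are plausible instruments.  *LPL* has a genuine acetone
signal but no ketone biology, so everything downstream is not investigated
(`×---`).  *CYP2E1* is acetone-only, failing ketone-body consistency
(`✓×--`).  *SLC2A4* fails the pleiotropy screen (a genome-wide-significant
blood-pressure association in the catalogue) but its positive-control column
is still evaluated and passes (`✓✓×✓`).  The agnostic analysis prints one
estimate per (ketone, control, method):

```sh
ketomr agnostic --bundle demo/manifest.yaml --seed 7 | head -4
```

```
ketone        control                method           n_variants  beta      se         ci_low      ci_high   pval
acetoacetate  cognitive_performance  egger            3           0.385313  0.0611334  0.265493    0.505132  2.92293e-10
acetoacetate  cognitive_performance  ivw              3           0.205858  0.0550464  0.0979687   0.313747  0.000184233
acetoacetate  cognitive_performance  weighted_median  3           0.195812  0.0200642  0.156487    0.235137  1.68354e-22
```

The same operations are available as library calls
(`ketomr.run_biological_pipeline`, `ketomr.run_agnostic_pipeline`,
`ketomr.ivw_estimate`, ...) on datasets read with
`ketomr.read_gwas_table`.

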