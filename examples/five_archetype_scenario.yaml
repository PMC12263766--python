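# The default five-archetype screening scenario, written out explicitly.
# Every key is optional; omitted keys fall back to the library defaults
# (SyntheticScenario).  Run with:
#   ketomr simulate --scenario examples/five_archetype_scenario.yaml --out bundle --seed 1
regions:
  - {gene_symbol: OXCT1, archetype: valid, n_variants: 20, n_causal: 5}
  - {gene_symbol: LPL, archetype: no_biology, n_variants: 20, n_causal: 5}
  - {gene_symbol: CYP2E1, archetype: inconsistent, n_variants: 20, n_causal: 5}
  - {gene_symbol: SLC2A4, archetype: pleiotropic, n_variants: 20, n_causal: 5}
  - {gene_symbol: HMGCS2, archetype: "null", n_variants: 20, n_causal: 5}
tau: 0.05
ketone_loadings:
  acetone: 1.0
  acetoacetate: 0.9
  beta_hydroxybutyrate: 0.8
control_effects:
  cognitive_performance: 0.1
  two_hour_glucose: -0.1
  insulin_fold_change: -0.1
mu_alpha: 0.02
sigma_alpha: 0.005
rho: 0.6
maf_range: [0.05, 0.5]
n_exposure: 500000
n_outcome: 500000
swap_fraction: 0.2
strand_flip_fraction: 0.1
palindromic_fraction: 0.1
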