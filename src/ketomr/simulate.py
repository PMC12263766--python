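"""Synthetic GWAS-summary-statistic bundles with known ground truth.

The generator emulates the statistical structure of the real screening
problem: three correlated ketone-body traits sharing regional genetics, two
independent acetone "studies", LD-correlated estimation noise within gene
regions, positive-control outcomes downstream of the exposure, and region
archetypes engineered to fail exactly one validity premise each:

* ``valid`` — ketone-relevant gene, consistent signal across all three
  ketone bodies, clean catalogue, real control effect;
* ``no_biology`` — genuine acetone signal in a gene with no ketone role;
* ``inconsistent`` — acetone-only signal (the other two ketone bodies are
  unaffected);
* ``pleiotropic`` — as valid, plus directional horizontal pleiotropy on the
  controls and a non-whitelisted catalogue trait at genome-wide significance;
* ``null`` — no signal at all, so the region never enters discovery.

Model: true per-allele exposure effects gamma_j ~ Normal(0, tau^2) on causal
variants (0 elsewhere); ketone body k has true effect lambda_k * gamma_j;
control c has true effect beta_c * gamma_j, plus sign(gamma_j) * alpha_j for
the pleiotropic archetype, with alpha_j ~ Normal(mu_alpha, sigma_alpha^2)
defined on the exposure-increasing allele (directional pleiotropy).
Observed estimates are drawn multivariate-normal around the truth with
per-variant standard error 1/sqrt(2 f_j (1-f_j) n) and cross-variant noise
correlation equal to the LD correlation r (the sampling correlation of
standardized effect estimates from a shared sample).  Exposure and outcome
samples are non-overlapping, matching a two-sample design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pipeline import Bundle, FAIL, NOT_EVALUATED, PASS
from .summary_data import (
    CatalogueRecord,
    GWASDataset,
    GeneAnnotation,
    LDMatrix,
    TraitAssociationCatalogue,
    VariantAssociation,
    derive_pvalue,
)

__all__ = [
    "ARCHETYPES",
    "SyntheticRegion",
    "SyntheticScenario",
    "RegionTruth",
    "TruthTable",
    "generate_ld_matrix",
    "generate_bundle",
    "truth",
    "simulate_instruments",
]

ARCHETYPES = ("valid", "no_biology", "inconsistent", "pleiotropic", "null")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("G", "A"), ("G", "T"),
    ("C", "A"), ("C", "T"), ("T", "G"), ("T", "C"),
)


@dataclass(frozen=True)
class SyntheticRegion:
    """One gene region of a scenario."""

    gene_symbol: str
    archetype: str
    n_variants: int = 20
    n_causal: int = 5

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")


def _default_regions() -> tuple[SyntheticRegion, ...]:
    return (
        SyntheticRegion("OXCT1", "valid"),
        SyntheticRegion("LPL", "no_biology"),
        SyntheticRegion("CYP2E1", "inconsistent"),
        SyntheticRegion("SLC2A4", "pleiotropic"),
        SyntheticRegion("HMGCS2", "null"),
    )


@dataclass(frozen=True)
class SyntheticScenario:
    """Full specification of one synthetic study.

    ``tau`` is the SD (trait SD units per allele copy) of true exposure
    effects at causal variants; ``ketone_loadings`` scale the shared regional
    genetics into each ketone body; ``control_effects`` are the true causal
    effects of the exposure on each positive control (SD/SD or
    control-unit/SD); ``mu_alpha``/``sigma_alpha`` parameterize directional
    pleiotropy in the pleiotropic archetype; ``rho`` the AR(1) LD decay.
    """

    regions: tuple[SyntheticRegion, ...] = field(default_factory=_default_regions)
    tau: float = 0.05
    ketone_loadings: tuple[tuple[str, float], ...] = (
        ("acetone", 1.0),
        ("acetoacetate", 0.9),
        ("beta_hydroxybutyrate", 0.8),
    )
    control_effects: tuple[tuple[str, float], ...] = (
        ("cognitive_performance", 0.1),
        ("two_hour_glucose", -0.1),
        ("insulin_fold_change", -0.1),
    )
    mu_alpha: float = 0.02
    sigma_alpha: float = 0.005
    rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 500_000
    n_outcome: int = 500_000
    swap_fraction: float = 0.2
    strand_flip_fraction: float = 0.1
    palindromic_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        symbols = [r.gene_symbol for r in self.regions]
        if len(set(symbols)) != len(symbols):
            raise ValueError("gene symbols must be unique across regions")


@dataclass
class RegionTruth:
    """Ground truth for one region: archetype, causal variants, verdicts."""

    gene_symbol: str
    archetype: str
    causal_variant_ids: list[str]
    expected_verdicts: tuple[str, str, str, str] | None
    control_effects: dict[str, float]


@dataclass
class TruthTable:
    regions: list[RegionTruth]

    def expected_matrix(self) -> dict[str, tuple[str, str, str, str]]:
        """Gene -> expected premise statuses, for regions that enter discovery."""
        return {
            r.gene_symbol: r.expected_verdicts
            for r in self.regions
            if r.expected_verdicts is not None
        }


def _ar1(n_variants: int, rho: float) -> np.ndarray:
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    idx = np.arange(n_variants)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def generate_ld_matrix(
    n_variants: int,
    rho: float,
    seed: int | None = None,
    variant_ids: list[str] | None = None,
) -> LDMatrix:
    """AR(1) LD matrix r(j,k) = rho^|j-k| (positive definite by construction).

    ``seed`` is accepted for interface symmetry; the AR(1) structure itself
    is deterministic.  Default variant ids are ``v1..vn``.
    """
    if variant_ids is None:
        variant_ids = [f"v{j + 1}" for j in range(n_variants)]
    return LDMatrix(variant_ids, _ar1(n_variants, rho))


def truth(scenario: SyntheticScenario) -> TruthTable:
    """The archetype -> premise-outcome mapping, without generating data."""
    controls = dict(scenario.control_effects)
    rows = []
    for region in scenario.regions:
        verdicts: tuple[str, str, str, str] | None
        if region.archetype == "valid":
            verdicts = (PASS, PASS, PASS, PASS)
        elif region.archetype == "no_biology":
            verdicts = (FAIL, NOT_EVALUATED, NOT_EVALUATED, NOT_EVALUATED)
        elif region.archetype == "inconsistent":
            verdicts = (PASS, FAIL, NOT_EVALUATED, NOT_EVALUATED)
        elif region.archetype == "pleiotropic":
            p4 = (
                PASS
                if (any(b != 0 for b in controls.values()) or scenario.mu_alpha != 0)
                else FAIL
            )
            verdicts = (PASS, PASS, FAIL, p4)
        else:  # null: absent from discovery
            verdicts = None
        rows.append(
            RegionTruth(
                gene_symbol=region.gene_symbol,
                archetype=region.archetype,
                causal_variant_ids=[],
                expected_verdicts=verdicts,
                control_effects=dict(controls) if verdicts is not None else {},
            )
        )
    return TruthTable(rows)


def _draw_alleles(rng: np.random.Generator, n: int, palindromic_fraction: float):
    pal = rng.random(n) < palindromic_fraction
    pairs = []
    for j in range(n):
        pool = _PALINDROMIC_PAIRS if pal[j] else _NONPALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])
    return pairs


def _reencode(
    rng: np.random.Generator,
    effect: str,
    other: str,
    beta: float,
    eaf: float,
    swap_fraction: float,
    strand_flip_fraction: float,
):
    """Randomly swap and/or strand-flip one variant's reported encoding."""
    if rng.random() < swap_fraction:
        effect, other = other, effect
        beta = -beta
        eaf = 1.0 - eaf
    if rng.random() < strand_flip_fraction:
        effect = _COMPLEMENT[effect]
        other = _COMPLEMENT[other]
    return effect, other, beta, eaf


def generate_bundle(
    scenario: SyntheticScenario = SyntheticScenario(),
) -> tuple[Bundle, TruthTable]:
    """Generate a complete, internally consistent screening bundle.

    Produces two acetone discovery datasets with independent noise, the three
    ketone-body datasets, one dataset per positive control, gene annotations,
    per-region LD matrices, a trait-association catalogue flagging the
    pleiotropic archetype, and the ground-truth table.  Bit-for-bit
    reproducible given the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    loadings = dict(scenario.ketone_loadings)
    controls = dict(scenario.control_effects)
    truth_table = truth(scenario)

    annotation: list[GeneAnnotation] = []
    ld: dict[str, LDMatrix] = {}
    catalogue_records: list[CatalogueRecord] = []

    # dataset name -> (sample size, list of rows accumulated across regions)
    dataset_names = (
        ["karjalainen_acetone", "borges_acetone"]
        + list(loadings)
        + list(controls)
    )
    rows: dict[str, list[VariantAssociation]] = {n: [] for n in dataset_names}

    for i, region in enumerate(scenario.regions):
        chrom = str(i + 1)
        gene_start, gene_end = 1_000_000, 1_010_000
        annotation.append(GeneAnnotation(region.gene_symbol, chrom, gene_start, gene_end))
        nv = region.n_variants
        positions = np.linspace(gene_start - 150_000, gene_end + 150_000, nv).astype(int)
        variant_ids = [f"rs{(i + 1) * 100_000 + j}" for j in range(nv)]
        eaf = rng.uniform(*scenario.maf_range, size=nv)
        alleles = _draw_alleles(rng, nv, scenario.palindromic_fraction)

        R = _ar1(nv, scenario.rho)
        ld[region.gene_symbol] = LDMatrix(variant_ids, R)
        L = np.linalg.cholesky(R) if scenario.rho > 0 else None

        gamma = np.zeros(nv)
        if region.archetype != "null" and region.n_causal > 0:
            # n_causal means that many *independent* signals: jittered but
            # evenly spread placement keeps causal variants far enough apart
            # in the AR(1) LD that clumping cannot merge them
            spacing = nv / region.n_causal
            causal = np.unique(
                (
                    (np.arange(region.n_causal)
                     + rng.uniform(0.3, 0.7, size=region.n_causal))
                    * spacing
                ).astype(int)
            )
            gamma[causal] = rng.normal(0.0, scenario.tau, size=causal.size)
            truth_table.regions[i].causal_variant_ids = sorted(
                variant_ids[c] for c in causal
            )

        # true effects per trait
        true_effects: dict[str, np.ndarray] = {}
        acetone_true = loadings["acetone"] * gamma
        true_effects["karjalainen_acetone"] = acetone_true
        true_effects["borges_acetone"] = acetone_true
        for k, lam in loadings.items():
            if region.archetype == "inconsistent" and k != "acetone":
                true_effects[k] = np.zeros(nv)
            else:
                true_effects[k] = lam * gamma
        for c, beta_c in controls.items():
            eff = beta_c * gamma
            if region.archetype == "pleiotropic":
                alpha = rng.normal(scenario.mu_alpha, scenario.sigma_alpha, size=nv)
                # directional pleiotropy defined on the exposure-raising allele
                eff = eff + np.sign(gamma) * alpha * (gamma != 0)
            true_effects[c] = eff

        for name in dataset_names:
            n_samp = scenario.n_outcome if name in controls else scenario.n_exposure
            se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_samp)
            z = rng.standard_normal(nv)
            noise = (L @ z) if L is not None else z
            beta_hat = true_effects[name] + noise * se
            reference_frame = name == "karjalainen_acetone"
            for j in range(nv):
                ea, oa = alleles[j]
                b, f = float(beta_hat[j]), float(eaf[j])
                if not reference_frame:
                    ea, oa, b, f = _reencode(
                        rng, ea, oa, b, f,
                        scenario.swap_fraction, scenario.strand_flip_fraction,
                    )
                rows[name].append(
                    VariantAssociation(
                        variant_id=variant_ids[j],
                        chrom=chrom,
                        pos=int(positions[j]),
                        effect_allele=ea,
                        other_allele=oa,
                        eaf=f,
                        beta=b,
                        se=float(se[j]),
                        pval=derive_pvalue(float(beta_hat[j]), float(se[j])),
                        n=n_samp,
                    )
                )

        if region.archetype == "pleiotropic":
            # the regional lead carries a reported association with a trait on
            # an alternative causal pathway, at genome-wide significance
            lead = variant_ids[int(np.argmax(np.abs(gamma)))]
            catalogue_records.append(
                CatalogueRecord(lead, region.gene_symbol, "systolic blood pressure", 1e-12)
            )
        if region.archetype != "null":
            # sub-threshold catalogue chatter that must never be flagged
            catalogue_records.append(
                CatalogueRecord(
                    variant_ids[0], region.gene_symbol, "serum metabolite levels", 1e-3
                )
            )

    bundle = Bundle(
        discovery={
            "karjalainen_acetone": GWASDataset(
                "karjalainen_acetone", rows["karjalainen_acetone"]
            ),
            "borges_acetone": GWASDataset("borges_acetone", rows["borges_acetone"]),
        },
        ketones={k: GWASDataset(k, rows[k]) for k in loadings},
        controls={c: GWASDataset(c, rows[c]) for c in controls},
        annotation=annotation,
        ld=ld,
        catalogue=TraitAssociationCatalogue(catalogue_records),
    )
    return bundle, truth_table


def simulate_instruments(
    n_instruments: int,
    beta: float,
    n_exposure: int = 100_000,
    n_outcome: int = 100_000,
    tau: float = 0.05,
    maf_range: tuple[float, float] = (0.05, 0.5),
    mu_alpha: float = 0.0,
    sigma_alpha: float = 0.0,
    n_pleiotropic: int = 0,
    rng: np.random.Generator | None = None,
):
    """Draw one replicate of independent-instrument summary statistics.

    A lighter companion to :func:`generate_bundle` for estimator studies:
    ``n_instruments`` unlinked variants with true exposure effects
    gamma_j ~ Normal(0, tau^2), outcome effects beta * gamma_j plus
    directional pleiotropy sign(gamma_j) * Normal(mu_alpha, sigma_alpha^2)
    on the first ``n_pleiotropic`` instruments, and estimation noise scaled
    by 1/sqrt(2 f (1-f) n) per sample.

    Returns a dict with keys ``gamma_hat``, ``se_exposure``, ``Gamma_hat``,
    ``se_outcome``, ``gamma_true``, ``alpha``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    J = n_instruments
    f = rng.uniform(*maf_range, size=J)
    se_x = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_outcome)
    gamma_true = rng.normal(0.0, tau, size=J)
    alpha = np.zeros(J)
    if n_pleiotropic > 0:
        alpha[:n_pleiotropic] = rng.normal(mu_alpha, sigma_alpha, size=n_pleiotropic)
    Gamma_true = beta * gamma_true + np.sign(gamma_true) * alpha
    return {
        "gamma_hat": gamma_true + rng.standard_normal(J) * se_x,
        "se_exposure": se_x,
        "Gamma_hat": Gamma_true + rng.standard_normal(J) * se_y,
        "se_outcome": se_y,
        "gamma_true": gamma_true,
        "alpha": alpha,
    }
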