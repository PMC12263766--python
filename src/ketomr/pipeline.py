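"""Four-premise instrument-validity screening and the agnostic MR pipeline.

A candidate gene region yields plausibly valid instruments for ketone
metabolism only when four premises hold:

1. **Biological relevance** — the region encodes a protein directly involved
   in ketone production or utilisation;
2. **Ketone-body consistency** — the region's lead variant associates with
   all three primary ketone bodies (acetone, acetoacetate,
   beta-hydroxybutyrate), not just the discovery trait;
3. **No horizontal pleiotropy** — previously reported trait associations for
   the region are limited to traits on the exposure's own pathway (a
   configurable whitelist of "vertical" traits);
4. **Positive-control association** — instruments in the region recover an
   effect on at least one trait with trial-established response to ketone
   supplementation.

Evaluation is stepwise: a failure at premise 1 or 2 short-circuits everything
downstream (those verdicts are reported as not evaluated), while premises 3
and 4 are evaluated independently once 1–2 pass, so a pleiotropy failure
still reports whether the positive controls responded.  The complementary
*agnostic* pipeline skips premises 1–3 and runs IVW, weighted-median and
MR-Egger over one genome-wide-significant lead variant per gene region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import estimators as est
from .harmonization import (
    DEFAULT_POLICY,
    HarmonizationPolicy,
    HarmonizedInstrumentSet,
    harmonize_set,
)
from .regions import (
    DEFAULT_FLANK,
    DISCOVERY_P,
    GENOME_WIDE_P,
    RegionAssignment,
    assign_regions,
    greedy_clump,
    lead_variant,
)
from .summary_data import (
    ConfigurationError,
    GWASDataset,
    GeneAnnotation,
    LDMatrix,
    TraitAssociationCatalogue,
)

__all__ = [
    "PASS",
    "FAIL",
    "NOT_EVALUATED",
    "SYMBOLS",
    "DEFAULT_KETONE_GENES",
    "PipelineConfig",
    "Bundle",
    "PremiseVerdict",
    "RegionReport",
    "PremiseMatrix",
    "AgnosticRow",
    "AgnosticResult",
    "discover_candidate_regions",
    "premise1_biological",
    "premise2_consistency",
    "premise3_pleiotropy",
    "premise4_positive_controls",
    "run_biological_pipeline",
    "run_agnostic_pipeline",
    "render_matrix",
    "render_agnostic",
]

PASS = "pass"
FAIL = "fail"
NOT_EVALUATED = "not_evaluated"

#: report glyphs: satisfied, not satisfied, not investigated
SYMBOLS = {PASS: "✓", FAIL: "×", NOT_EVALUATED: "-"}

#: gene regions encoding proteins directly involved in ketone production or
#: utilisation (hepatic ketogenesis enzymes, transport, and acetone oxidation)
DEFAULT_KETONE_GENES: tuple[str, ...] = (
    "ACAT1",
    "ACAT2",
    "HMGCS2",
    "HMGCL",
    "BDH1",
    "SLC2A4",
    "AACS",
    "OXCT1",
    "CYP2E1",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and policy knobs for both pipelines.

    Defaults follow the screening design: candidate discovery below
    genome-wide significance (p < 5e-6) so biologically relevant sub-threshold
    regions are not overlooked; instrument selection at genome-wide
    significance (p < 5e-8) with LD pruning at r^2 < 0.1 inside the gene
    window (+/- 200 kb); ketone-body consistency at p < 1e-4; catalogue
    pleiotropy screening at p < 5e-8; positive-control significance at
    alpha = 0.05 two-sided.
    """

    p_discovery: float = DISCOVERY_P
    p_genome_wide: float = GENOME_WIDE_P
    p_consistency: float = 1e-4
    p_catalogue: float = GENOME_WIDE_P
    r2_max: float = 0.1
    alpha: float = 0.05
    flank: int = DEFAULT_FLANK
    relevant_genes: tuple[str, ...] = DEFAULT_KETONE_GENES
    vertical_whitelist: tuple[str, ...] = ()
    require_sign_concordance: bool = False
    ivw_model: str = "ivw_mre"
    n_boot: int = 1000
    seed: int = 0
    harmonization: HarmonizationPolicy = DEFAULT_POLICY


@dataclass
class Bundle:
    """All inputs for one screening run.

    ``discovery`` holds the acetone GWAS used for candidate discovery, keyed
    by source name (e.g. two independent studies); ``ketones`` the three
    primary ketone-body GWAS; ``controls`` the positive-control outcome GWAS;
    ``ld`` one LD matrix per gene region, keyed by gene symbol.
    """

    discovery: dict[str, GWASDataset]
    ketones: dict[str, GWASDataset]
    controls: dict[str, GWASDataset]
    annotation: list[GeneAnnotation]
    ld: dict[str, LDMatrix]
    catalogue: TraitAssociationCatalogue

    def validate(self) -> None:
        for name, value in (
            ("discovery", self.discovery),
            ("ketones", self.ketones),
            ("controls", self.controls),
            ("annotation", self.annotation),
            ("ld", self.ld),
        ):
            if not value:
                raise ConfigurationError(f"bundle component {name!r} is missing/empty")
        if len(self.ketones) != 3:
            raise ConfigurationError(
                f"exactly three ketone datasets required, got {len(self.ketones)}"
            )
        if self.catalogue is None:
            raise ConfigurationError("bundle component 'catalogue' is missing/empty")


@dataclass
class PremiseVerdict:
    """Outcome of one premise check with its supporting evidence."""

    status: str  # pass | fail | not_evaluated
    evidence: dict = field(default_factory=dict)
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.status not in (PASS, FAIL, NOT_EVALUATED):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == NOT_EVALUATED and self.evidence:
            raise ValueError("not_evaluated verdicts carry no evidence")

    @property
    def symbol(self) -> str:
        return SYMBOLS[self.status]


_NOT_EVALUATED = PremiseVerdict(NOT_EVALUATED, reason="short_circuit")


@dataclass
class RegionReport:
    """One row of the premise matrix: a (source, gene region) assessment."""

    source: str
    gene_symbol: str
    chrom: str
    window_start: int
    window_end: int
    lead_variant: str | None
    secondary_variants: list[str]
    verdicts: tuple[PremiseVerdict, PremiseVerdict, PremiseVerdict, PremiseVerdict]

    @property
    def symbols(self) -> str:
        return "".join(v.symbol for v in self.verdicts)

    @property
    def all_pass(self) -> bool:
        return all(v.status == PASS for v in self.verdicts)


@dataclass
class PremiseMatrix:
    """All region assessments plus the stepwise survival counts per source."""

    rows: list[RegionReport]
    stepwise_counts: dict[str, list[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, source: str, gene_symbol: str) -> RegionReport:
        for r in self.rows:
            if r.source == source and r.gene_symbol == gene_symbol:
                return r
        raise KeyError(f"no row for ({source!r}, {gene_symbol!r})")


@dataclass
class AgnosticRow:
    """One (ketone, control, method) cell of the agnostic analysis."""

    ketone: str
    control: str
    method: str
    estimate: est.MREstimate | None
    n_variants: int
    note: str | None = None


@dataclass
class AgnosticResult:
    rows: list[AgnosticRow]

    def __len__(self) -> int:
        return len(self.rows)

    def cell(self, ketone: str, control: str, method: str) -> AgnosticRow:
        for r in self.rows:
            if (r.ketone, r.control, r.method) == (ketone, control, method):
                return r
        raise KeyError((ketone, control, method))


# ---------------------------------------------------------------------------
# discovery and premises
# ---------------------------------------------------------------------------


def discover_candidate_regions(
    acetone: GWASDataset,
    annotation: Sequence[GeneAnnotation],
    p_disc: float = DISCOVERY_P,
    flank: int = DEFAULT_FLANK,
) -> tuple[list[RegionAssignment], list[str]]:
    """Gene regions with at least one sub-threshold acetone association.

    Returns the candidate regions and, separately, the ids of sub-threshold
    variants falling inside no annotated window.
    """
    regions = assign_regions(acetone, annotation, flank=flank)
    hits = {a.variant_id for a in acetone if a.pval < p_disc}
    candidates = [r for r in regions if any(v in hits for v in r.variant_ids)]
    assigned = {v for r in regions for v in r.variant_ids}
    unassigned = sorted(hits - assigned)
    return candidates, unassigned


def premise1_biological(
    region: RegionAssignment, relevant_genes: Sequence[str]
) -> PremiseVerdict:
    """Premise 1: the region's gene encodes a ketone-metabolism protein."""
    if not relevant_genes:
        raise ConfigurationError("relevant_genes must be non-empty")
    genes = {g.upper() for g in relevant_genes}
    ok = region.gene_symbol.upper() in genes
    return PremiseVerdict(
        PASS if ok else FAIL,
        evidence={"gene_symbol": region.gene_symbol, "relevant": ok},
        reason=None if ok else "gene_not_ketone_relevant",
    )


def premise2_consistency(
    lead_id: str,
    ketone_datasets: Mapping[str, GWASDataset],
    p_thr: float = 1e-4,
    require_sign_concordance: bool = False,
) -> PremiseVerdict:
    """Premise 2: the lead variant associates with all three ketone bodies.

    Passes only when the lead is present in each dataset with p < ``p_thr``
    (and, when the flag is on, a concordant effect sign across the three).
    A lead missing from any dataset fails with reason ``missing``.
    """
    if len(ketone_datasets) != 3:
        raise ValueError(
            f"exactly three ketone datasets required, got {len(ketone_datasets)}"
        )
    per_trait: dict[str, dict] = {}
    missing = []
    for trait, ds in ketone_datasets.items():
        a = ds.get(lead_id)
        if a is None:
            missing.append(trait)
            per_trait[trait] = {"present": False}
        else:
            per_trait[trait] = {
                "present": True,
                "beta": a.beta,
                "se": a.se,
                "pval": a.pval,
            }
    evidence = {"lead_variant": lead_id, "per_trait": per_trait}
    if missing:
        return PremiseVerdict(FAIL, evidence=evidence, reason="missing")
    if not all(v["pval"] < p_thr for v in per_trait.values()):
        return PremiseVerdict(FAIL, evidence=evidence, reason="not_consistent")
    if require_sign_concordance:
        signs = {v["beta"] > 0 for v in per_trait.values()}
        if len(signs) > 1:
            return PremiseVerdict(FAIL, evidence=evidence, reason="sign_discordant")
    return PremiseVerdict(PASS, evidence=evidence)


def premise3_pleiotropy(
    region: RegionAssignment,
    catalogue: TraitAssociationCatalogue,
    p_thr: float = GENOME_WIDE_P,
    vertical_whitelist: Sequence[str] = (),
) -> PremiseVerdict:
    """Premise 3: no reported horizontal pleiotropy for the region.

    Catalogue traits matching the region (by gene symbol or member variant)
    at p < ``p_thr`` are flagged; the premise passes only when every flagged
    trait is whitelisted as vertical (on the exposure's own pathway).
    """
    flagged = catalogue.lookup(
        gene_symbol=region.gene_symbol,
        variant_ids=region.variant_ids,
        p_max=p_thr,
    )
    flagged = [f for f in flagged if f.pval < p_thr]
    whitelist = {t.upper() for t in vertical_whitelist}
    traits = []
    horizontal = []
    for rec in flagged:
        vertical = rec.trait_name.upper() in whitelist
        traits.append(
            {"trait": rec.trait_name, "pval": rec.pval, "vertical": vertical}
        )
        if not vertical:
            horizontal.append(rec.trait_name)
    evidence = {"flagged_traits": traits}
    if horizontal:
        return PremiseVerdict(
            FAIL, evidence=evidence, reason="horizontal_pleiotropy"
        )
    return PremiseVerdict(PASS, evidence=evidence)


def _control_estimate(
    hset: HarmonizedInstrumentSet, ivw_model: str
) -> est.MREstimate:
    """IVW for multiple variants, the ratio method for a single variant."""
    if len(hset) >= 2:
        return est.ivw_estimate(hset, model=ivw_model)
    return est.ratio_estimate(hset.pairs[0])


def premise4_positive_controls(
    instruments: Mapping[str, HarmonizedInstrumentSet],
    alpha: float = 0.05,
    ivw_model: str = "ivw_mre",
) -> PremiseVerdict:
    """Premise 4: instruments recover an effect on >= 1 positive control.

    Each control gets an IVW estimate (multiple variants) or a ratio estimate
    (single variant); the premise passes when any control's p-value is below
    ``alpha`` (two-sided).  With no harmonizable instruments for any control
    the premise fails with that reason.
    """
    if not instruments:
        raise ValueError("at least one control instrument set required")
    per_control: dict[str, dict] = {}
    any_instruments = False
    any_significant = False
    for control, hset in instruments.items():
        if len(hset) == 0:
            per_control[control] = {"n_variants": 0, "note": "no_instruments"}
            continue
        any_instruments = True
        estimate = _control_estimate(hset, ivw_model)
        per_control[control] = {
            "n_variants": len(hset),
            "method": estimate.method,
            "estimate": estimate.to_record(),
        }
        if estimate.pval < alpha:
            any_significant = True
    evidence = {"per_control": per_control, "alpha": alpha}
    if not any_instruments:
        return PremiseVerdict(
            FAIL, evidence=evidence, reason="no_harmonizable_instruments"
        )
    if any_significant:
        return PremiseVerdict(PASS, evidence=evidence)
    return PremiseVerdict(FAIL, evidence=evidence, reason="no_control_association")


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------


def _region_sort_key(r: RegionAssignment):
    return (r.chrom, r.window_start, r.gene_symbol)


def run_biological_pipeline(
    bundle: Bundle, config: PipelineConfig = PipelineConfig()
) -> PremiseMatrix:
    """Run the stepwise four-premise screen for every discovery source.

    Per source and candidate region: premise 1; if it passes, premise 2 on
    the region's lead variant; if both pass, genome-wide-significant variants
    in the window are LD-clumped into the instrument set and premises 3 and 4
    are evaluated independently.  Failures at premise 1 or 2 short-circuit
    everything downstream.
    """
    bundle.validate()
    rows: list[RegionReport] = []
    stepwise: dict[str, list[int]] = {}
    for source in sorted(bundle.discovery):
        ds = bundle.discovery[source]
        candidates, _ = discover_candidate_regions(
            ds, bundle.annotation, p_disc=config.p_discovery, flank=config.flank
        )
        counts = [len(candidates), 0, 0, 0, 0]
        for region in sorted(candidates, key=_region_sort_key):
            rows.append(_assess_region(source, region, ds, bundle, config))
        # survival counts: premise k passed for premises 1..4
        for r in rows:
            if r.source != source:
                continue
            ok = True
            for k in range(4):
                ok = ok and r.verdicts[k].status == PASS
                if ok:
                    counts[k + 1] += 1
        stepwise[source] = counts
    return PremiseMatrix(rows=rows, stepwise_counts=stepwise)


def _assess_region(
    source: str,
    region: RegionAssignment,
    ds: GWASDataset,
    bundle: Bundle,
    config: PipelineConfig,
) -> RegionReport:
    v1 = premise1_biological(region, config.relevant_genes)
    lead = lead_variant(region, ds) if region.variant_ids else None
    if v1.status != PASS:
        return _report(source, region, lead, [], (v1, _NOT_EVALUATED, _NOT_EVALUATED, _NOT_EVALUATED))
    v2 = premise2_consistency(
        lead,
        bundle.ketones,
        p_thr=config.p_consistency,
        require_sign_concordance=config.require_sign_concordance,
    )
    if v2.status != PASS:
        return _report(source, region, lead, [], (v1, v2, _NOT_EVALUATED, _NOT_EVALUATED))
    ld = bundle.ld.get(region.gene_symbol)
    if ld is None:
        raise ConfigurationError(
            f"bundle component 'ld' lacks a matrix for gene {region.gene_symbol!r}"
        )
    clump_input = [v for v in region.variant_ids if v in ld]
    clumped = greedy_clump(
        clump_input, ds, ld, r2_max=config.r2_max, p_max=config.p_genome_wide
    )
    v3 = premise3_pleiotropy(
        region,
        bundle.catalogue,
        p_thr=config.p_catalogue,
        vertical_whitelist=config.vertical_whitelist,
    )
    if clumped:
        instruments = {
            control: harmonize_set(ds, cds, clumped, policy=config.harmonization)
            for control, cds in sorted(bundle.controls.items())
        }
        v4 = premise4_positive_controls(
            instruments, alpha=config.alpha, ivw_model=config.ivw_model
        )
    else:
        v4 = PremiseVerdict(
            FAIL,
            evidence={"per_control": {}, "alpha": config.alpha},
            reason="no_genome_wide_significant_instruments",
        )
    secondary = [v for v in clumped if v != lead]
    return RegionReport(
        source=source,
        gene_symbol=region.gene_symbol,
        chrom=region.chrom,
        window_start=region.window_start,
        window_end=region.window_end,
        lead_variant=lead,
        secondary_variants=secondary,
        verdicts=(v1, v2, v3, v4),
    )


def _report(source, region, lead, secondary, verdicts) -> RegionReport:
    return RegionReport(
        source=source,
        gene_symbol=region.gene_symbol,
        chrom=region.chrom,
        window_start=region.window_start,
        window_end=region.window_end,
        lead_variant=lead,
        secondary_variants=secondary,
        verdicts=verdicts,
    )


def run_agnostic_pipeline(
    bundle: Bundle, config: PipelineConfig = PipelineConfig()
) -> AgnosticResult:
    """The agnostic analysis: one lead variant per gene region, all methods.

    Per ketone body, every gene region's lead variant reaching genome-wide
    significance becomes an instrument; the deduplicated set is harmonized to
    each control and IVW (or the ratio method for a single variant) is
    computed, with weighted-median and MR-Egger added when at least three
    variants survive.
    """
    bundle.validate()
    rows: list[AgnosticRow] = []
    for ketone in sorted(bundle.ketones):
        ds = bundle.ketones[ketone]
        regions = assign_regions(ds, bundle.annotation, flank=config.flank)
        leads: list[str] = []
        for region in sorted(regions, key=_region_sort_key):
            sig = [
                v for v in region.variant_ids if ds[v].pval < config.p_genome_wide
            ]
            if not sig:
                continue
            lead = min(sig, key=lambda v: (ds[v].pval, ds[v].pos, v))
            if lead not in leads:
                leads.append(lead)
        for control in sorted(bundle.controls):
            cds = bundle.controls[control]
            if not leads:
                for method in ("ivw", "weighted_median", "egger"):
                    rows.append(
                        AgnosticRow(ketone, control, method, None, 0, "no_instruments")
                    )
                continue
            hset = harmonize_set(ds, cds, leads, policy=config.harmonization)
            J = len(hset)
            if J == 0:
                for method in ("ivw", "weighted_median", "egger"):
                    rows.append(
                        AgnosticRow(
                            ketone, control, method, None, 0, "none_harmonized"
                        )
                    )
                continue
            rows.append(
                AgnosticRow(
                    ketone, control, "ivw", _control_estimate(hset, config.ivw_model), J
                )
            )
            if J >= 3:
                rows.append(
                    AgnosticRow(
                        ketone,
                        control,
                        "weighted_median",
                        est.weighted_median_estimate(
                            hset, n_boot=config.n_boot, seed=config.seed
                        ),
                        J,
                    )
                )
                rows.append(
                    AgnosticRow(ketone, control, "egger", est.egger_estimate(hset), J)
                )
            else:
                for method in ("weighted_median", "egger"):
                    rows.append(
                        AgnosticRow(
                            ketone, control, method, None, J, "requires_3_variants"
                        )
                    )
    return AgnosticResult(rows=rows)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_MATRIX_COLUMNS = [
    "source",
    "gene",
    "lead_variant",
    "secondary_variants",
    "biological_relevance",
    "ketone_consistency",
    "no_horizontal_pleiotropy",
    "positive_control",
]


def render_matrix(matrix: PremiseMatrix, style: str = "table") -> str:
    """Deterministic rendering of the premise matrix.

    ``style='tsv'`` gives a machine-readable tab-delimited table;
    ``style='table'`` a human-readable layout.  Verdicts use the glyphs
    "✓" (satisfied), "×" (not satisfied) and "-" (not investigated); rows are
    sorted by source, then genomic position.
    """
    rows = sorted(
        matrix.rows, key=lambda r: (r.source, r.chrom, r.window_start, r.gene_symbol)
    )
    table = [
        [
            r.source,
            r.gene_symbol,
            r.lead_variant or "-",
            ",".join(r.secondary_variants) or "-",
            *(v.symbol for v in r.verdicts),
        ]
        for r in rows
    ]
    if style == "tsv":
        lines = ["\t".join(_MATRIX_COLUMNS)]
        lines += ["\t".join(row) for row in table]
        return "\n".join(lines) + "\n"
    if style != "table":
        raise ValueError(f"unknown style {style!r}")
    widths = [
        max(len(_MATRIX_COLUMNS[i]), *(len(row[i]) for row in table), 1)
        if table
        else len(_MATRIX_COLUMNS[i])
        for i in range(len(_MATRIX_COLUMNS))
    ]
    lines = [
        "  ".join(c.ljust(widths[i]) for i, c in enumerate(_MATRIX_COLUMNS)).rstrip()
    ]
    for row in table:
        lines.append(
            "  ".join(c.ljust(widths[i]) for i, c in enumerate(row)).rstrip()
        )
    return "\n".join(lines) + "\n"


def render_agnostic(result: AgnosticResult) -> str:
    """Tab-delimited rendering of the agnostic analysis results."""
    cols = [
        "ketone",
        "control",
        "method",
        "n_variants",
        "beta",
        "se",
        "ci_low",
        "ci_high",
        "pval",
        "note",
    ]
    lines = ["\t".join(cols)]
    for r in sorted(result.rows, key=lambda r: (r.ketone, r.control, r.method)):
        if r.estimate is None:
            vals = ["NA"] * 5
        else:
            e = r.estimate
            vals = [
                f"{e.beta:.6g}",
                f"{e.se:.6g}",
                f"{e.ci_low:.6g}",
                f"{e.ci_high:.6g}",
                f"{e.pval:.6g}",
            ]
        lines.append(
            "\t".join(
                [r.ketone, r.control, r.method, str(r.n_variants), *vals, r.note or ""]
            )
        )
    return "\n".join(lines) + "\n"
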