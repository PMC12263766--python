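"""Place exposure and outcome associations on a common effect-allele frame.

Two summary files rarely report a variant on the same frame: the outcome study
may label the other allele as "effect" (a swap), report the opposite DNA
strand (a complement), or both.  Harmonization rewrites every outcome record
so its effect allele matches the exposure's, flipping the sign of the outcome
beta and mirroring its allele frequency where needed.  Palindromic variants
(A/T or C/G) are the hard case — strand cannot be resolved from the allele
labels — so orientation is inferred from allele-frequency agreement when both
frequencies are available and informative, and the variant is dropped
otherwise.

Standard errors are never changed by harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .summary_data import GWASDataset, VariantAssociation

__all__ = [
    "KEPT",
    "FLIPPED",
    "STRAND_FLIPPED",
    "DROPPED",
    "HarmonizationPolicy",
    "HarmonizedPair",
    "HarmonizedInstrumentSet",
    "harmonize_variant",
    "harmonize_set",
    "write_drop_log",
]

KEPT = "kept"
FLIPPED = "flipped"
STRAND_FLIPPED = "strand_flipped"
DROPPED = "dropped"

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Base complement of a single-nucleotide allele."""
    return "".join(_COMPLEMENT[b] for b in allele)


def is_palindromic(a: str, b: str) -> bool:
    """True when the allele pair is its own reverse complement (A/T or C/G)."""
    return len(a) == 1 and len(b) == 1 and _COMPLEMENT.get(a) == b


@dataclass(frozen=True)
class HarmonizationPolicy:
    """Tunable harmonization behaviour.

    ``palindrome_window`` is the EAF interval inside which a palindromic
    variant's orientation is considered unresolvable; both studies' EAFs must
    fall outside it for the variant to be kept.
    """

    palindrome_window: tuple[float, float] = (0.42, 0.58)
    drop_palindromic_missing_eaf: bool = True


DEFAULT_POLICY = HarmonizationPolicy()


@dataclass
class HarmonizedPair:
    """One variant's exposure/outcome quadruple on a common effect-allele frame."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    exposure_beta: float
    exposure_se: float
    outcome_beta: float | None
    outcome_se: float | None
    exposure_eaf: float | None = None
    outcome_eaf: float | None = None
    action: str = KEPT
    drop_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.action == DROPPED) != (self.drop_reason is not None):
            raise ValueError("drop_reason present iff action == dropped")

    @property
    def dropped(self) -> bool:
        return self.action == DROPPED


@dataclass
class HarmonizedInstrumentSet:
    """Kept exposure/outcome pairs for one exposure-outcome analysis."""

    exposure_trait: str
    outcome_trait: str
    pairs: list[HarmonizedPair]
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(p.dropped for p in self.pairs):
            raise ValueError("dropped pairs may not appear in the kept collection")
        ids = [p.variant_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in instrument set")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def exposure_betas(self) -> list[float]:
        return [p.exposure_beta for p in self.pairs]

    @property
    def outcome_betas(self) -> list[float]:
        return [p.outcome_beta for p in self.pairs]

    @classmethod
    def from_arrays(
        cls,
        exposure_beta,
        exposure_se,
        outcome_beta,
        outcome_se,
        exposure_trait: str = "exposure",
        outcome_trait: str = "outcome",
    ) -> "HarmonizedInstrumentSet":
        """Build a set directly from aligned effect arrays (testing/simulation)."""
        pairs = [
            HarmonizedPair(
                variant_id=f"v{i}",
                chrom="NA",
                pos=i + 1,
                effect_allele="A",
                other_allele="G",
                exposure_beta=float(bx),
                exposure_se=float(sx),
                outcome_beta=float(by),
                outcome_se=float(sy),
            )
            for i, (bx, sx, by, sy) in enumerate(
                zip(exposure_beta, exposure_se, outcome_beta, outcome_se)
            )
        ]
        return cls(exposure_trait, outcome_trait, pairs)


def _pair(
    exposure: VariantAssociation,
    outcome_beta: float | None,
    outcome_se: float | None,
    outcome_eaf: float | None,
    action: str,
    drop_reason: str | None = None,
) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exposure.variant_id,
        chrom=exposure.chrom,
        pos=exposure.pos,
        effect_allele=exposure.effect_allele,
        other_allele=exposure.other_allele,
        exposure_beta=exposure.beta,
        exposure_se=exposure.se,
        outcome_beta=outcome_beta,
        outcome_se=outcome_se,
        exposure_eaf=exposure.eaf,
        outcome_eaf=outcome_eaf,
        action=action,
        drop_reason=drop_reason,
    )


def _dropped(exposure: VariantAssociation, reason: str) -> HarmonizedPair:
    return _pair(exposure, None, None, None, DROPPED, reason)


def harmonize_variant(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    policy: HarmonizationPolicy = DEFAULT_POLICY,
) -> HarmonizedPair:
    """Harmonize one outcome association onto the exposure's allele frame.

    Resolution order: literal allele match (kept), swapped alleles (sign
    flip), strand complement then match/swap (non-palindromic only),
    EAF-guided orientation for palindromic pairs, otherwise dropped with
    ``allele_mismatch``.  Indel alleles are compared literally; no strand
    complement is attempted for them.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exposure.variant_id!r} vs {outcome.variant_id!r}"
        )
    e = (exposure.effect_allele, exposure.other_allele)
    o = (outcome.effect_allele, outcome.other_allele)
    beta, se, eaf = outcome.beta, outcome.se, outcome.eaf

    indel = exposure.is_indel or outcome.is_indel
    if indel:
        if o == e:
            return _pair(exposure, beta, se, eaf, KEPT)
        if o == (e[1], e[0]):
            return _pair(
                exposure, -beta, se, None if eaf is None else 1 - eaf, FLIPPED
            )
        return _dropped(exposure, "allele_mismatch")

    if is_palindromic(*e):
        # allele labels cannot resolve strand; align by label, then check
        # whether the allele frequencies agree with that alignment
        if o == e:
            aligned_beta, aligned_eaf, base_action = beta, eaf, KEPT
        elif o == (e[1], e[0]):
            aligned_beta = -beta
            aligned_eaf = None if eaf is None else 1 - eaf
            base_action = FLIPPED
        else:
            return _dropped(exposure, "allele_mismatch")
        if exposure.eaf is None or aligned_eaf is None:
            if policy.drop_palindromic_missing_eaf:
                return _dropped(exposure, "palindromic_ambiguous")
            return _pair(exposure, aligned_beta, se, aligned_eaf, base_action)
        lo, hi = policy.palindrome_window
        if lo <= exposure.eaf <= hi or lo <= aligned_eaf <= hi:
            return _dropped(exposure, "palindromic_ambiguous")
        if (exposure.eaf < 0.5) == (aligned_eaf < 0.5):
            return _pair(exposure, aligned_beta, se, aligned_eaf, base_action)
        # frequencies disagree with the label alignment: the outcome study is
        # on the opposite strand, which for a palindrome is a net sign flip
        final = FLIPPED if base_action == KEPT else KEPT
        return _pair(exposure, -aligned_beta, se, 1 - aligned_eaf, final)

    if o == e:
        return _pair(exposure, beta, se, eaf, KEPT)
    if o == (e[1], e[0]):
        return _pair(exposure, -beta, se, None if eaf is None else 1 - eaf, FLIPPED)
    oc = (complement(o[0]), complement(o[1]))
    if oc == e:
        return _pair(exposure, beta, se, eaf, STRAND_FLIPPED)
    if oc == (e[1], e[0]):
        return _pair(
            exposure,
            -beta,
            se,
            None if eaf is None else 1 - eaf,
            STRAND_FLIPPED,
        )
    return _dropped(exposure, "allele_mismatch")


def harmonize_set(
    exposure: GWASDataset,
    outcome: GWASDataset,
    variant_ids,
    policy: HarmonizationPolicy = DEFAULT_POLICY,
) -> HarmonizedInstrumentSet:
    """Harmonize a list of instruments between two datasets.

    Every requested id must be present in the exposure dataset; ids absent
    from the outcome are dropped with reason ``missing_in_outcome``.  Kept
    pairs are ordered by (chrom, pos) and the drop log accounts for every
    requested id that was not kept.
    """
    ids = list(variant_ids)
    if not ids:
        raise ValueError("variant_ids must be non-empty")
    kept: list[HarmonizedPair] = []
    drop_log: list[tuple[str, str]] = []
    for vid in ids:
        exp = exposure.get(vid)
        if exp is None:
            raise ValueError(
                f"variant {vid!r} absent from exposure dataset {exposure.trait_name!r}"
            )
        out = outcome.get(vid)
        if out is None:
            drop_log.append((vid, "missing_in_outcome"))
            continue
        pair = harmonize_variant(exp, out, policy)
        if pair.dropped:
            drop_log.append((vid, pair.drop_reason or "dropped"))
        else:
            kept.append(pair)
    kept.sort(key=lambda p: (p.chrom, p.pos, p.variant_id))
    return HarmonizedInstrumentSet(
        exposure_trait=exposure.trait_name,
        outcome_trait=outcome.trait_name,
        pairs=kept,
        drop_log=drop_log,
    )


def write_drop_log(hset: HarmonizedInstrumentSet, path) -> None:
    """Emit the drop log as tab-delimited (variant_id, reason)."""
    with open(path, "w") as fh:
        fh.write("variant_id\treason\n")
        for vid, reason in hset.drop_log:
            fh.write(f"{vid}\t{reason}\n")
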