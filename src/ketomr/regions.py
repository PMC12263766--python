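"""Gene-region windowing, lead-variant selection, and greedy LD clumping.

A gene region is the annotated gene interval plus a symmetric flank
(default 200 kb).  Instrument candidates live inside these windows; within a
window, clumping retains approximately independent variants by walking the
p-value order and discarding anything correlated (r^2 at or above the
threshold) with an already-retained variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .summary_data import DataError, GWASDataset, GeneAnnotation, LDMatrix

__all__ = [
    "DISCOVERY_P",
    "GENOME_WIDE_P",
    "DEFAULT_FLANK",
    "RegionAssignment",
    "assign_regions",
    "lead_variant",
    "greedy_clump",
    "write_retained",
]

#: sub-genome-wide discovery threshold for candidate gene regions
DISCOVERY_P = 5e-6
#: conventional genome-wide significance threshold
GENOME_WIDE_P = 5e-8
#: symmetric window flank around a gene, in base pairs
DEFAULT_FLANK = 200_000


@dataclass
class RegionAssignment:
    """Variants falling inside one gene's flanked window."""

    gene_symbol: str
    chrom: str
    window_start: int
    window_end: int
    variant_ids: list[str]

    def __len__(self) -> int:
        return len(self.variant_ids)


def assign_regions(
    dataset: GWASDataset,
    annotation: Sequence[GeneAnnotation],
    flank: int = DEFAULT_FLANK,
) -> list[RegionAssignment]:
    """Assign every variant to every gene window containing its position.

    Windows are ``[gene start - flank, gene end + flank]``, floored at 1,
    with inclusive boundaries.  Overlapping windows each receive the variant;
    variants inside no window are simply unassigned.
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    out = []
    for gene in annotation:
        ws = max(1, gene.start - flank)
        we = gene.end + flank
        members = [
            a.variant_id
            for a in dataset
            if a.chrom == gene.chrom and ws <= a.pos <= we
        ]
        out.append(
            RegionAssignment(
                gene_symbol=gene.gene_symbol,
                chrom=gene.chrom,
                window_start=ws,
                window_end=we,
                variant_ids=members,
            )
        )
    return out


def _sort_key(dataset: GWASDataset):
    def key(vid: str):
        a = dataset[vid]
        return (a.pval, a.pos, a.variant_id)

    return key


def lead_variant(region: RegionAssignment, dataset: GWASDataset) -> str:
    """The region member with the smallest p-value.

    Ties break to the smaller position, then the lexicographically smaller
    variant id, so the choice is deterministic.
    """
    if not region.variant_ids:
        raise ValueError(f"region {region.gene_symbol} has no member variants")
    return min(region.variant_ids, key=_sort_key(dataset))


def greedy_clump(
    variant_ids: Iterable[str],
    dataset: GWASDataset,
    ld: LDMatrix,
    r2_max: float = 0.1,
    p_max: float | None = None,
) -> list[str]:
    """Greedy LD clumping: retain p-value-ordered, approximately independent variants.

    Repeatedly retains the remaining variant with the smallest p-value (ties
    as in :func:`lead_variant`) and discards every remaining variant with
    r^2 >= ``r2_max`` against it, so all retained pairwise r^2 are strictly
    below the threshold.  ``p_max`` pre-filters on significance when given.
    The result is ordered by retention and independent of input order.
    """
    ids = list(variant_ids)
    missing = [v for v in ids if v not in ld]
    if missing:
        raise DataError(f"variants absent from LD matrix: {missing}")
    if p_max is not None:
        ids = [v for v in ids if dataset[v].pval <= p_max]
    remaining = sorted(ids, key=_sort_key(dataset))
    retained: list[str] = []
    while remaining:
        top = remaining.pop(0)
        retained.append(top)
        remaining = [v for v in remaining if ld.r2_between(top, v) < r2_max]
    return retained


def write_retained(
    gene_symbol: str,
    retained: Sequence[str],
    dataset: GWASDataset,
    path: str | Path,
) -> None:
    """Emit a retained set as tab-delimited (gene, variant_id, pval, order)."""
    with open(path, "w") as fh:
        fh.write("gene\tvariant_id\tpval\torder_retained\n")
        for i, vid in enumerate(retained, start=1):
            fh.write(f"{gene_symbol}\t{vid}\t{dataset[vid].pval:.6g}\t{i}\n")
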