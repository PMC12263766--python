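"""Domain types and file I/O for GWAS summary statistics and companions.

The in-memory containers here are deliberately small: a GWAS summary file
becomes a :class:`GWASDataset` of per-variant :class:`VariantAssociation`
records, gene annotations become 1-based inclusive :class:`GeneAnnotation`
intervals, and linkage disequilibrium comes in as an :class:`LDMatrix` of
pairwise correlations.  Everything downstream (harmonization, clumping, the
premise pipeline) speaks these types only.

Coordinate convention: internal positions are 1-based inclusive, the native
convention of GWAS summary files.  BED input (0-based half-open) is converted
on read and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DataError",
    "ConfigurationError",
    "VariantAssociation",
    "GWASDataset",
    "GeneAnnotation",
    "LDMatrix",
    "CatalogueRecord",
    "TraitAssociationCatalogue",
    "derive_pvalue",
    "derive_se",
    "read_gwas_table",
    "write_gwas_table",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_trait_catalogue",
    "write_trait_catalogue",
]

VALID_BASES = frozenset("ACGT")

#: smallest positive double; p-values are clipped here rather than to 0
_P_FLOOR = float(np.nextafter(0.0, 1.0))


class DataError(ValueError):
    """Malformed input data (bad row, duplicate id, out-of-range value)."""


class ConfigurationError(ValueError):
    """Invalid configuration (missing column mapping, empty gene list...)."""


def _is_allele(a: object) -> bool:
    return isinstance(a, str) and len(a) >= 1 and set(a) <= VALID_BASES


def derive_pvalue(beta: float, se: float) -> float:
    """Two-sided Wald p-value from an effect estimate and its standard error.

    Returns ``2 * Phi(-|beta/se|)``, clipped to the smallest positive double
    so downstream log/p filters never see an exact zero.
    """
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return max(float(p), _P_FLOOR)


def derive_se(beta: float, pval: float) -> float:
    """Back out a standard error from an effect estimate and a Wald p-value."""
    if not 0.0 < pval <= 1.0:
        raise ValueError(f"pval must be in (0, 1], got {pval}")
    if beta == 0:
        raise ValueError("cannot derive se when beta is 0")
    z = stats.norm.isf(pval / 2.0)
    if z <= 0:
        raise ValueError(f"pval {pval} gives non-positive z")
    return abs(beta) / float(z)


@dataclass
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the per effect-allele-copy association, with the trait in
    standard-deviation units unless the dataset's ``trait_units`` says
    otherwise.  ``eaf`` (effect-allele frequency) and ``n`` may be absent, as
    in some published summary files.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def problems(self) -> list[str]:
        """Invariant violations, empty when the record is well-formed."""
        out: list[str] = []
        if not self.variant_id:
            out.append("empty variant_id")
        if not _is_allele(self.effect_allele):
            out.append(f"invalid effect_allele {self.effect_allele!r}")
        if not _is_allele(self.other_allele):
            out.append(f"invalid other_allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele equals other_allele")
        if not (isinstance(self.se, float) and math.isfinite(self.se) and self.se > 0):
            out.append(f"se must be a positive real, got {self.se}")
        if not (math.isfinite(self.beta)):
            out.append(f"beta must be finite, got {self.beta}")
        if not (0.0 < self.pval <= 1.0):
            out.append(f"pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            out.append(f"eaf must be in (0, 1), got {self.eaf}")
        if self.n is not None and self.n <= 0:
            out.append(f"n must be positive, got {self.n}")
        return out

    @property
    def is_indel(self) -> bool:
        return len(self.effect_allele) > 1 or len(self.other_allele) > 1


@dataclass
class GWASDataset:
    """A trait's full set of variant associations, indexed by variant id."""

    trait_name: str
    associations: list[VariantAssociation]
    trait_units: str = "SD"
    ancestry: str = "NA"
    _index: dict[str, VariantAssociation] = field(
        init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self._index = {}
        for a in self.associations:
            if a.variant_id in self._index:
                raise DataError(
                    f"duplicate variant_id {a.variant_id!r} in dataset "
                    f"{self.trait_name!r}"
                )
            self._index[a.variant_id] = a

    def __len__(self) -> int:
        return len(self.associations)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.associations)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self._index.get(variant_id)

    def __getitem__(self, variant_id: str) -> VariantAssociation:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(
                f"variant {variant_id!r} not in dataset {self.trait_name!r}"
            ) from None

    @property
    def variant_ids(self) -> list[str]:
        return [a.variant_id for a in self.associations]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [a.variant_id for a in self.associations],
                "chrom": [a.chrom for a in self.associations],
                "pos": [a.pos for a in self.associations],
                "effect_allele": [a.effect_allele for a in self.associations],
                "other_allele": [a.other_allele for a in self.associations],
                "eaf": [a.eaf for a in self.associations],
                "beta": [a.beta for a in self.associations],
                "se": [a.se for a in self.associations],
                "pval": [a.pval for a in self.associations],
                "n": [a.n for a in self.associations],
            }
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval, 1-based inclusive."""

    gene_symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"gene {self.gene_symbol}: start {self.start} > end {self.end}"
            )


class LDMatrix:
    """Pairwise variant correlations (r, not r^2) for one set of variants.

    Construction symmetrizes within ``atol`` (by averaging), forces a unit
    diagonal, and rejects entries beyond |r| = 1 + atol.
    """

    def __init__(
        self,
        variant_ids: Sequence[str],
        r: np.ndarray,
        atol: float = 1e-8,
    ) -> None:
        r = np.asarray(r, dtype=float)
        ids = list(variant_ids)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise DataError(f"LD matrix must be square, got shape {r.shape}")
        if r.shape[0] != len(ids):
            raise DataError(
                f"LD matrix dimension {r.shape[0]} != {len(ids)} variant ids"
            )
        if len(set(ids)) != len(ids):
            raise DataError("duplicate variant ids in LD matrix")
        if np.any(np.abs(r) > 1.0 + atol):
            raise DataError("LD matrix has entries with |r| > 1")
        if np.any(np.abs(r - r.T) > atol):
            raise DataError("LD matrix asymmetric beyond tolerance")
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
        np.clip(r, -1.0, 1.0, out=r)
        self.variant_ids: list[str] = ids
        self.r: np.ndarray = r
        self._pos: dict[str, int] = {v: i for i, v in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._pos

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self._pos[a], self._pos[b]])

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2

    def submatrix(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._pos[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])


@dataclass(frozen=True)
class CatalogueRecord:
    """One reported trait association from a GWAS-Catalogue-style table."""

    variant_id: str
    gene_symbol: str
    trait_name: str
    pval: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pval <= 1.0:
            raise DataError(f"catalogue pval must be in (0, 1], got {self.pval}")


@dataclass
class TraitAssociationCatalogue:
    """A flat table of previously reported (variant/gene, trait, p) records."""

    records: list[CatalogueRecord]

    def lookup(
        self,
        gene_symbol: str | None = None,
        variant_ids: Iterable[str] | None = None,
        p_max: float = 1.0,
    ) -> list[CatalogueRecord]:
        """Records matching the gene symbol or any of the variant ids, at p <= p_max."""
        gene = gene_symbol.upper() if gene_symbol else None
        ids = set(variant_ids) if variant_ids is not None else set()
        out = []
        for rec in self.records:
            if rec.pval > p_max:
                continue
            if (gene and rec.gene_symbol.upper() == gene) or rec.variant_id in ids:
                out.append(rec)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta")

#: the default column names used by ``write_gwas_table``
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}


def read_gwas_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_units: str = "SD",
    ancestry: str = "NA",
    strict: bool = False,
) -> tuple[GWASDataset, list[str]]:
    """Read a tab-delimited GWAS summary-statistics file.

    ``column_map`` maps internal field names (``variant_id``, ``chrom``,
    ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
    ``pval``, ``n``) to the file's column names; at minimum the variant id,
    both alleles, ``beta`` and one of ``se``/``pval`` must be mapped.  When
    ``pval`` is absent it is derived from beta/se (two-sided Wald); when
    ``se`` is absent it is backed out from beta and pval.

    Rows violating the per-variant invariants are rejected with row-numbered
    diagnostics (returned alongside the dataset); ``strict=True`` escalates
    any rejection to :class:`DataError`.  gzip input is handled
    transparently.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    for f in _REQUIRED_FIELDS:
        if f not in cmap:
            raise ConfigurationError(f"column_map missing required field {f!r}")
    if "se" not in cmap and "pval" not in cmap:
        raise ConfigurationError("column_map must provide 'se' or 'pval'")

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"columns {missing} named in column_map absent from {path}"
        )

    def _get(row: pd.Series, fld: str) -> str | None:
        if fld not in cmap:
            return None
        v = row[cmap[fld]]
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return str(v)

    associations: list[VariantAssociation] = []
    diagnostics: list[str] = []
    seen: set[str] = set()
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            vid = _get(row, "variant_id") or ""
            beta = float(_get(row, "beta"))  # type: ignore[arg-type]
            se_raw = _get(row, "se")
            p_raw = _get(row, "pval")
            se = float(se_raw) if se_raw is not None else None
            pval = float(p_raw) if p_raw is not None else None
            if pval is None:
                if se is None:
                    raise ValueError("neither se nor pval present")
                pval = derive_pvalue(beta, se)
            if se is None:
                se = derive_se(beta, pval)
            eaf_raw = _get(row, "eaf")
            n_raw = _get(row, "n")
            assoc = VariantAssociation(
                variant_id=vid,
                chrom=_get(row, "chrom") or "NA",
                pos=int(float(_get(row, "pos") or 0)),
                effect_allele=(_get(row, "effect_allele") or "").upper(),
                other_allele=(_get(row, "other_allele") or "").upper(),
                eaf=float(eaf_raw) if eaf_raw is not None else None,
                beta=beta,
                se=se,
                pval=pval,
                n=int(float(n_raw)) if n_raw is not None else None,
            )
        except (TypeError, ValueError) as exc:
            diagnostics.append(f"row {i}: unparseable ({exc})")
            continue
        probs = assoc.problems()
        if probs:
            diagnostics.append(f"row {i}: {'; '.join(probs)}")
            continue
        if assoc.variant_id in seen:
            raise DataError(
                f"duplicate variant_id {assoc.variant_id!r} at row {i} of {path}"
            )
        seen.add(assoc.variant_id)
        associations.append(assoc)

    if strict and diagnostics:
        raise DataError(
            f"{len(diagnostics)} malformed rows in {path}: {diagnostics[0]}"
        )
    dataset = GWASDataset(
        trait_name=trait_name,
        associations=associations,
        trait_units=trait_units,
        ancestry=ancestry,
    )
    return dataset, diagnostics


def write_gwas_table(dataset: GWASDataset, path: str | Path) -> None:
    """Write a dataset in the default tab-delimited layout (round-trippable)."""
    df = dataset.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED file (0-based half-open: chrom, start, end, name).

    Coordinates are converted to the internal 1-based inclusive convention;
    overlapping genes are retained as-is.
    """
    out: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise DataError(f"{path}:{lineno}: expected 4 BED columns")
            chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if name in seen:
                raise DataError(f"{path}:{lineno}: duplicate gene symbol {name!r}")
            seen.add(name)
            out.append(GeneAnnotation(name, chrom, start0 + 1, end0))
    return out


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_symbol}\n")


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a tab-delimited square correlation matrix with id header/index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    return LDMatrix(ids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_trait_catalogue(path: str | Path) -> TraitAssociationCatalogue:
    """Read a tab-delimited (variant_id, gene_symbol, trait, pval) table."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene_symbol": str})
    records = [
        CatalogueRecord(
            variant_id=str(row.variant_id),
            gene_symbol=str(row.gene_symbol),
            trait_name=str(row.trait),
            pval=float(row.pval),
        )
        for row in df.itertuples()
    ]
    return TraitAssociationCatalogue(records)


def write_trait_catalogue(
    catalogue: TraitAssociationCatalogue, path: str | Path
) -> None:
    pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in catalogue.records],
            "gene_symbol": [r.gene_symbol for r in catalogue.records],
            "trait": [r.trait_name for r in catalogue.records],
            "pval": [r.pval for r in catalogue.records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
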