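"""Read and write screening bundles as a directory of plain-text files.

A bundle directory holds one tab-delimited summary-statistics file per
dataset, a BED gene annotation, one LD matrix per gene region, the trait
catalogue, optionally the ground-truth table of a synthetic bundle, and a
``manifest.yaml`` tying the pieces together.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .pipeline import Bundle
from .simulate import RegionTruth, TruthTable
from .summary_data import (
    ConfigurationError,
    read_gene_annotation,
    read_gwas_table,
    read_ld_matrix,
    read_trait_catalogue,
    write_gene_annotation,
    write_gwas_table,
    write_ld_matrix,
    write_trait_catalogue,
)

__all__ = ["write_bundle", "read_bundle", "write_truth", "read_truth"]


def write_bundle(bundle: Bundle, out_dir: str | Path, truth: TruthTable | None = None) -> Path:
    """Write a bundle (and optional truth table) to a directory; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"discovery": {}, "ketones": {}, "controls": {}, "ld": {}}
    for group, datasets in (
        ("discovery", bundle.discovery),
        ("ketones", bundle.ketones),
        ("controls", bundle.controls),
    ):
        for name, ds in datasets.items():
            fname = f"{group}_{name}.tsv"
            write_gwas_table(ds, out / fname)
            manifest[group][name] = fname
    write_gene_annotation(bundle.annotation, out / "annotation.bed")
    manifest["annotation"] = "annotation.bed"
    for gene, ld in bundle.ld.items():
        fname = f"ld_{gene}.tsv"
        write_ld_matrix(ld, out / fname)
        manifest["ld"][gene] = fname
    write_trait_catalogue(bundle.catalogue, out / "catalogue.tsv")
    manifest["catalogue"] = "catalogue.tsv"
    if truth is not None:
        write_truth(truth, out / "truth.tsv")
        manifest["truth"] = "truth.tsv"
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def read_bundle(manifest_path: str | Path) -> Bundle:
    """Load a bundle from a manifest written by :func:`write_bundle`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    for key in ("discovery", "ketones", "controls", "annotation", "ld", "catalogue"):
        if key not in manifest:
            raise ConfigurationError(f"manifest missing component {key!r}")

    def _datasets(group: str):
        out = {}
        for name, fname in manifest[group].items():
            ds, _ = read_gwas_table(root / fname, trait_name=name)
            out[name] = ds
        return out

    return Bundle(
        discovery=_datasets("discovery"),
        ketones=_datasets("ketones"),
        controls=_datasets("controls"),
        annotation=read_gene_annotation(root / manifest["annotation"]),
        ld={
            gene: read_ld_matrix(root / fname)
            for gene, fname in manifest["ld"].items()
        },
        catalogue=read_trait_catalogue(root / manifest["catalogue"]),
    )


def write_truth(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\tarchetype\tpremise1\tpremise2\tpremise3\tpremise4\tcausal_variants\n"
        )
        for r in truth.regions:
            v = r.expected_verdicts or ("absent",) * 4
            fh.write(
                f"{r.gene_symbol}\t{r.archetype}\t" + "\t".join(v)
                + "\t" + (",".join(r.causal_variant_ids) or "-") + "\n"
            )


def read_truth(path: str | Path) -> TruthTable:
    regions = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            gene, archetype, p1, p2, p3, p4, causal = line.rstrip("\n").split("\t")
            verdicts = None if p1 == "absent" else (p1, p2, p3, p4)
            regions.append(
                RegionTruth(
                    gene_symbol=gene,
                    archetype=archetype,
                    causal_variant_ids=[] if causal == "-" else causal.split(","),
                    expected_verdicts=verdicts,
                    control_effects={},
                )
            )
    return TruthTable(regions)
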