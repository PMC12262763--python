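"""Readers and writers for the pipeline's text artifacts.

Genotypes go to VCF (GT field, via pysam) and a plain dosage TSV; counts to
Matrix Market plus cell/gene TSVs; tracks and LD blocks to BED (0-based
half-open); GWAS summary statistics and the truth ledger to TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import pysam
from scipy import io as spio
from scipy import sparse

from .datatypes import AnnotationTrack, GenotypeMatrix, GwasSumstats, TruthLedger

__all__ = [
    "write_dosage_tsv", "read_dosage_tsv", "write_vcf",
    "write_counts", "read_counts",
    "write_tracks", "read_tracks",
    "write_gwas", "read_gwas",
    "write_truth",
]

_GT_CODES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(genotypes.dosage.T, columns=genotypes.donors)
    out = pd.concat([genotypes.variants.reset_index(drop=True), df], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["chrom", "pos", "ref", "alt", "id"]
    donors = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        donors=donors,
        variants=df[meta_cols].copy(),
        dosage=df[donors].to_numpy(float).T,
    )


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Hard-call genotypes as an uncompressed VCF with a GT field."""
    header = pysam.VariantHeader()
    for chrom, sub in genotypes.variants.groupby("chrom", sort=False):
        header.contigs.add(chrom, length=int(sub["pos"].max()) + 10_000)
    header.formats.add("GT", 1, "String", "Genotype")
    for d in genotypes.donors:
        header.add_sample(str(d))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, v in genotypes.variants.iterrows():
            rec = vcf.new_record(
                contig=v["chrom"], start=int(v["pos"]) - 1, stop=int(v["pos"]),
                alleles=(v["ref"], v["alt"]), id=v["id"],
            )
            for i, d in enumerate(genotypes.donors):
                rec.samples[str(d)]["GT"] = _GT_CODES[int(round(genotypes.dosage[i, j]))]
            vcf.write(rec)


def write_counts(adata: ad.AnnData, prefix) -> None:
    """Counts as Matrix Market plus cell/gene metadata TSVs (prefix.mtx/.cells.tsv/.genes.tsv)."""
    prefix = Path(prefix)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), X)
    adata.obs.to_csv(prefix.with_suffix(".cells.tsv"), sep="\t")
    adata.var.to_csv(prefix.with_suffix(".genes.tsv"), sep="\t")


def read_counts(prefix) -> ad.AnnData:
    prefix = Path(prefix)
    X = sparse.csr_matrix(spio.mmread(str(prefix.with_suffix(".mtx"))))
    obs = pd.read_csv(prefix.with_suffix(".cells.tsv"), sep="\t", index_col=0)
    var = pd.read_csv(prefix.with_suffix(".genes.tsv"), sep="\t", index_col=0)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_tracks(track: AnnotationTrack, prefix) -> None:
    """Intervals and LD blocks as BED files (prefix.annotations.bed / prefix.ldblocks.bed)."""
    prefix = Path(prefix)
    ann = track.intervals[["chrom", "start", "end", "cls"]]
    ann.to_csv(prefix.parent / (prefix.name + ".annotations.bed"), sep="\t", index=False, header=False)
    blk = track.ld_blocks[["chrom", "start", "end", "block"]]
    blk.to_csv(prefix.parent / (prefix.name + ".ldblocks.bed"), sep="\t", index=False, header=False)


def read_tracks(prefix) -> AnnotationTrack:
    prefix = Path(prefix)
    ann = pd.read_csv(
        prefix.parent / (prefix.name + ".annotations.bed"), sep="\t",
        names=["chrom", "start", "end", "cls"],
    )
    blk = pd.read_csv(
        prefix.parent / (prefix.name + ".ldblocks.bed"), sep="\t",
        names=["chrom", "start", "end", "block"],
    )
    return AnnotationTrack(intervals=ann, ld_blocks=blk)


def write_gwas(gwas: GwasSumstats, path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False)


def read_gwas(path, trait: str = "trait") -> GwasSumstats:
    return GwasSumstats(table=pd.read_csv(path, sep="\t"), trait=trait)


def write_truth(truth: TruthLedger, prefix) -> None:
    prefix = Path(prefix)
    truth.genes.to_csv(prefix.parent / (prefix.name + ".genes.tsv"), sep="\t", index=False)
    eq = truth.eqtls.copy()
    if len(eq):
        eq["annotations"] = eq["annotations"].map(lambda t: ",".join(t))
    eq.to_csv(prefix.parent / (prefix.name + ".eqtls.tsv"), sep="\t", index=False)
    truth.ieqtls.to_csv(prefix.parent / (prefix.name + ".ieqtls.tsv"), sep="\t", index=False)
    truth.gwas.to_csv(prefix.parent / (prefix.name + ".gwas.tsv"), sep="\t", index=False)
    with open(prefix.parent / (prefix.name + ".seeds.json"), "w") as fh:
        json.dump({k: int(v) for k, v in truth.seeds.items()}, fh)
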