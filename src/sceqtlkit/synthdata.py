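"""Synthetic cohort generator with a ground-truth ledger.

Generates LD-structured hard-call genotypes, single cells whose counts carry
planted cis-regulatory effects active at chosen cellular resolutions, GWAS
summary statistics from an independently drawn cohort, and promoter/enhancer
annotation tracks with LD-block tiling.  Every draw flows from one seeded
`numpy.random.Generator` per operation, so identical seeds give identical
outputs.

The count model is deliberately simple: per-cell counts are Poisson around a
donor-level mean whose natural-log shift is ``beta * dosage`` in the active
annotations only, plus a donor-level Gaussian noise term shared by all of the
donor's cells.  This preserves exactly the mean structure the pseudobulk
pipeline estimates while avoiding untestable dispersion knobs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .datatypes import (
    RESOLUTIONS,
    SITES,
    GenotypeMatrix,
    GwasSumstats,
    AnnotationTrack,
    TruthLedger,
)

__all__ = [
    "simulate_genotypes",
    "make_gene_table",
    "plant_eqtl",
    "simulate_cells",
    "simulate_gwas",
    "simulate_tracks",
]


def simulate_genotypes(
    n_donors: int,
    n_variants: int,
    block_size: int = 10,
    maf_range: tuple = (0.05, 0.5),
    seed: int = 0,
    chrom: str = "chr1",
    start_pos: int = 1_000_000,
    spacing_bp: int = 5_000,
    ld_rho: float = 0.9,
) -> GenotypeMatrix:
    """Draw hard-call dosages from block-correlated haplotypes under HWE.

    Haplotype alleles are thresholded latent Gaussians that share a common
    factor within each LD block (latent correlation ``ld_rho``), so pairwise
    r-squared is elevated within blocks and near zero across blocks.
    Variants are placed every ``spacing_bp`` bp on one chromosome.
    """
    if n_donors < 2 or n_variants < 1 or block_size < 1:
        raise ValueError("n_donors >= 2, n_variants >= 1 and block_size >= 1 required")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")

    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    block = np.arange(n_variants) // block_size
    n_hap = 2 * n_donors
    n_blocks = block.max() + 1

    shared = rng.standard_normal((n_hap, n_blocks))
    noise = rng.standard_normal((n_hap, n_variants))
    z = np.sqrt(ld_rho) * shared[:, block] + np.sqrt(1.0 - ld_rho) * noise
    haplotypes = (z < stats.norm.ppf(mafs)).astype(np.int8)
    dosage = haplotypes[0::2] + haplotypes[1::2]

    pos = start_pos + spacing_bp * np.arange(n_variants)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "id": [f"{chrom}_{p}_A_G" for p in pos],
        }
    )
    donors = [f"D{i:04d}" for i in range(n_donors)]
    sim_params = {
        "mafs": mafs,
        "block": block,
        "ld_rho": ld_rho,
        "seed": seed,
    }
    return GenotypeMatrix(donors=donors, variants=variants, dosage=dosage.astype(float), sim_params=sim_params)


def make_gene_table(
    n_genes: int,
    chrom: str = "chr1",
    tss_start: int = 1_050_000,
    tss_spacing: int = 50_000,
    base_mean_range: tuple = (1.0, 5.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Catalogue of simulated gene models: TSS position and baseline mean count per cell."""
    rng = np.random.default_rng(seed)
    tss = tss_start + tss_spacing * np.arange(n_genes)
    return pd.DataFrame(
        {
            "gene": [f"GENE{i:04d}" for i in range(n_genes)],
            "chrom": chrom,
            "tss": tss,
            "strand": "+",
            "base_mean": rng.uniform(*base_mean_range, size=n_genes),
        }
    )


def plant_eqtl(
    truth: TruthLedger,
    hierarchy: Mapping[str, str],
    gene: str,
    variant: str,
    beta: float,
    resolution: str,
    annotation: Optional[str] = None,
    placement: str = "neither",
) -> None:
    """Register a planted cis-eQTL, expanding its active annotation (cell-type) set.

    ``resolution='ubiquitous'`` activates the effect in every cell type,
    ``'population'`` in the cell types of one major population (``annotation``),
    ``'cell_type'`` in a single cell type.
    """
    if resolution == "ubiquitous":
        active = tuple(sorted(hierarchy))
    elif resolution == "population":
        active = tuple(sorted(ct for ct, pop in hierarchy.items() if pop == annotation))
        if not active:
            raise ValueError(f"no cell types in population {annotation!r}")
    elif resolution == "cell_type":
        if annotation not in hierarchy:
            raise ValueError(f"unknown cell type {annotation!r}")
        active = (annotation,)
    else:
        raise ValueError(f"unknown resolution class {resolution!r}")
    truth.eqtls.loc[len(truth.eqtls)] = {
        "gene": gene,
        "variant": variant,
        "beta": float(beta),
        "annotations": active,
        "resolution": resolution,
        "placement": placement,
    }


_IVAR_NAMES = ("sex", "age_bin", "disease", "smoking", "inflammation")


def _draw_donor_metadata(donors: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    """Donor-level interaction variables: sex, 5-year age bins, disease, smoking, inflammation."""
    n = len(donors)
    disease = rng.choice(["healthy", "CD"], size=n, p=[0.7, 0.3])
    inflammation = np.where(
        disease == "CD", rng.poisson(6.0, size=n), rng.poisson(0.5, size=n)
    )
    return pd.DataFrame(
        {
            "donor": donors,
            "sex": rng.choice(["F", "M"], size=n),
            "age_bin": rng.integers(4, 16, size=n) * 5,  # bin lower bounds, 20..75
            "disease": disease,
            "smoking": rng.choice(["never", "ever"], size=n, p=[0.6, 0.4]),
            "inflammation": inflammation,
        }
    ).set_index("donor")


def encode_ivar(values: pd.Series, name: str) -> np.ndarray:
    """Numeric encoding of an interaction variable (binary 0/1 or ordered integer)."""
    if name == "sex":
        return (values == "M").to_numpy(float)
    if name == "disease":
        return (values == "CD").to_numpy(float)
    if name == "smoking":
        return (values == "ever").to_numpy(float)
    return values.to_numpy(float)


def simulate_cells(
    genotypes: GenotypeMatrix,
    hierarchy: Mapping[str, str],
    cells_per_donor_per_type: int,
    truth: TruthLedger,
    noise_sd: float = 0.3,
    seed: int = 0,
    sites: Sequence[str] = SITES,
    donor_meta: Optional[pd.DataFrame] = None,
) -> ad.AnnData:
    """Draw per-cell Poisson counts around donor means carrying the planted effects.

    Every (donor, cell type) pair receives exactly ``cells_per_donor_per_type``
    cells, assigned to ``sites`` round-robin.  The ln-scale donor mean of a gene
    is its baseline plus ``beta * dosage`` for planted eQTLs whose active
    annotation set contains the cell's type, plus ``beta * dosage * I`` for
    planted interaction effects (I standardized across donors), plus a donor-level
    N(0, noise_sd) term shared across the donor's cells.
    """
    if not hierarchy:
        raise ValueError("hierarchy must map at least one cell type")
    if cells_per_donor_per_type < 1:
        raise ValueError("cells_per_donor_per_type must be positive")
    truth.validate_against(genotypes)
    unknown_genes = set(truth.eqtls["gene"]) | set(truth.ieqtls["gene"])
    unknown_genes -= set(truth.genes["gene"])
    if unknown_genes:
        raise ValueError(f"planted genes absent from gene table: {sorted(unknown_genes)}")

    rng = np.random.default_rng(seed)
    donors = list(genotypes.donors)
    genes = truth.genes.reset_index(drop=True)
    n_genes = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes["gene"])}
    cell_types = sorted(hierarchy)

    if donor_meta is None:
        donor_meta = _draw_donor_metadata(donors, rng)

    # ln-scale donor x gene shifts per cell type: baseline + eQTL + ieQTL + donor noise
    base_ln = np.log(genes["base_mean"].to_numpy())
    donor_noise = rng.normal(0.0, noise_sd, size=(len(donors), n_genes))

    shift_common = np.tile(base_ln, (len(donors), 1)) + donor_noise
    for _, row in truth.ieqtls.iterrows():
        g = gene_idx[row["gene"]]
        dos = genotypes.column(row["variant"])
        ival = encode_ivar(donor_meta[row["ivar"]], row["ivar"])
        isd = ival.std()
        istd = (ival - ival.mean()) / (isd if isd > 0 else 1.0)
        shift_common[:, g] += row["beta"] * dos * istd

    per_type_shift = {}
    for ct in cell_types:
        shift = shift_common.copy()
        for _, row in truth.eqtls.iterrows():
            if ct in row["annotations"]:
                g = gene_idx[row["gene"]]
                shift[:, g] += row["beta"] * genotypes.column(row["variant"])
        per_type_shift[ct] = shift

    blocks = []
    obs_rows = []
    site_cycle = list(sites)
    for d_i, donor in enumerate(donors):
        for ct in cell_types:
            lam = np.exp(per_type_shift[ct][d_i])
            counts = rng.poisson(lam, size=(cells_per_donor_per_type, n_genes))
            blocks.append(counts)
            for c in range(cells_per_donor_per_type):
                obs_rows.append(
                    {
                        "donor": donor,
                        "site": site_cycle[c % len(site_cycle)],
                        "cell_type": ct,
                        "major_population": hierarchy[ct],
                        "lineage": hierarchy[ct],
                    }
                )

    counts = sparse.csr_matrix(np.vstack(blocks))
    obs = pd.DataFrame(obs_rows)
    obs = obs.join(donor_meta, on="donor")
    obs.index = [f"cell{i:07d}" for i in range(len(obs))]
    var = genes.set_index("gene")[["chrom", "tss", "strand"]]
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["hierarchy"] = dict(hierarchy)
    truth.seeds["cells"] = seed
    return adata


def simulate_gwas(
    genotypes: GenotypeMatrix,
    causal: Mapping[str, float],
    n_gwas: int,
    seed: int = 0,
    trait: str = "trait",
) -> GwasSumstats:
    """Marginal GWAS summary statistics from an independently redrawn cohort.

    A fresh cohort of ``n_gwas`` individuals is simulated with the same
    per-variant MAFs and LD-block design as ``genotypes`` (two-sample
    design), a quantitative phenotype is built from the causal map plus unit
    Gaussian noise, and each variant's simple-regression beta/se/p is
    reported.  Variants in LD with a causal variant show attenuated signal.
    """
    if n_gwas < 10:
        raise ValueError("n_gwas must be at least 10")
    missing = set(causal) - set(genotypes.variants["id"])
    if missing:
        raise ValueError(f"causal variants absent from genotypes: {sorted(missing)}")
    if genotypes.sim_params is None:
        raise ValueError("genotypes must carry generator design (sim_params) to redraw a cohort")

    rng = np.random.default_rng(seed)
    p = genotypes.sim_params
    mafs, block, rho = p["mafs"], p["block"], p["ld_rho"]
    n_hap = 2 * n_gwas
    shared = rng.standard_normal((n_hap, block.max() + 1))
    noise = rng.standard_normal((n_hap, len(mafs)))
    z = np.sqrt(rho) * shared[:, block] + np.sqrt(1.0 - rho) * noise
    hap = (z < stats.norm.ppf(mafs)).astype(np.int8)
    G = (hap[0::2] + hap[1::2]).astype(float)

    y = rng.standard_normal(n_gwas)
    var_ids = list(genotypes.variants["id"])
    col = {v: i for i, v in enumerate(var_ids)}
    for v, eff in causal.items():
        y = y + eff * G[:, col[v]]

    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ss_g = (Gc**2).sum(axis=0)
    ss_g = np.where(ss_g > 0, ss_g, np.nan)
    beta = Gc.T @ yc / ss_g
    resid_ss = (yc**2).sum() - beta**2 * ss_g
    se = np.sqrt(resid_ss / (n_gwas - 2) / ss_g)
    zstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))

    table = genotypes.variants.copy()
    table["beta"] = beta
    table["se"] = se
    table["p"] = np.clip(pvals, 1e-300, 1.0)
    table["n"] = n_gwas
    table = table.dropna(subset=["beta", "se"]).reset_index(drop=True)
    return GwasSumstats(table=table, trait=trait)


def simulate_tracks(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window_bp: int = 1_000,
    enhancer_variants: Iterable[str] = (),
    block_size_bp: int = 100_000,
    enhancer_halfwidth_bp: int = 250,
) -> AnnotationTrack:
    """Place promoter windows around TSSs, enhancers over flagged variants, and tile LD blocks.

    BED conventions throughout: 0-based half-open intervals.  LD blocks tile
    each chromosome gaplessly so every variant falls in exactly one block.
    """
    if promoter_window_bp < 1 or block_size_bp < 1 or enhancer_halfwidth_bp < 1:
        raise ValueError("window sizes must be positive")

    rows = []
    for _, g in genes.iterrows():
        rows.append(
            {
                "chrom": g["chrom"],
                "start": max(0, int(g["tss"]) - promoter_window_bp - 1),
                "end": int(g["tss"]) + promoter_window_bp,
                "cls": "promoter",
            }
        )
    flagged = set(enhancer_variants)
    vsub = variants[variants["id"].isin(flagged)]
    for _, v in vsub.iterrows():
        rows.append(
            {
                "chrom": v["chrom"],
                "start": max(0, int(v["pos"]) - enhancer_halfwidth_bp - 1),
                "end": int(v["pos"]) + enhancer_halfwidth_bp,
                "cls": "enhancer",
            }
        )
    intervals = _merge_by_class(pd.DataFrame(rows, columns=["chrom", "start", "end", "cls"]))

    blocks = []
    bid = 0
    for chrom, sub in variants.groupby("chrom", sort=False):
        last = int(sub["pos"].max())
        n_blocks = last // block_size_bp + 1
        for k in range(n_blocks):
            blocks.append(
                {"chrom": chrom, "start": k * block_size_bp, "end": (k + 1) * block_size_bp, "block": bid}
            )
            bid += 1
    return AnnotationTrack(intervals=intervals, ld_blocks=pd.DataFrame(blocks))


def _merge_by_class(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals within each (class, chromosome)."""
    merged = []
    for (cls, chrom), sub in intervals.groupby(["cls", "chrom"], sort=False):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for _, r in sub.iterrows():
            if cur_s is None:
                cur_s, cur_e = r["start"], r["end"]
            elif r["start"] <= cur_e:
                cur_e = max(cur_e, r["end"])
            else:
                merged.append({"chrom": chrom, "start": cur_s, "end": cur_e, "cls": cls})
                cur_s, cur_e = r["start"], r["end"]
        if cur_s is not None:
            merged.append({"chrom": chrom, "start": cur_s, "end": cur_e, "cls": cls})
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "cls"])
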