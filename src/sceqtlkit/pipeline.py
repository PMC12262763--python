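"""End-to-end orchestration from a single config.

``run_all`` executes simulate -> qc -> pseudobulk -> map-eqtl -> map-ieqtl ->
clump -> coloc -> nominate -> enrich, writing each stage's text outputs into a
run directory and recording parameters, timings and sha256 checksums in a
manifest.  Every stage's randomness flows from the config seed, so a rerun
with the same config produces identical checksums.  Disabling a stage makes
any downstream stage that consumes its outputs refuse to run.

All scientific thresholds live in :class:`RunConfig` with the pipeline's
standard defaults (MAF 0.05 / interaction 0.1, cis window 1 Mb, coloc window
2 Mb, FDR 0.05, clump r2 0.5, PP4 0.75, coloc priors 1e-4/1e-4/1e-5, 500 kb
locus assignment, HLA chr6:28,510,120-33,480,577); overrides are logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cis_eqtl, coloc, effector, enrichment, io, pseudobulk, qc, signals, synthdata
from .datatypes import RESOLUTIONS, TruthLedger
from .interaction import (
    InteractionVariable,
    interaction_permutation_pvalue,
    prepare_interaction_covariates,
)
from .synthdata import encode_ivar

logger = logging.getLogger("sceqtlkit")

ALL_STAGES = (
    "simulate", "qc", "pseudobulk", "map-eqtl", "map-ieqtl",
    "clump", "coloc", "nominate", "enrich",
)

DEFAULT_HIERARCHY = {
    "Tcm": "Tcell", "Tem": "Tcell",
    "NaiveB": "Bcell", "MemoryB": "Bcell",
    "Monocyte": "Myeloid", "Macrophage": "Myeloid",
}


@dataclass
class RunConfig:
    """All tunables of a run; defaults are the pipeline's standard thresholds."""

    seed: int = 0
    stages: tuple = ALL_STAGES

    # synthetic cohort
    n_donors: int = 120
    n_variants: int = 240
    block_size: int = 8
    spacing_bp: int = 5_000
    maf_range: tuple = (0.1, 0.5)
    # enough genes at these depths for cells to clear the absolute QC
    # thresholds (>= 250 genes expressed, >= 500 counts per cell)
    n_genes: int = 300
    n_map_genes: int = 30
    tss_spacing: int = 3_500
    cells_per_donor_per_type: int = 18
    noise_sd: float = 0.3
    n_gwas: int = 2_000
    hierarchy: dict = field(default_factory=lambda: dict(DEFAULT_HIERARCHY))
    planted_beta: float = 0.6
    gwas_effect: float = 0.5

    # mapping thresholds
    min_maf: float = 0.05
    interaction_min_maf: float = 0.1
    cis_window_bp: int = 1_000_000
    coloc_window_bp: int = 2_000_000
    fdr: float = 0.05
    clump_r2: float = 0.5
    clump_window_bp: int = 1_000_000
    pp4_cut: float = 0.75
    coloc_priors: dict = field(default_factory=lambda: dict(coloc.DEFAULT_PRIORS))
    gwas_p_cut: float = 5e-5
    assign_bp: int = 500_000
    hla: tuple = coloc.HLA_REGION
    n_genotype_pcs: int = 5
    n_expression_pcs: int = 2
    select_pcs: bool = False
    pc_grid: tuple = (2, 4, 6)
    n_perm: int = 200
    beta_approx: bool = True
    pc_r_cut: float = 0.25
    interaction_vars: tuple = ("inflammation",)
    n_boot: int = 1000
    promoter_window_bp: int = 1_000
    ld_block_bp: int = 50_000

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        defaults = RunConfig()
        unknown = set(data) - {f.name for f in dataclasses.fields(RunConfig)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in data.items():
            if value != getattr(defaults, key):
                logger.info("config override: %s = %r", key, value)
        for key in ("stages", "maf_range", "pc_grid", "interaction_vars", "hla"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest_entry: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest_entry[path.name] = _sha256(path)


def run_all(config: RunConfig, outdir) -> dict:
    """Run the enabled stages in order; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(config), "stages": {}}
    state: dict = {}
    enabled = list(config.stages)
    for stage in enabled:
        if stage not in ALL_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    for stage in ALL_STAGES:
        if stage not in enabled:
            continue
        t0 = time.time()
        entry: dict = {"outputs": {}}
        logger.info("stage %s starting", stage)
        try:
            _STAGE_FUNCS[stage](config, state, outdir, entry["outputs"])
        except KeyError as exc:
            raise RuntimeError(
                f"stage {stage!r} requires outputs of a disabled or failed stage: {exc}"
            ) from exc
        entry["elapsed_s"] = round(time.time() - t0, 3)
        manifest["stages"][stage] = entry
        logger.info("stage %s done in %.1fs", stage, entry["elapsed_s"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    state["manifest"] = manifest
    return state


def _stage_simulate(cfg: RunConfig, state: dict, outdir: Path, outputs: dict) -> None:
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    genotypes = synthdata.simulate_genotypes(
        cfg.n_donors, cfg.n_variants, block_size=cfg.block_size,
        maf_range=cfg.maf_range, seed=int(seeds[0]), spacing_bp=cfg.spacing_bp,
    )
    genes = synthdata.make_gene_table(
        cfg.n_genes, tss_spacing=cfg.tss_spacing, seed=int(seeds[1]),
    )
    truth = TruthLedger.empty(genes)
    hier = cfg.hierarchy
    pops = sorted(set(hier.values()))
    cts = sorted(hier)
    v = genotypes.variants

    def nearest_variant(tss, offset=0):
        return v.iloc[(v["pos"] - (tss + offset)).abs().argmin()]["id"]

    # plant one eQTL per resolution class plus an interaction effect
    g = genes["gene"]
    synthdata.plant_eqtl(truth, hier, g[0], nearest_variant(genes["tss"][0]),
                         cfg.planted_beta, "ubiquitous", placement="promoter")
    synthdata.plant_eqtl(truth, hier, g[2], nearest_variant(genes["tss"][2], 20_000),
                         cfg.planted_beta, "population", annotation=pops[0])
    synthdata.plant_eqtl(truth, hier, g[4], nearest_variant(genes["tss"][4], 120_000),
                         cfg.planted_beta * 1.5, "cell_type", annotation=cts[0],
                         placement="enhancer")
    truth.ieqtls.loc[0] = {
        "gene": g[6], "variant": nearest_variant(genes["tss"][6]),
        "ivar": "inflammation", "beta": cfg.planted_beta,
    }
    shared = truth.eqtls["variant"].iloc[0]
    truth.gwas.loc[0] = {"variant": shared, "beta": cfg.gwas_effect, "shared_with_eqtl": True}

    cells = synthdata.simulate_cells(
        genotypes, hier, cfg.cells_per_donor_per_type, truth,
        noise_sd=cfg.noise_sd, seed=int(seeds[2]),
    )
    gwas = synthdata.simulate_gwas(
        genotypes, dict(zip(truth.gwas["variant"], truth.gwas["beta"])),
        cfg.n_gwas, seed=int(seeds[3]), trait="IBD",
    )
    enh = truth.eqtls.loc[truth.eqtls["placement"] == "enhancer", "variant"]
    tracks = synthdata.simulate_tracks(
        genotypes.variants, genes, promoter_window_bp=cfg.promoter_window_bp,
        enhancer_variants=enh, block_size_bp=cfg.ld_block_bp,
    )

    io.write_dosage_tsv(genotypes, outdir / "genotypes.tsv")
    io.write_vcf(genotypes, outdir / "genotypes.vcf")
    io.write_counts(cells, outdir / "counts")
    io.write_gwas(gwas, outdir / "gwas.tsv")
    io.write_tracks(tracks, outdir / "tracks")
    io.write_truth(truth, outdir / "truth")
    for name in ("genotypes.tsv", "genotypes.vcf", "counts.mtx", "gwas.tsv",
                 "tracks.annotations.bed", "truth.eqtls.tsv"):
        outputs[name] = _sha256(outdir / name)
    state.update(genotypes=genotypes, cells=cells, gwas=gwas, tracks=tracks, truth=truth)


def _stage_qc(cfg: RunConfig, state: dict, outdir: Path, outputs: dict) -> None:
    cells, summary = qc.apply_qc(state["cells"])
    _write(summary, outdir / "qc_summary.tsv", outputs)
    kept = set(cells.obs_names)
    mask = pd.DataFrame(
        {"cell": state["cells"].obs_names,
         "keep": [c in kept for c in state["cells"].obs_names]}
    )
    _write(mask, outdir / "qc_keep_mask.tsv", outputs)
    state["cells_qc"] = cells


def _stage_pseudobulk(cfg: RunConfig, state: dict, outdir: Path, outputs: dict) -> None:
    contexts = pseudobulk.build_contexts(state["cells_qc"])
    rows = [
        {
            "context_id": cid,
            "resolution": pb.context.resolution,
            "annotation": pb.context.annotation,
            "site_mode": pb.context.site_mode,
            "n_donors": len(pb.donors),
            "n_genes": len(pb.genes),
        }
        for cid, pb in contexts.items()
    ]
    _write(pd.DataFrame(rows), outdir / "context_manifest.tsv", outputs)
    state["contexts"] = contexts
    # raw (pre-INT) pseudobulk medians feed effector eligibility later
    raw = pseudobulk.build_contexts(state["cells_qc"], apply_int=False)
    state["contexts_raw"] = raw


def _map_gene_set(cfg: RunConfig, truth: TruthLedger) -> pd.DataFrame:
    """Genes taken through eQTL mapping: every planted gene plus leading nulls."""
    planted = set(truth.eqtls["gene"]) | set(truth.ieqtls["gene"])
    head = list(truth.genes["gene"].head(cfg.n_map_genes))
    wanted = sorted(planted | set(head))
    return truth.genes[truth.genes["gene"].isin(wanted)].reset_index(drop=True)


def _stage_map_eqtl(cfg: RunConfig, state: dict, outdir: Path, outputs: dict) -> None:
    genotypes = state["genotypes"]
    genes = _map_gene_set(cfg, state["truth"])
    gt_pcs = cis_eqtl.genotype_pcs(genotypes, cfg.n_genotype_pcs)
    donor_index = {d: i for i, d in enumerate(genotypes.donors)}
    egene_tables, egenes_all, nominal_tables = [], [], {}
    for cid, pb in state["contexts"].items():
        rows = [donor_index[d] for d in pb.donors]
        if cfg.select_pcs:
            k, _ = cis_eqtl.select_expression_pcs(
                pb, genotypes, gt_pcs[rows], genes, grid=cfg.pc_grid,
                fdr=cfg.fdr, n_perm=cfg.n_perm, seed=cfg.seed,
            )
        else:
            k = cfg.n_expression_pcs
        cov = cis_eqtl.CovariateSet(gt_pcs[rows], cis_eqtl.expression_pcs(pb, k))
        results = []
        for _, gi in genes.iterrows():
            if gi["gene"] not in pb.expr.columns:
                continue
            cand = cis_eqtl.cis_candidates(
                gi["tss"], genotypes, gi["chrom"], donors=pb.donors,
                window_bp=cfg.cis_window_bp, min_maf=cfg.min_maf,
            )
            if len(cand) == 0:
                continue
            nominal_tables[(cid, gi["gene"])] = cis_eqtl.nominal_scan(
                pb, genotypes, cov, gi["gene"], candidates=cand,
            )
            results.append(
                cis_eqtl.permutation_scan(
                    gi["gene"], pb, genotypes, cov, n_perm=cfg.n_perm,
                    seed=cfg.seed, context=cid, candidates=cand,
                    beta_approx=cfg.beta_approx,
                )
            )
        table = cis_eqtl.call_egenes_fdr(results, fdr=cfg.fdr)
        egene_tables.append(table)
        egenes_all.extend(results)
        state.setdefault("covariates", {})[cid] = cov
    egenes = pd.concat(egene_tables, ignore_index=True) if egene_tables else pd.DataFrame()
    _write(egenes, outdir / "egenes.tsv", outputs)
    state["egenes"] = egenes
    state["egene_results"] = egenes_all
    state["nominal_tables"] = nominal_tables

    # forward conditional signals for eGenes
    gene_info = genes.set_index("gene")
    sig_rows = []
    for res in egenes_all:
        if res.fdr_q is None or res.fdr_q > cfg.fdr:
            continue
        pb = state["contexts"][res.context]
        thr = max(cfg.fdr * max((state["egenes"]["q"] <= cfg.fdr).sum(), 1)
                  / max(len(state["egenes"]), 1), 1.5 / (cfg.n_perm + 1))
        sigs = cis_eqtl.forward_conditional(
            res, pb, state["genotypes"], state["covariates"][res.context],
            alpha_stop=thr, gene_tss=int(gene_info.loc[res.gene, "tss"]),
            chrom=str(gene_info.loc[res.gene, "chrom"]),
            n_perm=cfg.n_perm, seed=cfg.seed,
        )
        for s in sigs:
            sig_rows.append(dataclasses.asdict(s))
    _write(pd.DataFrame(sig_rows), outdir / "conditional_signals.tsv", outputs)


def _stage_map_ieqtl(cfg: RunConfig, state: dict, outdir: Path, outputs: dict) -> None:
    genotypes = state["genotypes"]
    cells = state["cells_qc"]
    genes = state["truth"].genes.set_index("gene")
    rows_out = []
    # interaction mapping runs in the all-cells cross-site context
    cid = "all_cells:ALL:cross_site"
    pb = state["contexts"][cid]
    donor_meta = cells.obs.drop_duplicates("donor").set_index("donor").loc[pb.donors]
    cov = state["covariates"][cid]
    for name in cfg.interaction_vars:
        ivar = InteractionVariable(name, encode_ivar(donor_meta[name], name))
        pcs, dropped = prepare_interaction_covariates(
            cov.expression_pcs, ivar, r_cut=cfg.pc_r_cut,
        )
        red = cis_eqtl.CovariateSet(cov.genotype_pcs, pcs)
        test_genes = set(state["truth"].ieqtls["gene"]) | set(genes.index[:2])
        for gene in sorted(test_genes):
            if gene not in pb.expr.columns:
                continue
            try:
                p_gene, obs = interaction_permutation_pvalue(
                    pb, genotypes, red, ivar, gene, n_perm=min(cfg.n_perm, 100),
                    seed=cfg.seed, gene_tss=int(genes.loc[gene, "tss"]),
                    chrom=str(genes.loc[gene, "chrom"]),
                )
            except ValueError:
                continue
            best = obs.sort_values("p_gxi").iloc[0]
            rows_out.append(
                {
                    "gene": gene, "ivar": name, "variant": best["variant"],
                    "beta_gxi": best["beta_gxi"], "se_gxi": best["se_gxi"],
                    "p_gxi": best["p_gxi"], "p_perm": p_gene,
                    "n_pcs_dropped": len(dropped),
                }
            )
    table = pd.DataFrame(rows_out)
    if len(table):
        from statsmodels.stats.multitest import multipletests

        table["q"] = multipletests(table["p_perm"], method="fdr_bh")[1]
    _write(table, outdir / "iegenes.tsv", outputs)
    state["iegenes"] = table


def _stage_clump(cfg: RunConfig, state: dict, outdir: Path, outputs: dict) -> None:
    genotypes = state["genotypes"]
    egenes = state["egenes"]
    positions = dict(zip(genotypes.variants["id"], genotypes.variants["pos"]))
    ctx_meta = {
        cid: (pb.context.resolution, pb.context.site_mode)
        for cid, pb in state["contexts"].items()
    }
    r2 = signals.in_sample_r2(genotypes)
    groups = []
    hits = egenes[egenes["is_egene"]]
    for gene, sub in hits.groupby("gene"):
        leads = sub.rename(columns={"lead_variant": "variant", "p_perm": "p"})[
            ["context", "gene", "variant", "p"]
        ].copy()
        leads["resolution"] = leads["context"].map(lambda c: ctx_meta[c][0])
        leads["site_mode"] = leads["context"].map(lambda c: ctx_meta[c][1])
        gene_groups = signals.clump_leads(
            leads.reset_index(drop=True), r2, positions,
            r2_cut=cfg.clump_r2, window_bp=cfg.clump_window_bp,
        )
        for gr in gene_groups:
            signals.attribute_resolution(gr)
            gr.site_class = signals.classify_site_sharing(gr.members["site_mode"])
        groups.extend(gene_groups)
    state["signal_groups"] = groups
    _write(signals.signals_table(groups), outdir / "signals.tsv", outputs)


def _stage_coloc(cfg: RunConfig, state: dict, outdir: Path, outputs: dict) -> None:
    genotypes = state["genotypes"]
    # known-locus table anchored at the simulated causal GWAS variants
    truth = state["truth"]
    vpos = genotypes.variants.set_index("id")
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{i + 1}" for i in range(len(truth.gwas))],
            "chrom": [vpos.loc[v, "chrom"] for v in truth.gwas["variant"]],
            "pos": [int(vpos.loc[v, "pos"]) for v in truth.gwas["variant"]],
        }
    )
    results = coloc.scan_gwas_coloc(
        state["egene_results"], state["nominal_tables"], state["gwas"],
        genotypes.variants, window_bp=cfg.coloc_window_bp,
        gwas_p_cut=cfg.gwas_p_cut, egene_fdr_cut=cfg.fdr,
        priors=cfg.coloc_priors,
    )
    results = coloc.postfilter_and_assign(
        results, loci=loci, hla=cfg.hla, assign_bp=cfg.assign_bp, pp4_cut=cfg.pp4_cut,
    )
    state["coloc_results"] = results
    _write(coloc.coloc_table(results), outdir / "coloc.tsv", outputs)


def _stage_nominate(cfg: RunConfig, state: dict, outdir: Path, outputs: dict) -> None:
    genotypes = state["genotypes"]
    rows = []
    nominations = []
    for i, r in enumerate(state["coloc_results"]):
        if not r.colocalised:
            continue
        nominal_p, median_expr = {}, {}
        for cid, pb in state["contexts"].items():
            tab = state["nominal_tables"].get((cid, r.egene))
            if tab is None:
                continue
            hit = tab[tab["variant"] == r.lead_eqtl]
            if len(hit):
                nominal_p[cid] = float(hit["p"].iloc[0])
            raw = state["contexts_raw"].get(cid)
            if raw is not None and r.egene in raw.expr.columns:
                median_expr[cid] = float(raw.expr[r.egene].median())
        nom = effector.nominate_annotation(
            f"coloc{i}", r.lead_eqtl, state["contexts"], genotypes, r.egene,
            nominal_p, median_expr,
        )
        nominations.append(nom)
        for ann in nom.r2.index:
            rows.append(
                {
                    "coloc_id": nom.coloc_id, "egene": r.egene, "annotation": ann,
                    "r2": nom.r2[ann], "best": ann in nom.best,
                }
            )
    state["nominations"] = nominations
    _write(pd.DataFrame(rows), outdir / "effector_nominations.tsv", outputs)

    # per-resolution odds ratios: eGene attribution vs effector attribution
    egene_counts = {r: 0 for r in RESOLUTIONS}
    effector_counts = {r: 0 for r in RESOLUTIONS}
    coloc_genes = {r.egene for r in state["coloc_results"] if r.colocalised}
    seen = set()
    for gr in state.get("signal_groups", []):
        if gr.gene in seen:
            continue
        seen.add(gr.gene)
        egene_counts[gr.min_resolution] += 1
        if gr.gene in coloc_genes:
            effector_counts[gr.min_resolution] += 1
    try:
        ors = effector.resolution_odds_ratio(egene_counts, effector_counts)
        _write(
            ors.rename("odds_ratio").reset_index().rename(columns={"index": "resolution"}),
            outdir / "resolution_odds_ratios.tsv", outputs,
        )
    except ValueError:
        logger.info("no colocalised effector genes; odds ratios skipped")


def _stage_enrich(cfg: RunConfig, state: dict, outdir: Path, outputs: dict) -> None:
    genotypes = state["genotypes"]
    vpos = genotypes.variants.set_index("id")
    sig_rows = []
    for gr in state.get("signal_groups", []):
        sig_rows.append(
            {
                "gene": gr.gene,
                "index_variant": gr.index_variant,
                "chrom": vpos.loc[gr.index_variant, "chrom"],
                "index_pos": int(vpos.loc[gr.index_variant, "pos"]),
                "min_resolution": gr.min_resolution,
            }
        )
    sig = pd.DataFrame(sig_rows)
    if sig.empty:
        logger.info("no signals to enrich")
        return
    stats_table = enrichment.tss_and_nearest_stats(sig, state["truth"].genes)
    _write(stats_table, outdir / "tss_stats.tsv", outputs)

    by_res = {
        res: sub.rename(columns={"index_pos": "pos"})[["chrom", "pos"]]
        for res, sub in sig.groupby("min_resolution")
    }
    rand = genotypes.variants[["chrom", "pos"]]
    result = enrichment.bootstrap_relative_enrichment(
        by_res, state["tracks"], rand, n_boot=cfg.n_boot, seed=cfg.seed,
    )
    out = result.fractions.copy()
    out["relative_enrichment"] = out["resolution"].map(result.point)
    out["ci_low"] = out["resolution"].map(result.ci_low)
    out["ci_high"] = out["resolution"].map(result.ci_high)
    _write(out, outdir / "enrichment.tsv", outputs)
    state["enrichment"] = result


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "pseudobulk": _stage_pseudobulk,
    "map-eqtl": _stage_map_eqtl,
    "map-ieqtl": _stage_map_ieqtl,
    "clump": _stage_clump,
    "coloc": _stage_coloc,
    "nominate": _stage_nominate,
    "enrich": _stage_enrich,
}
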