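"""Approximate-Bayes-factor colocalisation.

For each variant, the Wakefield approximate Bayes factor against the null is
computed from the estimated effect and its standard error with a Gaussian
effect prior N(0, W):

    lABF = 0.5 * [ ln(V / (V + W)) + z^2 * W / (V + W) ],   V = se^2, z = beta/se

Five hypotheses are weighed for a pair of traits over Q shared variants:
H0 no association, H1/H2 association in one trait only, H3 two distinct
causal variants, H4 one shared causal variant.  With prior per-variant
probabilities p1, p2 (single-trait) and p12 (shared), the unnormalised
weights are

    S0 = 1
    S1 = p1 * sum_i BF1_i
    S2 = p2 * sum_i BF2_i
    S3 = p1 * p2 * (sum_i BF1_i * sum_j BF2_j - sum_i BF1_i BF2_i)
    S4 = p12 * sum_i BF1_i BF2_i

normalised to the posteriors PP0..PP4; everything is evaluated in log space
(log-sum-exp) for stability.  Default priors p1 = p2 = 1e-4, p12 = 1e-5;
default effect-prior SDs 0.15 for a quantitative trait and 0.2 on the
log-odds scale for a case-control trait.  A colocalisation is called at
PP4 > 0.75; results whose lead GWAS variant falls in the HLA region
(chr6:28,510,120-33,480,577, GRCh38) are masked, and surviving calls are
assigned to the closest known disease locus within 500 kb.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cis_eqtl import EGeneResult
from .datatypes import ColocResult, GwasSumstats

__all__ = [
    "wakefield_labf",
    "coloc_abf",
    "harmonise",
    "scan_gwas_coloc",
    "postfilter_and_assign",
    "HLA_REGION",
]

HLA_REGION = ("chr6", 28_510_120, 33_480_577)

DEFAULT_PRIORS = {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5}
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_CASE_CONTROL = 0.20


def wakefield_labf(beta, se, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor for association from beta, se and a prior effect SD."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be non-negative")
    V = se**2
    W = prior_sd**2
    z = beta / se
    return 0.5 * (np.log(V / (V + W)) + z**2 * W / (V + W))


def coloc_abf(
    labf1: np.ndarray,
    labf2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> np.ndarray:
    """Five posteriors PP0..PP4 from two traits' per-variant log ABFs."""
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape:
        raise ValueError("traits must share one variant set")
    if labf1.size < 2:
        raise ValueError("need at least 2 shared variants")

    lsum1 = logsumexp(labf1)
    lsum2 = logsumexp(labf2)
    lsum12 = logsumexp(labf1 + labf2)

    lS0 = 0.0
    lS1 = np.log(p1) + lsum1
    lS2 = np.log(p2) + lsum2
    lS4 = np.log(p12) + lsum12
    # S3 = p1 p2 (sum1*sum2 - sum12); the bracket can underflow to <=0 numerically
    diff = lsum12 - (lsum1 + lsum2)
    if diff >= 0:
        if diff > 1e-12:
            warnings.warn("negative cross-term in H3 weight; clamped to 0")
        lS3 = -np.inf
    else:
        lS3 = np.log(p1) + np.log(p2) + lsum1 + lsum2 + np.log1p(-np.exp(diff))

    ls = np.array([lS0, lS1, lS2, lS3, lS4])
    pp = np.exp(ls - logsumexp(ls))
    return pp / pp.sum()


def harmonise(eqtl: pd.DataFrame, gwas: pd.DataFrame) -> pd.DataFrame:
    """Join eQTL and GWAS rows on (chrom, pos) with allele-flip sign correction.

    Both frames need chrom, pos, ref, alt, beta, se (shared column names are
    suffixed _eqtl/_gwas on the join).  A GWAS row whose ref/alt are swapped
    relative to the eQTL row has its beta negated; mismatched allele pairs
    are dropped.
    """
    merged = eqtl.merge(gwas, on=["chrom", "pos"], suffixes=("_eqtl", "_gwas"))
    same = (merged["ref_eqtl"] == merged["ref_gwas"]) & (merged["alt_eqtl"] == merged["alt_gwas"])
    flipped = (merged["ref_eqtl"] == merged["alt_gwas"]) & (merged["alt_eqtl"] == merged["ref_gwas"])
    merged = merged[same | flipped].copy()
    flip_rows = flipped[same | flipped]
    merged.loc[flip_rows, "beta_gwas"] = -merged.loc[flip_rows, "beta_gwas"]
    return merged.reset_index(drop=True)


def scan_gwas_coloc(
    egenes: Sequence[EGeneResult],
    nominal_tables: dict,
    gwas: GwasSumstats,
    variant_positions: pd.DataFrame,
    window_bp: int = 2_000_000,
    gwas_p_cut: float = 5e-5,
    egene_fdr_cut: float = 0.05,
    prior_sd_eqtl: float = PRIOR_SD_QUANTITATIVE,
    prior_sd_gwas: float = PRIOR_SD_QUANTITATIVE,
    priors: Optional[dict] = None,
    min_shared: int = 25,
) -> list[ColocResult]:
    """Colocalise every qualifying (eGene context, trait) pair.

    A pair is tested when the eGene's FDR q-value is below ``egene_fdr_cut``
    and the minimum GWAS p inside the 2 Mb window centred on the eQTL lead is
    below the suggestive threshold.  ``nominal_tables`` maps (context, gene)
    to the full nominal association table of that gene (the coloc input);
    ``variant_positions`` supplies chrom/pos/ref/alt per variant id.
    """
    priors = {**DEFAULT_PRIORS, **(priors or {})}
    vpos = variant_positions.set_index("id")
    results = []
    for eg in egenes:
        if eg.fdr_q is None or eg.fdr_q > egene_fdr_cut:
            continue
        lead = vpos.loc[eg.lead_variant]
        chrom, centre = lead["chrom"], int(lead["pos"])
        lo, hi = centre - window_bp // 2, centre + window_bp // 2

        nom = nominal_tables[(eg.context, eg.gene)].copy()
        nom = nom.join(vpos[["chrom", "pos", "ref", "alt"]], on="variant")
        nom = nom[(nom["chrom"] == chrom) & (nom["pos"] >= lo) & (nom["pos"] <= hi)]

        g = gwas.table
        g_win = g[(g["chrom"] == chrom) & (g["pos"] >= lo) & (g["pos"] <= hi)]
        if len(g_win) == 0 or g_win["p"].min() >= gwas_p_cut:
            continue

        merged = harmonise(
            nom[["chrom", "pos", "ref", "alt", "beta", "se", "variant"]],
            g_win[["chrom", "pos", "ref", "alt", "beta", "se", "id"]].rename(
                columns={"id": "variant_gwas"}
            ),
        )
        if len(merged) < min_shared:
            warnings.warn(
                f"{eg.gene} ({eg.context}) x {gwas.trait}: only {len(merged)} shared variants; skipped"
            )
            continue

        labf_eqtl = wakefield_labf(merged["beta_eqtl"], merged["se_eqtl"], prior_sd_eqtl)
        labf_gwas = wakefield_labf(merged["beta_gwas"], merged["se_gwas"], prior_sd_gwas)
        pp = coloc_abf(labf_eqtl, labf_gwas, **priors)
        gwas_lead_row = merged.iloc[int(np.argmax(labf_gwas))]
        results.append(
            ColocResult(
                egene=eg.gene,
                context=eg.context,
                trait=gwas.trait,
                window=(chrom, lo, hi),
                pp=pp,
                lead_eqtl=eg.lead_variant,
                lead_gwas=str(gwas_lead_row["variant_gwas"]),
                lead_gwas_pos=int(gwas_lead_row["pos"]),
                lead_gwas_chrom=str(gwas_lead_row["chrom"]),
                n_variants=len(merged),
            )
        )
    return results


def postfilter_and_assign(
    results: Sequence[ColocResult],
    loci: Optional[pd.DataFrame] = None,
    hla: tuple = HLA_REGION,
    assign_bp: int = 500_000,
    pp4_cut: float = 0.75,
) -> list[ColocResult]:
    """Call colocalisations, mask the HLA region, and assign known loci.

    ``loci`` has columns locus_id, chrom, pos (the locus anchor).  Returns
    the results with ``colocalised``/``hla_masked``/``locus_id`` set; HLA-masked
    results are excluded from the colocalised set but retained in the list.
    """
    hla_chrom, hla_lo, hla_hi = hla
    out = []
    for r in results:
        r.colocalised = bool(r.pp[4] > pp4_cut)
        in_hla = r.lead_gwas_chrom == hla_chrom and hla_lo <= r.lead_gwas_pos <= hla_hi
        r.hla_masked = in_hla
        if in_hla:
            r.colocalised = False
        if r.colocalised and loci is not None and len(loci):
            cand = loci[loci["chrom"] == r.lead_gwas_chrom].copy()
            if len(cand):
                cand["dist"] = (cand["pos"] - r.lead_gwas_pos).abs()
                cand = cand[cand["dist"] <= assign_bp]
                if len(cand):
                    cand = cand.sort_values(["dist", "locus_id"], kind="mergesort")
                    r.locus_id = str(cand["locus_id"].iloc[0])
        out.append(r)
    return out


def coloc_table(results: Sequence[ColocResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "egene": r.egene,
                "context": r.context,
                "trait": r.trait,
                "lead_eqtl": r.lead_eqtl,
                "lead_gwas": r.lead_gwas,
                "n_variants": r.n_variants,
                "pp0": r.pp[0],
                "pp1": r.pp[1],
                "pp2": r.pp[2],
                "pp3": r.pp[3],
                "pp4": r.pp[4],
                "colocalised": r.colocalised,
                "hla_masked": r.hla_masked,
                "locus_id": r.locus_id if r.locus_id is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "egene", "context", "trait", "lead_eqtl", "lead_gwas", "n_variants",
            "pp0", "pp1", "pp2", "pp3", "pp4", "colocalised", "hla_masked", "locus_id",
        ],
    )
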