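"""Interaction (context-dependent) cis-eQTL mapping.

Extends the base model with an interaction variable I (sex, 5-year age bin,
disease status, smoking, or inflammation score):

    E[Ex] = a + b*GT + c*I + d*(GT x I) + e' PC_GT + f' PC_Ex

with two departures from the base scan: a stricter MAF filter of 0.1 applied
within every level of the interaction variable (continuous variables are
binned at the median for the filter only), and removal of any expression PC
whose Pearson correlation with I exceeds 0.25 in absolute value.  Gene-level
ieGene significance comes from permuting the interaction-variable assignments
across donors (genotype main effects stay intact) followed by BH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cis_eqtl import CovariateSet, _check_design, cis_candidates
from .datatypes import GenotypeMatrix, PseudobulkMatrix

__all__ = [
    "InteractionVariable",
    "prepare_interaction_covariates",
    "interaction_maf_filter",
    "interaction_scan",
    "interaction_permutation_pvalue",
]

IVAR_NAMES = ("sex", "age_bin", "disease", "smoking", "inflammation")


@dataclass
class InteractionVariable:
    """Donor-aligned interaction variable, binary (0/1) or ordered integer."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.unique(self.values).size < 2:
            raise ValueError(f"interaction variable {self.name!r} has fewer than 2 levels")

    def standardized(self) -> np.ndarray:
        """Zero-mean unit-SD encoding used in the model (continuous scores included)."""
        return (self.values - self.values.mean()) / self.values.std()

    def levels_for_filter(self) -> np.ndarray:
        """Discrete levels for the per-level MAF filter; continuous values binned at the median."""
        uniq = np.unique(self.values)
        if uniq.size <= 4:
            return self.values
        return (self.values > np.median(self.values)).astype(float)


def prepare_interaction_covariates(
    expression_pcs: np.ndarray,
    ivar: InteractionVariable,
    r_cut: float = 0.25,
) -> tuple[np.ndarray, list[int]]:
    """Drop expression PCs correlated with the interaction variable (|r| > r_cut).

    Returns the reduced PC matrix and the dropped column indices.
    """
    if np.unique(ivar.values).size < 2:
        raise ValueError("constant interaction variable")
    if expression_pcs.size == 0:
        return expression_pcs, []
    z = ivar.standardized()
    keep, dropped = [], []
    for j in range(expression_pcs.shape[1]):
        r = np.corrcoef(expression_pcs[:, j], z)[0, 1]
        (dropped if abs(r) > r_cut else keep).append(j)
    return expression_pcs[:, keep], dropped


def interaction_maf_filter(
    genotypes: GenotypeMatrix,
    ivar: InteractionVariable,
    donors: Optional[Sequence] = None,
    min_maf: float = 0.1,
    candidates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Keep variants whose MAF exceeds ``min_maf`` within every level of I.

    Levels with fewer than 2 donors are skipped with a warning.
    """
    if candidates is None:
        candidates = genotypes.variants.copy().reset_index()
    rows = (
        np.arange(genotypes.n_donors)
        if donors is None
        else np.array([genotypes.donors.index(d) for d in donors])
    )
    levels = ivar.levels_for_filter()
    used = 0
    keep = np.ones(len(candidates), dtype=bool)
    for lev in np.unique(levels):
        sub = rows[levels == lev]
        if len(sub) < 2:
            warnings.warn(f"interaction level {lev!r} has fewer than 2 donors; skipped")
            continue
        used += 1
        dosage = genotypes.dosage[np.ix_(sub, candidates["index"].to_numpy())]
        af = dosage.mean(axis=0) / 2.0
        keep &= np.minimum(af, 1 - af) > min_maf
    if used < 2:
        raise ValueError("need at least 2 usable interaction levels")
    return candidates[keep].reset_index(drop=True)


def interaction_scan(
    pb: PseudobulkMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet,
    ivar: InteractionVariable,
    gene: str,
    gene_tss: Optional[int] = None,
    chrom: Optional[str] = None,
    window_bp: int = 1_000_000,
    candidates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """OLS with genotype, interaction variable and their product per candidate variant.

    Returns per-variant beta_gt, beta_i, beta_gxi, se_gxi and the two-sided
    t-test p-value on the product-term coefficient.
    """
    if candidates is None:
        candidates = cis_candidates(gene_tss, genotypes, chrom, donors=pb.donors, window_bp=window_bp)
        candidates = interaction_maf_filter(genotypes, ivar, donors=pb.donors, candidates=candidates)
    y = pb.expr[gene].to_numpy(float)
    C = covariates.matrix()
    _check_design(C)
    rows = [genotypes.donors.index(d) for d in pb.donors]
    z = ivar.standardized()
    n = len(y)
    out = []
    for _, cand in candidates.iterrows():
        g = genotypes.dosage[rows, int(cand["index"])]
        gxi = g * z
        X = np.column_stack([np.ones(n), g, z, gxi] + ([C] if C.size else []))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"product column collinear with main effects for {cand['id']!r}")
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = n - X.shape[1]
        sigma2 = resid @ resid / dof
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * np.diag(XtX_inv))
        t_gxi = coef[3] / se[3]
        out.append(
            {
                "gene": gene,
                "variant": cand["id"],
                "ivar": ivar.name,
                "beta_gt": coef[1],
                "beta_i": coef[2],
                "beta_gxi": coef[3],
                "se_gxi": se[3],
                "p_gxi": 2.0 * stats.t.sf(abs(t_gxi), dof),
            }
        )
    return pd.DataFrame(out, columns=["gene", "variant", "ivar", "beta_gt", "beta_i", "beta_gxi", "se_gxi", "p_gxi"])


def interaction_permutation_pvalue(
    pb: PseudobulkMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet,
    ivar: InteractionVariable,
    gene: str,
    n_perm: int = 200,
    seed: int = 0,
    **scan_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Gene-level empirical p for the strongest interaction, by permuting I across donors.

    Permuting the interaction assignments preserves the genotype main effect
    and the expression distribution while breaking both I and GT x I, giving a
    calibrated null for the min interaction p-value.
    """
    obs = interaction_scan(pb, genotypes, covariates, ivar, gene, **scan_kwargs)
    if len(obs) == 0:
        raise ValueError(f"no candidate variants for {gene!r} after the interaction MAF filter")
    obs_min = obs["p_gxi"].min()
    rng = np.random.default_rng(seed)
    perm_mins = np.empty(n_perm)
    cand = scan_kwargs.get("candidates")
    if cand is None:
        cand = cis_candidates(
            scan_kwargs.get("gene_tss"), genotypes, scan_kwargs.get("chrom"), donors=pb.donors
        )
        cand = interaction_maf_filter(genotypes, ivar, donors=pb.donors, candidates=cand)
    for b in range(n_perm):
        perm = InteractionVariable(ivar.name, rng.permutation(ivar.values))
        perm_mins[b] = interaction_scan(
            pb, genotypes, covariates, perm, gene, candidates=cand
        )["p_gxi"].min()
    p_emp = (1.0 + np.sum(perm_mins <= obs_min)) / (1.0 + n_perm)
    return float(p_emp), obs
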