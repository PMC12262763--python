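"""Per-context cis-eQTL mapping.

The association model regresses inverse-normal-transformed pseudobulk
expression on alternative-allele dosage plus genotype and expression principal
components:

    E[Ex | GT] = a + b * GT + c' PC_GT + d' PC_Ex

Candidate variants lie within 1 Mb of the gene's TSS with in-sample MAF > 0.05.
Gene-level significance comes from a permutation scheme: the expression vector
is permuted across donors (covariates stay aligned to expression, i.e. both
expression and dosages are residualised against covariates first), the minimum
nominal p across candidates is recorded per permutation, and the empirical
p-value is (1 + #{perm <= obs}) / (1 + n_perm), optionally replaced by the
tail of a Beta distribution fitted to the permutation minima by maximum
likelihood.  eGenes are called by Benjamini-Hochberg over genes within a
context; conditionally independent signals come from a forward regression that
adds each lead's dosage to the covariates until the permutation p-value of the
residual model is no longer significant.

The scan itself uses the standard correlation shortcut: after residualising
expression and dosages against the covariates, the per-variant t statistic is
r * sqrt(dof / (1 - r^2)) with dof = n_donors - n_covariates - 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix, PseudobulkMatrix

__all__ = [
    "CovariateSet",
    "EGeneResult",
    "ConditionalSignal",
    "genotype_pcs",
    "expression_pcs",
    "cis_candidates",
    "nominal_scan",
    "permutation_scan",
    "call_egenes_fdr",
    "select_expression_pcs",
    "forward_conditional",
]

PC_GRID = tuple(range(2, 101, 2))


@dataclass
class CovariateSet:
    """Genotype PCs, expression PCs and any conditioning dosages, donor-aligned."""

    genotype_pcs: np.ndarray  # donors x n_gt_pcs
    expression_pcs: np.ndarray  # donors x K
    extra: list = field(default_factory=list)  # conditioning dosage vectors

    def matrix(self) -> np.ndarray:
        parts = [np.atleast_2d(np.asarray(p, float)) for p in (self.genotype_pcs, self.expression_pcs)]
        parts = [p if p.shape[0] != 1 or p.size == 0 else p.T for p in parts]
        parts += [np.asarray(e, float).reshape(-1, 1) for e in self.extra]
        parts = [p for p in parts if p.size]
        if not parts:
            return np.empty((0, 0))
        X = np.hstack(parts)
        return X - X.mean(axis=0)

    def with_extra(self, dosage: np.ndarray) -> "CovariateSet":
        return CovariateSet(self.genotype_pcs, self.expression_pcs, self.extra + [np.asarray(dosage, float)])

    @property
    def n_covariates(self) -> int:
        m = self.matrix()
        return 0 if m.size == 0 else m.shape[1]

    @staticmethod
    def empty(n_donors: int) -> "CovariateSet":
        return CovariateSet(np.empty((n_donors, 0)), np.empty((n_donors, 0)))


@dataclass
class EGeneResult:
    """Gene-level permutation result for one context."""

    gene: str
    context: str
    lead_variant: str
    beta: float
    se: float
    p_nominal: float
    maf: float
    n_donors: int
    p_perm: float
    n_perm: int
    fdr_q: Optional[float] = None
    p_beta: Optional[float] = None
    beta_shape: Optional[tuple] = None


@dataclass
class ConditionalSignal:
    """One rank of the forward conditional decomposition of a gene's cis signal."""

    gene: str
    context: str
    rank: int
    lead_variant: str
    beta: float
    se: float
    p_perm: float


def genotype_pcs(genotypes: GenotypeMatrix, n_components: int = 5) -> np.ndarray:
    """Principal components of the full dosage matrix (population-structure covariates)."""
    X = genotypes.dosage - genotypes.dosage.mean(axis=0)
    n_components = min(n_components, min(X.shape) - 1)
    return PCA(n_components=n_components, svd_solver="full").fit_transform(X)


def expression_pcs(pb: PseudobulkMatrix, k: int) -> np.ndarray:
    """Principal components of the (INT) pseudobulk matrix for one context."""
    X = pb.expr.to_numpy()
    k = min(k, min(X.shape) - 1)
    return PCA(n_components=k, svd_solver="full").fit_transform(X - X.mean(axis=0))


def cis_candidates(
    gene_tss: int,
    genotypes: GenotypeMatrix,
    chrom: str,
    donors: Optional[Sequence] = None,
    window_bp: int = 1_000_000,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Variants within ``window_bp`` of the TSS (both bounds inclusive) with MAF > min_maf.

    MAF is computed in-sample over ``donors`` (default: all genotyped donors).
    """
    if gene_tss is None or not np.isfinite(gene_tss):
        raise ValueError("gene TSS unknown")
    v = genotypes.variants
    mask = (v["chrom"] == chrom) & ((v["pos"] - gene_tss).abs() <= window_bp)
    dosage = genotypes.dosage
    if donors is not None:
        rows = [genotypes.donors.index(d) for d in donors]
        dosage = dosage[rows]
    af = dosage.mean(axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    mask &= maf > min_maf
    out = v[mask].copy()
    out["maf"] = maf[mask.to_numpy()]
    return out.reset_index()  # keeps original column index in "index"


def _residualize(M: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M against [1, covariates]."""
    n = M.shape[0]
    X = np.hstack([np.ones((n, 1))] + ([covariates] if covariates.size else []))
    Q, _ = np.linalg.qr(X)
    return M - Q @ (Q.T @ M)


def _check_design(covariates: np.ndarray) -> None:
    if covariates.size == 0:
        return
    n = covariates.shape[0]
    X = np.hstack([np.ones((n, 1)), covariates])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design: {X.shape[1]} columns but rank {rank}; "
            "check for collinear covariates (including conditioning dosages)"
        )


def _scan_stats(y_resid: np.ndarray, G_resid: np.ndarray, dof: int):
    """Per-variant beta, se, p from residualised expression and dosages."""
    sy = y_resid.std()
    sg = G_resid.std(axis=0)
    ok = (sg > 1e-12) & (sy > 1e-12)
    r = np.zeros(G_resid.shape[1])
    n = len(y_resid)
    r[ok] = (y_resid @ G_resid[:, ok]) / (n * sy * sg[ok])
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    tstat = r * np.sqrt(dof / (1 - r**2))
    beta = np.where(ok, r * sy / np.where(ok, sg, 1.0), np.nan)
    se = np.where(tstat != 0, np.abs(beta / np.where(tstat != 0, tstat, 1.0)), np.nan)
    # zero-effect variants: se from the usual formula
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(np.isnan(se) & ok, sy / (np.where(ok, sg, 1.0) * np.sqrt(dof)), se)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(ok, np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
    return beta, se, p, ok


def _aligned(pb: PseudobulkMatrix, genotypes: GenotypeMatrix) -> np.ndarray:
    rows = [genotypes.donors.index(d) for d in pb.donors]
    return genotypes.dosage[rows]


def nominal_scan(
    pb: PseudobulkMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet,
    gene: str,
    gene_tss: Optional[int] = None,
    chrom: Optional[str] = None,
    window_bp: int = 1_000_000,
    min_maf: float = 0.05,
    candidates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """OLS of INT expression on dosage plus covariates for every cis candidate.

    Returns a DataFrame with gene, variant, beta, se, p, maf, n_donors.
    """
    if candidates is None:
        candidates = cis_candidates(gene_tss, genotypes, chrom, donors=pb.donors, window_bp=window_bp, min_maf=min_maf)
    y = pb.expr[gene].to_numpy(float)
    C = covariates.matrix()
    _check_design(C)
    dosage = _aligned(pb, genotypes)[:, candidates["index"].to_numpy()]
    n = len(y)
    dof = n - C.shape[1] - 2 if C.size else n - 2
    if dof < 1:
        raise ValueError("not enough donors for the covariate count")
    y_res = _residualize(y.reshape(-1, 1), C).ravel()
    G_res = _residualize(dosage, C)
    beta, se, p, ok = _scan_stats(y_res, G_res, dof)
    out = pd.DataFrame(
        {
            "gene": gene,
            "variant": candidates["id"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
            "maf": candidates["maf"].to_numpy(),
            "n_donors": n,
        }
    )
    return out[ok].reset_index(drop=True)


def permutation_scan(
    gene: str,
    pb: PseudobulkMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet,
    n_perm: int = 1000,
    seed: int = 0,
    beta_approx: bool = False,
    context: str = "",
    gene_tss: Optional[int] = None,
    chrom: Optional[str] = None,
    window_bp: int = 1_000_000,
    min_maf: float = 0.05,
    candidates: Optional[pd.DataFrame] = None,
) -> EGeneResult:
    """Gene-level empirical p-value from donor-label permutations of expression."""
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse empirical p-value")
    if candidates is None:
        candidates = cis_candidates(gene_tss, genotypes, chrom, donors=pb.donors, window_bp=window_bp, min_maf=min_maf)
    if len(candidates) == 0:
        raise ValueError(f"no cis candidate variants for gene {gene!r}")

    y = pb.expr[gene].to_numpy(float)
    C = covariates.matrix()
    _check_design(C)
    dosage = _aligned(pb, genotypes)[:, candidates["index"].to_numpy()]
    n = len(y)
    dof = n - C.shape[1] - 2 if C.size else n - 2
    y_res = _residualize(y.reshape(-1, 1), C).ravel()
    G_res = _residualize(dosage, C)

    beta, se, p, ok = _scan_stats(y_res, G_res, dof)
    if not ok.any():
        raise ValueError(f"all candidate dosages collinear with covariates for {gene!r}")
    best = int(np.nanargmin(np.where(ok, p, np.inf)))
    obs_min_p = float(p[best])

    # permutation null of the min-p statistic: |r| is monotone in p, so track max |r|
    sg = G_res.std(axis=0)
    Gs = np.where(sg > 1e-12, G_res / np.where(sg > 1e-12, sg, 1.0), 0.0)
    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = y_res[perm_idx]
    Yp = (Yp - Yp.mean(axis=1, keepdims=True)) / Yp.std(axis=1, keepdims=True)
    r_perm = np.abs(Yp @ Gs) / n
    r_perm[:, ~ok] = 0.0
    max_r = np.clip(r_perm.max(axis=1), 0, 1 - 1e-15)
    t_perm = max_r * np.sqrt(dof / (1 - max_r**2))
    perm_min_p = np.clip(2.0 * stats.t.sf(t_perm, dof), np.finfo(float).tiny, 1.0)

    p_emp = (1.0 + np.sum(perm_min_p <= obs_min_p)) / (1.0 + n_perm)
    res = EGeneResult(
        gene=gene,
        context=context,
        lead_variant=str(candidates["id"].iloc[best]),
        beta=float(beta[best]),
        se=float(se[best]),
        p_nominal=obs_min_p,
        maf=float(candidates["maf"].iloc[best]),
        n_donors=n,
        p_perm=float(p_emp),
        n_perm=n_perm,
    )
    if beta_approx:
        x = np.clip(perm_min_p, 1e-12, 1 - 1e-12)
        a, b, _, _ = stats.beta.fit(x, floc=0, fscale=1)
        res.p_beta = float(np.clip(stats.beta.cdf(obs_min_p, a, b), np.finfo(float).tiny, 1.0))
        res.beta_shape = (a, b)
        res.p_perm = res.p_beta
    return res


def call_egenes_fdr(perm_results: Sequence[EGeneResult], fdr: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg over genes within a context; eGene iff q <= fdr."""
    if len(perm_results) == 0:
        return pd.DataFrame(columns=["gene", "context", "lead_variant", "p_perm", "q", "is_egene"])
    p = np.array([r.p_perm for r in perm_results])
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    for r, qv in zip(perm_results, q):
        r.fdr_q = float(qv)
    return pd.DataFrame(
        {
            "gene": [r.gene for r in perm_results],
            "context": [r.context for r in perm_results],
            "lead_variant": [r.lead_variant for r in perm_results],
            "beta": [r.beta for r in perm_results],
            "se": [r.se for r in perm_results],
            "p_nominal": [r.p_nominal for r in perm_results],
            "p_perm": p,
            "q": q,
            "is_egene": reject,
        }
    )


def select_expression_pcs(
    pb: PseudobulkMatrix,
    genotypes: GenotypeMatrix,
    gt_pcs: np.ndarray,
    gene_info: pd.DataFrame,
    grid: Sequence[int] = PC_GRID,
    fdr: float = 0.05,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the expression-PC count maximising eGene discoveries.

    Runs the permutation scan and BH calling once per grid value; returns the
    K with the most eGenes (ties broken by the smallest K) plus the per-K
    counts.  The grid is truncated so the design keeps positive degrees of
    freedom: K < n_donors - n_genotype_pcs - 2.
    """
    n = len(pb.donors)
    n_gt = gt_pcs.shape[1] if gt_pcs.size else 0
    feasible = [k for k in grid if k < n - n_gt - 2 and k < min(pb.expr.shape)]
    if not feasible:
        raise ValueError("no feasible expression-PC count for this donor count")
    rows = []
    for k in feasible:
        cov = CovariateSet(gt_pcs, expression_pcs(pb, k))
        results = []
        for _, g in gene_info.iterrows():
            try:
                results.append(
                    permutation_scan(
                        g["gene"], pb, genotypes, cov, n_perm=n_perm, seed=seed,
                        gene_tss=g["tss"], chrom=g["chrom"],
                    )
                )
            except ValueError:
                continue
        table = call_egenes_fdr(results, fdr=fdr)
        rows.append({"k": k, "n_egenes": int(table["is_egene"].sum()) if len(table) else 0})
    counts = pd.DataFrame(rows)
    best = counts.sort_values(["n_egenes", "k"], ascending=[False, True]).iloc[0]
    return int(best["k"]), counts


def forward_conditional(
    egene: EGeneResult,
    pb: PseudobulkMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet,
    alpha_stop: float,
    gene_tss: int,
    chrom: str,
    n_perm: int = 200,
    seed: int = 0,
    max_signals: int = 10,
) -> list[ConditionalSignal]:
    """Forward regression: peel off conditionally independent cis signals.

    The rank-1 signal is the unconditional lead.  Each round adds the current
    lead's dosage to the covariates and re-runs the permutation scan; a new
    signal is appended while its permutation p-value stays below
    ``alpha_stop`` (typically the context's BH threshold).
    """
    signals = [
        ConditionalSignal(
            gene=egene.gene, context=egene.context, rank=1,
            lead_variant=egene.lead_variant, beta=egene.beta, se=egene.se, p_perm=egene.p_perm,
        )
    ]
    cov = covariates
    dosage_all = _aligned(pb, genotypes)
    prior = [egene.lead_variant]
    for rank in range(2, max_signals + 1):
        lead_col = dosage_all[:, genotypes.index_of(prior[-1])]
        # a lead perfectly collinear with an earlier one cannot be conditioned on
        skip = False
        for e in cov.extra:
            r = np.corrcoef(e, lead_col)[0, 1]
            if np.isclose(abs(r), 1.0):
                warnings.warn(f"lead {prior[-1]} collinear with a prior lead; stopping")
                skip = True
        if skip:
            break
        cov = cov.with_extra(lead_col)
        try:
            res = permutation_scan(
                egene.gene, pb, genotypes, cov, n_perm=n_perm, seed=seed + rank,
                context=egene.context, gene_tss=gene_tss, chrom=chrom,
            )
        except ValueError:
            break
        if res.p_perm >= alpha_stop:
            break
        signals.append(
            ConditionalSignal(
                gene=egene.gene, context=egene.context, rank=rank,
                lead_variant=res.lead_variant, beta=res.beta, se=res.se, p_perm=res.p_perm,
            )
        )
        prior.append(res.lead_variant)
    return signals
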