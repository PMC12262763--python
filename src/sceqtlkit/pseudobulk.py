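"""Normalisation and donor-level aggregation at nested cellular resolutions.

Counts are normalised per cell to 10,000 total counts and log-transformed
(``ln[cp10k+1]``), then averaged over each donor's cells within an annotation
context — one (resolution, annotation, site-mode) triple.  Contexts keep a
donor only with at least five contributing cells, are retained only with at
least 30 donors, and keep a gene only if it is non-zero in at least 20% of the
pre-filter donor rows.  Each gene is then inverse normal transformed across
donors before eQTL mapping.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .datatypes import SITES, AnnotationContext, PseudobulkMatrix

__all__ = [
    "normalize_ln_cp10k",
    "aggregate",
    "filter_context",
    "inverse_normal_transform",
    "transform_matrix",
    "enumerate_contexts",
    "build_contexts",
]


def normalize_ln_cp10k(counts, scale: float = 1e4):
    """ln(1 + scale * count / cell_total) per cell; zero counts map to zero.

    Accepts a dense array or scipy sparse matrix (cells x genes); returns the
    same kind.  Raises if any cell has zero total counts, naming the first.
    """
    if sparse.issparse(counts):
        totals = np.asarray(counts.sum(axis=1)).ravel()
        _check_totals(totals)
        out = counts.tocsr(copy=True).astype(float)
        out.data = np.log1p(scale * out.data / np.repeat(totals, np.diff(out.indptr)))
        return out
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    _check_totals(totals)
    return np.log1p(scale * counts / totals[:, None])


def _check_totals(totals: np.ndarray) -> None:
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(f"cell {zero[0]} has zero total counts; remove it before normalising")


def aggregate(
    norm,
    meta: pd.DataFrame,
    context: AnnotationContext,
    min_cells: int = 5,
) -> PseudobulkMatrix:
    """Mean normalised expression per donor over the cells matching the context.

    ``meta`` must carry donor, site, cell_type and major_population columns
    aligned to the rows of ``norm``.  Cross-site mode pools cells from every
    site into one donor row; donors with fewer than ``min_cells`` matching
    cells are dropped.
    """
    if context.resolution == "all_cells":
        ann_mask = np.ones(len(meta), dtype=bool)
    elif context.resolution == "major_population":
        ann_mask = (meta["major_population"] == context.annotation).to_numpy()
    else:
        ann_mask = (meta["cell_type"] == context.annotation).to_numpy()
    if context.site_mode != "cross_site":
        ann_mask &= (meta["site"] == context.site_mode).to_numpy()

    if not ann_mask.any():
        warnings.warn(f"context {context.context_id} matches no cells; empty matrix")
    sub_meta = meta[ann_mask]
    idx = np.flatnonzero(ann_mask)

    gene_names = getattr(norm, "columns", None)
    X = norm.to_numpy() if isinstance(norm, pd.DataFrame) else norm

    rows, donors, n_cells = [], [], []
    # row positions (into norm) of each donor's cells within the masked subset
    positions = pd.Series(idx, index=sub_meta.index)
    for donor, cell_pos in positions.groupby(sub_meta["donor"], sort=True, observed=True):
        if len(cell_pos) < min_cells:
            continue
        block = X[cell_pos.to_numpy()]
        mean = np.asarray(block.mean(axis=0)).ravel()
        rows.append(mean)
        donors.append(donor)
        n_cells.append(len(cell_pos))

    n_genes = X.shape[1]
    expr = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_genes)),
        index=donors,
        columns=gene_names if gene_names is not None else range(n_genes),
    )
    return PseudobulkMatrix(
        context=context,
        expr=expr,
        cells_per_donor=pd.Series(n_cells, index=donors, dtype=int),
    )


def filter_context(
    pb: PseudobulkMatrix,
    min_donors: int = 30,
    min_gene_frac: float = 0.2,
) -> Optional[PseudobulkMatrix]:
    """Reject contexts with too few donors; drop genes expressed in too few donors.

    Returns None for a rejected context (a typed result, not an exception).
    The gene-presence fraction is computed on the pre-filter donor set of this
    context.
    """
    if len(pb.expr) < min_donors:
        return None
    nonzero_frac = (pb.expr > 0).mean(axis=0)
    keep = nonzero_frac >= min_gene_frac
    return PseudobulkMatrix(
        context=pb.context,
        expr=pb.expr.loc[:, keep],
        cells_per_donor=pb.cells_per_donor,
    )


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based mapping to normal quantiles: value_i -> Phi^-1((rank_i - 0.5) / n).

    Ties take the average rank, so tied inputs map to identical outputs.
    A constant vector has no usable ranks and raises.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("inverse normal transform needs at least 3 values")
    if np.ptp(values) == 0:
        raise ValueError("cannot transform an all-tied (constant) vector")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def transform_matrix(pb: PseudobulkMatrix) -> PseudobulkMatrix:
    """Inverse normal transform every gene of a pseudobulk matrix; constant genes are dropped."""
    cols = {}
    for gene in pb.expr.columns:
        v = pb.expr[gene].to_numpy()
        if np.ptp(v) == 0:
            continue
        cols[gene] = inverse_normal_transform(v)
    expr = pd.DataFrame(cols, index=pb.expr.index)
    return PseudobulkMatrix(context=pb.context, expr=expr, cells_per_donor=pb.cells_per_donor)


def enumerate_contexts(meta: pd.DataFrame, site_modes: Iterable[str] = SITES) -> list[AnnotationContext]:
    """The full (resolution x annotation x site-mode) grid present in the metadata."""
    modes = list(site_modes) + ["cross_site"]
    contexts = [AnnotationContext("all_cells", "ALL", m) for m in modes]
    for pop in sorted(meta["major_population"].unique()):
        contexts += [AnnotationContext("major_population", pop, m) for m in modes]
    for ct in sorted(meta["cell_type"].unique()):
        contexts += [AnnotationContext("cell_type", ct, m) for m in modes]
    return contexts


def build_contexts(
    adata: ad.AnnData,
    min_cells: int = 5,
    min_donors: int = 30,
    min_gene_frac: float = 0.2,
    site_modes: Optional[Iterable[str]] = None,
    apply_int: bool = True,
) -> dict[str, PseudobulkMatrix]:
    """Normalise once, then aggregate + filter (+ INT) every context in the grid.

    Returns retained contexts keyed by context id.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    keep = totals > 0
    adata = adata[keep]
    norm = normalize_ln_cp10k(adata.X)
    if sparse.issparse(norm):
        norm = np.asarray(norm.todense())
    norm = pd.DataFrame(norm, columns=adata.var_names)
    meta = adata.obs.reset_index(drop=True)

    if site_modes is None:
        site_modes = sorted(meta["site"].unique())
    out: dict[str, PseudobulkMatrix] = {}
    for ctx in enumerate_contexts(meta, site_modes):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pb = aggregate(norm, meta, ctx, min_cells=min_cells)
        pb = filter_context(pb, min_donors=min_donors, min_gene_frac=min_gene_frac)
        if pb is None or pb.expr.shape[1] == 0:
            continue
        if apply_int:
            pb = transform_matrix(pb)
        out[ctx.context_id] = pb
    return out
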