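"""Cell-level quality control.

Two layers of filtering, applied to the standard per-cell metrics (number of
genes expressed, total counts, mitochondrial percentage):

* an absolute filter with fixed thresholds (>= 250 genes, >= 500 counts,
  mitochondrial fraction <= 20% for blood-derived cells and <= 50% otherwise);
* a lineage-relative filter keeping cells within ``median +/- n_mads * MAD``
  of each metric inside their lineage, with a tighter 2-MAD window for the
  epithelial lineage (whose spread is much larger) and 2.5 MADs elsewhere.

The MAD is unscaled (no 1.4826 normal-consistency factor) and window bounds
are inclusive, so a degenerate MAD of zero keeps exactly the cells at the
median.
"""

from __future__ import annotations

from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "compute_metrics",
    "absolute_filter",
    "relative_mad_filter",
    "apply_qc",
    "EPITHELIAL_N_MADS",
    "DEFAULT_N_MADS",
]

DEFAULT_N_MADS = 2.5
EPITHELIAL_N_MADS = 2.0

METRIC_COLUMNS = ("n_genes", "total_counts", "pct_mito")
REQUIRED_COLUMNS = METRIC_COLUMNS + ("is_blood_derived", "lineage")


def compute_metrics(adata: ad.AnnData, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics from a raw count AnnData.

    Returns a DataFrame indexed like ``adata.obs`` with n_genes, total_counts,
    pct_mito, is_blood_derived (site == blood) and lineage.
    """
    X = adata.X
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    if mito_mask.any():
        mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    else:
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(int),
            "total_counts": total.astype(int),
            "pct_mito": pct,
            "is_blood_derived": (adata.obs["site"] == "blood").to_numpy(),
            "lineage": adata.obs["lineage"].to_numpy(),
        },
        index=adata.obs_names,
    )


def _check_metrics(metrics: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics missing required columns: {missing}")
    if ((metrics["pct_mito"] < 0) | (metrics["pct_mito"] > 100)).any():
        raise ValueError("pct_mito must lie in [0, 100]")


def absolute_filter(
    metrics: pd.DataFrame,
    min_genes: int = 250,
    min_counts: int = 500,
    max_mito_blood: float = 20.0,
    max_mito_other: float = 50.0,
) -> np.ndarray:
    """Keep-mask from fixed thresholds; mitochondrial cap depends on blood origin."""
    _check_metrics(metrics)
    mito_cap = np.where(metrics["is_blood_derived"], max_mito_blood, max_mito_other)
    keep = (
        (metrics["n_genes"] >= min_genes)
        & (metrics["total_counts"] >= min_counts)
        & (metrics["pct_mito"] <= mito_cap)
    )
    return keep.to_numpy()


def _mad_window_mask(values: np.ndarray, n_mads: float) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    lo, hi = med - n_mads * mad, med + n_mads * mad
    return (values >= lo) & (values <= hi)


def relative_mad_filter(
    metrics: pd.DataFrame,
    lineage: str,
    n_mads: Optional[float] = None,
    epithelial_label: str = "epithelial",
) -> np.ndarray:
    """Keep-mask over the cells of one lineage from MAD windows on all three metrics.

    The mask has one entry per cell of ``metrics`` restricted to the lineage
    (cells outside the lineage are not returned).  The window count defaults
    to 2.5 MADs, or 2.0 for the epithelial lineage.
    """
    _check_metrics(metrics)
    sub = metrics[metrics["lineage"] == lineage]
    if len(sub) == 0:
        raise ValueError(f"no cells in lineage {lineage!r}")
    if len(sub) < 3:
        raise ValueError(f"lineage {lineage!r} has fewer than 3 cells")
    if n_mads is None:
        n_mads = EPITHELIAL_N_MADS if lineage.lower() == epithelial_label else DEFAULT_N_MADS
    keep = np.ones(len(sub), dtype=bool)
    for col in METRIC_COLUMNS:
        keep &= _mad_window_mask(sub[col].to_numpy(float), n_mads)
    return keep


def apply_qc(
    adata: ad.AnnData,
    mito_prefix: str = "MT-",
    relative: bool = True,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Absolute then lineage-relative filtering; returns the filtered cells and a summary.

    The summary table reports, per lineage, cells in, cells removed by each
    layer and cells kept.
    """
    metrics = compute_metrics(adata, mito_prefix=mito_prefix)
    abs_keep = absolute_filter(metrics)
    kept = adata[abs_keep].copy()
    metrics_kept = metrics[abs_keep]

    rel_keep = np.ones(len(kept), dtype=bool)
    if relative:
        for lineage in metrics_kept["lineage"].unique():
            idx = metrics_kept["lineage"] == lineage
            if idx.sum() < 3:
                continue  # too few cells for a meaningful window: keep them
            rel_keep[idx.to_numpy()] = relative_mad_filter(metrics_kept, lineage)
    final = kept[rel_keep].copy()

    rows = []
    for lineage, sub in metrics.groupby("lineage"):
        n_in = len(sub)
        n_abs = int((~abs_keep[metrics["lineage"] == lineage]).sum())
        n_kept = int((final.obs["lineage"] == lineage).sum())
        rows.append(
            {
                "lineage": lineage,
                "n_cells_in": n_in,
                "n_removed_absolute": n_abs,
                "n_removed_relative": n_in - n_abs - n_kept,
                "n_cells_kept": n_kept,
            }
        )
    return final, pd.DataFrame(rows)
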