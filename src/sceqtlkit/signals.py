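"""Cross-context signal grouping and attribution.

Lead variants for the same gene can differ across annotation contexts through
minor significance shifts, so per-context leads are grouped into signals by
greedy LD clumping (plink style): sort leads by p ascending, let the best
unassigned lead seed a clump that absorbs every unassigned lead with
r-squared above the cutoff within the distance window, repeat.  Each signal
(or eGene) is then attributed to the *minimum* cellular resolution at which it
was detected — the coarsest of all cells < major population < cell type — and
to a site-sharing class, with "cross_site_only" marking detections that appear
only when sites are combined.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

from .datatypes import RESOLUTION_ORDER, GenotypeMatrix, SignalGroup

__all__ = [
    "in_sample_r2",
    "clump_leads",
    "attribute_resolution",
    "classify_site_sharing",
    "signals_table",
]


def in_sample_r2(genotypes: GenotypeMatrix) -> Callable[[str, str], float]:
    """Squared Pearson correlation between dosage vectors, by variant id."""

    def r2(a: str, b: str) -> float:
        if a == b:
            return 1.0
        x, y = genotypes.column(a), genotypes.column(b)
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    return r2


def clump_leads(
    leads: pd.DataFrame,
    r2_func: Callable[[str, str], float],
    positions: dict,
    r2_cut: float = 0.5,
    window_bp: int = 1_000_000,
) -> list[SignalGroup]:
    """Greedy LD clumping of one gene's per-context lead variants.

    ``leads`` needs columns context, gene, variant, p (optionally resolution,
    site_mode).  Ties on p break lexicographically on variant id.  A missing
    r-squared is treated as 0 with a warning.
    """
    if leads.empty:
        return []
    genes = leads["gene"].unique()
    if len(genes) != 1:
        raise ValueError("clump_leads groups the leads of a single gene")
    gene = genes[0]

    order = leads.sort_values(["p", "variant"], kind="mergesort").index.to_list()
    unassigned = set(order)
    groups = []
    k = 0
    for seed_idx in order:
        if seed_idx not in unassigned:
            continue
        seed = leads.loc[seed_idx]
        member_idx = [seed_idx]
        unassigned.discard(seed_idx)
        for other_idx in list(unassigned):
            other = leads.loc[other_idx]
            if abs(positions[other["variant"]] - positions[seed["variant"]]) > window_bp:
                continue
            try:
                r2 = r2_func(seed["variant"], other["variant"])
            except KeyError:
                warnings.warn(f"missing r2 for ({seed['variant']}, {other['variant']}); treated as 0")
                r2 = 0.0
            if r2 > r2_cut:
                member_idx.append(other_idx)
                unassigned.discard(other_idx)
        members = leads.loc[member_idx].reset_index(drop=True)
        groups.append(
            SignalGroup(
                signal_id=f"{gene}:signal{k + 1}",
                gene=gene,
                members=members,
                index_variant=str(seed["variant"]),
            )
        )
        k += 1
    return groups


def attribute_resolution(group: SignalGroup) -> str:
    """Coarsest resolution among the group's members (all_cells < major_population < cell_type)."""
    if group.members.empty:
        raise ValueError("cannot attribute an empty signal group")
    if "resolution" not in group.members.columns:
        raise ValueError("members must carry a 'resolution' column")
    label = min(group.members["resolution"], key=lambda r: RESOLUTION_ORDER[r])
    group.min_resolution = label
    return label


def classify_site_sharing(detected_site_modes: Iterable[str]) -> frozenset:
    """Site-sharing class from the site modes in which an eGene was detected.

    Returns the set of single sites with a detection, or {"cross_site_only"}
    when the gene is detected only in the combined-site analysis.
    """
    modes = set(detected_site_modes)
    single = frozenset(m for m in modes if m != "cross_site")
    if single:
        return single
    if "cross_site" in modes:
        return frozenset({"cross_site_only"})
    return frozenset()


def signals_table(groups: Iterable[SignalGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        rows.append(
            {
                "signal_id": g.signal_id,
                "gene": g.gene,
                "index_variant": g.index_variant,
                "n_members": len(g.members),
                "min_resolution": g.min_resolution,
                "site_class": ",".join(sorted(g.site_class)) if g.site_class else "",
            }
        )
    return pd.DataFrame(
        rows, columns=["signal_id", "gene", "index_variant", "n_members", "min_resolution", "site_class"]
    )
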