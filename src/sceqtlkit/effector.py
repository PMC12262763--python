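"""Effector-annotation nomination and per-resolution colocalisation enrichment.

Detection of colocalisation depends on per-annotation statistical power, so
the effector annotation for a colocalised locus is nominated power-agnostically:
for every annotation with a nominal eQTL effect (p < 0.05) and median
expression above zero, the proportion of variance in the (inverse normal
transformed) pseudobulk expression explained by the lead colocalising variant
is computed by simple linear regression, and the annotation with the maximum
r-squared wins (ties are all reported, in deterministic order).

Per-resolution enrichment is summarised as the ratio of odds of a resolution
class between effector genes and eGenes:  OR_r = [a/(A-a)] / [b/(B-b)] with
a effector genes attributed to r out of A, and b eGenes attributed to r out
of B; zero cells take the Haldane-Anscombe +0.5 correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import RESOLUTIONS

__all__ = ["EffectorNomination", "variance_explained", "nominate_annotation", "resolution_odds_ratio"]


@dataclass
class EffectorNomination:
    """Per-annotation variance explained for one colocalisation, plus the winner(s)."""

    coloc_id: str
    r2: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    eligible: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    best: tuple = ()
    empty: bool = False


def variance_explained(expr_int: np.ndarray, dosage: np.ndarray) -> Optional[float]:
    """Coefficient of determination of expression on dosage (== squared Pearson r).

    Returns None for a constant dosage vector, where r-squared is undefined.
    """
    expr_int = np.asarray(expr_int, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if expr_int.size != dosage.size or expr_int.size < 3:
        raise ValueError("need aligned vectors of at least 3 donors")
    if dosage.std() == 0:
        return None
    if expr_int.std() == 0:
        return 0.0
    r = np.corrcoef(expr_int, dosage)[0, 1]
    return float(r**2)


def nominate_annotation(
    coloc_id: str,
    lead_variant: str,
    contexts: Mapping[str, object],
    genotypes,
    gene: str,
    nominal_p: Mapping[str, float],
    median_expr: Mapping[str, float],
    p_cut: float = 0.05,
    tie_tol: float = 1e-12,
) -> EffectorNomination:
    """Nominate the effector annotation for one colocalised gene.

    ``contexts`` maps annotation (context id) to its INT PseudobulkMatrix;
    ``nominal_p`` and ``median_expr`` give, per annotation, the gene's nominal
    eQTL p-value at the lead variant and its median raw pseudobulk expression
    (the eligibility gates).
    """
    r2s, eligible = {}, {}
    for ann, pb in contexts.items():
        if gene not in pb.expr.columns:
            continue
        ok = nominal_p.get(ann, 1.0) < p_cut and median_expr.get(ann, 0.0) > 0
        eligible[ann] = ok
        if not ok:
            continue
        rows = [genotypes.donors.index(d) for d in pb.donors]
        dosage = genotypes.column(lead_variant)[rows]
        r2 = variance_explained(pb.expr[gene].to_numpy(), dosage)
        if r2 is not None:
            r2s[ann] = r2
    nom = EffectorNomination(
        coloc_id=coloc_id,
        r2=pd.Series(r2s, dtype=float).sort_index(),
        eligible=pd.Series(eligible, dtype=bool).sort_index(),
    )
    if not r2s:
        nom.empty = True
        return nom
    best_val = nom.r2.max()
    nom.best = tuple(sorted(a for a, v in r2s.items() if best_val - v <= tie_tol))
    return nom


def resolution_odds_ratio(
    egene_counts: Mapping[str, int],
    effector_counts: Mapping[str, int],
) -> pd.Series:
    """Odds ratio of each resolution class between effector genes and eGenes.

    Counts are of genes attributed (by minimum detection resolution) to each
    of the three classes.  Zero cells are corrected by adding 0.5 to every
    cell of the affected 2x2 table.
    """
    A = sum(effector_counts.get(r, 0) for r in RESOLUTIONS)
    B = sum(egene_counts.get(r, 0) for r in RESOLUTIONS)
    if A == 0 or B == 0:
        raise ValueError("need at least one effector gene and one eGene")
    out = {}
    for r in RESOLUTIONS:
        a = effector_counts.get(r, 0)
        b = egene_counts.get(r, 0)
        cells = np.array([a, A - a, b, B - b], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
        out[r] = (cells[0] / cells[1]) / (cells[2] / cells[3])
    return pd.Series(out)
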