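"""Shared domain containers.

Light dataclass wrappers around numpy/pandas objects.  Each container
validates its own invariants on construction via ``validate()``; heavier
numerical work lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

RESOLUTIONS = ("all_cells", "major_population", "cell_type")
#: coarse-to-fine ordering used for "minimum resolution" attribution
RESOLUTION_ORDER = {r: i for i, r in enumerate(RESOLUTIONS)}
SITES = ("blood", "TI", "rectum")
SITE_MODES = SITES + ("cross_site",)

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "id"]


@dataclass
class GenotypeMatrix:
    """Donor x variant alternative-allele dosage matrix.

    dosage[i, j] is the number of alternative alleles (0/1/2 for hard calls)
    carried by donor i at variant j.  ``variants`` is a DataFrame with columns
    chrom, pos (1-based), ref, alt, id, ordered by position within chromosome.
    ``sim_params`` records the generator design (per-variant MAF, LD-block
    assignment, latent correlation) so that an independent cohort with matched
    LD structure can be redrawn, e.g. for a two-sample GWAS.
    """

    donors: list
    variants: pd.DataFrame
    dosage: np.ndarray
    sim_params: Optional[dict] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.variants = self.variants.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.donors):
            raise ValueError("dosage rows must match donors")
        if m != len(self.variants):
            raise ValueError("dosage columns must match variants")
        if self.dosage.min(initial=0) < 0 or self.dosage.max(initial=0) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        ids = self.variants["id"]
        if ids.duplicated().any():
            raise ValueError("duplicate variant ids")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError("variant positions must be strictly increasing per chromosome")

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """In-sample minor allele frequency per variant."""
        af = self.dosage.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"unknown variant id {variant_id!r}")
        return int(idx[0])

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.index_of(variant_id)]


@dataclass
class TruthLedger:
    """Ground truth of planted effects for recovery testing.

    ``genes`` catalogues the simulated gene models (chrom, tss, strand and a
    baseline mean count per cell); ``eqtls`` the planted cis effects with
    their active annotation set, resolution class and regulatory-track
    placement; ``ieqtls`` the planted genotype-by-context interactions;
    ``gwas`` the causal spec of the simulated trait.
    """

    genes: pd.DataFrame
    eqtls: pd.DataFrame
    ieqtls: pd.DataFrame
    gwas: pd.DataFrame
    seeds: dict = field(default_factory=dict)

    @staticmethod
    def empty(genes: pd.DataFrame) -> "TruthLedger":
        return TruthLedger(
            genes=genes,
            eqtls=pd.DataFrame(
                columns=["gene", "variant", "beta", "annotations", "resolution", "placement"]
            ),
            ieqtls=pd.DataFrame(columns=["gene", "variant", "ivar", "beta"]),
            gwas=pd.DataFrame(columns=["variant", "beta", "shared_with_eqtl"]),
        )

    def validate_against(self, genotypes: GenotypeMatrix) -> None:
        known = set(genotypes.variants["id"])
        planted = set(self.eqtls["variant"]) | set(self.ieqtls["variant"]) | set(self.gwas["variant"])
        missing = planted - known
        if missing:
            raise ValueError(f"planted variants absent from genotypes: {sorted(missing)}")


@dataclass
class GwasSumstats:
    """Per-variant marginal association statistics for one trait."""

    table: pd.DataFrame  # chrom, pos, ref, alt, id, beta, se, p, n
    trait: str = "trait"

    def __post_init__(self) -> None:
        t = self.table
        if (t["se"] <= 0).any():
            raise ValueError("all standard errors must be positive")
        from scipy import stats

        z = t["beta"] / t["se"]
        expected = 2.0 * stats.norm.sf(np.abs(z))
        ok = np.isclose(t["p"], expected, rtol=1e-6, atol=1e-300)
        if not ok.all():
            raise ValueError("p-values inconsistent with beta/se under the normal approximation")


@dataclass
class AnnotationTrack:
    """Promoter/enhancer intervals and LD blocks, BED-style half-open 0-based."""

    intervals: pd.DataFrame  # chrom, start, end, cls in {promoter, enhancer}
    ld_blocks: pd.DataFrame  # chrom, start, end, block

    def __post_init__(self) -> None:
        for cls, sub in self.intervals.groupby("cls"):
            sub = sub.sort_values(["chrom", "start"])
            for _, chrom_sub in sub.groupby("chrom"):
                starts = chrom_sub["start"].to_numpy()
                ends = chrom_sub["end"].to_numpy()
                if (starts[1:] < ends[:-1]).any():
                    raise ValueError(f"overlapping merged intervals in class {cls!r}")

    def block_of(self, chrom: str, pos: int) -> int:
        """LD block id containing the 1-based position; every tested position maps to one."""
        sub = self.ld_blocks[self.ld_blocks["chrom"] == chrom]
        hit = sub[(sub["start"] < pos) & (pos <= sub["end"])]
        if len(hit) != 1:
            raise ValueError(f"position {chrom}:{pos} maps to {len(hit)} LD blocks")
        return int(hit["block"].iloc[0])


@dataclass(frozen=True)
class AnnotationContext:
    """One (resolution, annotation, site mode) aggregation context."""

    resolution: str
    annotation: str
    site_mode: str

    def __post_init__(self) -> None:
        if self.resolution not in RESOLUTIONS:
            raise ValueError(f"unknown resolution {self.resolution!r}")
        if self.site_mode not in SITE_MODES:
            raise ValueError(f"unknown site mode {self.site_mode!r}")
        if self.resolution == "all_cells" and self.annotation != "ALL":
            raise ValueError("all_cells contexts must carry the annotation label 'ALL'")

    @property
    def context_id(self) -> str:
        return f"{self.resolution}:{self.annotation}:{self.site_mode}"


@dataclass
class PseudobulkMatrix:
    """Donor x gene mean ln[cp10k+1] expression for one context."""

    context: AnnotationContext
    expr: pd.DataFrame  # index: donor ids, columns: gene ids
    cells_per_donor: pd.Series

    def validate(self, min_cells: int = 5, min_donors: int = 30) -> None:
        if not np.isfinite(self.expr.to_numpy()).all():
            raise ValueError("pseudobulk expression must be finite")
        if (self.cells_per_donor < min_cells).any():
            raise ValueError(f"retained donors must have >= {min_cells} cells")
        if len(self.expr) < min_donors:
            raise ValueError(f"retained context must have >= {min_donors} donors")

    @property
    def donors(self) -> list:
        return list(self.expr.index)

    @property
    def genes(self) -> list:
        return list(self.expr.columns)


@dataclass
class SignalGroup:
    """LD-clumped group of per-context lead variants for one gene."""

    signal_id: str
    gene: str
    members: pd.DataFrame  # context, gene, variant, p
    index_variant: str
    min_resolution: Optional[str] = None
    site_class: Optional[frozenset] = None


@dataclass
class ColocResult:
    """Five-hypothesis colocalisation posteriors for one (eGene context, trait) pair."""

    egene: str
    context: str
    trait: str
    window: tuple  # (chrom, start, end) 1-based inclusive
    pp: np.ndarray  # PP0..PP4
    lead_eqtl: str
    lead_gwas: str
    lead_gwas_pos: int
    lead_gwas_chrom: str
    n_variants: int
    colocalised: bool = False
    hla_masked: bool = False
    locus_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,):
            raise ValueError("pp must hold five posteriors")
        if abs(self.pp.sum() - 1.0) > 1e-9:
            raise ValueError("posteriors must sum to 1")
        if ((self.pp < 0) | (self.pp > 1)).any():
            raise ValueError("posteriors must lie in [0, 1]")
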