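"""Shared fixtures: a small synthetic cohort with planted effects."""

import numpy as np
import pandas as pd
import pytest

from sceqtlkit import cis_eqtl, pseudobulk, synthdata
from sceqtlkit.datatypes import TruthLedger

HIERARCHY = {
    "Tcm": "Tcell", "Tem": "Tcell",
    "NaiveB": "Bcell", "MemoryB": "Bcell",
    "Monocyte": "Myeloid", "Macrophage": "Myeloid",
}


@pytest.fixture(scope="session")
def genotypes():
    return synthdata.simulate_genotypes(120, 60, block_size=6, maf_range=(0.1, 0.5), seed=11)


@pytest.fixture(scope="session")
def gene_table():
    return synthdata.make_gene_table(20, tss_spacing=15_000, seed=12)


@pytest.fixture(scope="session")
def truth(genotypes, gene_table):
    t = TruthLedger.empty(gene_table)
    v = genotypes.variants
    synthdata.plant_eqtl(t, HIERARCHY, "GENE0000", v["id"].iloc[10], 0.6, "ubiquitous")
    synthdata.plant_eqtl(t, HIERARCHY, "GENE0005", v["id"].iloc[30], 0.8, "cell_type",
                         annotation="Monocyte", placement="enhancer")
    t.ieqtls.loc[0] = {"gene": "GENE0010", "variant": v["id"].iloc[45],
                       "ivar": "inflammation", "beta": 0.6}
    t.gwas.loc[0] = {"variant": v["id"].iloc[10], "beta": 0.5, "shared_with_eqtl": True}
    return t


@pytest.fixture(scope="session")
def cells(genotypes, truth):
    return synthdata.simulate_cells(genotypes, HIERARCHY, 18, truth, noise_sd=0.3, seed=13)


@pytest.fixture(scope="session")
def contexts(cells):
    return pseudobulk.build_contexts(cells)


@pytest.fixture(scope="session")
def gt_pcs(genotypes):
    return cis_eqtl.genotype_pcs(genotypes, 5)
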