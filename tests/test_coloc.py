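"""ABF colocalisation: closed forms, enumeration oracle, gates, HLA mask, locus assignment."""

import math

import numpy as np
import pandas as pd
import pytest

from sceqtlkit import coloc
from sceqtlkit.cis_eqtl import EGeneResult
from sceqtlkit.datatypes import ColocResult


def coloc_oracle(labf1, labf2, p1=1e-4, p2=1e-4, p12=1e-5):
    """Direct enumeration of the five hypothesis weights with fsum accumulation."""
    bf1 = [math.exp(v) for v in labf1]
    bf2 = [math.exp(v) for v in labf2]
    s1 = math.fsum(bf1)
    s2 = math.fsum(bf2)
    s12 = math.fsum(a * b for a, b in zip(bf1, bf2))
    cross = math.fsum(a * b for i, a in enumerate(bf1) for j, b in enumerate(bf2) if i != j)
    S = [1.0, p1 * s1, p2 * s2, p1 * p2 * cross, p12 * s12]
    tot = math.fsum(S)
    return np.array([s / tot for s in S])


class TestWakefieldLabf:
    def test_symmetry_case(self):
        # z = 0 and V = W: lABF = 0.5 ln(1/2)
        assert coloc.wakefield_labf(0.0, 0.1, 0.1) == pytest.approx(0.5 * np.log(0.5), abs=1e-12)

    def test_prior_collapse(self):
        assert coloc.wakefield_labf(0.5, 0.1, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value(self):
        # V=0.01, W=0.0225, z=5: 0.5*(ln(0.01/0.0325) + 25*0.0225/0.0325)
        assert coloc.wakefield_labf(0.5, 0.1, 0.15) == pytest.approx(8.0645, abs=5e-4)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            coloc.wakefield_labf(0.5, 0.0, 0.15)


class TestColocAbf:
    def test_all_zero_labf_closed_form(self):
        pp = coloc.coloc_abf(np.zeros(100), np.zeros(100))
        # S = [1, 0.01, 0.01, 9.9e-5, 1e-3], total 1.021099
        assert pp[4] == pytest.approx(1e-3 / 1.021099, rel=1e-6)
        assert pp[4] == pytest.approx(9.79e-4, abs=1e-6)

    def test_dominant_shared_variant(self):
        labf = np.zeros(50)
        labf[10] = 50.0
        pp = coloc.coloc_abf(labf, labf)
        assert pp[4] > 0.99

    def test_dominant_single_trait_variant(self):
        # with flat trait-2 evidence S1/S4 = p1/p12 = 10, so PP1 tops out at ~10/11
        labf1 = np.zeros(50)
        labf1[10] = 50.0
        pp = coloc.coloc_abf(labf1, np.zeros(50))
        assert pp.argmax() == 1
        assert pp[1] > 0.9

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            q = int(rng.integers(2, 201))
            labf1 = rng.uniform(-5, 25, q)
            labf2 = rng.uniform(-5, 25, q)
            pp = coloc.coloc_abf(labf1, labf2)
            expected = coloc_oracle(labf1, labf2)
            np.testing.assert_allclose(pp, expected, atol=1e-12)
            assert pp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        labf1, labf2 = rng.uniform(0, 10, 40), rng.uniform(0, 10, 40)
        a = coloc.coloc_abf(labf1, labf2)
        b = coloc.coloc_abf(labf1 + 3.7, labf2)
        # adding a constant to one trait's lABFs rescales BF sums but the
        # posteriors change only through the prior-weighted mixture; the
        # normalisation-free ratios PP4/PP3 must be preserved
        assert a[4] / a[3] == pytest.approx(b[4] / b[3], rel=1e-9)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        labf1, labf2 = rng.uniform(0, 10, 40), rng.uniform(-2, 8, 40)
        a = coloc.coloc_abf(labf1, labf2)
        b = coloc.coloc_abf(labf2, labf1)
        assert a[0] == pytest.approx(b[0], rel=1e-10)
        assert a[3] == pytest.approx(b[3], rel=1e-10)
        assert a[4] == pytest.approx(b[4], rel=1e-10)
        assert a[1] == pytest.approx(b[2], rel=1e-10)
        assert a[2] == pytest.approx(b[1], rel=1e-10)

    def test_pp4_monotone_in_weaker_trait_z(self):
        labf1 = np.zeros(30)
        labf1[5] = 20.0
        pp4 = []
        for z in np.linspace(0, 6, 7):
            labf2 = np.zeros(30)
            labf2[5] = coloc.wakefield_labf(z * 0.1, 0.1, 0.15)
            pp4.append(coloc.coloc_abf(labf1, labf2)[4])
        assert (np.diff(pp4) >= -1e-12).all()

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            coloc.coloc_abf(np.zeros(5), np.zeros(6))


class TestHarmonise:
    def test_allele_flip_negates_beta(self):
        eqtl = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [100, 200],
                             "ref": ["A", "A"], "alt": ["G", "G"],
                             "beta": [0.5, 0.5], "se": [0.1, 0.1]})
        gwas = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [100, 200, 300],
                             "ref": ["G", "A"] + ["A"], "alt": ["A", "G"] + ["G"],
                             "beta": [0.3, 0.2, 0.1], "se": [0.1] * 3})
        out = coloc.harmonise(eqtl, gwas)
        assert len(out) == 2
        assert out.loc[out["pos"] == 100, "beta_gwas"].iloc[0] == pytest.approx(-0.3)
        assert out.loc[out["pos"] == 200, "beta_gwas"].iloc[0] == pytest.approx(0.2)

    def test_mismatched_alleles_dropped(self):
        eqtl = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "ref": ["A"], "alt": ["G"],
                             "beta": [0.5], "se": [0.1]})
        gwas = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "ref": ["A"], "alt": ["T"],
                             "beta": [0.3], "se": [0.1]})
        assert len(coloc.harmonise(eqtl, gwas)) == 0


def _dummy_result(pp4, chrom="chr1", pos=1_000_000):
    pp = np.array([0.0, 0.0, 0.0, 1 - pp4, pp4])
    return ColocResult(
        egene="g", context="c", trait="t", window=(chrom, pos - 1_000_000, pos + 1_000_000),
        pp=pp, lead_eqtl="ve", lead_gwas="vg", lead_gwas_pos=pos, lead_gwas_chrom=chrom,
        n_variants=50,
    )


class TestPostfilterAndAssign:
    def test_pp4_threshold_strict(self):
        out = coloc.postfilter_and_assign([_dummy_result(0.74), _dummy_result(0.76)])
        assert [r.colocalised for r in out] == [False, True]

    def test_hla_lead_discarded(self):
        r = _dummy_result(0.99, chrom="chr6", pos=30_000_000)
        out = coloc.postfilter_and_assign([r])[0]
        assert out.hla_masked and not out.colocalised

    def test_locus_assignment_distance(self):
        loci = pd.DataFrame({"locus_id": ["L1"], "chrom": ["chr1"], "pos": [5_000_000]})
        near = coloc.postfilter_and_assign([_dummy_result(0.9, pos=5_400_000)], loci=loci)[0]
        far = coloc.postfilter_and_assign([_dummy_result(0.9, pos=5_600_000)], loci=loci)[0]
        assert near.locus_id == "L1"
        assert far.locus_id is None

    def test_tie_breaks_to_smaller_locus_id(self):
        loci = pd.DataFrame({"locus_id": ["L2", "L1"], "chrom": ["chr1", "chr1"],
                             "pos": [5_100_000, 4_900_000]})
        r = coloc.postfilter_and_assign([_dummy_result(0.9, pos=5_000_000)], loci=loci)[0]
        assert r.locus_id == "L1"


class TestScanGwasColoc:
    def _setup(self, genotypes, gwas_min_p, q):
        from sceqtlkit.datatypes import GwasSumstats
        from scipy import stats as ss

        eg = EGeneResult("G", "ctx", genotypes.variants["id"].iloc[30], 0.5, 0.1,
                         1e-8, 0.3, 100, 1e-3, 1000, fdr_q=q)
        nom = pd.DataFrame({
            "variant": genotypes.variants["id"],
            "beta": np.full(genotypes.n_variants, 0.1),
            "se": np.full(genotypes.n_variants, 0.1),
        })
        z = ss.norm.isf(gwas_min_p / 2)
        table = genotypes.variants.copy()
        table["beta"] = 0.01
        table["se"] = 0.1
        table.loc[30, "beta"] = z * 0.1
        table["p"] = 2 * ss.norm.sf(np.abs(table["beta"] / table["se"]))
        table["n"] = 1000
        gwas = GwasSumstats(table=table, trait="T")
        return eg, {("ctx", "G"): nom}, gwas

    def test_gwas_suggestive_gate(self, genotypes):
        eg, noms, gwas = self._setup(genotypes, 6e-5, 0.01)
        assert coloc.scan_gwas_coloc([eg], noms, gwas, genotypes.variants) == []
        eg, noms, gwas = self._setup(genotypes, 4e-5, 0.01)
        assert len(coloc.scan_gwas_coloc([eg], noms, gwas, genotypes.variants)) == 1

    def test_egene_fdr_gate(self, genotypes):
        eg, noms, gwas = self._setup(genotypes, 1e-8, 0.06)
        assert coloc.scan_gwas_coloc([eg], noms, gwas, genotypes.variants) == []

    def test_min_shared_variants(self, genotypes):
        eg, noms, gwas = self._setup(genotypes, 1e-8, 0.01)
        with pytest.warns(UserWarning, match="shared variants"):
            out = coloc.scan_gwas_coloc([eg], noms, gwas, genotypes.variants, min_shared=1000)
        assert out == []
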