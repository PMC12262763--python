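"""cis-eQTL scan: OLS oracles, candidate windows, permutation calibration, FDR, conditioning."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from sceqtlkit import cis_eqtl, synthdata
from sceqtlkit.cis_eqtl import CovariateSet
from sceqtlkit.datatypes import AnnotationContext, PseudobulkMatrix


def _pb_from_vector(y, donors, gene="G"):
    expr = pd.DataFrame({gene: y}, index=donors)
    return PseudobulkMatrix(
        context=AnnotationContext("all_cells", "ALL", "cross_site"),
        expr=expr, cells_per_donor=pd.Series(10, index=donors),
    )


class TestCisCandidates:
    def test_window_boundaries_inclusive(self):
        gt = synthdata.simulate_genotypes(50, 3, seed=1)
        gt.variants["pos"] = [3_999_999, 4_000_001, 5_000_000]
        gt.variants["id"] = [f"v{p}" for p in gt.variants["pos"]]
        out = cis_eqtl.cis_candidates(5_000_000, gt, "chr1")
        assert "v3999999" not in set(out["id"])
        assert "v4000001" in set(out["id"])

    def test_maf_computation_and_strict_threshold(self):
        gt = synthdata.simulate_genotypes(4, 2, seed=2)
        gt.dosage = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [2.0, 1.0]])
        out = cis_eqtl.cis_candidates(gt.variants["pos"][0], gt, "chr1", min_maf=0.05)
        row = out[out["index"] == 0]
        assert row["maf"].iloc[0] == pytest.approx(0.375)
        # second variant has MAF 1/8 = 0.125 > 0.05; check strictness at the boundary
        out2 = cis_eqtl.cis_candidates(gt.variants["pos"][0], gt, "chr1", min_maf=0.125)
        assert 1 not in set(out2["index"])

    def test_unknown_tss_rejected(self, genotypes):
        with pytest.raises(ValueError):
            cis_eqtl.cis_candidates(float("nan"), genotypes, "chr1")


class TestNominalScan:
    def test_exact_fit_recovers_slope(self, genotypes):
        donors = genotypes.donors
        y = 2.0 * genotypes.dosage[:, 5]
        pb = _pb_from_vector(y, donors)
        out = cis_eqtl.nominal_scan(
            pb, genotypes, CovariateSet.empty(len(donors)), "G",
            gene_tss=int(genotypes.variants["pos"][5]), chrom="chr1",
        )
        hit = out[out["variant"] == genotypes.variants["id"][5]].iloc[0]
        assert hit["beta"] == pytest.approx(2.0, abs=1e-10)
        assert hit["p"] < 1e-100

    def test_matches_statsmodels_ols(self, genotypes, gt_pcs):
        """Full-model beta/se/p agree with an independent OLS fit per variant."""
        rng = np.random.default_rng(5)
        donors = genotypes.donors[:10]
        rows = list(range(10))
        y = rng.normal(size=10)
        pb = _pb_from_vector(y, donors)
        cov = CovariateSet(gt_pcs[rows, :2], np.empty((10, 0)))
        out = cis_eqtl.nominal_scan(
            pb, genotypes_sub(genotypes, rows), cov, "G",
            gene_tss=int(genotypes.variants["pos"][0]), chrom="chr1", min_maf=0.01,
        )
        C = cov.matrix()
        for _, r in out.head(8).iterrows():
            g = genotypes.dosage[np.ix_(rows, [list(genotypes.variants["id"]).index(r["variant"])])]
            X = sm.add_constant(np.hstack([g, C]))
            fit = sm.OLS(y, X).fit()
            assert r["beta"] == pytest.approx(fit.params[1], abs=1e-10)
            assert r["se"] == pytest.approx(fit.bse[1], abs=1e-10)
            assert r["p"] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_beta_equals_partial_correlation_identity(self, genotypes):
        """On standardized inputs beta equals correlation times the SD ratio."""
        rng = np.random.default_rng(6)
        donors = genotypes.donors[:10]
        y = rng.normal(size=10)
        pb = _pb_from_vector(y, donors)
        out = cis_eqtl.nominal_scan(
            pb, genotypes_sub(genotypes, range(10)), CovariateSet.empty(10), "G",
            gene_tss=int(genotypes.variants["pos"][0]), chrom="chr1", min_maf=0.01,
        )
        for _, r in out.head(5).iterrows():
            g = genotypes.dosage[:10, list(genotypes.variants["id"]).index(r["variant"])]
            yc, gc = y - y.mean(), g - g.mean()
            corr = np.corrcoef(yc, gc)[0, 1]
            assert r["beta"] == pytest.approx(corr * yc.std() / gc.std(), abs=1e-10)

    def test_null_pvalues_uniform_across_genes(self, genotypes):
        rng = np.random.default_rng(7)
        donors = genotypes.donors
        ps = []
        for _ in range(200):
            y = rng.normal(size=len(donors))
            pb = _pb_from_vector(y, donors)
            out = cis_eqtl.nominal_scan(
                pb, genotypes, CovariateSet.empty(len(donors)), "G",
                gene_tss=int(genotypes.variants["pos"][0]), chrom="chr1",
            )
            ps.append(out["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_rank_deficient_design_rejected(self, genotypes):
        donors = genotypes.donors
        bad = np.ones((len(donors), 2))
        cov = CovariateSet(bad, np.empty((len(donors), 0)))
        pb = _pb_from_vector(np.random.default_rng(1).normal(size=len(donors)), donors)
        with pytest.raises(ValueError, match="rank-deficient"):
            cis_eqtl.nominal_scan(pb, genotypes, cov, "G",
                                  gene_tss=int(genotypes.variants["pos"][0]), chrom="chr1")


def genotypes_sub(gt, rows):
    from sceqtlkit.datatypes import GenotypeMatrix

    rows = list(rows)
    return GenotypeMatrix(
        donors=[gt.donors[i] for i in rows],
        variants=gt.variants.copy(),
        dosage=gt.dosage[rows],
        sim_params=gt.sim_params,
    )


class TestPermutationScan:
    def test_empirical_p_floor_convention(self, genotypes):
        """A strong signal below every permutation minimum gives p = 1/(B+1)."""
        y = 2.0 * genotypes.dosage[:, 5] + np.random.default_rng(2).normal(0, 0.1, len(genotypes.donors))
        pb = _pb_from_vector(y, genotypes.donors)
        res = cis_eqtl.permutation_scan(
            "G", pb, genotypes, CovariateSet.empty(len(genotypes.donors)),
            n_perm=999, seed=3, gene_tss=int(genotypes.variants["pos"][5]), chrom="chr1",
        )
        assert res.p_perm == pytest.approx(1 / 1000)

    def test_null_calibration(self, genotypes):
        rng = np.random.default_rng(4)
        ps = []
        for rep in range(100):
            y = rng.normal(size=len(genotypes.donors))
            pb = _pb_from_vector(y, genotypes.donors)
            res = cis_eqtl.permutation_scan(
                "G", pb, genotypes, CovariateSet.empty(len(genotypes.donors)),
                n_perm=150, seed=rep, gene_tss=int(genotypes.variants["pos"][20]), chrom="chr1",
            )
            ps.append(res.p_perm)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_beta_approximation_close_to_empirical(self, genotypes):
        rng = np.random.default_rng(8)
        diffs = []
        for rep in range(30):
            y = rng.normal(size=len(genotypes.donors)) + 0.15 * genotypes.dosage[:, 10] * (rep % 2)
            pb = _pb_from_vector(y, genotypes.donors)
            emp = cis_eqtl.permutation_scan(
                "G", pb, genotypes, CovariateSet.empty(len(genotypes.donors)),
                n_perm=1000, seed=rep, gene_tss=int(genotypes.variants["pos"][10]), chrom="chr1",
            )
            approx = cis_eqtl.permutation_scan(
                "G", pb, genotypes, CovariateSet.empty(len(genotypes.donors)),
                n_perm=1000, seed=rep, beta_approx=True,
                gene_tss=int(genotypes.variants["pos"][10]), chrom="chr1",
            )
            diffs.append(abs(approx.p_beta - emp.p_perm))
        assert np.median(diffs) < 0.02
        assert max(diffs) < 0.06

    def test_perm_count_validation(self, genotypes):
        pb = _pb_from_vector(np.random.default_rng(0).normal(size=len(genotypes.donors)), genotypes.donors)
        with pytest.raises(ValueError):
            cis_eqtl.permutation_scan("G", pb, genotypes, CovariateSet.empty(len(genotypes.donors)),
                                      n_perm=5, gene_tss=1_000_000, chrom="chr1")
        with pytest.warns(UserWarning):
            cis_eqtl.permutation_scan("G", pb, genotypes, CovariateSet.empty(len(genotypes.donors)),
                                      n_perm=50, gene_tss=1_000_000, chrom="chr1")


class TestCallEgenesFdr:
    def test_hand_computed_bh(self):
        results = [
            cis_eqtl.EGeneResult(f"g{i}", "c", "v", 0, 1, p, 0.2, 50, p, 100)
            for i, p in enumerate([0.001, 0.02, 0.04, 0.5])
        ]
        table = cis_eqtl.call_egenes_fdr(results, fdr=0.05)
        assert table["is_egene"].tolist() == [True, True, False, False]

    def test_all_ones_and_single_gene(self):
        rs = [cis_eqtl.EGeneResult("g", "c", "v", 0, 1, 1.0, 0.2, 50, 1.0, 100)]
        assert not cis_eqtl.call_egenes_fdr(rs)["is_egene"].any()
        rs = [cis_eqtl.EGeneResult("g", "c", "v", 0, 1, 0.04, 0.2, 50, 0.04, 100)]
        assert cis_eqtl.call_egenes_fdr(rs)["is_egene"].all()

    def test_empty_input(self):
        assert len(cis_eqtl.call_egenes_fdr([])) == 0


class TestSelectExpressionPcs:
    def test_grid_truncated_by_degrees_of_freedom(self, genotypes, contexts, gt_pcs):
        pb = contexts["all_cells:ALL:cross_site"]
        small = PseudobulkMatrix(context=pb.context, expr=pb.expr.iloc[:35],
                                 cells_per_donor=pb.cells_per_donor.iloc[:35])
        genes = pd.DataFrame({"gene": [], "tss": [], "chrom": []})
        # n=35 with 5 genotype PCs: feasible K < 28, i.e. grid caps at 26
        rows = [genotypes.donors.index(d) for d in small.donors]
        with pytest.raises(ValueError):
            cis_eqtl.select_expression_pcs(small, genotypes, gt_pcs[rows], genes, grid=[30, 40])
        k, counts = cis_eqtl.select_expression_pcs(
            small, genotypes, gt_pcs[rows],
            pd.DataFrame({"gene": ["GENE0000"], "tss": [1_050_000], "chrom": ["chr1"]}),
            grid=range(2, 101, 2), n_perm=20,
        )
        assert counts["k"].max() <= 26

    def test_tie_breaks_to_fewest_covariates(self, genotypes, contexts, gt_pcs, gene_table):
        pb = contexts["all_cells:ALL:cross_site"]
        rows = [genotypes.donors.index(d) for d in pb.donors]
        k, counts = cis_eqtl.select_expression_pcs(
            pb, genotypes, gt_pcs[rows], gene_table.head(3), grid=[2, 4], n_perm=30, seed=1,
        )
        best = counts["n_egenes"].max()
        assert k == counts[counts["n_egenes"] == best]["k"].min()


class TestForwardConditional:
    def _egene(self, pb, genotypes, cov, tss):
        res = cis_eqtl.permutation_scan("G", pb, genotypes, cov, n_perm=200, seed=0,
                                        gene_tss=tss, chrom="chr1")
        res.fdr_q = res.p_perm
        return res

    def test_two_independent_signals_recovered(self, genotypes):
        """Two strong planted variants in different LD blocks give two signals."""
        rng = np.random.default_rng(10)
        hits = 0
        v1, v2 = 5, 40  # different blocks (block size 6)
        assert np.corrcoef(genotypes.dosage[:, v1], genotypes.dosage[:, v2])[0, 1] ** 2 < 0.1
        for rep in range(10):
            y = (0.5 * genotypes.dosage[:, v1] + 0.5 * genotypes.dosage[:, v2]
                 + rng.normal(0, 0.45, len(genotypes.donors)))
            pb = _pb_from_vector(y, genotypes.donors)
            cov = CovariateSet.empty(len(genotypes.donors))
            eg = self._egene(pb, genotypes, cov, int(genotypes.variants["pos"][20]))
            sigs = cis_eqtl.forward_conditional(
                eg, pb, genotypes, cov, alpha_stop=0.05,
                gene_tss=int(genotypes.variants["pos"][20]), chrom="chr1", n_perm=200, seed=rep,
            )
            hits += len(sigs) == 2
        assert hits >= 9

    def test_single_signal_stops_after_one(self, genotypes):
        rng = np.random.default_rng(11)
        hits = 0
        for rep in range(10):
            y = 0.5 * genotypes.dosage[:, 12] + rng.normal(0, 0.8, len(genotypes.donors))
            pb = _pb_from_vector(y, genotypes.donors)
            cov = CovariateSet.empty(len(genotypes.donors))
            eg = self._egene(pb, genotypes, cov, int(genotypes.variants["pos"][12]))
            sigs = cis_eqtl.forward_conditional(
                eg, pb, genotypes, cov, alpha_stop=0.05,
                gene_tss=int(genotypes.variants["pos"][12]), chrom="chr1", n_perm=200, seed=rep,
            )
            hits += len(sigs) == 1
        assert hits >= 9

    def test_ranks_contiguous_and_rank1_is_lead(self, genotypes):
        y = 0.8 * genotypes.dosage[:, 12] + np.random.default_rng(1).normal(0, 0.5, len(genotypes.donors))
        pb = _pb_from_vector(y, genotypes.donors)
        cov = CovariateSet.empty(len(genotypes.donors))
        eg = self._egene(pb, genotypes, cov, int(genotypes.variants["pos"][12]))
        sigs = cis_eqtl.forward_conditional(eg, pb, genotypes, cov, alpha_stop=0.05,
                                            gene_tss=int(genotypes.variants["pos"][12]),
                                            chrom="chr1", n_perm=100, seed=2)
        assert [s.rank for s in sigs] == list(range(1, len(sigs) + 1))
        assert sigs[0].lead_variant == eg.lead_variant
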