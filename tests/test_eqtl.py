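import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hcpnorm.eqtl import (
    CisPairTable,
    EQTLResult,
    bh_fdr,
    consistency,
    count_discoveries,
    pair_cis,
    pairwise_overlap,
    spearman_scan,
)
from hcpnorm.matrix import ExpressionMatrix, GeneAnnotation, GenotypeMatrix


def _annotation(genes):
    """genes: list of (gene_id, tss)."""
    return GeneAnnotation(
        pd.DataFrame(
            {
                "chrom": ["chr1"] * len(genes),
                "tss": [t for _, t in genes],
                "strand": ["+"] * len(genes),
                "length_bp": [1000] * len(genes),
                "gc_fraction": [0.5] * len(genes),
            },
            index=pd.Index([g for g, _ in genes], name="gene_id"),
        )
    )


def _genotypes(snps, dosages):
    """snps: list of (snp_id, pos); dosages: subjects x snps."""
    dosages = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(
        dosages,
        [f"s{i}" for i in range(dosages.shape[0])],
        [s for s, _ in snps],
        pd.DataFrame(
            {"chrom": ["chr1"] * len(snps), "pos": [p for _, p in snps]},
            index=pd.Index([s for s, _ in snps], name="snp_id"),
        ),
    )


class TestPairCis:
    def test_window_boundary_inclusive(self):
        ann = _annotation([("gA", 1_000_000)])
        geno = _genotypes(
            [("in", 1_100_000), ("out", 1_100_001)], np.tile([0.0, 1.0], (4, 1))
        )
        pairs = pair_cis(ann, geno, window=100_000)
        assert list(pairs.table["snp_id"]) == ["in"]
        assert pairs.table["distance_bp"].iloc[0] == 100_000

    def test_snp_assigned_to_closest_gene_only(self):
        ann = _annotation([("gA", 1_000_000), ("gB", 1_100_000)])
        # SNP 40 kb from gA's TSS, 60 kb from gB's
        geno = _genotypes([("snp", 1_040_000)], np.zeros((3, 1)))
        pairs = pair_cis(ann, geno)
        assert list(pairs.table["gene_id"]) == ["gA"]

    def test_equidistant_tie_goes_to_lower_tss(self):
        ann = _annotation([("gHigh", 1_100_000), ("gLow", 1_000_000)])
        geno = _genotypes([("snp", 1_050_000)], np.zeros((3, 1)))
        pairs = pair_cis(ann, geno)
        assert list(pairs.table["gene_id"]) == ["gLow"]

    def test_signed_distance(self):
        ann = _annotation([("g", 1_000_000)])
        geno = _genotypes([("up", 990_000), ("down", 1_010_000)], np.zeros((2, 2)))
        pairs = pair_cis(ann, geno).table.set_index("snp_id")
        assert pairs.loc["up", "distance_bp"] == -10_000
        assert pairs.loc["down", "distance_bp"] == 10_000


class TestSpearmanScan:
    def _expr(self, values, gene_ids):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(values, [f"s{i}" for i in range(values.shape[0])], gene_ids)

    def _pairs(self, items):
        return CisPairTable(pd.DataFrame(items, columns=["gene_id", "snp_id", "distance_bp"]))

    def test_expression_equal_to_dosage_gives_rho_one(self):
        dos = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 2], dtype=float)
        expr = self._expr(dos[:, None], ["g"])
        geno = _genotypes([("snp", 1_000_000)], dos[:, None])
        res = spearman_scan(expr, geno, self._pairs([("g", "snp", 0)]))
        assert res.table["rho"].iloc[0] == pytest.approx(1.0)

    def test_six_subject_rho_matches_pearson_on_ranks(self, rng):
        dos = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        vals = rng.standard_normal(6)
        expr = self._expr(vals[:, None], ["g"])
        geno = _genotypes([("snp", 1)], dos[:, None])
        res = spearman_scan(expr, geno, self._pairs([("g", "snp", 0)]))
        expected, _ = stats.pearsonr(stats.rankdata(dos), stats.rankdata(vals))
        assert res.table["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        # monotone 5-subject pair: one-in-120 two-sided -> p = 2/120
        dos = np.array([0, 0, 1, 1, 2], dtype=float)
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expr = self._expr(vals[:, None], ["g"])
        geno = _genotypes([("snp", 1)], dos[:, None])
        res = spearman_scan(expr, geno, self._pairs([("g", "snp", 0)]))
        # ties in dosage enlarge the tail set: 2 signs x 2! x 2! within-tie
        # rearrangements of the extreme ordering -> exactly 8 of 120 perms
        rho = res.table["rho"].iloc[0]
        p = res.table["p"].iloc[0]
        assert rho == pytest.approx(stats.spearmanr(dos, vals).statistic)
        assert p == pytest.approx(8 / 120)

    def test_permuted_dosage_usually_null(self, rng):
        n = 50
        vals = rng.standard_normal(n)
        dos = rng.permutation(np.repeat([0.0, 1.0, 2.0], [20, 20, 10]))
        expr = self._expr(vals[:, None], ["g"])
        geno = _genotypes([("snp", 1)], dos[:, None])
        res = spearman_scan(expr, geno, self._pairs([("g", "snp", 0)]))
        assert abs(res.table["rho"].iloc[0]) < 0.35
        assert res.table["p"].iloc[0] > 0.01

    def test_monomorphic_and_sparse_pairs_dropped(self):
        vals = np.arange(10.0)
        dos = np.column_stack([np.ones(10), np.r_[[0, 1], [np.nan] * 8]])
        expr = self._expr(vals[:, None], ["g"])
        geno = _genotypes([("mono", 1), ("sparse", 2)], dos)
        res = spearman_scan(
            expr, geno, self._pairs([("g", "mono", 0), ("g", "sparse", 0)])
        )
        assert len(res.table) == 0
        assert len(res.dropped) == 2

    def test_missing_dosages_use_pairwise_complete(self):
        vals = np.arange(8.0)
        dos = vals.copy()
        dos[[1, 5]] = np.nan
        expr = self._expr(vals[:, None], ["g"])
        geno = _genotypes([("snp", 1)], np.clip(dos, 0, 2)[:, None])
        res = spearman_scan(expr, geno, self._pairs([("g", "snp", 0)]))
        assert len(res.table) == 1  # 6 informative subjects suffice

    def test_invariant_under_monotone_transform(self, rng):
        n, g = 30, 5
        vals = rng.standard_normal((n, g))
        dos = rng.integers(0, 3, size=(n, g)).astype(float)
        expr = self._expr(vals, [f"g{j}" for j in range(g)])
        transformed = self._expr(np.exp(vals * 2.0) + 5.0, expr.gene_ids)
        snps = [(f"snp{j}", j + 1) for j in range(g)]
        geno = _genotypes(snps, dos)
        pairs = self._pairs([(f"g{j}", f"snp{j}", 0) for j in range(g)])
        r1 = spearman_scan(expr, geno, pairs)
        r2 = spearman_scan(transformed, geno, pairs)
        assert np.allclose(r1.table["rho"], r2.table["rho"], atol=1e-12)
        assert np.allclose(r1.table["p"], r2.table["p"], atol=1e-12)


class TestBHFdr:
    def test_worked_stepup_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_matches_bruteforce_stepup(self, rng):
        p = rng.uniform(1e-6, 1, size=37)
        m = len(p)
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.clip(q_sorted, 0, 1)
        assert np.allclose(bh_fdr(p), expected, atol=1e-12)

    def test_all_equal_p(self):
        assert np.allclose(bh_fdr(np.full(5, 0.2)), 0.2)

    def test_single_p(self):
        assert bh_fdr(np.array([0.07]))[0] == pytest.approx(0.07)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([1.5]))


def _result(genes, snps, qs, ps=None):
    ps = qs if ps is None else ps
    return EQTLResult(
        pd.DataFrame({"gene_id": genes, "snp_id": snps, "rho": 0.5, "p": ps, "q": qs})
    )


class TestDiscoveriesAndOverlap:
    def test_counts_from_bh_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]))
        res = _result(list("abcd"), list("wxyz"), q)
        counts = count_discoveries(res)
        assert counts[0.05] == {"pairs": 3, "genes": 3}
        assert counts[0.01] == {"pairs": 0, "genes": 0}

    def test_empty_result(self):
        res = _result([], [], [])
        assert count_discoveries(res)[0.10] == {"pairs": 0, "genes": 0}

    def test_counts_monotone_in_level(self, rng):
        q = rng.uniform(0, 1, 50)
        res = _result([f"g{i}" for i in range(50)], [f"s{i}" for i in range(50)], q)
        counts = count_discoveries(res, levels=(0.01, 0.05, 0.10, 0.5))
        pair_counts = [counts[x]["pairs"] for x in (0.01, 0.05, 0.10, 0.5)]
        assert pair_counts == sorted(pair_counts)

    def test_overlap_identical_and_disjoint(self):
        a = _result(["g1", "g2"], ["s1", "s2"], [0.05, 0.05])
        b = _result(["g3", "g4"], ["s3", "s4"], [0.05, 0.05])
        m = pairwise_overlap([a, a], level=0.10)
        assert np.allclose(m, 1.0)
        m = pairwise_overlap([a, b], level=0.10)
        assert m[0, 1] == 0.0 and m[1, 0] == 0.0 and m[0, 0] == 1.0

    def test_overlap_nested_sets(self):
        sub = _result(["g1"], ["s1"], [0.05])
        sup = _result(["g1", "g2", "g3"], ["s1", "s2", "s3"], [0.05] * 3)
        m = pairwise_overlap([sub, sup], level=0.10)
        assert m[0, 1] == pytest.approx(1.0)
        assert m[1, 0] == pytest.approx(1 / 3)

    def test_empty_discovery_set_is_nan(self):
        none = _result(["g1"], ["s1"], [0.9])
        some = _result(["g1"], ["s1"], [0.05])
        m = pairwise_overlap([none, some], level=0.10)
        assert np.isnan(m[0, 0]) and np.isnan(m[0, 1])


class TestConsistency:
    def test_identical_vectors(self, rng):
        p = pd.Series(rng.uniform(0, 1, 20), index=[f"k{i}" for i in range(20)])
        rho, ci = consistency(p, p)
        assert rho == pytest.approx(1.0)
        assert ci[0] <= 1.0 <= ci[1] + 1e-12

    def test_reversed_ranking(self):
        p = pd.Series(np.linspace(0.01, 0.99, 15), index=[f"k{i}" for i in range(15)])
        rho, _ = consistency(p, 1 - p)
        assert rho == pytest.approx(-1.0)

    def test_matches_scipy_on_shared_keys(self, rng):
        keys = [f"k{i}" for i in range(30)]
        a = pd.Series(rng.uniform(0, 1, 30), index=keys)
        b = pd.Series(rng.uniform(0, 1, 30), index=keys[:20] + [f"x{i}" for i in range(10)])
        rho, ci = consistency(a, b)
        shared = a.index.intersection(b.index)
        expected, _ = stats.spearmanr(a.loc[shared], b.loc[shared])
        assert rho == pytest.approx(expected)
        assert ci[0] < rho < ci[1]

    def test_too_few_shared_keys(self):
        a = pd.Series([0.1] * 5, index=list("abcde"))
        with pytest.raises(ValueError, match="shared"):
            consistency(a, a)

    def test_gene_level_p_is_min_over_snps(self):
        res = _result(["g1", "g1", "g2"], ["s1", "s2", "s3"], [0.5, 0.5, 0.5], ps=[0.3, 0.1, 0.2])
        gp = res.gene_pvalues()
        assert gp["g1"] == 0.1 and gp["g2"] == 0.2
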