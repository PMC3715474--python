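"""cis-eQTL evaluation: cis pairing, Spearman scan, BH FDR, consistency.

A cis-eQTL here is a SNP within `window` bp (default 100 kb, inclusive) of a
gene's transcription start site whose dosage associates with that gene's
(residual) expression by Spearman rank correlation. SNPs falling inside the
window of several genes are assigned only to the closest gene. Multiple
testing is controlled with Benjamini–Hochberg FDR over all tested pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, GeneAnnotation, GenotypeMatrix

__all__ = [
    "CisPairTable",
    "EQTLResult",
    "pair_cis",
    "spearman_scan",
    "bh_fdr",
    "count_discoveries",
    "consistency",
    "pairwise_overlap",
]

logger = logging.getLogger(__name__)


@dataclass
class CisPairTable:
    """Gene–SNP cis pairings with signed TSS-relative distance (pos − tss)."""

    table: pd.DataFrame  # columns gene_id, snp_id, distance_bp
    window: int = 100_000

    def __post_init__(self) -> None:
        t = self.table
        if (t["distance_bp"].abs() > self.window).any():
            raise ValueError("pair with |distance| exceeding the window")
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"SNP {dup!r} paired with more than one gene")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class EQTLResult:
    """Per-pair Spearman rho, p-value and BH q-value."""

    table: pd.DataFrame  # columns gene_id, snp_id, rho, p, q
    dropped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    def discoveries(self, level: float) -> pd.DataFrame:
        return self.table[self.table["q"] <= level]

    def gene_pvalues(self) -> pd.Series:
        """Gene-level p-value: minimum over the gene's tested cis-SNPs."""
        return self.table.groupby("gene_id")["p"].min()


def pair_cis(
    annotation: GeneAnnotation,
    genotypes: GenotypeMatrix,
    window: int = 100_000,
) -> CisPairTable:
    """Pair each SNP with genes whose TSS lies within `window` bp (inclusive).

    A SNP within the window of several genes is assigned to the gene with
    the smallest |pos − tss|; equidistant ties go to the lower TSS, then the
    lexicographically smaller gene id.
    """
    ann = annotation.table
    snp_pos = genotypes.snp_positions
    gene_chroms = set(ann["chrom"])
    snp_chroms = set(snp_pos["chrom"])
    if gene_chroms != snp_chroms:
        logger.warning(
            "chromosome name mismatch: %d gene-only, %d snp-only",
            len(gene_chroms - snp_chroms),
            len(snp_chroms - gene_chroms),
        )
    rows = []
    for chrom, snps in snp_pos.groupby("chrom", sort=False):
        genes = ann[ann["chrom"] == chrom]
        if genes.empty:
            continue
        tss = genes["tss"].to_numpy()
        gids = genes.index.to_numpy()
        for snp_id, pos in zip(snps.index, snps["pos"].to_numpy()):
            dist = pos - tss
            in_win = np.abs(dist) <= window
            if not in_win.any():
                continue
            cand = sorted(
                zip(np.abs(dist[in_win]), tss[in_win], gids[in_win], dist[in_win]),
                key=lambda r: (r[0], r[1], r[2]),
            )
            _, _, gid, d = cand[0]
            rows.append((gid, snp_id, int(d)))
    table = pd.DataFrame(rows, columns=["gene_id", "snp_id", "distance_bp"])
    return CisPairTable(table=table, window=window)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry0 = ry - ry.mean()
    denom = np.sqrt((ry0**2).sum()) * np.sqrt(len(x))
    count = total = 0
    for perm in itertools.permutations(ry0):
        rho = float(rx @ np.asarray(perm)) / denom
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman_scan(
    residual: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    pairs: CisPairTable,
    exact_below_n: int = 8,
) -> EQTLResult:
    """Spearman association of each cis pair over subjects with observed dosage.

    Ties get mid-ranks; two-sided p-values come from the t-approximation
    except for very small samples (n < exact_below_n), where the exact
    permutation null is enumerated. Pairs with fewer than 3 informative
    subjects or a monomorphic SNP are dropped and logged.
    """
    if len(pairs) == 0:
        raise ValueError("empty cis pair table")
    shared = [s for s in residual.subject_ids if s in set(genotypes.subject_ids)]
    if not shared:
        raise ValueError("no shared subjects between expression and genotypes")
    e_idx = [residual.subject_ids.index(s) for s in shared]
    g_idx = [genotypes.subject_ids.index(s) for s in shared]
    expr = residual.values[e_idx]
    dos = genotypes.dosages[g_idx]
    gene_pos = {g: i for i, g in enumerate(residual.gene_ids)}
    snp_pos = {s: i for i, s in enumerate(genotypes.snp_ids)}

    rows, dropped = [], []
    for gene_id, snp_id in zip(pairs.table["gene_id"], pairs.table["snp_id"]):
        if gene_id not in gene_pos or snp_id not in snp_pos:
            dropped.append(f"{gene_id}/{snp_id}: absent from matrices")
            continue
        y = expr[:, gene_pos[gene_id]]
        x = dos[:, snp_pos[snp_id]]
        ok = ~np.isnan(x)
        x, y = x[ok], y[ok]
        if len(x) < 3:
            dropped.append(f"{gene_id}/{snp_id}: <3 informative subjects")
            continue
        if np.all(x == x[0]) or np.all(y == y[0]):
            dropped.append(f"{gene_id}/{snp_id}: monomorphic or constant")
            continue
        rho, p = stats.spearmanr(x, y)
        if len(x) < exact_below_n:
            p = _exact_spearman_p(x, y, rho)
        p = max(float(p), np.finfo(float).tiny)  # keep p in (0, 1]
        rows.append((gene_id, snp_id, float(rho), min(p, 1.0)))
    for msg in dropped:
        logger.info("dropped pair %s", msg)
    table = pd.DataFrame(rows, columns=["gene_id", "snp_id", "rho", "p"])
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else np.empty(0)
    return EQTLResult(table=table, dropped=dropped)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values q_(i) = min_{j≥i} m·p_(j)/j, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def count_discoveries(
    result: EQTLResult,
    levels: tuple[float, ...] = (0.01, 0.05, 0.10),
) -> dict[float, dict[str, int]]:
    """Number of significant pairs (and distinct genes among them) per FDR level."""
    out = {}
    for level in levels:
        disc = result.discoveries(level)
        out[level] = {"pairs": int(len(disc)), "genes": int(disc["gene_id"].nunique())}
    return out


def consistency(
    pvals_a: pd.Series,
    pvals_b: pd.Series,
    min_shared: int = 10,
) -> tuple[float, tuple[float, float]]:
    """Cross-dataset consistency: Spearman rho of two p-value vectors on shared keys.

    Returns the correlation and its 90% confidence interval via the Fisher
    z-transform.
    """
    shared = pvals_a.index.intersection(pvals_b.index)
    n = len(shared)
    if n < min_shared:
        raise ValueError(f"only {n} shared keys (< {min_shared})")
    rho, _ = stats.spearmanr(pvals_a.loc[shared], pvals_b.loc[shared])
    rho = float(rho)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.95)
    ci = (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))
    return rho, ci


def pairwise_overlap(
    results: list[EQTLResult],
    level: float = 0.10,
) -> np.ndarray:
    """Fraction of one method's discoveries re-discovered by another.

    Entry (i, j) = |D_i ∩ D_j| / |D_i| where D is the set of significant
    (gene, SNP) pairs at `level`; NaN where D_i is empty.
    """
    if len(results) < 2:
        raise ValueError("need at least two result sets")
    sets = [
        set(zip(r.discoveries(level)["gene_id"], r.discoveries(level)["snp_id"]))
        for r in results
    ]
    n = len(sets)
    out = np.full((n, n), np.nan)
    for i in range(n):
        if not sets[i]:
            continue
        for j in range(n):
            out[i, j] = len(sets[i] & sets[j]) / len(sets[i])
    return out
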