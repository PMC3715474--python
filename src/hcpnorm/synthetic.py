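"""Seeded generators of synthetic datasets with the model's assumed structure.

The generative scheme mirrors the residual framework itself: log-scale
expression is known-covariate effects F·beta, plus hidden-covariate effects
Z·B in which the hidden covariates are correlated with the known ones
(Z = F·U + factor noise), plus optional co-expressed gene modules, plus
optional planted cis-genetic effects, plus Gaussian noise. Every draw comes
from a seeded generator; expression, genotype and label streams are
decoupled, so regenerating one component leaves the others bit-identical.

Default scales put the hidden confounder at roughly 50–70% of per-gene
variance — the broad-trend regime in which normalization matters most.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import KnownCovariates
from .eqtl import CisPairTable
from .matrix import ExpressionMatrix, GeneAnnotation, GenotypeMatrix

__all__ = [
    "SyntheticTruth",
    "generate_annotation",
    "generate_expression",
    "generate_genotypes",
    "plant_eqtls",
    "generate_function_labels",
]

logger = logging.getLogger(__name__)

# distinct sub-stream tags so the component streams stay independent
_STREAM_EXPR, _STREAM_GENO, _STREAM_EQTL, _STREAM_LABELS, _STREAM_ANN = range(5)


@dataclass
class SyntheticTruth:
    """Planted parameters behind a synthetic dataset, for recovery tests."""

    F_true: np.ndarray  # n × m known covariates
    U_true: np.ndarray  # m × k covariate-to-factor map
    Z_true: np.ndarray  # n × k hidden covariates (= F·U + factor noise)
    B_true: np.ndarray  # k × g hidden-covariate loadings
    beta_true: np.ndarray  # m × g direct known-covariate effects
    module_assignments: dict[str, int] = field(default_factory=dict)  # gene → module (unassigned absent)
    module_signal: np.ndarray | None = None  # n × g module component of Y
    eqtl_effects: dict[str, tuple[str, float]] = field(default_factory=dict)  # snp → (gene, effect)
    factor_noise_sd: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0


def generate_annotation(
    g: int,
    seed: int = 0,
    chrom: str = "chr1",
    tss_spacing: int = 1_000_000,
) -> GeneAnnotation:
    """Synthetic gene annotation on one chromosome, TSSs evenly spaced.

    The default 1 Mb spacing keeps 100 kb cis windows disjoint between
    genes, so cis SNP assignment is unambiguous.
    """
    rng = np.random.default_rng([seed, _STREAM_ANN])
    tss = tss_spacing * np.arange(1, g + 1)
    lengths = np.maximum(200, rng.lognormal(mean=7.5, sigma=0.8, size=g)).astype(int)
    gc = rng.uniform(0.3, 0.7, size=g)
    strand = rng.choice(["+", "-"], size=g)
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "tss": tss,
            "strand": strand,
            "length_bp": lengths,
            "gc_fraction": gc,
        },
        index=pd.Index([f"G{i:04d}" for i in range(g)], name="gene_id"),
    )
    return GeneAnnotation(table)


def generate_expression(
    n: int = 60,
    g: int = 200,
    m: int = 3,
    k: int = 2,
    beta_scale: float = 0.3,
    b_scale: float = 1.0,
    factor_noise_sd: float = 1.0,
    noise_sd: float = 1.0,
    n_modules: int = 0,
    module_size: int = 30,
    module_scale: float = 1.2,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, KnownCovariates, SyntheticTruth]:
    """Simulate log-scale expression from the residual framework's own model.

    Y = F·beta + Z·B + module signal + N(0, noise_sd²), with hidden
    covariates Z = F·U + N(0, factor_noise_sd²) partially predictable from
    the known covariates F. Modules (disjoint gene blocks sharing one
    activity per subject, scaled by module_scale) model co-functional
    co-expression; set n_modules=0 to disable.
    """
    if not 1 <= k <= min(n, g):
        raise ValueError(f"k must be in [1, min(n, g)]={min(n, g)}")
    if m < 1:
        raise ValueError("m must be >= 1")
    if n_modules * module_size > g:
        raise ValueError("modules do not fit: n_modules * module_size > g")
    rng = np.random.default_rng([seed, _STREAM_EXPR])
    F = rng.standard_normal((n, m))
    F = (F - F.mean(axis=0)) / F.std(axis=0, ddof=1)
    U = rng.standard_normal((m, k)) / np.sqrt(m)
    Z = F @ U + factor_noise_sd * rng.standard_normal((n, k))
    B = b_scale * rng.standard_normal((k, g))
    beta = beta_scale * rng.standard_normal((m, g))
    Y = F @ beta + Z @ B + noise_sd * rng.standard_normal((n, g))

    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(g)]
    subject_ids = [f"S{i:03d}" for i in range(n)]

    module_assignments: dict[str, int] = {}
    module_signal = np.zeros((n, g))
    if n_modules > 0:
        activity = rng.standard_normal((n, n_modules))
        order = rng.permutation(g)
        for mod in range(n_modules):
            genes = order[mod * module_size : (mod + 1) * module_size]
            module_signal[:, genes] = module_scale * activity[:, [mod]]
            for gi in genes:
                module_assignments[gene_ids[gi]] = mod
        Y = Y + module_signal

    expr = ExpressionMatrix(Y, subject_ids, gene_ids, standardized=False)
    cov = KnownCovariates(F, subject_ids, [f"F{j}" for j in range(m)], standardized=True)
    truth = SyntheticTruth(
        F_true=F, U_true=U, Z_true=Z, B_true=B, beta_true=beta,
        module_assignments=module_assignments,
        module_signal=module_signal if n_modules else None,
        factor_noise_sd=factor_noise_sd, noise_sd=noise_sd, seed=seed,
    )
    return expr, cov, truth


def generate_genotypes(
    n: int,
    annotation: GeneAnnotation,
    snps_per_gene: int = 2,
    maf_range: tuple[float, float] = (0.1, 0.5),
    window: int = 100_000,
    seed: int = 0,
    subject_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Independent Binomial(2, maf) dosages with SNPs placed in each gene's cis window."""
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng([seed, _STREAM_GENO])
    snp_ids, chroms, poss = [], [], []
    for gene_id, row in annotation.table.iterrows():
        offsets = rng.integers(-window, window + 1, size=snps_per_gene)
        for j, off in enumerate(sorted(offsets)):
            snp_ids.append(f"snp_{gene_id}_{j}")
            chroms.append(row["chrom"])
            poss.append(max(1, int(row["tss"]) + int(off)))
    s = len(snp_ids)
    maf = rng.uniform(lo, hi, size=s)
    dosages = rng.binomial(2, maf, size=(n, s)).astype(float)
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(n)]
    pos_df = pd.DataFrame({"chrom": chroms, "pos": poss}, index=pd.Index(snp_ids, name="snp_id"))
    return GenotypeMatrix(dosages, list(subject_ids), snp_ids, pos_df)


def plant_eqtls(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    pairs: CisPairTable,
    fraction_of_genes: float = 0.3,
    effect_size: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, tuple[str, float]]]:
    """Add a cis-genetic effect (effect_size × dosage) to a fraction of genes.

    For each selected gene one of its cis SNPs is chosen at random; genes
    without any cis SNP are skipped with a log entry. Returns the modified
    expression and the truth map snp_id → (gene_id, effect_size).
    """
    rng = np.random.default_rng([seed, _STREAM_EQTL])
    snps_by_gene: dict[str, list[str]] = {}
    for gene_id, snp_id in zip(pairs.table["gene_id"], pairs.table["snp_id"]):
        snps_by_gene.setdefault(gene_id, []).append(snp_id)
    n_target = int(fraction_of_genes * expr.n_genes)
    chosen = rng.permutation(expr.gene_ids)[:n_target]
    snp_index = {s: i for i, s in enumerate(genotypes.snp_ids)}
    gene_index = {gid: i for i, gid in enumerate(expr.gene_ids)}
    Y = expr.values.copy()
    truth: dict[str, tuple[str, float]] = {}
    for gene_id in chosen:
        cands = snps_by_gene.get(gene_id)
        if not cands:
            logger.info("gene %s has no cis SNP; skipped", gene_id)
            continue
        snp_id = cands[int(rng.integers(len(cands)))]
        dos = genotypes.dosages[:, snp_index[snp_id]]
        dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        Y[:, gene_index[gene_id]] += effect_size * dos
        truth[snp_id] = (gene_id, effect_size)
    return expr.with_values(Y), truth


def generate_function_labels(
    module_assignments: dict[str, int],
    all_genes: list[str],
    terms_per_module: int = 2,
    size_range: tuple[int, int] = (15, 25),
    purity: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Function-term annotation table with terms anchored on planted modules.

    Each term draws round(purity × size) genes from one module and the rest
    from outside it. Returns a (gene_id, term_id, evidence) table with
    evidence 'EXP' throughout, ready for `filter_labels`.
    """
    if not module_assignments:
        raise ValueError("no modules to anchor terms on")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size_range")
    rng = np.random.default_rng([seed, _STREAM_LABELS])
    by_module: dict[int, list[str]] = {}
    for gene, mod in module_assignments.items():
        by_module.setdefault(mod, []).append(gene)
    rows = []
    for mod in sorted(by_module):
        members = sorted(by_module[mod])
        outside = sorted(set(all_genes) - set(members))
        for t in range(terms_per_module):
            size = int(rng.integers(lo, hi + 1))
            n_in = round(purity * size)
            if n_in > len(members):
                raise ValueError(
                    f"term size {size} at purity {purity} needs {n_in} genes "
                    f"but module {mod} has only {len(members)}"
                )
            n_out = size - n_in
            if n_out > len(outside):
                raise ValueError("not enough genes outside the module")
            genes = list(rng.choice(members, n_in, replace=False))
            if n_out:
                genes += list(rng.choice(outside, n_out, replace=False))
            term_id = f"TERM_{mod}_{t}"
            rows.extend((gene, term_id, "EXP") for gene in genes)
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "evidence"])
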