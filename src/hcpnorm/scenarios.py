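"""Benchmark scenarios: fixed synthetic study conditions for the two evaluations.

These functions wire the synthetic generator to the normalizers and the two
evaluation pipelines under one fixed set of conditions each, so that tests,
examples and the reproduction script all measure the same thing:

* a confounded cis-eQTL scenario (planted cis effects under a strong hidden
  confounder partially correlated with the known covariates),
* a co-expression scenario (planted co-functional modules under the same
  kind of confounder),
* a null FDR-calibration scenario (no planted genetic effects at all).

Method settings follow the published operating points: 10 principal
components for SVD removal, 20 HCP factors; the HCP penalties
(λ1 = 20, λ2 = 5, λ3 = 1) are one fixed setting shared by both tasks,
standing in for the per-task cross-validation procedure (see docs).
"""

from __future__ import annotations

import numpy as np

from .coexpression import cross_validated_aup, filter_labels, pearson_network
from .eqtl import count_discoveries, pair_cis, spearman_scan
from .hcp import HCPParams, hcp_fit, hcp_residual
from .matrix import standardize_genes
from .normalize import residual_known, ridge_fit, svd_remove
from .synthetic import (
    generate_annotation,
    generate_expression,
    generate_function_labels,
    generate_genotypes,
    plant_eqtls,
)

__all__ = [
    "EQTL_METHODS",
    "confounded_eqtl_discoveries",
    "module_coexpression_aup",
    "null_fdr_calibration",
]

SVD_K = 10  # principal components removed for the cis-eQTL task
HCP_PARAMS = HCPParams(k=20, lambda1=20.0, lambda2=5.0, lambda3=1.0, tol=1e-6, max_iter=500)
RIDGE_LAMBDA = 1.0
NETWORK_POWER = 6.0  # soft-threshold exponent for co-expression networks
PROPAGATION_ALPHA = 0.5

EQTL_METHODS = ("raw", "ridge", "svd", "hcp")


def _normalized_versions(Ys, F, seed: int) -> dict:
    """Residuals from each normalization method, on gene-standardized input."""
    params = HCPParams(**{**HCP_PARAMS.__dict__, "seed": seed})
    rfit = ridge_fit(Ys, F, RIDGE_LAMBDA)
    _, svd_resid = svd_remove(Ys, SVD_K)
    model = hcp_fit(Ys, F, params)
    return {
        "raw": Ys,
        "ridge": residual_known(Ys, rfit, F),
        "svd": svd_resid,
        "hcp": hcp_residual(Ys, model),
    }


def confounded_eqtl_discoveries(
    seed: int,
    n: int = 60,
    g: int = 80,
    fdr_level: float = 0.10,
    effect_size: float = 1.0,
    fraction_with_eqtl: float = 0.4,
):
    """cis-eQTL discovery counts per normalization method under confounding.

    Expression carries a strong broad hidden confounder (partially explained
    by the known covariates) plus planted cis effects on a fraction of
    genes. Returns ({method: pairs discovered at fdr_level}, truth map).
    """
    ann = generate_annotation(g, seed=seed)
    expr, F, _ = generate_expression(
        n=n, g=g, m=3, k=2, beta_scale=0.3, b_scale=1.0,
        factor_noise_sd=1.0, noise_sd=1.0, seed=seed,
    )
    geno = generate_genotypes(n, ann, snps_per_gene=2, seed=seed, subject_ids=expr.subject_ids)
    pairs = pair_cis(ann, geno)
    expr, truth = plant_eqtls(
        expr, geno, pairs, fraction_of_genes=fraction_with_eqtl,
        effect_size=effect_size, seed=seed,
    )
    Ys = standardize_genes(expr)
    residuals = _normalized_versions(Ys, F, seed)
    counts = {}
    for method, resid in residuals.items():
        result = spearman_scan(resid, geno, pairs)
        counts[method] = count_discoveries(result, levels=(fdr_level,))[fdr_level]["pairs"]
    return counts, truth


def module_coexpression_aup(
    seed: int,
    n: int = 60,
    g: int = 200,
    n_modules: int = 5,
    module_size: int = 30,
):
    """Mean AUP of gene-function prediction per normalization method.

    Expression carries planted co-expression modules (the biological signal)
    plus a broad hidden confounder; function terms are anchored on the
    modules. Compares the uncorrected baseline, SVD at the cis-eQTL
    operating point (k=10), and HCP at its cis-eQTL settings — the
    robustness question of whether removing hidden covariates tuned for
    eQTL detection destroys co-expression signal.
    """
    expr, F, truth = generate_expression(
        n=n, g=g, m=3, k=2, beta_scale=0.3, b_scale=1.0,
        factor_noise_sd=1.0, noise_sd=1.0,
        n_modules=n_modules, module_size=module_size, module_scale=1.2,
        seed=seed,
    )
    ann_table = generate_function_labels(
        truth.module_assignments, expr.gene_ids,
        terms_per_module=2, size_range=(15, 25), purity=0.9, seed=seed,
    )
    labels = filter_labels(ann_table, min_size=10, max_size=50, exclude_codes=set())
    Ys = standardize_genes(expr)
    versions = _normalized_versions(Ys, F, seed)
    aups = {}
    for method in ("raw", "svd", "hcp"):
        net = pearson_network(versions[method], transform="abs", power=NETWORK_POWER)
        mean_aup, _ = cross_validated_aup(
            net, labels, folds=5, seed=seed, alpha=PROPAGATION_ALPHA
        )
        aups[method] = mean_aup
    return aups


def null_fdr_calibration(
    seed: int,
    reps: int = 100,
    n: int = 50,
    g: int = 100,
    snps_per_gene: int = 2,
    level: float = 0.10,
):
    """Empirical FDR of the Spearman/BH scan on fully null data.

    Each replicate draws pure-noise expression and independent genotypes
    (g × snps_per_gene cis pairs, no planted effects), runs the scan, and
    records the false-discovery proportion R/max(R,1) — every discovery is
    false by construction. Returns (mean FDP, Monte-Carlo SE, per-rep FDPs).
    """
    rng = np.random.default_rng([seed, 90210])
    ann = generate_annotation(g, seed=seed)
    fdps = []
    for _ in range(reps):
        sub = int(rng.integers(0, 2**31 - 1))
        expr, _, _ = generate_expression(
            n=n, g=g, m=1, k=1, beta_scale=0.0, b_scale=0.0,
            factor_noise_sd=0.0, noise_sd=1.0, seed=sub,
        )
        geno = generate_genotypes(
            n, ann, snps_per_gene=snps_per_gene, seed=sub, subject_ids=expr.subject_ids
        )
        pairs = pair_cis(ann, geno)
        result = spearman_scan(expr, geno, pairs)
        r = int((result.table["q"] <= level).sum())
        fdps.append(r / max(r, 1))
    fdps = np.asarray(fdps, dtype=float)
    mc_se = fdps.std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0
    return float(fdps.mean()), float(mc_se), fdps
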