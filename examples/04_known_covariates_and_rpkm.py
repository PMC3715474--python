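"""Build the three known technical covariates and log2-RPKM from counts.

Simulates a count matrix via the generator's Poisson-free log-normal path,
then derives per-subject sequencing depth, GC bias and gene-length bias —
the columns of the known-covariate matrix F — and RPKM expression.
"""

import numpy as np

from hcpnorm import CountMatrix, filter_expressed, log_transform, rpkm, technical_covariates
from hcpnorm.synthetic import generate_annotation

rng = np.random.default_rng(7)
n, g = 12, 300
ann = generate_annotation(g, seed=7)
# counts with a per-subject depth factor and mild GC-dependent bias
depth_factor = rng.uniform(0.5, 2.0, size=n)[:, None]
gc = ann.table["gc_fraction"].to_numpy()[None, :]
lam = 80 * depth_factor * np.exp(0.8 * (gc - 0.5) * rng.standard_normal((n, 1)))
counts = CountMatrix(rng.poisson(lam), [f"s{i}" for i in range(n)], ann.gene_ids)

kept = filter_expressed(counts, min_reads=30, min_subjects=10)
print(f"expressed-gene filter (>=30 reads in >=10 subjects): {kept.n_genes}/{g} genes kept")

cov = technical_covariates(kept, ann)
print("known covariate matrix F:", cov.values.shape, "columns:", cov.names)

log_expr = log_transform(kept)
rpkm_expr = rpkm(kept, ann)
r = np.corrcoef(cov.values[:, 0], np.log(kept.counts.sum(axis=1)))[0, 1]
print(f"depth covariate vs log total reads, correlation: {r:.3f}")
print(f"log2 RPKM range: [{rpkm_expr.values.min():.2f}, {rpkm_expr.values.max():.2f}]")
# Depth enters RPKM as a shared offset per subject; the regression-based
# normalizers instead let depth affect each gene with its own coefficient.
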