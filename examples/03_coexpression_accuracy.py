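"""Function prediction from co-expression networks after normalization.

Plants five co-expressed gene modules (the biological signal) under a broad
hidden confounder, builds a soft-thresholded |Pearson| network from each
normalized version, and scores gene-function prediction by label propagation
(mean area under the precision-recall curve, 5-fold CV). Unguided removal of
10 principal components strips the modules along with the confounder; HCP's
covariate prior removes only the confounder.
"""

from hcpnorm.scenarios import module_coexpression_aup

aups = module_coexpression_aup(seed=7)

print("mean AUP of gene-function prediction (prior ~ 0.10):")
for method, label in [("raw", "no correction"), ("svd", "remove 10 PCs"), ("hcp", "HCP")]:
    print(f"  {label:>14}: {aups[method]:.3f}")
# svd below raw reproduces the robustness failure of unguided PC removal;
# hcp above raw shows prior-guided removal preserves module structure.
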