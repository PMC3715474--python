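"""Compare normalization methods on cis-eQTL detection power.

Plants cis-genetic effects on 40% of genes under a strong hidden confounder
and counts Spearman/BH discoveries at 10% FDR after each normalization:
no correction, ridge on known covariates, removal of 10 principal
components, and HCP. Removing hidden covariates recovers associations the
confounder was masking.
"""

from hcpnorm.scenarios import confounded_eqtl_discoveries

counts, truth = confounded_eqtl_discoveries(seed=7)

print(f"planted cis-eQTLs: {len(truth)} of 160 tested gene-SNP pairs")
print("discoveries at 10% FDR by normalization method:")
for method in ("raw", "ridge", "svd", "hcp"):
    print(f"  {method:>6}: {counts[method]:3d}")
print(f"fold increase hcp vs raw: {counts['hcp'] / max(counts['raw'], 1):.1f}x")
# Higher counts mean more of the planted effects survive multiple-testing
# correction once confounder-driven rank noise is removed.
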