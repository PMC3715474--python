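# hcpnorm

Residual normalization of RNA-seq expression matrices with **known and
hidden covariates**, centered on the HCP model (Hidden Covariates with
Prior), for analysts who need expression data cleaned of technical and
broad unwanted biological variation before eQTL mapping or co-expression
analysis.

## The model

Log-scale expression Y (subjects × genes) is modeled as

    Y = F·beta + Z·B + E

with known subject-level covariates F (sequencing depth, per-subject GC and
gene-length bias, …), inferred hidden covariates Z, per-gene effect
matrices beta and B, and Gaussian noise E. Normalized expression is the
residual after removing estimated covariate effects. The package provides
the classical special cases — ridge on known covariates, truncated-SVD
(principal component) removal, and their alternating combination — and the
HCP estimator, which ties the hidden covariates to the known ones through a
Gaussian prior Z ~ N(F·U, 1/λ1):

    min  ‖Y − Z·B‖² + λ1‖Z − F·U‖² + λ2‖B‖² + λ3‖U‖²

solved by closed-form block coordinate descent (monotone, seconds on a
laptop-scale panel). Large λ1 removes only covariate-like patterns; small
λ1 behaves like unguided factor removal. Two evaluation pipelines are
included: a cis-eQTL scan (100 kb TSS windows, Spearman, Benjamini–Hochberg
FDR) and a co-expression accuracy test (|Pearson| network, label
propagation, mean area under the precision–recall curve over function
terms), plus a seeded synthetic-data generator so everything is testable
without downloads.

## Worked example

`examples/02_cis_eqtl_comparison.py` plants cis-eQTLs on 40% of 80 genes
under a strong hidden confounder and compares discovery counts:

```
planted cis-eQTLs: 32 of 160 tested gene-SNP pairs
discoveries at 10% FDR by normalization method:
     raw:  21
   ridge:  24
     svd:  28
     hcp:  36
fold increase hcp vs raw: 1.7x
```

Raw data misses planted effects because the confounder perturbs the
expression ranks; ridge removes only what the measured covariates explain;
removing 10 principal components does better but also eats signal; HCP
removes the confounder while its prior protects gene-specific variation.
The complementary robustness check, `examples/03_coexpression_accuracy.py`,
scores gene-function prediction from co-expression networks built on the
same kind of data with planted co-expressed modules:

```
mean AUP of gene-function prediction (prior ~ 0.10):
   no correction: 0.318
   remove 10 PCs: 0.121
             HCP: 0.415
```

Unguided PC removal strips the modules along with the confounder, falling
below the uncorrected baseline, while HCP at the same operating point does
not. `examples/01_hcp_normalization.py` shows the fit diagnostics
(objective trace, share of removed variance explained by known covariates)
and `examples/04_known_covariates_and_rpkm.py` the covariate construction
and log2-RPKM path.

A thin CLI mirrors the pipeline stages:

```bash
hcpnorm simulate --n 60 --genes 200 --eqtl-fraction 0.3 --seed 1 --outdir sim/
hcpnorm normalize --expression sim/expression.tsv --covariates sim/covariates.tsv \
    --method hcp --k 20 --lambda1 20 --lambda2 5 --out sim/residual.tsv
hcpnorm eqtl --residual sim/residual.tsv --dosages sim/dosages.tsv \
    --snp-map sim/snp_map.tsv --annotation sim/annotation.tsv --out sim/eqtl.tsv
```

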