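"""Construction of subject-level known technical covariates and RPKM.

The three covariates used throughout — sequencing depth, per-subject GC bias
and per-subject gene-length bias — are the columns of the known-covariate
matrix F (subjects × m, m = 3 when only these are used).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ExpressionMatrix, GeneAnnotation

__all__ = [
    "KnownCovariates",
    "sequencing_depth",
    "gc_bias_covariate",
    "length_bias_covariate",
    "rpkm",
    "assemble_covariates",
]


@dataclass
class KnownCovariates:
    """Subjects × m matrix F of known covariates."""

    values: np.ndarray
    subject_ids: list[str]
    names: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("covariate values must be finite")
        n, m = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject label count does not match covariate rows")
        if len(self.names) != m:
            raise ValueError("covariate name count does not match columns")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.names)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="subject_id")

    @classmethod
    def from_tsv(cls, path, standardized: bool = False) -> "KnownCovariates":
        t = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=t.to_numpy(dtype=float),
            subject_ids=[str(s) for s in t.index],
            names=[str(c) for c in t.columns],
            standardized=standardized,
        )


def sequencing_depth(counts: CountMatrix) -> np.ndarray:
    """Total mapped reads per subject (row sums), in reads."""
    if counts.counts.size == 0:
        raise ValueError("empty count matrix")
    return counts.counts.sum(axis=1).astype(float)


def _per_subject_correlation(expr: ExpressionMatrix, regressor: np.ndarray, what: str) -> np.ndarray:
    """Pearson correlation of each subject's per-gene log counts with a per-gene regressor."""
    x = np.asarray(regressor, dtype=float)
    if x.std() == 0:
        raise ValueError(f"constant regressor: {what} does not vary across genes")
    xc = x - x.mean()
    y = expr.values - expr.values.mean(axis=1, keepdims=True)
    denom = np.sqrt((y**2).sum(axis=1)) * np.sqrt((xc**2).sum())
    if (denom == 0).any():
        raise ValueError("subject with constant expression: correlation undefined")
    return (y @ xc) / denom


def gc_bias_covariate(expr: ExpressionMatrix, annotation: GeneAnnotation) -> np.ndarray:
    """Per-subject GC bias: correlation of a subject's per-gene log counts with percent GC.

    Measures the per-subject variation in log read counts explainable by GC
    content; GC bias varies by sequencing lane, hence acts as a
    subject-specific covariate. Expects log-scale, unstandardized expression.
    """
    gc = annotation.column("gc_fraction", expr.gene_ids) * 100.0
    return _per_subject_correlation(expr, gc, "GC content")


def length_bias_covariate(expr: ExpressionMatrix, annotation: GeneAnnotation) -> np.ndarray:
    """Per-subject length bias: correlation of per-gene log counts with gene length (bp)."""
    length = annotation.column("length_bp", expr.gene_ids).astype(float)
    return _per_subject_correlation(expr, length, "gene length")


def rpkm(counts: CountMatrix, annotation: GeneAnnotation, pseudocount: float = 0.5) -> ExpressionMatrix:
    """log2 RPKM: reads per kilobase of gene length per million mapped reads.

    value(s, g) = log2((count + pc) / (depth_s / 1e6) / (length_g / 1e3))
                = log2(count + pc) - log2(depth_s / 1e6) - log2(length_g / 1e3)

    i.e. depth and length enter as per-subject and per-gene additive offsets
    in log space — the special case of the known-covariate regression in
    which sequencing depth has the same coefficient for every gene.
    """
    depth = sequencing_depth(counts)
    if (depth <= 0).any():
        bad = counts.subject_ids[int(np.argmax(depth <= 0))]
        raise ValueError(f"zero sequencing depth for subject {bad!r}")
    length = annotation.column("length_bp", counts.gene_ids).astype(float)
    values = (
        np.log2(counts.counts + float(pseudocount))
        - np.log2(depth / 1e6)[:, None]
        - np.log2(length / 1e3)[None, :]
    )
    return ExpressionMatrix(
        values=values,
        subject_ids=list(counts.subject_ids),
        gene_ids=list(counts.gene_ids),
        standardized=False,
    )


def assemble_covariates(
    columns: dict[str, np.ndarray],
    subject_ids: list[str],
    standardize: bool = True,
) -> KnownCovariates:
    """Column-bind named subject-level vectors into a KnownCovariates matrix.

    Columns are standardized to zero mean / unit SD by default so that
    ridge-type penalties act on comparable scales.
    """
    n = len(subject_ids)
    vecs = []
    for name, v in columns.items():
        if isinstance(v, pd.Series):
            if [str(s) for s in v.index] != [str(s) for s in subject_ids]:
                raise ValueError(f"covariate {name!r}: subject order does not match")
            v = v.to_numpy()
        v = np.asarray(v, dtype=float).ravel()
        if v.shape[0] != n:
            raise ValueError(f"covariate {name!r} has length {v.shape[0]}, expected {n}")
        vecs.append(v)
    values = np.column_stack(vecs)
    if standardize:
        sd = values.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = list(columns)[int(np.argmax(sd == 0))]
            raise ValueError(f"constant covariate column {bad!r} cannot be standardized")
        values = (values - values.mean(axis=0)) / sd
    return KnownCovariates(
        values=values,
        subject_ids=list(subject_ids),
        names=list(columns),
        standardized=standardize,
    )


def technical_covariates(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    log_expr: ExpressionMatrix | None = None,
    standardize: bool = True,
) -> KnownCovariates:
    """The standard three-covariate matrix: depth, GC bias, length bias."""
    if log_expr is None:
        from .matrix import log_transform

        log_expr = log_transform(counts)
    return assemble_covariates(
        {
            "sequencing_depth": sequencing_depth(counts),
            "gc_bias": gc_bias_covariate(log_expr, annotation),
            "length_bias": length_bias_covariate(log_expr, annotation),
        },
        subject_ids=list(counts.subject_ids),
        standardize=standardize,
    )
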