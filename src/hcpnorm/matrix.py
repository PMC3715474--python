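"""Core containers and expression preprocessing.

All matrices are oriented subjects × genes (rows are subjects, columns are
genes); every operation validates label lengths against this convention.
Counts are mapped reads aggregated per gene; expression is log-scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "GeneAnnotation",
    "GenotypeMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "filter_expressed",
    "log_transform",
    "standardize_genes",
]


def _check_labels(labels, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} id: {lab!r}")
        seen.add(lab)
    return labels


@dataclass
class CountMatrix:
    """Subjects × genes matrix of nonnegative integer read counts."""

    counts: np.ndarray
    subject_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional (subjects x genes)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts).astype(np.int64)
            if not np.allclose(self.counts, as_int, atol=0, rtol=0):
                raise ValueError("counts must be whole numbers")
            self.counts = as_int
        if (self.counts < 0).any():
            s, g = np.argwhere(self.counts < 0)[0]
            raise ValueError(f"negative count at subject row {s}, gene column {g}")
        self.subject_ids = _check_labels(self.subject_ids, "subject")
        self.gene_ids = _check_labels(self.gene_ids, "gene")
        n, g = self.counts.shape
        if len(self.subject_ids) != n or len(self.gene_ids) != g:
            raise ValueError(
                f"label counts ({len(self.subject_ids)} subjects, "
                f"{len(self.gene_ids)} genes) do not match matrix shape {self.counts.shape}"
            )

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.subject_ids, columns=self.gene_ids)


@dataclass
class ExpressionMatrix:
    """Subjects × genes real matrix of log-scale expression (the Y of the model)."""

    values: np.ndarray
    subject_ids: list[str]
    gene_ids: list[str]
    standardized: bool = False
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional (subjects x genes)")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite (missing values unsupported)")
        self.subject_ids = _check_labels(self.subject_ids, "subject")
        self.gene_ids = _check_labels(self.gene_ids, "gene")
        n, g = self.values.shape
        if len(self.subject_ids) != n or len(self.gene_ids) != g:
            raise ValueError("label counts do not match matrix shape")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, standardized: bool | None = None) -> "ExpressionMatrix":
        return replace(
            self,
            values=values,
            standardized=self.standardized if standardized is None else standardized,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.gene_ids)


@dataclass
class GeneAnnotation:
    """Per-gene annotation: chromosome, TSS (1-based), strand, length and GC.

    Backed by a DataFrame indexed by gene_id with columns
    chrom, tss, strand, length_bp, gc_fraction.
    """

    table: pd.DataFrame

    REQUIRED = ("chrom", "tss", "strand", "length_bp", "gc_fraction")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate gene id in annotation: {dup!r}")
        if (t["tss"] < 1).any():
            raise ValueError("tss must be >= 1 (1-based coordinates)")
        if (t["length_bp"] < 1).any():
            raise ValueError("length_bp must be >= 1")
        if ((t["gc_fraction"] < 0) | (t["gc_fraction"] > 1)).any():
            raise ValueError("gc_fraction must lie in [0, 1]")
        bad = set(t["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"strand must be '+' or '-', got {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.table.index]

    def subset(self, gene_ids: list[str]) -> "GeneAnnotation":
        missing = [g for g in gene_ids if g not in self.table.index]
        if missing:
            raise KeyError(f"gene missing from annotation: {missing[0]!r}")
        return GeneAnnotation(self.table.loc[gene_ids])

    def column(self, name: str, gene_ids: list[str]) -> np.ndarray:
        """Values of one annotation column aligned to gene_ids; errors on missing genes."""
        return self.subset(gene_ids).table[name].to_numpy()

    @classmethod
    def from_tsv(cls, path) -> "GeneAnnotation":
        t = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        t = t.set_index("gene_id")
        return cls(t)

    @classmethod
    def from_bed(cls, path) -> "GeneAnnotation":
        """BED6 + length_bp + gc_fraction columns; 0-based start → 1-based TSS by strand."""
        t = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "gene_id", "score", "strand", "length_bp", "gc_fraction"],
            dtype={"chrom": str, "gene_id": str},
        )
        # BED start is 0-based; the TSS is the 5' end, which depends on strand.
        tss = np.where(t["strand"] == "+", t["start"] + 1, t["end"])
        out = pd.DataFrame(
            {
                "chrom": t["chrom"].to_numpy(),
                "tss": tss.astype(int),
                "strand": t["strand"].to_numpy(),
                "length_bp": t["length_bp"].to_numpy(dtype=int),
                "gc_fraction": t["gc_fraction"].to_numpy(dtype=float),
            },
            index=pd.Index(t["gene_id"].to_numpy(), name="gene_id"),
        )
        return cls(out)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GenotypeMatrix:
    """Subjects × SNPs dosage matrix (0/1/2; NaN = missing) with SNP positions."""

    dosages: np.ndarray
    subject_ids: list[str]
    snp_ids: list[str]
    snp_positions: pd.DataFrame  # index snp_id, columns chrom, pos (1-based)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional (subjects x snps)")
        vals = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        self.subject_ids = _check_labels(self.subject_ids, "subject")
        self.snp_ids = _check_labels(self.snp_ids, "snp")
        n, s = self.dosages.shape
        if len(self.subject_ids) != n or len(self.snp_ids) != s:
            raise ValueError("label counts do not match dosage shape")
        pos = self.snp_positions
        if list(pos.index) != self.snp_ids:
            pos = pos.loc[self.snp_ids]
        # sort SNPs by (chrom, pos) so positions are ordered within chromosome
        order = np.lexsort((pos["pos"].to_numpy(), pos["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(s)):
            self.dosages = self.dosages[:, order]
            self.snp_ids = [self.snp_ids[i] for i in order]
            pos = pos.iloc[order]
        self.snp_positions = pos

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @classmethod
    def from_tsv(cls, dosage_path, snp_map_path) -> "GenotypeMatrix":
        d = pd.read_csv(dosage_path, sep="\t", index_col=0)
        m = pd.read_csv(snp_map_path, sep="\t", dtype={"snp_id": str, "chrom": str}).set_index("snp_id")
        return cls(
            dosages=d.to_numpy(dtype=float),
            subject_ids=[str(s) for s in d.index],
            snp_ids=[str(s) for s in d.columns],
            snp_positions=m[["chrom", "pos"]],
        )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Minimal VCF reader: GT fields of biallelic records to allele-count dosages."""
        snp_ids, chroms, poss, rows = [], [], [], []
        subjects: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    subjects = fields[9:]
                    continue
                chrom, pos, vid = fields[0], int(fields[1]), fields[2]
                fmt = fields[8].split(":")
                gt_idx = fmt.index("GT")
                dos = []
                for cell in fields[9:]:
                    gt = cell.split(":")[gt_idx].replace("|", "/")
                    if "." in gt:
                        dos.append(np.nan)
                    else:
                        dos.append(float(sum(int(a) > 0 for a in gt.split("/"))))
                snp_ids.append(vid if vid != "." else f"{chrom}:{pos}")
                chroms.append(chrom)
                poss.append(pos)
                rows.append(dos)
        pos_df = pd.DataFrame(
            {"chrom": chroms, "pos": poss}, index=pd.Index(snp_ids, name="snp_id")
        )
        return cls(np.array(rows, dtype=float).T, subjects, snp_ids, pos_df)

    def to_tsv(self, dosage_path, snp_map_path) -> None:
        pd.DataFrame(self.dosages, index=self.subject_ids, columns=self.snp_ids).to_csv(
            dosage_path, sep="\t", index_label="subject_id"
        )
        self.snp_positions.to_csv(snp_map_path, sep="\t", index_label="snp_id")


# ---------------------------------------------------------------------------
# I/O for subjects × genes tables


def _read_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", index_col=0)
    if t.isna().to_numpy().any():
        raise ValueError(f"missing values in {path}: not supported")
    for col in t.columns:
        if not np.issubdtype(t[col].dtype, np.number):
            bad = t.index[~t[col].apply(lambda x: isinstance(x, (int, float, np.number)))]
            where = f"row {bad[0]!r}" if len(bad) else "unknown row"
            raise ValueError(f"non-numeric cell in column {col!r}, {where}")
    _check_labels(t.index, "subject")
    _check_labels(t.columns, "gene")
    return t


def read_count_matrix(path) -> CountMatrix:
    """Read a TSV with header row of gene ids and first column of subject ids."""
    t = _read_table(path)
    return CountMatrix(
        counts=t.to_numpy(),
        subject_ids=[str(s) for s in t.index],
        gene_ids=[str(g) for g in t.columns],
    )


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="subject_id")


def read_expression_matrix(path, standardized: bool = False) -> ExpressionMatrix:
    t = _read_table(path)
    return ExpressionMatrix(
        values=t.to_numpy(dtype=float),
        subject_ids=[str(s) for s in t.index],
        gene_ids=[str(g) for g in t.columns],
        standardized=standardized,
    )


def write_expression_matrix(em: ExpressionMatrix, path, float_format: str = "%.10g") -> None:
    em.to_frame().to_csv(path, sep="\t", index_label="subject_id", float_format=float_format)


# ---------------------------------------------------------------------------
# Preprocessing


def filter_expressed(counts: CountMatrix, min_reads: int = 30, min_subjects: int = 10) -> CountMatrix:
    """Keep genes with at least `min_reads` reads in at least `min_subjects` subjects.

    The default (30 reads in 10 individuals) is the expressed-gene rule used
    for LCL RNA-seq panels of 60-70 subjects. Subject set and gene order are
    preserved.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if min_subjects < 1:
        raise ValueError("min_subjects must be >= 1")
    if min_subjects > counts.n_subjects:
        raise ValueError(
            f"min_subjects={min_subjects} exceeds number of subjects ({counts.n_subjects})"
        )
    keep = (counts.counts >= min_reads).sum(axis=0) >= min_subjects
    return CountMatrix(
        counts=counts.counts[:, keep],
        subject_ids=counts.subject_ids,
        gene_ids=[g for g, k in zip(counts.gene_ids, keep) if k],
    )


_LOG_BASE = {2: np.log(2.0), 10: np.log(10.0), "e": 1.0, np.e: 1.0}


def log_transform(counts: CountMatrix, pseudocount: float = 1.0, base=2) -> ExpressionMatrix:
    """log_base(count + pseudocount), returned unstandardized."""
    if base not in _LOG_BASE:
        raise ValueError(f"base must be one of 2, 'e', 10; got {base!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (counts.counts == 0).any():
        raise ValueError("log of zero: zero counts present with pseudocount=0")
    values = np.log(counts.counts + float(pseudocount)) / _LOG_BASE[base]
    return ExpressionMatrix(
        values=values,
        subject_ids=list(counts.subject_ids),
        gene_ids=list(counts.gene_ids),
        standardized=False,
    )


def standardize_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene to mean 0 and scale to unit sample SD (ddof=1).

    Constant genes are set to all-zero (not dropped, so gene indices stay
    aligned across methods) and recorded in `constant_genes` with a warning.
    """
    if expr.n_subjects < 2:
        raise ValueError("standardization requires at least 2 subjects")
    v = expr.values
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    const = sd == 0
    out = np.zeros_like(v)
    out[:, ~const] = (v[:, ~const] - mean[~const]) / sd[~const]
    constant_genes = [g for g, c in zip(expr.gene_ids, const) if c]
    if constant_genes:
        warnings.warn(
            f"{len(constant_genes)} constant gene(s) zeroed during standardization",
            stacklevel=2,
        )
    return ExpressionMatrix(
        values=out,
        subject_ids=list(expr.subject_ids),
        gene_ids=list(expr.gene_ids),
        standardized=True,
        constant_genes=constant_genes,
    )
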