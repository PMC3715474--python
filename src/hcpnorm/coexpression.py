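"""Co-expression network accuracy: Pearson network, label propagation, AUP.

A co-expression network is built from pairwise Pearson correlation of
(residual) expression across subjects; gene function is then predicted by
propagating known function labels over the network, and accuracy is scored
as the mean area under the precision–recall curve (AUP) over function terms
in 5-fold cross-validation — the guilt-by-association test of whether
normalization preserved biological co-variation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from .matrix import ExpressionMatrix

__all__ = [
    "CoexpressionNetwork",
    "FunctionLabels",
    "pearson_network",
    "filter_labels",
    "label_propagation",
    "cross_validated_aup",
]

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionNetwork:
    """Symmetric genes × genes nonnegative weight matrix with zero diagonal."""

    weights: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if not np.isfinite(W).all():
            raise ValueError("non-finite network weights")
        if not np.allclose(W, W.T):
            raise ValueError("network weights must be symmetric")
        if np.abs(np.diag(W)).max(initial=0.0) > 1e-12:
            raise ValueError("network diagonal must be zero")
        if len(self.gene_ids) != W.shape[0]:
            raise ValueError("gene label count does not match weight matrix")
        self.weights = W


@dataclass
class FunctionLabels:
    """Function-term annotations: term id → set of gene ids."""

    terms: dict[str, set[str]]
    evidence: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.terms)


_TRANSFORMS = {
    "abs": np.abs,
    "positive": lambda r: np.clip(r, 0.0, None),
    "shifted": lambda r: (r + 1.0) / 2.0,
}


def pearson_network(
    residual: ExpressionMatrix,
    transform: str = "abs",
    power: float = 1.0,
) -> CoexpressionNetwork:
    """Pairwise per-gene Pearson correlation mapped to nonnegative edge weights.

    transform: 'abs' |r| (default), 'positive' max(r, 0), 'shifted' (r+1)/2.
    `power` raises the transformed weights to a soft-threshold exponent
    (as in weighted co-expression network practice), suppressing the dense
    background of weak sample-noise correlations; 1.0 leaves weights as-is.
    Constant genes get zero rows/columns with a warning.
    """
    if power <= 0:
        raise ValueError("power must be > 0")
    if residual.n_subjects < 3:
        raise ValueError("need at least 3 subjects for a correlation network")
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    v = residual.values
    sd = v.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s) zeroed in network", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(v, rowvar=False)
    r[const, :] = 0.0
    r[:, const] = 0.0
    W = _TRANSFORMS[transform](r)
    if power != 1.0:
        W = W**power
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0  # remove numerical asymmetry
    return CoexpressionNetwork(weights=W, gene_ids=list(residual.gene_ids))


def filter_labels(
    annotations: pd.DataFrame,
    min_size: int = 30,
    max_size: int = 300,
    exclude_codes: set[str] = frozenset({"IEA"}),
) -> FunctionLabels:
    """Filter a (gene_id, term_id, evidence) annotation table to usable terms.

    Rows with excluded evidence codes (default the uncurated IEA code) are
    dropped first; a term is then kept iff its remaining gene count lies in
    [min_size, max_size] (both bounds inclusive).
    """
    required = {"gene_id", "term_id"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    ann = annotations
    if "evidence" in ann.columns and exclude_codes:
        ann = ann[~ann["evidence"].isin(exclude_codes)]
    terms: dict[str, set[str]] = {}
    for term_id, grp in ann.groupby("term_id"):
        genes = set(grp["gene_id"])
        if min_size <= len(genes) <= max_size:
            terms[str(term_id)] = {str(g) for g in genes}
    return FunctionLabels(terms=terms, evidence=annotations)


def label_propagation(
    net: CoexpressionNetwork,
    labels: np.ndarray,
    alpha: float = 0.95,
) -> np.ndarray:
    """Semi-supervised label spreading over the network.

    Solves (I − α·S)·f = (1 − α)·y with S the symmetrically degree-normalized
    weight matrix D^{-1/2} W D^{-1/2}; y holds +1 (known positives), −1
    (known negatives) and 0 (unlabeled). Isolated nodes receive (1 − α)·y.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    y = np.asarray(labels, dtype=float)
    W = net.weights
    if y.shape[0] != W.shape[0]:
        raise ValueError("label vector length does not match network size")
    deg = W.sum(axis=0)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    S = inv_sqrt[:, None] * W * inv_sqrt[None, :]
    f = np.linalg.solve(np.eye(len(y)) - alpha * S, (1.0 - alpha) * y)
    return f


def label_propagation_iterative(
    net: CoexpressionNetwork,
    labels: np.ndarray,
    alpha: float = 0.95,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Fixed-point iteration f ← α·S·f + (1 − α)·y (same solution as the solve)."""
    y = np.asarray(labels, dtype=float)
    W = net.weights
    deg = W.sum(axis=0)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    S = inv_sqrt[:, None] * W * inv_sqrt[None, :]
    f = np.zeros_like(y)
    for _ in range(max_iter):
        f_new = alpha * (S @ f) + (1.0 - alpha) * y
        if np.max(np.abs(f_new - f)) < tol:
            return f_new
        f = f_new
    return f


def aup(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision–recall curve, step-interpolated.

    Σ_i (R_i − R_{i−1})·P_i over the score-ranked list; for a single positive
    ranked r-th this equals 1/r.
    """
    return float(average_precision_score(y_true, scores))


def cross_validated_aup(
    net: CoexpressionNetwork,
    labels: FunctionLabels,
    folds: int = 5,
    seed: int = 0,
    alpha: float = 0.95,
) -> tuple[float, dict[str, float]]:
    """Mean AUP of predicting each function term by label propagation, k-fold CV.

    Per term, genes are split into stratified folds (positives = annotated
    genes, negatives = all others); training labels are ±1, held-out genes
    are 0, and the AUP is computed over held-out genes only. Terms with
    fewer than `folds` positives in the network are skipped.
    """
    gene_index = {g: i for i, g in enumerate(net.gene_ids)}
    n = len(net.gene_ids)
    per_term: dict[str, float] = {}
    for term_id, genes in sorted(labels.terms.items()):
        pos = np.zeros(n, dtype=bool)
        for g in genes:
            if g in gene_index:
                pos[gene_index[g]] = True
        if pos.sum() < folds:
            logger.info("term %s skipped: %d positives < %d folds", term_id, pos.sum(), folds)
            continue
        y_full = np.where(pos, 1.0, -1.0)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        truths, preds = [], []
        for _, test_idx in skf.split(np.zeros(n), pos.astype(int)):
            y_train = y_full.copy()
            y_train[test_idx] = 0.0
            f = label_propagation(net, y_train, alpha=alpha)
            truths.append(pos[test_idx].astype(int))
            preds.append(f[test_idx])
        per_term[term_id] = aup(np.concatenate(truths), np.concatenate(preds))
    if not per_term:
        raise ValueError("no term had enough positives for cross-validation")
    mean_aup = float(np.mean(list(per_term.values())))
    return mean_aup, per_term
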