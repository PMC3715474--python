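"""Hidden Covariates with Prior (HCP).

HCP infers k hidden covariates Z (subjects × k) and their per-gene effects
B (k × genes) while centering the hidden covariates, through a Gaussian
prior, on linear combinations F·U of the known covariates F (subjects × m).
The penalized negative log likelihood is

    obj(Z, B, U) = ‖Y − Z·B‖²_F + λ1·‖Z − F·U‖²_F + λ2·‖B‖²_F + λ3·‖U‖²_F

λ1 sets the prior strength — how strongly hidden covariates are pulled
toward patterns expressible by the known covariates; λ2 and λ3 are ridge
penalties on the effect sizes and on the covariate-to-factor map. The
objective is not jointly convex but is convex in each block with the others
fixed, so it is minimized by cyclic closed-form block coordinate descent:

    U ← (FᵀF + (λ3/λ1)·I)⁻¹ Fᵀ Z
    Z ← (Y·Bᵀ + λ1·F·U) (B·Bᵀ + λ1·I)⁻¹
    B ← (Zᵀ·Z + λ2·I)⁻¹ Zᵀ Y

each of which is the exact minimizer of the objective in its block, so the
objective is non-increasing at every update. The cleaned expression is the
residual Y − Z·B; the known covariates act only through the prior on Z and
are never subtracted directly.

With no known covariates the λ1 and λ3 terms drop and the model reduces to
a ridge-penalized rank-k matrix factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .covariates import KnownCovariates
from .matrix import ExpressionMatrix

__all__ = [
    "HCPParams",
    "HCPModel",
    "hcp_objective",
    "hcp_fit",
    "hcp_no_covariates",
    "hcp_residual",
    "variance_explained_by_known",
]


@dataclass
class HCPParams:
    """Hyperparameters of the HCP model.

    k        number of hidden covariates (default 20, the setting used for
             cis-eQTL-style analyses on ~60-70 subject panels)
    lambda1  strength of the prior tying Z to F·U (dimensionless; larger
             forces Z into the column space of F)
    lambda2  ridge penalty on the loadings B
    lambda3  ridge penalty on the covariate-to-factor map U
    tol      relative objective-change convergence threshold
    max_iter maximum coordinate-descent sweeps
    seed     seed for the (deterministic) random initialization

    The λ defaults of 1.0 are placeholders: the intended procedure is to
    choose them by cross-validation on the downstream task of interest.
    """

    k: int = 20
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if min(self.lambda1, self.lambda2, self.lambda3) <= 0:
            raise ValueError("all lambda must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class HCPModel:
    """Fitted HCP model: hidden covariates, loadings, covariate-to-factor map."""

    Z: np.ndarray  # subjects × k hidden covariates
    B: np.ndarray  # k × genes loadings
    U: np.ndarray | None  # m × k map from known covariates to hidden covariates
    params: HCPParams
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    iterations: int = 0

    def __post_init__(self) -> None:
        for name, M in (("Z", self.Z), ("B", self.B), ("U", self.U)):
            if M is not None and not np.isfinite(M).all():
                raise ValueError(f"non-finite entries in {name}")

    @property
    def removed(self) -> np.ndarray:
        """The artifactual component Z·B subtracted from the data."""
        return self.Z @ self.B


def _as_array(Y) -> np.ndarray:
    return Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, dtype=float)


def _as_cov(F) -> np.ndarray:
    return F.values if isinstance(F, KnownCovariates) else np.asarray(F, dtype=float)


def hcp_objective(Y, F, Z, B, U, params: HCPParams) -> float:
    """Evaluate the HCP objective; with F (and U) absent the prior terms drop."""
    Ym = _as_array(Y)
    if Z.shape[0] != Ym.shape[0] or B.shape[1] != Ym.shape[1] or Z.shape[1] != B.shape[0]:
        raise ValueError("shape mismatch among Y, Z, B")
    obj = np.sum((Ym - Z @ B) ** 2) + params.lambda2 * np.sum(B**2)
    if F is not None:
        Fm = _as_cov(F)
        if U is None or Fm.shape[1] != U.shape[0] or U.shape[1] != Z.shape[1]:
            raise ValueError("shape mismatch among F, U, Z")
        obj += params.lambda1 * np.sum((Z - Fm @ U) ** 2) + params.lambda3 * np.sum(U**2)
    return float(obj)


def _check_finite(M: np.ndarray, block: str, it: int) -> np.ndarray:
    if not np.isfinite(M).all():
        raise FloatingPointError(f"NaN/Inf in {block} update at iteration {it}")
    return M


def hcp_fit(Y, F, params: HCPParams | None = None) -> HCPModel:
    """Fit HCP by block coordinate descent (sweep order U → Z → B).

    Initialization is deterministic given params.seed: U⁰ is standard normal
    scaled by 1/√m and Z⁰ = F·U⁰, i.e. the start lies on the prior manifold.
    Convergence is declared when the relative objective change over one full
    sweep falls below params.tol.
    """
    if F is None:
        return hcp_no_covariates(Y, params)
    params = params or HCPParams()
    Ym, Fm = _as_array(Y), _as_cov(F)
    if isinstance(Y, ExpressionMatrix) and not Y.standardized:
        warnings.warn("expression is not gene-standardized; HCP is usually fit on standardized genes", stacklevel=2)
    n, g = Ym.shape
    if Fm.shape[0] != n:
        raise ValueError("Y and F must have the same number of subjects")
    m, k = Fm.shape[1], params.k
    l1, l2, l3 = params.lambda1, params.lambda2, params.lambda3

    rng = np.random.default_rng(params.seed)
    U = rng.standard_normal((m, k)) / np.sqrt(m)
    Z = Fm @ U
    B = np.zeros((k, g))

    FtF = Fm.T @ Fm
    eye_m, eye_k = np.eye(m), np.eye(k)
    trace = [hcp_objective(Ym, Fm, Z, B, U, params)]
    converged = False
    for it in range(1, params.max_iter + 1):
        U = _check_finite(np.linalg.solve(FtF + (l3 / l1) * eye_m, Fm.T @ Z), "U", it)
        Z = _check_finite(
            np.linalg.solve((B @ B.T + l1 * eye_k).T, (Ym @ B.T + l1 * Fm @ U).T).T, "Z", it
        )
        B = _check_finite(np.linalg.solve(Z.T @ Z + l2 * eye_k, Z.T @ Ym), "B", it)
        obj = hcp_objective(Ym, Fm, Z, B, U, params)
        trace.append(obj)
        if abs(trace[-2] - obj) <= params.tol * max(abs(obj), 1.0):
            converged = True
            break
    if not converged:
        warnings.warn(f"HCP did not converge in {params.max_iter} iterations", stacklevel=2)
    return HCPModel(
        Z=Z, B=B, U=U, params=params,
        objective_trace=np.asarray(trace), converged=converged, iterations=len(trace) - 1,
    )


def hcp_no_covariates(Y, params: HCPParams | None = None) -> HCPModel:
    """HCP with no known covariates: ridge-penalized rank-k factorization.

    The prior terms drop, leaving ‖Y − Z·B‖²_F + λ2‖B‖²_F; Z is updated by
    (pseudo-inverse) least squares and B by ridge, alternating from a seeded
    random Z⁰.
    """
    params = params or HCPParams()
    Ym = _as_array(Y)
    n, g = Ym.shape
    k, l2 = params.k, params.lambda2
    rng = np.random.default_rng(params.seed)
    Z = rng.standard_normal((n, k)) / np.sqrt(k)
    B = np.zeros((k, g))
    eye_k = np.eye(k)
    trace = [hcp_objective(Ym, None, Z, B, None, params)]
    converged = False
    for it in range(1, params.max_iter + 1):
        B = _check_finite(np.linalg.solve(Z.T @ Z + l2 * eye_k, Z.T @ Ym), "B", it)
        Z = _check_finite(Ym @ np.linalg.pinv(B), "Z", it)
        obj = hcp_objective(Ym, None, Z, B, None, params)
        trace.append(obj)
        if abs(trace[-2] - obj) <= params.tol * max(abs(obj), 1.0):
            converged = True
            break
    if not converged:
        warnings.warn(f"HCP (no covariates) did not converge in {params.max_iter} iterations", stacklevel=2)
    return HCPModel(
        Z=Z, B=B, U=None, params=params,
        objective_trace=np.asarray(trace), converged=converged, iterations=len(trace) - 1,
    )


def hcp_residual(Y, model: HCPModel):
    """Cleaned expression Y − Z·B (the hidden-covariate component removed)."""
    Ym = _as_array(Y)
    removed = model.removed
    if removed.shape != Ym.shape:
        raise ValueError(f"model shape {removed.shape} does not match Y shape {Ym.shape}")
    resid = Ym - removed
    if isinstance(Y, ExpressionMatrix):
        return Y.with_values(resid, standardized=False)
    return resid


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """Coefficient of determination of OLS of y on X (with intercept)."""
    Xc = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    ss_res = np.sum((y - Xc @ coef) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - ss_res / ss_tot)


def _augment_nonlinear(Fm: np.ndarray) -> np.ndarray:
    """Append squares and pairwise products of covariate columns."""
    cols = [Fm]
    m = Fm.shape[1]
    cols.append(Fm**2)
    for i in range(m):
        for j in range(i + 1, m):
            cols.append((Fm[:, i] * Fm[:, j])[:, None])
    return np.column_stack(cols)


def variance_explained_by_known(model: HCPModel, F, nonlinear: bool = False):
    """How much of the removed expression Z·B the known covariates explain.

    Returns (overall, per_factor): per_factor[j] is the R² of regressing
    hidden covariate Z[:, j] on F; overall is the per-factor R² weighted by
    each factor's contribution ‖B[j, :]‖² to the removed variance. With
    nonlinear=True, F is augmented with squared and pairwise-product columns
    to capture non-linear combinations of the known covariates.
    """
    if model.Z.shape[1] == 0:
        raise ValueError("model has no hidden covariates")
    Fm = _as_cov(F)
    if nonlinear:
        Fm = _augment_nonlinear(Fm)
    per_factor = np.array([_r2(model.Z[:, j], Fm) for j in range(model.Z.shape[1])])
    weights = np.sum(model.B**2, axis=1)
    total = weights.sum()
    overall = float(per_factor.mean()) if total == 0 else float((per_factor * weights).sum() / total)
    return overall, per_factor
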