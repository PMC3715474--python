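"""Special cases of the unified residual framework.

Observed log expression Y (subjects × genes) is modeled as known-covariate
effects F·beta plus hidden-covariate effects Z·W plus noise; each normalizer
estimates some of these terms and returns the residual as the cleaned signal:

* known only    — ridge regression of Y on F, residual Y − F·beta
* hidden only   — truncated SVD, residual Y minus the top-k rank approximation
* known + hidden — alternate the two until the joint objective stabilizes
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .covariates import KnownCovariates
from .matrix import ExpressionMatrix

__all__ = [
    "RidgeFit",
    "SVDFit",
    "ridge_fit",
    "residual_known",
    "svd_remove",
    "svd_plus_tech",
    "iterate_known_hidden",
]


def _as_array(Y) -> np.ndarray:
    return Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, dtype=float)


def _as_cov(F) -> np.ndarray:
    return F.values if isinstance(F, KnownCovariates) else np.asarray(F, dtype=float)


def _like(Y, values: np.ndarray):
    if isinstance(Y, ExpressionMatrix):
        return Y.with_values(values, standardized=False)
    return values


@dataclass
class RidgeFit:
    """Ridge coefficients beta (m × genes) for known covariates, with penalty lambda."""

    beta: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.isfinite(self.beta).all():
            raise ValueError("non-finite ridge coefficients")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class SVDFit:
    """Truncated SVD of an expression matrix: components (n × k), loadings (k × g)."""

    components: np.ndarray
    loadings: np.ndarray
    singular_values: np.ndarray
    k: int = field(default=0)

    def __post_init__(self) -> None:
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.k == 0:
            self.k = len(self.singular_values)
        sv = self.singular_values
        if len(sv) and (np.diff(sv) > 1e-12 * sv[0]).any():
            raise ValueError("singular values must be nonincreasing")


def ridge_fit(Y, F, lam: float = 0.0) -> RidgeFit:
    """Analytic ridge solution beta = (FᵀF + λI)⁻¹ Fᵀ Y.

    Minimizes ‖Y − F·beta‖²_F + λ‖beta‖²_F, the penalized least squares fit
    of every gene on the known covariates with one shared penalty.
    """
    Ym, Fm = _as_array(Y), _as_cov(F)
    if Ym.shape[0] != Fm.shape[0]:
        raise ValueError("Y and F must have the same number of subjects")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    m = Fm.shape[1]
    gram = Fm.T @ Fm + lam * np.eye(m)
    if lam == 0 and np.linalg.matrix_rank(Fm) < m:
        raise np.linalg.LinAlgError(
            "FᵀF is singular with lambda=0; use lambda > 0 (ridge) or drop collinear covariates"
        )
    beta = np.linalg.solve(gram, Fm.T @ Ym)
    return RidgeFit(beta=beta, lam=float(lam))


def residual_known(Y, fit: RidgeFit, F):
    """Residual Y − F·beta: expression with known-covariate effects removed."""
    Ym, Fm = _as_array(Y), _as_cov(F)
    if Fm.shape[1] != fit.beta.shape[0] or Ym.shape[1] != fit.beta.shape[1]:
        raise ValueError("shape mismatch between Y, F and fitted coefficients")
    return _like(Y, Ym - Fm @ fit.beta)


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic SVD sign: largest-|.| element of each left component positive."""
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    return U, Vt


def svd_remove(Y, k: int) -> tuple[SVDFit, ExpressionMatrix | np.ndarray]:
    """Remove the top-k principal components: residual = Y − U_k S_k V_kᵀ.

    By the Eckart–Young theorem the removed part is the best rank-k
    approximation of Y, so ‖Y‖²_F − ‖residual‖²_F = Σ_{i≤k} σᵢ².
    """
    Ym = _as_array(Y)
    n, g = Ym.shape
    if not 1 <= k <= min(n, g):
        raise ValueError(f"k must be in [1, {min(n, g)}], got {k}")
    U, s, Vt = np.linalg.svd(Ym, full_matrices=False)
    U, Vt = _fix_signs(U, Vt)
    fit = SVDFit(
        components=U[:, :k],
        loadings=s[:k, None] * Vt[:k],
        singular_values=s[:k],
        k=k,
    )
    residual = Ym - fit.components @ fit.loadings
    return fit, _like(Y, residual)


def svd_plus_tech(Y, F, lam: float, k: int):
    """Ridge removal of known covariates followed by SVD removal of k components.

    The two-step scheme: regress out F first, then strip the top principal
    components of what remains (a simplified approximation to joint
    known+hidden estimation). k=0 is a passthrough returning the ridge
    residual alone.
    """
    fit = ridge_fit(Y, F, lam)
    resid = residual_known(Y, fit, F)
    if k == 0:
        return resid
    _, resid2 = svd_remove(resid, k)
    return resid2


def iterate_known_hidden(
    Y,
    F,
    lam: float,
    k: int,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[RidgeFit, SVDFit, ExpressionMatrix | np.ndarray, np.ndarray]:
    """Jointly estimate known and hidden effects by alternating minimization.

    Minimizes ‖Y − F·beta − Z·W‖²_F + λ‖beta‖²_F over beta and a rank-k
    Z·W, by iterating (i) ridge of Y − Z·W on F and (ii) truncated SVD of
    Y − F·beta, starting from Z·W = 0 (so iteration 1 reproduces the
    two-step ridge-then-SVD scheme). Returns the two fits, the residual and
    the objective trace; the objective is non-increasing across half-steps.
    """
    Ym, Fm = _as_array(Y), _as_cov(F)
    hidden = np.zeros_like(Ym)
    trace = []
    rfit = svdfit = None
    obj_prev = np.inf
    for _ in range(max_iter):
        rfit = ridge_fit(Ym - hidden, Fm, lam)
        known = Fm @ rfit.beta
        svdfit, _ = svd_remove(Ym - known, k)
        hidden = svdfit.components @ svdfit.loadings
        obj = np.sum((Ym - known - hidden) ** 2) + lam * np.sum(rfit.beta**2)
        trace.append(obj)
        if obj_prev - obj <= tol * max(obj, 1.0):
            break
        obj_prev = obj
    else:
        warnings.warn(
            f"known+hidden alternation did not converge in {max_iter} iterations",
            stacklevel=2,
        )
    residual = Ym - Fm @ rfit.beta - hidden
    return rfit, svdfit, _like(Y, residual), np.asarray(trace)
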