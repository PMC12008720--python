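"""Exploratory factor analysis of the neuropsychological battery.

Minimum-residual (minres) extraction of two common factors from the test
correlation matrix, varimax rotation with Kaiser normalization, the usual
sampling-adequacy gates (Bartlett sphericity, KMO), approximate fit
indices (ML-discrepancy chi-square with Bartlett's correction, CFI against
the independence model, RMSEA), and Thurstone regression factor scores
with weights W = R^{-1} Lambda.

The extraction objective is the classic one: choose uniquenesses psi
minimizing the off-diagonal residuals of R - Lambda Lambda', where Lambda
comes from the rank-k eigendecomposition of R with its diagonal replaced
by the communalities 1 - psi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

__all__ = [
    "FactorModel",
    "FactorAdequacyError",
    "bartlett_sphericity",
    "kmo",
    "varimax",
    "factor_analysis",
    "thurstone_scores",
    "tucker_congruence",
]


class FactorAdequacyError(RuntimeError):
    """Raised when the data do not support a factor analysis."""


@dataclass
class FactorModel:
    loadings: pd.DataFrame            # variables x factors, varimax-rotated
    uniquenesses: pd.Series
    ss_loadings: np.ndarray           # per-factor sum of squared loadings
    variance_explained: float         # cumulative proportion of total variance
    rotation: str
    chi_square: float
    chi_square_dof: int
    chi_square_p: float
    cfi: float
    rmsea: float
    bartlett_chi2: float
    bartlett_p: float
    kmo: float
    n_obs: int
    correlation: pd.DataFrame = field(repr=False, default=None)
    means: pd.Series = field(repr=False, default=None)
    sds: pd.Series = field(repr=False, default=None)
    scores: pd.DataFrame = field(repr=False, default=None)
    factor_weights: pd.DataFrame = field(repr=False, default=None)


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, float]:
    """Bartlett's test that the correlation matrix is the identity."""
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix is singular")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    dof = p * (p - 1) // 2
    return float(chi2), float(sps.chi2.sf(chi2, dof))


def kmo(R: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy (overall)."""
    Rinv = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    q2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def _minres_loadings(R: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Minres extraction: returns (loadings p x k, uniquenesses p)."""
    p = R.shape[0]
    off = ~np.eye(p, dtype=bool)

    def loadings_for(psi: np.ndarray) -> np.ndarray:
        Rs = R.copy()
        np.fill_diagonal(Rs, 1.0 - psi)
        vals, vecs = linalg.eigh(Rs, subset_by_index=(p - k, p - 1))
        vals = np.clip(vals[::-1], 0.0, None)
        vecs = vecs[:, ::-1]
        return vecs * np.sqrt(vals)

    def objective(psi: np.ndarray) -> float:
        lam = loadings_for(psi)
        resid = R - lam @ lam.T
        return float((resid[off] ** 2).sum())

    # start from 1 - squared multiple correlation
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.01, 0.99)
    res = optimize.minimize(objective, psi0, method="L-BFGS-B",
                            bounds=[(0.005, 1.0)] * p,
                            options={"maxiter": 1000})
    psi = res.x
    return loadings_for(psi), psi


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-10,
            max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt((L ** 2).sum(axis=1)) if normalize else np.ones(p)
    h[h == 0] = 1.0
    L = L / h[:, None]
    T = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ T
        B = L.T @ (Lr ** 3 - Lr * (Lr ** 2).sum(axis=0) / p)
        U, s, Vt = np.linalg.svd(B)
        T = U @ Vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    Lr = (L @ T) * h[:, None]
    return Lr, T


def _fit_indices(R: np.ndarray, lam: np.ndarray, psi: np.ndarray, n: int,
                 ) -> tuple[float, int, float, float, float]:
    """ML-discrepancy chi-square (Bartlett-corrected), CFI, RMSEA."""
    p, k = lam.shape
    sigma = lam @ lam.T
    np.fill_diagonal(sigma, 1.0)
    sign_s, logdet_s = np.linalg.slogdet(sigma)
    sign_r, logdet_r = np.linalg.slogdet(R)
    if sign_s <= 0 or sign_r <= 0:
        raise np.linalg.LinAlgError("singular matrix in fit computation")
    F = logdet_s - logdet_r + np.trace(R @ np.linalg.inv(sigma)) - p
    F = max(F, 0.0)
    correction = n - 1 - (2 * p + 5) / 6.0 - (2 * k) / 3.0
    chi2 = correction * F
    dof = ((p - k) ** 2 - (p + k)) // 2
    pval = float(sps.chi2.sf(chi2, dof)) if dof > 0 else float("nan")
    null_chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet_r
    null_dof = p * (p - 1) / 2.0
    num = max(chi2 - dof, 0.0)
    den = max(null_chi2 - null_dof, num, np.finfo(float).tiny)
    cfi = 1.0 - num / den
    rmsea = np.sqrt(max(chi2 / dof - 1.0, 0.0) / (n - 1)) if dof > 0 else float("nan")
    return float(chi2), int(dof), pval, float(cfi), float(rmsea)


def factor_analysis(test_scores: pd.DataFrame, n_factors: int = 2,
                    min_kmo: float = 0.6, compute_scores: bool = True,
                    ) -> FactorModel:
    """Fit the rotated common-factor model to raw test scores.

    Scores are standardized internally.  The run is refused (with the
    diagnostic values) when Bartlett's sphericity test is not significant
    at 0.05 or the overall KMO falls below ``min_kmo``.
    """
    X = pd.DataFrame(test_scores).astype(float)
    n, p = X.shape
    if n < 50:
        raise ValueError(f"factor analysis requires n >= 50, got {n}")
    if p < n_factors + 1:
        raise ValueError("need more variables than factors")
    means, sds = X.mean(), X.std(ddof=1)
    if (sds == 0).any():
        raise ValueError(f"constant columns: {list(sds.index[sds == 0])}")
    Z = (X - means) / sds
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    sign, _ = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular correlation matrix")

    b_chi2, b_p = bartlett_sphericity(R, n)
    kmo_val = kmo(R)
    if b_p >= 0.05 or kmo_val < min_kmo:
        raise FactorAdequacyError(
            f"data unsuited for factor analysis: Bartlett p = {b_p:.3g} "
            f"(need < 0.05), KMO = {kmo_val:.3f} (need >= {min_kmo})")

    lam, psi = _minres_loadings(R, n_factors)
    lam_rot, _ = varimax(lam)
    # order factors by explained variance, orient dominant loadings positive
    ss = (lam_rot ** 2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    lam_rot = lam_rot[:, order]
    ss = ss[order]
    for j in range(n_factors):
        if lam_rot[np.argmax(np.abs(lam_rot[:, j])), j] < 0:
            lam_rot[:, j] = -lam_rot[:, j]

    chi2, dof, chi_p, cfi, rmsea = _fit_indices(R, lam_rot, psi, n)
    cols = [f"factor{j + 1}" for j in range(n_factors)]
    model = FactorModel(
        loadings=pd.DataFrame(lam_rot, index=X.columns, columns=cols),
        uniquenesses=pd.Series(psi, index=X.columns),
        ss_loadings=ss, variance_explained=float(ss.sum() / p),
        rotation="varimax", chi_square=chi2, chi_square_dof=dof,
        chi_square_p=chi_p, cfi=cfi, rmsea=rmsea,
        bartlett_chi2=b_chi2, bartlett_p=b_p, kmo=kmo_val, n_obs=n,
        correlation=pd.DataFrame(R, index=X.columns, columns=X.columns),
        means=means, sds=sds,
    )
    if compute_scores:
        model.scores = thurstone_scores(model, X)
    return model


def thurstone_scores(model: FactorModel, test_scores: pd.DataFrame,
                     ridge: float = 1e-8) -> pd.DataFrame:
    """Thurstone regression factor scores: Z @ (R^{-1} Lambda).

    Near-singular correlation matrices fall back to a ridge-regularized
    inverse with a warning carrying the regularization strength.
    """
    X = pd.DataFrame(test_scores).astype(float)
    if list(X.columns) != list(model.loadings.index):
        raise ValueError("test columns differ from the fitted model's")
    Z = ((X - model.means) / model.sds).to_numpy()
    R = model.correlation.to_numpy()
    lam = model.loadings.to_numpy()
    try:
        cond = np.linalg.cond(R)
        if cond > 1e10:
            raise np.linalg.LinAlgError(f"condition number {cond:.2g}")
        W = np.linalg.solve(R, lam)
    except np.linalg.LinAlgError:
        eps = ridge * np.trace(R) / R.shape[0]
        warnings.warn(f"near-singular correlation matrix; using ridge "
                      f"epsilon = {eps:.3g}", stacklevel=2)
        W = np.linalg.solve(R + eps * np.eye(R.shape[0]), lam)
    model.factor_weights = pd.DataFrame(W, index=model.loadings.index,
                                        columns=model.loadings.columns)
    return pd.DataFrame(Z @ W, index=X.index, columns=model.loadings.columns)


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-factor Tucker congruence after best sign/permutation matching.

    Returns the matched |phi| per factor of ``A`` (sorted pairing by the
    greedy maximum over the congruence cross-matrix).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("loading matrices must have equal shape")
    k = A.shape[1]
    phi = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            num = (A[:, i] * B[:, j]).sum()
            den = np.sqrt((A[:, i] ** 2).sum() * (B[:, j] ** 2).sum())
            phi[i, j] = abs(num / den) if den > 0 else 0.0
    matched = np.zeros(k)
    used: set[int] = set()
    for i in np.argsort(-phi.max(axis=1)):
        j = int(np.argmax([phi[i, j] if j not in used else -1 for j in range(k)]))
        matched[i] = phi[i, j]
        used.add(j)
    return matched
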