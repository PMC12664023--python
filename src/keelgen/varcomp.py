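"""REML variance components and heritability for GRM animal models.

Two model families:

* single-GRM:  y = Xb + u + e,  u ~ N(0, G su2),  e ~ N(0, I se2).
  Fitted exactly by rotating into the eigenbasis of G and profiling the
  REML log-likelihood over the variance ratio lambda = su2/se2 (1-D
  optimization; the residual variance has a closed form at each lambda).

* two-GRM partition:  y = Xb + u1 + u0 + e with u1 ~ N(0, G1 s1),
  u0 ~ N(0, G0 s0): average-information (AI) REML with EM fallback
  steps whenever an AI update would leave the parameter space, and
  projection onto a small positive floor at the boundary.

Standard errors come from the inverse AI matrix at the optimum; the
heritability SE uses the first-order delta method.  Variance components
are constrained non-negative by projection (boundary estimates such as
h2 -> 0 stay representable).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings

import numpy as np
from scipy import optimize

from keelgen.grm import GRM

__all__ = ["VarCompFit", "fit_reml_single", "fit_reml_two_grm", "heritability_from_components"]


@dataclasses.dataclass
class VarCompFit:
    """REML fit: variance components, SEs, heritability, convergence state."""

    sigma_u2: float
    sigma_e2: float
    se_u2: float
    se_e2: float
    h2: float
    se_h2: float
    loglik_reml: float
    converged: bool
    n_iter: int
    # two-GRM partition extras (NaN / unset for the single-GRM model)
    sigma_u1_2: float = float("nan")
    sigma_u0_2: float = float("nan")
    se_u1_2: float = float("nan")
    se_u0_2: float = float("nan")
    block_proportion: float = float("nan")
    se_block_proportion: float = float("nan")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def heritability_from_components(sigma_u2: float, sigma_e2: float) -> tuple[float, float]:
    """h2 = su2/(su2+se2) and the additive genetic SD sqrt(su2)."""
    if sigma_u2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma_u2 + sigma_e2
    if total <= 0:
        raise ValueError("variance components sum to zero")
    return sigma_u2 / total, math.sqrt(sigma_u2)


def _as_matrix(grm) -> np.ndarray:
    return grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)


def _clean_design(X: np.ndarray, n: int) -> np.ndarray:
    """Prepend an intercept and drop redundant columns (QR rank filter)."""
    if X is None:
        X = np.empty((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = np.column_stack([np.ones(n), X])
    # rank-revealing pass: keep columns whose residual norm is non-negligible
    keep = []
    basis = np.empty((n, 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            col = col - basis @ (basis.T @ col)
        nrm = np.linalg.norm(col)
        if nrm > 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            keep.append(j)
            basis = np.column_stack([basis, col / nrm])
    return X[:, keep]


def _profile_negloglik(log_lam: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray) -> float:
    """-2 * REML loglik profiled over sigma_e2, up to a constant."""
    lam = math.exp(log_lam)
    n, p = Xt.shape
    w = 1.0 / (1.0 + lam * d)
    XtW = Xt * w[:, None]
    A = Xt.T @ XtW
    b = np.linalg.solve(A, XtW.T @ yt)
    resid = yt - Xt @ b
    rss = float(resid @ (w * resid))
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0 or rss <= 0:
        return np.inf
    nm = n - p
    se2 = rss / nm
    return nm * math.log(se2) + float(np.sum(np.log1p(lam * d))) + logdetA + nm


def _reml_loglik_value(neg2: float) -> float:
    return -0.5 * neg2


def fit_reml_single(y, fixed_design, grm) -> VarCompFit:
    """REML for y = Xb + u + e with u ~ N(0, G su2) via eigen-rotation.

    ``fixed_design`` is a matrix of covariate columns (an intercept is
    added and redundant columns dropped) or None.  A non-PSD G is shifted
    by its smallest eigenvalue with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    G = _as_matrix(grm)
    if G.shape != (n, n):
        raise ValueError("y length must equal GRM dimension")
    X = _clean_design(fixed_design, n)
    p = X.shape[1]

    d, U = np.linalg.eigh((G + G.T) / 2.0)
    if d[0] < -1e-8 * max(1.0, abs(d[-1])):
        warnings.warn(f"GRM is not PSD (min eigenvalue {d[0]:.3e}); shifting spectrum")
        d = d - d[0]
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    obj = lambda ll: _profile_negloglik(ll, yt, Xt, d)
    res = optimize.minimize_scalar(obj, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-9})
    lam = math.exp(res.x)
    # compare against the lambda -> 0 boundary (no genetic variance)
    at_zero = _profile_negloglik(-30.0, yt, Xt, d)
    boundary = at_zero <= res.fun + 1e-9
    if boundary:
        lam = 0.0
        neg2 = at_zero
    else:
        neg2 = res.fun

    w = 1.0 / (1.0 + lam * d)
    XtW = Xt * w[:, None]
    A = Xt.T @ XtW
    b = np.linalg.solve(A, XtW.T @ yt)
    resid = yt - Xt @ b
    rss = float(resid @ (w * resid))
    se2 = rss / (n - p)
    su2 = lam * se2

    # average-information SEs over (su2, se2) in the rotated basis
    def P_apply(v: np.ndarray) -> np.ndarray:
        wv = w * v
        return (wv - XtW @ np.linalg.solve(A, XtW.T @ v)) / se2

    Py = P_apply(yt)
    GPy = d * Py
    PGPy = P_apply(GPy)
    PPy = P_apply(Py)
    AI = 0.5 * np.array(
        [
            [float(GPy @ PGPy), float(GPy @ PPy)],
            [float(GPy @ PPy), float(Py @ PPy)],
        ]
    )
    try:
        cov = np.linalg.inv(AI)
        se_u2, se_e2 = math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))
        cov_ue = cov[0, 1]
    except np.linalg.LinAlgError:
        se_u2 = se_e2 = float("nan")
        cov_ue = 0.0

    h2 = su2 / (su2 + se2)
    se_h2 = _h2_se_delta(su2, se2, se_u2**2, se_e2**2, cov_ue)
    return VarCompFit(
        sigma_u2=su2,
        sigma_e2=se2,
        se_u2=se_u2,
        se_e2=se_e2,
        h2=h2,
        se_h2=se_h2,
        loglik_reml=_reml_loglik_value(neg2),
        converged=True,
        n_iter=int(getattr(res, "nfev", 0) or getattr(res, "nit", 0) or 0),
    )


def _h2_se_delta(su2, se2, var_u, var_e, cov_ue) -> float:
    total = su2 + se2
    if total <= 0 or not np.isfinite(var_u) or not np.isfinite(var_e):
        return float("nan")
    # gradient of su2/(su2+se2)
    gu = se2 / total**2
    ge = -su2 / total**2
    var = gu * gu * var_u + ge * ge * var_e + 2 * gu * ge * cov_ue
    return math.sqrt(max(var, 0.0))


def reml_loglik_dense(y, fixed_design, grm, sigma_u2: float, sigma_e2: float) -> float:
    """Direct dense REML log-likelihood, omitting the 2*pi constant.

    Same normalization as the ``loglik_reml`` the fitters report, so the
    two evaluation paths are directly comparable; also serves as the
    brute-force grid oracle.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    G = _as_matrix(grm)
    X = _clean_design(fixed_design, n)
    p = X.shape[1]
    V = sigma_u2 * G + sigma_e2 * np.eye(n)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    signA, logdetA = np.linalg.slogdet(A)
    if signA <= 0:
        return -np.inf
    b = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ b
    quad = float(r @ Vi @ r)
    return -0.5 * (logdetV + logdetA + quad)


def fit_reml_two_grm(y, fixed_design, grm_blocks, grm_rest, max_iter: int = 200, tol: float = 1e-8) -> VarCompFit:
    """AI-REML for y = Xb + u1 + u0 + e with two GRMs.

    ``grm_blocks`` (G1) carries the SNP set of interest (e.g. significant
    and suggestive haplotype blocks), ``grm_rest`` (G0) the remainder of
    the genome.  Returns the partition proportion s1/(s1+s0) in
    ``block_proportion``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    G1, G0 = _as_matrix(grm_blocks), _as_matrix(grm_rest)
    if G1.shape != (n, n) or G0.shape != (n, n):
        raise ValueError("GRMs must match the phenotype dimension")
    if np.allclose(G1, G0, atol=1e-10):
        raise ValueError("grm_blocks and grm_rest are identical; model is non-identifiable")
    X = _clean_design(fixed_design, n)
    p = X.shape[1]
    I = np.eye(n)
    Vs = [G1, G0, I]

    vary = float(np.var(y, ddof=1))
    theta = np.array([vary / 4, vary / 4, vary / 2])
    floor = 1e-8 * vary

    def reml_parts(th):
        V = th[0] * G1 + th[1] * G0 + th[2] * I
        L = np.linalg.cholesky(V)
        Vi = np.linalg.inv(V)
        A = X.T @ Vi @ X
        Ai = np.linalg.inv(A)
        ViX = Vi @ X
        P = Vi - ViX @ Ai @ ViX.T
        logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
        signA, logdetA = np.linalg.slogdet(A)
        Py = P @ y
        ll = -0.5 * (logdetV + logdetA + float(y @ Py))
        return P, Py, ll

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P, Py, ll = reml_parts(theta)
        PVs = [P @ Vk for Vk in Vs]
        VPy = [Vk @ Py for Vk in Vs]
        score = np.array(
            [-0.5 * (np.trace(PVs[k]) - float(Py @ VPy[k])) for k in range(3)]
        )
        PVPy = [P @ v for v in VPy]
        AI = 0.5 * np.array([[float(VPy[i] @ PVPy[j]) for j in range(3)] for i in range(3)])
        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = None
        new = theta + step if step is not None else None
        if new is None or np.any(new < 0):
            # EM fallback: guaranteed direction, stays near the feasible region
            em = theta + (theta**2) * np.array(
                [float(Py @ VPy[k]) - np.trace(PVs[k]) for k in range(3)]
            ) / n
            new = np.maximum(em, floor)
        new = np.maximum(new, floor)
        if np.max(np.abs(new - theta) / (np.abs(theta) + 1e-12)) < tol or abs(ll - ll_old) < tol:
            theta = new
            converged = True
            break
        theta, ll_old = new, ll

    P, Py, ll = reml_parts(theta)
    VPy = [Vk @ Py for Vk in Vs]
    PVPy = [P @ v for v in VPy]
    AI = 0.5 * np.array([[float(VPy[i] @ PVPy[j]) for j in range(3)] for i in range(3)])
    try:
        cov = np.linalg.inv(AI)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)
        ses = np.full(3, np.nan)

    s1, s0, se2 = (float(t) for t in theta)
    su2 = s1 + s0
    prop = s1 / su2 if su2 > 0 else float("nan")
    # delta-method SE of the proportion s1/(s1+s0)
    if su2 > 0 and np.isfinite(cov[0, 0]):
        g = np.array([s0 / su2**2, -s1 / su2**2, 0.0])
        se_prop = math.sqrt(max(float(g @ cov @ g), 0.0))
    else:
        se_prop = float("nan")
    var_u = float(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1]) if np.isfinite(cov[0, 0]) else float("nan")
    gv = np.array([se2, se2, -(su2)]) / (su2 + se2) ** 2
    se_h2 = math.sqrt(max(float(gv @ cov @ gv), 0.0)) if np.isfinite(cov[0, 0]) else float("nan")

    if not converged:
        warnings.warn(f"AI-REML did not converge in {max_iter} iterations")
    return VarCompFit(
        sigma_u2=su2,
        sigma_e2=se2,
        se_u2=math.sqrt(max(var_u, 0.0)) if np.isfinite(var_u) else float("nan"),
        se_e2=float(ses[2]),
        h2=su2 / (su2 + se2),
        se_h2=se_h2,
        loglik_reml=ll,
        converged=converged,
        n_iter=it,
        sigma_u1_2=s1,
        sigma_u0_2=s0,
        se_u1_2=float(ses[0]),
        se_u0_2=float(ses[1]),
        block_proportion=prop,
        se_block_proportion=se_prop,
    )
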