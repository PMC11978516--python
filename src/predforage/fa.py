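"""Exploratory factor analysis: parallel analysis, oblique rotation,
loading-based item pruning and Bartlett factor scores.

The factor count comes from a conservative parallel analysis: observed
correlation-matrix eigenvalues are retained while they exceed the 99th
percentile of eigenvalues from simulated Gaussian noise data of matched
shape (5,000 iterations by default).  Extraction is maximum-likelihood
(via scikit-learn), followed by an oblimin (quartimin) rotation computed
with the gradient-projection algorithm, so factors are free to
correlate.  Items are retained only if they load clearly on exactly one
factor (loading > 0.4, no cross-loading > 0.4); pruning repeats parallel
analysis and refits until the rule holds.  Factor scores use the
Bartlett (weighted least squares) estimator, which preserves the
inter-factor correlation structure in the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

__all__ = [
    "PAResult",
    "FAResult",
    "parallel_analysis",
    "fit_fa",
    "prune_and_refit",
    "bartlett_scores",
    "oblimin_rotate",
    "align_loadings",
    "tucker_congruence",
]


@dataclass
class PAResult:
    n_factors: int
    observed_eigenvalues: np.ndarray
    thresholds: np.ndarray
    n_iterations: int


@dataclass
class FAResult:
    loadings: pd.DataFrame  # items x factors (pattern matrix)
    phi: np.ndarray  # factor correlation matrix
    uniquenesses: pd.Series
    n_factors: int
    retained_items: list
    pruning_history: list = field(default_factory=list)
    heywood: bool = False


def _as_frame(data) -> pd.DataFrame:
    df = pd.DataFrame(data)
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise TypeError("factor analysis requires numeric columns only")
    return df


def parallel_analysis(data, n_iter: int = 5000, percentile: float = 99.0, rng=None) -> PAResult:
    """Factor count by comparison with noise eigenvalues.

    Retains leading factors whose observed eigenvalue exceeds the given
    percentile of eigenvalues of standard-normal data of the same shape.
    """
    df = _as_frame(data)
    n, p = df.shape
    if n < p / 2:
        import warnings

        warnings.warn("fewer than items/2 observations; parallel analysis may be unstable")
    rng = np.random.default_rng(rng)
    X = df.to_numpy(dtype=float)
    obs = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))[::-1]
    sims = np.empty((n_iter, p))
    for i in range(n_iter):
        Z = rng.standard_normal((n, p))
        sims[i] = np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False))[::-1]
    thr = np.percentile(sims, percentile, axis=0)
    k = 0
    while k < p and obs[k] > thr[k]:
        k += 1
    return PAResult(n_factors=k, observed_eigenvalues=obs, thresholds=thr, n_iterations=n_iter)


def _quartimin(L):
    L2 = L**2
    k = L.shape[1]
    N = np.ones((k, k)) - np.eye(k)
    M = L2 @ N
    f = np.sum(L2 * M) / 4.0
    Gq = L * M
    return f, Gq


def oblimin_rotate(A: np.ndarray, max_iter: int = 1000, tol: float = 1e-8):
    """Oblique quartimin rotation by gradient projection.

    Returns (pattern loadings, phi).  For a single factor the rotation
    is the identity.
    """
    p, k = A.shape
    if k == 1:
        return A.copy(), np.ones((1, 1))
    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(50):
            X = T - al * Gp
            X = X @ np.diag(1.0 / np.sqrt(np.sum(X**2, axis=0)))
            Ti = np.linalg.inv(X)
            L = A @ Ti.T
            fn, Gq = _quartimin(L)
            if fn < f - 0.5 * s**2 * al:
                T = X
                f = fn
                G = -(L.T @ Gq @ Ti).T
                break
            al /= 2.0
    phi = T.T @ T
    return L, phi


def fit_fa(data, n_factors: int, rotation: str = "oblimin", seed: int = 0) -> FAResult:
    """ML extraction + oblique rotation on standardized items."""
    df = _as_frame(data)
    X = df.to_numpy(dtype=float)
    X = (X - X.mean(0)) / X.std(0)
    fa = FactorAnalysis(n_components=n_factors, svd_method="lapack", random_state=seed)
    fa.fit(X)
    A = fa.components_.T  # items x factors, unrotated
    uniq = fa.noise_variance_.copy()
    heywood = bool(np.any(uniq < 0.005))
    uniq = np.clip(uniq, 0.005, None)
    if rotation == "oblimin":
        L, phi = oblimin_rotate(A)
    elif rotation in (None, "none"):
        L, phi = A, np.eye(n_factors)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")
    # orient each factor so its dominant loadings are positive
    signs = np.sign(np.sum(L**3, axis=0))
    signs[signs == 0] = 1.0
    L = L * signs
    phi = phi * np.outer(signs, signs)
    return FAResult(
        loadings=pd.DataFrame(L, index=df.columns, columns=[f"F{i+1}" for i in range(n_factors)]),
        phi=phi,
        uniquenesses=pd.Series(uniq, index=df.columns),
        n_factors=n_factors,
        retained_items=list(df.columns),
        heywood=heywood,
    )


def prune_and_refit(data, cutoff: float = 0.4, n_iter_pa: int = 1000,
                    percentile: float = 99.0, rng=None, fa: FAResult = None) -> FAResult:
    """Iterate PA -> FA -> drop unclear items until every retained item
    has exactly one loading above the cutoff and no cross-loading."""
    df = _as_frame(data)
    rng = np.random.default_rng(rng)
    history = []
    while True:
        if df.shape[1] < 2:
            raise ValueError("all items pruned")
        pa = parallel_analysis(df, n_iter=n_iter_pa, percentile=percentile, rng=rng)
        k = max(pa.n_factors, 1)
        fa_res = fit_fa(df, k)
        absL = fa_res.loadings.abs()
        primary = absL.max(axis=1)
        n_big = (absL > cutoff).sum(axis=1)
        bad = df.columns[(primary <= cutoff) | (n_big > 1)].tolist()
        history.append({"n_items": df.shape[1], "n_factors": k, "dropped": bad})
        if not bad:
            fa_res.pruning_history = history
            return fa_res
        df = df.drop(columns=bad)


def bartlett_scores(data, fa: FAResult) -> pd.DataFrame:
    """Weighted-least-squares factor scores.

    scores = Z Psi^-1 L (L' Psi^-1 L)^-1 on standardized retained items;
    missing cells are mean-imputed before scoring.
    """
    df = _as_frame(data)[fa.retained_items]
    X = df.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    X = (X - X.mean(0)) / X.std(0)
    L = fa.loadings.to_numpy()
    psi_inv = 1.0 / fa.uniquenesses.to_numpy()
    M = L.T * psi_inv  # k x p
    W = np.linalg.solve(M @ L, M)  # k x p
    S = X @ W.T
    return pd.DataFrame(S, index=df.index, columns=fa.loadings.columns)


def tucker_congruence(a, b) -> float:
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def align_loadings(est: np.ndarray, target: np.ndarray):
    """Greedy congruence matching + sign fix of estimated factors onto a
    target loading matrix; returns (aligned estimate, per-factor
    congruences)."""
    est = np.asarray(est, dtype=float)
    target = np.asarray(target, dtype=float)
    k = target.shape[1]
    used = set()
    order = []
    signs = []
    congs = []
    for j in range(k):
        best, best_c = None, 0.0
        for m in range(est.shape[1]):
            if m in used:
                continue
            c = tucker_congruence(est[:, m], target[:, j])
            if best is None or abs(c) > abs(best_c):
                best, best_c = m, c
        used.add(best)
        order.append(best)
        signs.append(np.sign(best_c) or 1.0)
        congs.append(abs(best_c))
    aligned = est[:, order] * np.asarray(signs)
    return aligned, np.asarray(congs)
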