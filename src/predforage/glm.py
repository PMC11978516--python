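"""Regularized GLMs with monotonic ordinal coding.

All per-participant analyses share one estimation contract: maximum a
posteriori estimation under independent Normal(0, prior_sd^2) priors on
every coefficient (default prior_sd = 3), with four outcome families —
gaussian, bernoulli, poisson and shifted-lognormal — and optional
monotonic coding for ordered task factors (predator speed, number of
check segments).

Monotonic coding expresses the effect of an ordered K-level factor as a
total low-to-high effect ``b`` times the cumulative sum of a (K-1)-
simplex ``zeta``: effect(lowest) = 0, effect(highest) = b, and the
profile is non-decreasing (for b >= 0) without assuming equal spacing.
The simplex is parameterized through a softmax of unconstrained values
with a weak Normal(0, 1.5^2) prior, which keeps the MAP problem smooth
and the simplex away from degenerate corners.

Uncertainty is curvature-based: posterior standard deviations are taken
from the inverse Hessian of the negative log posterior at the mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["MonotonicCoding", "FitResult", "encode_monotonic", "fit_glm"]

FAMILIES = ("gaussian", "bernoulli", "poisson", "shifted_lognormal")


@dataclass
class MonotonicCoding:
    b: float
    zeta: np.ndarray

    def __post_init__(self):
        self.zeta = np.asarray(self.zeta, dtype=float)
        if np.any(self.zeta < 0) or not math.isclose(self.zeta.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("zeta must be a simplex (non-negative, summing to 1)")


def encode_monotonic(levels, coding: MonotonicCoding) -> np.ndarray:
    """Per-observation effect of an ordinal factor under monotonic coding."""
    levels = np.asarray(levels, dtype=int)
    K = len(coding.zeta) + 1
    if levels.min() < 0 or levels.max() >= K:
        raise ValueError("unseen ordinal level")
    cum = np.concatenate([[0.0], np.cumsum(coding.zeta)])
    return coding.b * cum[levels]


@dataclass
class FitResult:
    coef: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    family: str = "gaussian"
    n: int = 0
    converged: bool = False
    prior_sd: float = 3.0
    skip_reason: str = ""
    sigma: float = float("nan")  # gaussian / shifted-lognormal scale
    shift: float = float("nan")  # shifted-lognormal shift
    mono: dict = field(default_factory=dict)  # name -> MonotonicCoding

    @property
    def skipped(self) -> bool:
        return bool(self.skip_reason)

    def predict_eta(self, X, mono_levels=None):
        names = [k for k in self.coef if not k.startswith("mo(")]
        beta = np.array([self.coef[k] for k in names])
        eta = X @ beta[1:] + beta[0] if names[0] == "intercept" else X @ beta
        for name, coding in self.mono.items():
            eta = eta + encode_monotonic(mono_levels[name], coding)
        return eta


def _softmax(u):
    z = np.exp(u - u.max())
    return z / z.sum()


def fit_glm(
    X,
    y,
    family: str = "gaussian",
    prior_sd: float = 3.0,
    mono: dict = None,
    names=None,
    mode: str = "map",
    compute_sd: bool = True,
    tol: str = "tight",
) -> FitResult:
    """MAP fit of y ~ intercept + X (+ monotonic terms).

    ``X`` excludes the intercept, which is always added.  ``mono`` maps a
    term name to ``(levels, K)`` with integer levels 0..K-1.  The outcome
    is never standardized; regressor scaling is the caller's concern.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if mode != "map":
        raise ValueError("only MAP estimation is provided")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0 or X.size == 0:
        X = X.reshape(len(y), 0)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    mono = mono or {}
    mono_items = [(k, np.asarray(v[0], dtype=int), int(v[1])) for k, v in mono.items()]
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("names must match X columns")

    if family == "gaussian" and not mono_items:
        return _gaussian_closed_form(X, y, prior_sd, names, compute_sd)

    # parameter vector layout:
    # [beta0, beta_1..p, (b_m, u_m[0..K-2]) per mono term, extras...]
    n_mono = len(mono_items)
    extras = {"gaussian": 1, "bernoulli": 0, "poisson": 0, "shifted_lognormal": 2}[family]
    sizes = [1 + p] + [1 + (K - 1) for _, _, K in mono_items] + [extras]
    total = sum(sizes)
    tau2 = prior_sd**2

    if family == "shifted_lognormal":
        if np.any(y <= 0):
            raise ValueError("shifted-lognormal outcomes must be positive")
        s_max = 0.999 * float(y.min())

    # per-term constants reused across optimizer evaluations
    mono_ind = [
        (np.arange(K - 1)[None, :] < lv[:, None]).astype(float) for _, lv, K in mono_items
    ]

    def unpack(theta):
        beta = theta[: 1 + p]
        pos = 1 + p
        monos = []
        for _, lv, K in mono_items:
            b = theta[pos]
            u = theta[pos + 1 : pos + K]
            monos.append((b, u))
            pos += K
        return beta, monos, theta[pos:]

    def eta_of(theta):
        beta, monos, _ = unpack(theta)
        eta = beta[0] + X @ beta[1:]
        caches = []
        for (name, lv, K), (b, u) in zip(mono_items, monos):
            zeta = _softmax(u)
            cum = np.concatenate([[0.0], np.cumsum(zeta)])
            eta = eta + b * cum[lv]
            caches.append((zeta, cum))
        return eta, caches

    def nll_grad(theta):
        beta, monos, ext = unpack(theta)
        eta, caches = eta_of(theta)
        if family == "gaussian":
            s = math.exp(ext[0])
            r = y - eta
            nll = n * ext[0] + 0.5 * float(r @ r) / s**2
            deta = -r / s**2
            dext = np.array([n - float(r @ r) / s**2])
        elif family == "bernoulli":
            # stable log(1+exp(eta)) - y*eta
            nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
            deta = 1.0 / (1.0 + np.exp(-eta)) - y
            dext = np.zeros(0)
        elif family == "poisson":
            mu = np.exp(np.clip(eta, -30, 30))
            nll = float(np.sum(mu - y * eta))
            deta = mu - y
            dext = np.zeros(0)
        else:  # shifted_lognormal
            s = math.exp(ext[0])
            shift = s_max / (1.0 + math.exp(-ext[1]))
            w = y - shift
            z = np.log(w)
            r = z - eta
            nll = float(np.sum(np.log(w))) + n * ext[0] + 0.5 * float(r @ r) / s**2
            deta = -r / s**2
            dlog_s = n - float(r @ r) / s**2
            dshift = float(np.sum(-1.0 / w - (r / s**2) / w))
            dv = dshift * shift * (1.0 - shift / s_max)
            dext = np.array([dlog_s, dv])
        grad = np.empty(total)
        grad[0] = float(np.sum(deta))
        grad[1 : 1 + p] = X.T @ deta
        pos = 1 + p
        for (name, lv, K), (b, u), (zeta, cum), ind in zip(
            mono_items, monos, caches, mono_ind
        ):
            cl = cum[lv]
            grad[pos] = float(deta @ cl)
            # d cum[l] / du_j = zeta_j * ((j < l) - cum[l])
            dcu = zeta[None, :] * (ind - cl[:, None])
            grad[pos + 1 : pos + K] = b * (deta @ dcu)
            pos += K
        grad[pos:] = dext
        # priors: N(0, tau2) on beta and b; N(0, 1.5^2) on u
        nlp = nll + 0.5 * float(beta @ beta) / tau2
        grad[: 1 + p] += beta / tau2
        pos = 1 + p
        for (_, _, K), (b, u) in zip(mono_items, monos):
            nlp += 0.5 * b * b / tau2 + 0.5 * float(u @ u) / 1.5**2
            grad[pos] += b / tau2
            grad[pos + 1 : pos + K] += u / 1.5**2
            pos += K
        return nlp, grad

    theta0 = np.zeros(total)
    if family == "gaussian":
        # warm start at the ridge solution of the linear part
        Xa = np.column_stack([np.ones(n), X])
        try:
            b0 = np.linalg.solve(Xa.T @ Xa + np.eye(p + 1) / tau2, Xa.T @ y)
            theta0[: 1 + p] = b0
            resid = y - Xa @ b0
            theta0[-1] = math.log(max(float(np.std(resid)), 1e-3))
        except np.linalg.LinAlgError:
            theta0[0] = float(np.mean(y))
            theta0[-1] = math.log(max(np.std(y), 1e-3))
    elif family == "shifted_lognormal":
        theta0[-2] = math.log(max(np.std(np.log(np.maximum(y, 1e-9))), 1e-2))
        theta0[-1] = -2.0
        theta0[0] = float(np.mean(np.log(np.maximum(y, 1e-9))))
    opts = (
        {"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6}
        if tol == "tight"
        else {"maxiter": 100, "ftol": 1e-8, "gtol": 3e-4}
    )
    res = optimize.minimize(nll_grad, theta0, jac=True, method="L-BFGS-B", options=opts)
    theta = res.x
    beta, monos, ext = unpack(theta)

    # curvature-based sds via finite-difference Hessian of the gradient
    sd_vec = _hessian_sds(nll_grad, theta) if compute_sd else np.full(total, np.nan)

    coef = {"intercept": float(beta[0])}
    sds = {"intercept": sd_vec[0]}
    for i, nm in enumerate(names):
        coef[nm] = float(beta[1 + i])
        sds[nm] = sd_vec[1 + i]
    mono_out = {}
    pos = 1 + p
    for (nm, lv, K), (b, u) in zip(mono_items, monos):
        zeta = _softmax(u)
        coef[f"mo({nm})"] = float(b)
        sds[f"mo({nm})"] = sd_vec[pos]
        mono_out[nm] = MonotonicCoding(float(b), zeta)
        pos += K
    fit = FitResult(
        coef=coef,
        sd=sds,
        family=family,
        n=n,
        converged=bool(res.success),
        prior_sd=prior_sd,
        mono=mono_out,
    )
    if family == "gaussian":
        fit.sigma = math.exp(ext[0])
    elif family == "shifted_lognormal":
        fit.sigma = math.exp(ext[0])
        fit.shift = s_max / (1.0 + math.exp(-ext[1]))
    return fit


def _gaussian_closed_form(X, y, prior_sd, names, compute_sd):
    """Profile the gaussian MAP: beta is ridge given sigma, sigma^2 = RSS/n."""
    n, p = X.shape
    Xa = np.column_stack([np.ones(n), X])
    G = Xa.T @ Xa
    Xty = Xa.T @ y
    s2 = float(np.var(y)) or 1.0
    beta = np.zeros(p + 1)
    for _ in range(200):
        beta_new = np.linalg.solve(G + s2 / prior_sd**2 * np.eye(p + 1), Xty)
        r = y - Xa @ beta_new
        s2_new = float(r @ r) / n
        done = np.allclose(beta_new, beta, rtol=0, atol=1e-14) and abs(s2_new - s2) < 1e-14
        beta, s2 = beta_new, max(s2_new, 1e-12)
        if done:
            break
    if compute_sd:
        cov = np.linalg.inv(G / s2 + np.eye(p + 1) / prior_sd**2)
        sd_vec = np.sqrt(np.clip(np.diag(cov), 0, None))
    else:
        sd_vec = np.full(p + 1, np.nan)
    coef = {"intercept": float(beta[0])}
    sds = {"intercept": float(sd_vec[0])}
    for i, nm in enumerate(names):
        coef[nm] = float(beta[1 + i])
        sds[nm] = float(sd_vec[1 + i])
    fit = FitResult(coef=coef, sd=sds, family="gaussian", n=n, converged=True,
                    prior_sd=prior_sd)
    fit.sigma = math.sqrt(s2)
    return fit


def _hessian_sds(nll_grad, theta, eps=1e-5):
    k = len(theta)
    H = np.empty((k, k))
    for i in range(k):
        tp = theta.copy()
        tp[i] += eps
        _, gp = nll_grad(tp)
        tm = theta.copy()
        tm[i] -= eps
        _, gm = nll_grad(tm)
        H[i] = (gp - gm) / (2 * eps)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)
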