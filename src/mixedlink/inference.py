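"""Likelihood, MLE fitting, and Wald inference for mixed-link models.

The model: for covariate setting x_i the J-1 linear predictors are
eta_ij = beta0_j + beta_j' x_i (npo) or beta0_j + beta' x_i (po); each
eta_ij maps through its own inverse link to a ratio rho_ij, and the
structure turns the rho vector into category probabilities pi_i.  The
counts Y_i are multinomial(n_i, pi_i), so up to a constant in theta

    l(theta) = sum_i sum_j Y_ij log pi_ij(theta).

Fitting is Fisher scoring on theta with a step-halving line search:
the chain rule eta -> rho -> pi gives the score and the expected
information in closed form, and halving keeps the likelihood monotone
and backs off from infeasible iterates (a cumulative-structure theta
whose rho is non-monotone scores -inf and is never accepted).  If
scoring stalls before the gradient tolerance is met, a derivative-free
Nelder-Mead pass polishes the optimum.

The reported covariance is the inverse observed information at the
optimum (numerically differentiated analytic score), falling back to
the expected information when the optimum sits too close to the
feasibility boundary for finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .links import DEFAULT_EPS, link_inverse, link_inverse_derivative
from .model import ModelSpec, SampleTable
from .structures import pi_from_rho, rho_from_pi, structure_matrices

__all__ = [
    "linear_predictor",
    "category_probs",
    "log_likelihood",
    "fit_mle",
    "wald_inference",
    "ParameterizedModel",
]


def _split_theta(spec: ModelSpec, theta: np.ndarray, d: int):
    """theta -> (beta0 of length J-1, slope matrix B of shape (d, J-1))."""
    K = spec.J - 1
    theta = np.asarray(theta, dtype=float)
    p = spec.n_params(d)
    if theta.shape != (p,):
        raise ValueError(f"theta must have length {p}, got shape {theta.shape}")
    beta0 = theta[:K]
    if spec.odds == "po":
        B = np.tile(theta[K:, None], (1, K))
    else:
        B = theta[K:].reshape(K, d).T
    return beta0, B


def _design_tensor(spec: ModelSpec, X: np.ndarray) -> np.ndarray:
    """Z with Z[i] mapping theta -> eta_i; shape (m, J-1, p)."""
    m, d = X.shape
    K = spec.J - 1
    p = spec.n_params(d)
    Z = np.zeros((m, K, p))
    idx = np.arange(K)
    Z[:, idx, idx] = 1.0
    if spec.odds == "po":
        Z[:, :, K:] = X[:, None, :]
    else:
        for j in range(K):
            Z[:, j, K + j * d : K + (j + 1) * d] = X
    return Z


def linear_predictor(spec: ModelSpec, theta, X) -> np.ndarray:
    """eta_ij = beta0_j + beta_j' x_i; returns shape (m, J-1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta0, B = _split_theta(spec, np.asarray(theta, float), X.shape[1])
    return beta0[None, :] + X @ B


def category_probs(
    spec: ModelSpec, theta, X, clip_eps: float = DEFAULT_EPS, check: bool = True
) -> np.ndarray:
    """Category probabilities pi_i(theta), shape (m, J).

    With ``check=True`` an infeasible theta (cumulative structure with
    non-monotone rho) raises; with ``check=False`` the raw arithmetic
    result is returned so callers can detect infeasibility cheaply.
    """
    eta = linear_predictor(spec, theta, X)
    rho = np.column_stack(
        [link_inverse(spec.links[j], eta[:, j], eps=clip_eps) for j in range(spec.J - 1)]
    )
    return pi_from_rho(spec.structure, rho, check=check)


def log_likelihood(spec: ModelSpec, theta, data: SampleTable) -> float:
    """Multinomial log-likelihood sum_ij Y_ij log pi_ij (constants dropped).

    Returns -inf for infeasible theta rather than raising, so that line
    searches can treat infeasibility as just a very bad step.
    """
    if data.m == 0:
        raise ValueError("data is empty")
    pi = category_probs(spec, theta, data.X, check=False)
    if not np.all(np.isfinite(pi)) or np.any(pi <= 0.0):
        return -np.inf
    return float(np.sum(data.Y * np.log(pi)))


def _score_and_info(spec: ModelSpec, theta, data: SampleTable, clip_eps=DEFAULT_EPS):
    """Analytic score vector and expected (Fisher) information matrix.

    Returns (score, info, loglik); score/info are NaN-free only when the
    current theta is feasible.
    """
    X, Y = data.X, data.Y
    K = spec.J - 1
    eta = linear_predictor(spec, theta, X)
    rho = np.column_stack(
        [link_inverse(spec.links[j], eta[:, j], eps=clip_eps) for j in range(K)]
    )
    rhop = np.column_stack(
        [link_inverse_derivative(spec.links[j], eta[:, j]) for j in range(K)]
    )
    pi = pi_from_rho(spec.structure, rho, check=False)
    if not np.all(np.isfinite(pi)) or np.any(pi <= 0.0):
        p = spec.n_params(data.d)
        return np.full(p, np.nan), np.full((p, p), np.nan), -np.inf

    head, piJ = pi[:, :K], pi[:, -1]
    mats = structure_matrices(spec.structure, spec.J)
    L, R, b = mats.L, mats.R, mats.b
    u = head @ L.T
    v = head @ R.T + piJ[:, None] * b
    Rb = R - b[:, None]  # d v_j / d pi~ = R_j - b_j * 1
    D = (L[None] * v[:, :, None] - u[:, :, None] * Rb[None]) / (v**2)[:, :, None]

    # score: dl/deta_i = diag(rho') D^{-T} (Y_head/pi~ - Y_J/pi_J)
    s = Y[:, :K] / head - (Y[:, -1] / piJ)[:, None]
    a = np.linalg.solve(np.swapaxes(D, 1, 2), s[..., None])[..., 0]
    dl_deta = rhop * a

    # expected information in eta: M' Omega M with M = D^{-1} diag(rho')
    eyeK = np.eye(K)
    M = np.linalg.solve(D, eyeK[None] * rhop[:, None, :])
    n_i = data.row_totals
    Omega = eyeK[None] * (1.0 / head)[:, None, :] + (1.0 / piJ)[:, None, None]
    Omega = Omega * n_i[:, None, None]
    W = np.einsum("mja,mjk,mkb->mab", M, Omega, M, optimize=True)

    Z = _design_tensor(spec, X)
    score = np.einsum("mja,mj->a", Z, dl_deta)
    info = np.einsum("mja,mjk,mkb->ab", Z, W, Z, optimize=True)
    ll = float(np.sum(Y * np.log(pi)))
    return score, info, ll


def _initial_theta(spec: ModelSpec, data: SampleTable) -> np.ndarray:
    """Feasible start: intercepts from marginal category frequencies, slopes 0."""
    freq = data.Y.sum(axis=0) / data.n
    freq = np.clip(freq, 1e-6, None)
    freq = freq / freq.sum()
    rho = rho_from_pi(spec.structure, freq)
    from .links import link_apply

    beta0 = np.array(
        [link_apply(spec.links[j], rho[j]) for j in range(spec.J - 1)]
    )
    theta = np.zeros(spec.n_params(data.d))
    theta[: spec.J - 1] = beta0
    return theta


@dataclass
class ParameterizedModel:
    """A fitted mixed-link model: theta-hat with likelihood and covariance."""

    spec: ModelSpec
    theta: np.ndarray
    loglik: float
    vcov: np.ndarray
    converged: bool
    n_iter: int
    n: int
    coef_names: list[str] = field(default_factory=list)
    category_labels: list[str] = field(default_factory=list)
    vcov_kind: str = "observed"
    ll_trace: list[float] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.theta)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.p

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n) * self.p

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def predict_proba(self, X) -> np.ndarray:
        return category_probs(self.spec, self.theta, X)

    def coef_index(self, coef) -> int:
        if isinstance(coef, (int, np.integer)):
            return int(coef)
        return self.coef_names.index(coef)

    def to_dict(self) -> dict:
        return {
            "structure": self.spec.structure,
            "links": list(self.spec.links),
            "odds": self.spec.odds,
            "coef_names": list(self.coef_names),
            "theta": [float(t) for t in self.theta],
            "se": [float(s) for s in self.se()],
            "loglik": self.loglik,
            "n": self.n,
            "p": self.p,
            "aic": self.aic,
            "bic": self.bic,
            "converged": bool(self.converged),
            "n_iter": self.n_iter,
            "vcov_kind": self.vcov_kind,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _observed_info(spec, theta, data, clip_eps):
    """Observed information by central differences of the analytic score."""
    p = len(theta)
    H = np.zeros((p, p))
    for k in range(p):
        h = 1e-6 * max(1.0, abs(theta[k]))
        up = theta.copy()
        up[k] += h
        dn = theta.copy()
        dn[k] -= h
        gu, _, _ = _score_and_info(spec, up, data, clip_eps)
        gd, _, _ = _score_and_info(spec, dn, data, clip_eps)
        H[:, k] = (gu - gd) / (2.0 * h)
    return -(H + H.T) / 2.0


def fit_mle(
    spec: ModelSpec,
    data: SampleTable,
    *,
    init: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
    grad_tol: float = 1e-6,
    clip_eps: float = DEFAULT_EPS,
    compute_vcov: bool = True,
) -> ParameterizedModel:
    """Maximum-likelihood fit by monotone Fisher scoring.

    Accepted steps never decrease the log-likelihood (step-halving);
    convergence requires both a relative log-likelihood change below
    ``tol`` and a score max-norm below ``grad_tol``.  Non-convergence is
    flagged on the result, never raised.
    """
    if data.m == 0:
        raise ValueError("data is empty")
    spec = spec.with_d(data.d) if spec.d != data.d else spec
    theta = (
        np.asarray(init, dtype=float).copy()
        if init is not None
        else _initial_theta(spec, data)
    )
    ll = log_likelihood(spec, theta, data)
    if not np.isfinite(ll):
        raise ValueError("initial theta is infeasible")
    ll_trace = [ll]

    converged = False
    n_iter = 0
    stalls = 0
    collapsed = 0
    at_boundary = False
    for n_iter in range(1, max_iter + 1):
        score, info, ll = _score_and_info(spec, theta, data, clip_eps)
        gmax = float(np.max(np.abs(score)))
        # Scoring direction with step-halving; one damped retry keeps
        # ascent possible when the optimum sits near the feasibility
        # boundary (Levenberg-style regularization of the information)
        best_cand, best_ll = None, ll
        scale = float(np.mean(np.abs(np.diag(info)))) or 1.0
        for lam in (0.0, 1e-3, 1e-1):
            try:
                delta = np.linalg.solve(info + lam * scale * np.eye(len(theta)), score)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(info, score, rcond=None)[0]
            step = 1.0
            for _ in range(30):
                ll_new = log_likelihood(spec, theta + step * delta, data)
                # accept non-decreasing steps (within rounding): Newton
                # keeps polishing the score even once the likelihood is
                # flat at machine precision
                if np.isfinite(ll_new) and ll_new >= ll - 1e-13 * max(1.0, abs(ll)):
                    best_cand, best_ll = theta + step * delta, ll_new
                    break
                step *= 0.5
            if best_cand is not None:
                break
        if best_cand is None:
            converged = gmax < grad_tol  # at the optimum, no ascent exists
            break
        rel = abs(best_ll - ll) / max(1.0, abs(ll))
        theta, ll = best_cand, best_ll
        ll_trace.append(ll)
        if gmax < grad_tol and rel < tol:
            converged = True
            break
        stalls = stalls + 1 if rel < tol else 0
        if stalls >= 40:
            break  # likelihood has flatlined without meeting the score tolerance
        # repeatedly collapsed line searches mean the supremum sits on
        # the feasibility boundary and is not attained
        collapsed = collapsed + 1 if step < 1e-6 else 0
        if collapsed >= 5:
            at_boundary = True
            break

    if not converged and not at_boundary:
        # polish with a derivative-free pass, then re-check the score
        def neg(th):
            v = log_likelihood(spec, th, data)
            return np.inf if not np.isfinite(v) else -v

        res = optimize.minimize(
            neg, theta, method="Nelder-Mead",
            options={"maxiter": 200 + 120 * len(theta), "xatol": 1e-9, "fatol": 1e-11},
        )
        if np.isfinite(res.fun) and -res.fun >= ll:
            theta, ll = res.x, -res.fun
            ll_trace.append(ll)
        score, info, ll = _score_and_info(spec, theta, data, clip_eps)
        converged = bool(np.max(np.abs(score)) < max(grad_tol, 1e-4))

    # covariance: observed information, expected as fallback
    if compute_vcov:
        vcov_kind = "observed"
        obs = _observed_info(spec, theta, data, clip_eps)
        if not np.all(np.isfinite(obs)):
            _, obs, _ = _score_and_info(spec, theta, data, clip_eps)
            vcov_kind = "expected"
        try:
            vcov = np.linalg.inv(obs)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(obs)
            vcov_kind += "-pinv"
    else:
        vcov = np.full((len(theta), len(theta)), np.nan)
        vcov_kind = "none"

    return ParameterizedModel(
        spec=spec,
        theta=np.asarray(theta, float),
        loglik=float(ll),
        vcov=vcov,
        converged=converged,
        n_iter=n_iter,
        n=data.n,
        coef_names=spec.coef_names(data.covariate_names),
        category_labels=list(data.category_labels),
        vcov_kind=vcov_kind,
        ll_trace=ll_trace,
    )


def wald_inference(model: ParameterizedModel, coef, level: float = 0.95):
    """Wald CI and two-sided p-value for one coefficient.

    Returns (lower, upper, p) with lower < upper; H0: theta_k = 0.
    """
    if not model.converged:
        raise ValueError("Wald inference requires a converged model")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    k = model.coef_index(coef)
    est = model.theta[k]
    se = model.se()[k]
    z = stats.norm.ppf(0.5 + level / 2.0)
    if se == 0.0:
        raise ValueError("zero standard error; covariance is degenerate")
    pval = 2.0 * stats.norm.sf(abs(est) / se)
    return est - z * se, est + z * se, float(pval)
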