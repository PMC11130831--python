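"""Link functions applied to category ratios.

Each link is a strictly increasing, differentiable bijection from (0, 1)
onto the real line.  Four links are supported, named by the lower-case
strings used throughout configs and report tables:

``logit``
    g(rho) = log(rho / (1 - rho))
``probit``
    g(rho) = Phi^{-1}(rho), the standard-normal quantile
``loglog``
    g(rho) = -log(-log(rho))
``cloglog``
    g(rho) = log(-log(1 - rho))

Inverse links are clipped away from {0, 1} by a small epsilon so that
downstream likelihood evaluations never take log(0); at any reportable
precision the clipping is invisible.  Derivatives of the inverse links
are closed-form (the Jacobian term needed by Fisher scoring).
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "LINK_NAMES",
    "link_apply",
    "link_inverse",
    "link_inverse_derivative",
]

LINK_NAMES: tuple[str, ...] = ("logit", "probit", "loglog", "cloglog")

#: default clip distance from the {0, 1} boundary for inverse links
DEFAULT_EPS = 1e-12

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _check_link(link: str) -> None:
    if link not in LINK_NAMES:
        raise ValueError(f"unknown link {link!r}; expected one of {LINK_NAMES}")


def link_apply(link: str, rho):
    """Evaluate the link g(rho) for rho strictly inside (0, 1).

    Parameters
    ----------
    link : str
        One of :data:`LINK_NAMES`.
    rho : array_like
        Probabilities in the open interval (0, 1).

    Returns
    -------
    ndarray or scalar
        g(rho), elementwise.

    Raises
    ------
    ValueError
        If ``link`` is unknown or any element of ``rho`` lies outside (0, 1).
    """
    _check_link(link)
    rho = np.asarray(rho, dtype=float)
    if np.any((rho <= 0.0) | (rho >= 1.0)) or not np.all(np.isfinite(rho)):
        raise ValueError("rho must lie strictly inside (0, 1)")
    if link == "logit":
        out = np.log(rho) - np.log1p(-rho)
    elif link == "probit":
        out = special.ndtri(rho)
    elif link == "loglog":
        out = -np.log(-np.log(rho))
    else:  # cloglog
        out = np.log(-np.log1p(-rho))
    return out if out.ndim else out.item()


def link_inverse(link: str, eta, eps: float = DEFAULT_EPS):
    """Map a linear predictor back to a probability, g^{-1}(eta).

    The result is clipped into [eps, 1 - eps]; total on finite input.
    """
    _check_link(link)
    eta = np.asarray(eta, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        if link == "logit":
            out = special.expit(eta)
        elif link == "probit":
            out = special.ndtr(eta)
        elif link == "loglog":
            out = np.exp(-np.exp(-eta))
        else:  # cloglog
            out = -np.expm1(-np.exp(eta))
    out = np.clip(out, eps, 1.0 - eps)
    return out if out.ndim else out.item()


def link_inverse_derivative(link: str, eta):
    """Derivative d rho / d eta of the inverse link; strictly positive."""
    _check_link(link)
    eta = np.asarray(eta, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        if link == "logit":
            p = special.expit(eta)
            out = p * (1.0 - p)
        elif link == "probit":
            out = np.exp(-0.5 * eta * eta) / _SQRT_2PI
        elif link == "loglog":
            out = np.exp(-eta - np.exp(-eta))
        else:  # cloglog
            out = np.exp(eta - np.exp(eta))
    out = np.maximum(out, 0.0)
    return out if out.ndim else out.item()
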