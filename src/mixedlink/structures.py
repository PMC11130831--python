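"""Response structures: how the modelled ratios rho relate to category
probabilities pi.

For a J-category response the model links J-1 ratios rho_j to linear
predictors.  Four structures are supported (names are the exact strings
used in configs and reports):

``baseline``
    rho_j = pi_j / (pi_j + pi_J) — each category against the baseline J.
``cumulative``
    rho_j = pi_1 + ... + pi_j — cumulative probabilities (ordinal).
``adjacent``
    rho_j = pi_j / (pi_j + pi_{j+1}) — adjacent-categories comparisons.
``continuation``
    rho_j = pi_j / (pi_j + ... + pi_J) — continuation ratios.

Every structure can be written uniformly as

    rho_j = (L_j' pi~) / (R_j' pi~ + pi_J b_j)

with pi~ the first J-1 probabilities and (L, R, b) constant 0/1
matrices; :func:`structure_matrices` returns that triple, and the core
fitting code uses it to get the Jacobian d rho / d pi~ without
per-structure special cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STRUCTURE_NAMES",
    "StructureMatrices",
    "InfeasibleRhoError",
    "structure_matrices",
    "rho_from_pi",
    "pi_from_rho",
]

STRUCTURE_NAMES: tuple[str, ...] = (
    "baseline",
    "cumulative",
    "adjacent",
    "continuation",
)


class InfeasibleRhoError(ValueError):
    """A rho vector has no valid probability vector under the structure.

    Only the cumulative structure can be infeasible: its rho must be
    strictly increasing.  ``index`` is the first offending position j
    (0-based) with rho_j <= rho_{j-1}.
    """

    def __init__(self, message: str, index: int):
        super().__init__(message)
        self.index = index


@dataclass(frozen=True)
class StructureMatrices:
    """The (L, R, b) encoding of rho_j = L_j'pi~ / (R_j'pi~ + pi_J b_j)."""

    L: np.ndarray
    R: np.ndarray
    b: np.ndarray


def _check_structure(structure: str) -> None:
    if structure not in STRUCTURE_NAMES:
        raise ValueError(
            f"unknown structure {structure!r}; expected one of {STRUCTURE_NAMES}"
        )


def structure_matrices(structure: str, J: int) -> StructureMatrices:
    """Constant (L, R, b) for a structure at J response categories."""
    _check_structure(structure)
    if J < 2:
        raise ValueError(f"J must be >= 2, got {J}")
    k = J - 1
    eye = np.eye(k)
    ones = np.ones(k)
    if structure == "baseline":
        return StructureMatrices(eye.copy(), eye.copy(), ones.copy())
    if structure == "cumulative":
        return StructureMatrices(np.tril(np.ones((k, k))), np.ones((k, k)), ones.copy())
    if structure == "adjacent":
        R = np.eye(k) + np.diag(np.ones(k - 1), 1) if k > 1 else np.ones((1, 1))
        b = np.zeros(k)
        b[-1] = 1.0
        return StructureMatrices(eye.copy(), R, b)
    # continuation
    return StructureMatrices(eye.copy(), np.triu(np.ones((k, k))), ones.copy())


def _validate_pi(pi: np.ndarray) -> None:
    if np.any(pi <= 0.0) or np.any(pi >= 1.0):
        raise ValueError("pi must lie strictly inside the open simplex")
    if np.any(np.abs(pi.sum(axis=-1) - 1.0) > 1e-8):
        raise ValueError("pi rows must sum to 1")


def rho_from_pi(structure: str, pi) -> np.ndarray:
    """Map category probabilities to structure ratios.

    ``pi`` has shape (..., J) on the open simplex; returns shape (..., J-1)
    with every component in (0, 1).
    """
    pi = np.asarray(pi, dtype=float)
    _validate_pi(pi)
    J = pi.shape[-1]
    mats = structure_matrices(structure, J)
    head, piJ = pi[..., :-1], pi[..., -1:]
    num = head @ mats.L.T
    den = head @ mats.R.T + piJ * mats.b
    return num / den


def pi_from_rho(structure: str, rho, *, check: bool = True) -> np.ndarray:
    """Invert the structure: probabilities pi (..., J) from ratios rho (..., J-1).

    Round-trips with :func:`rho_from_pi`.  For the cumulative structure rho
    must be strictly increasing along the last axis; a violation raises
    :class:`InfeasibleRhoError` carrying the first offending index.  With
    ``check=False`` the raw arithmetic result is returned instead (it may
    contain non-positive entries), which lets an optimizer detect
    infeasibility via the likelihood rather than via exceptions.
    """
    _check_structure(structure)
    rho = np.asarray(rho, dtype=float)
    if check and (np.any(rho <= 0.0) or np.any(rho >= 1.0)):
        raise ValueError("rho components must lie strictly inside (0, 1)")

    if structure == "cumulative":
        diffs = np.diff(rho, axis=-1)
        if check and np.any(diffs <= 0.0):
            idx = int(np.argmax(np.any(diffs <= 0.0, axis=tuple(range(diffs.ndim - 1)))) + 1)
            raise InfeasibleRhoError(
                f"cumulative rho must be strictly increasing; violated at index {idx}",
                index=idx,
            )
        pi = np.concatenate(
            [rho[..., :1], np.diff(rho, axis=-1), 1.0 - rho[..., -1:]], axis=-1
        )
        return pi

    if structure == "baseline":
        odds = rho / (1.0 - rho)
        denom = 1.0 + odds.sum(axis=-1, keepdims=True)
        return np.concatenate([odds, np.ones_like(rho[..., :1])], axis=-1) / denom

    # adjacent and continuation: accumulate in log space to dodge underflow
    log_r = np.log(rho)
    log_1mr = np.log1p(-rho)
    if structure == "adjacent":
        # pi_j / pi_{j+1} = rho_j / (1 - rho_j); anchor at pi_J
        log_odds = log_r - log_1mr
        # log pi_j - log pi_J = sum_{k>=j} log_odds_k
        cum = np.flip(np.cumsum(np.flip(log_odds, axis=-1), axis=-1), axis=-1)
        log_unnorm = np.concatenate([cum, np.zeros_like(rho[..., :1])], axis=-1)
    else:  # continuation: pi_j = rho_j * prod_{k<j}(1 - rho_k)
        surv = np.cumsum(log_1mr, axis=-1)
        shifted = np.concatenate([np.zeros_like(rho[..., :1]), surv[..., :-1]], axis=-1)
        log_head = log_r + shifted
        log_unnorm = np.concatenate([log_head, surv[..., -1:]], axis=-1)
    log_unnorm -= log_unnorm.max(axis=-1, keepdims=True)
    pi = np.exp(log_unnorm)
    return pi / pi.sum(axis=-1, keepdims=True)
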