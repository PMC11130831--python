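"""Study-shaped synthetic data with known ground truth.

Real inputs for this kind of analysis are a clinical sample table (a
mitotic-age score per tissue sample, a 5-level gastric-atrophy factor,
and a 3-level Normal/MIM/IM response) plus a CpG beta-value matrix.
This module fabricates both so every stage of the pipeline is testable
offline: covariates are drawn from simple marginals, responses from a
known mixed-link model, and beta matrices are constructed to hit
prescribed TNSC targets exactly.

Three published fitted models serve as generating laws (``study_model``):

1. cumulative po with loglog/logit links, TNSC only;
2. adjacent-categories po logit with TNSC and the 5-class atrophy
   dummies (Marked baseline);
3. adjacent-categories po probit with TNSC and the 3-class atrophy
   dummies (Negative baseline), i.e. the restricted cohort without
   Marked/Unknown rows.

Defaults mimic the study scale: TNSC ~ Uniform(2000, 20000) — the range
over which the reference models' linear predictors traverse the
informative probability region — and n = 124 samples with one response
per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epitoc2 import NOMINAL_NC, EpiTOCParams
from .inference import category_probs
from .io import IM_LABELS, design_matrix
from .model import ModelSpec

__all__ = [
    "GeneratorConfig",
    "study_model",
    "simulate_covariates",
    "simulate_responses",
    "simulate_dataset",
    "simulate_beta_matrix",
    "synthetic_epitoc_params",
]

#: default 5-class atrophy frequencies (Marked, Moderate, Mild, Negative,
#: Unknown).  Only the rare-Marked and Unknown shares are anchored in the
#: study description; the remainder spreads the mass realistically and is
#: freely overridable.
DEFAULT_ATROPHY_PROBS_5 = {
    "Marked": 0.024,
    "Moderate": 0.20,
    "Mild": 0.30,
    "Negative": 0.29,
    "Unknown": 0.186,
}

#: default 3-class frequencies for the restricted cohort
DEFAULT_ATROPHY_PROBS_3 = {"Negative": 0.37, "Mild": 0.38, "Moderate": 0.25}

_STUDY_MODELS = {
    1: (
        ModelSpec("cumulative", ("loglog", "logit"), "po", d=1),
        np.array([4.023, 4.905, -4.228e-4]),
        "tnsc",
    ),
    2: (
        ModelSpec("adjacent", ("logit", "logit"), "po", d=5),
        np.array([-1.859, 0.136, -4.586e-4, -1.144, -2.103, 6.469, 3.663]),
        "tnsc+atrophy5",
    ),
    3: (
        ModelSpec("adjacent", ("probit", "probit"), "po", d=3),
        np.array([3.153, 5.275, -3.446e-4, -4.260, -5.347]),
        "tnsc+atrophy3",
    ),
}


def study_model(which: int):
    """(spec, theta, covariate_set) for reference model 1, 2 or 3."""
    if which not in _STUDY_MODELS:
        raise ValueError("model must be 1, 2 or 3")
    spec, theta, covset = _STUDY_MODELS[which]
    return spec, theta.copy(), covset


@dataclass
class GeneratorConfig:
    """Everything needed to draw one synthetic study dataset."""

    n: int = 124
    tnsc_range: tuple[float, float] = (2000.0, 20000.0)
    atrophy_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATROPHY_PROBS_5)
    )
    spec: ModelSpec | None = None
    theta: np.ndarray | None = None
    covariate_set: str = "tnsc"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.tnsc_range
        if not lo < hi:
            raise ValueError("tnsc_range must satisfy low < high")
        total = sum(self.atrophy_probs.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"atrophy_probs must sum to 1, got {total}")
        if any(p < 0 for p in self.atrophy_probs.values()):
            raise ValueError("atrophy_probs must be non-negative")


def simulate_covariates(config: GeneratorConfig) -> pd.DataFrame:
    """Sample table covariates: sample_id, tnsc, atrophy."""
    rng = np.random.default_rng(config.seed)
    tnsc = rng.uniform(*config.tnsc_range, size=config.n)
    levels = list(config.atrophy_probs)
    probs = np.array([config.atrophy_probs[k] for k in levels])
    atrophy = rng.choice(levels, size=config.n, p=probs / probs.sum())
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(config.n)],
            "tnsc": tnsc,
            "atrophy": atrophy,
        }
    )


def simulate_responses(
    spec: ModelSpec,
    theta,
    covariates: pd.DataFrame,
    seed: int,
    covariate_set: str = "tnsc",
) -> pd.DataFrame:
    """Draw one Normal/MIM/IM label per row from the model's probabilities.

    Returns a copy of ``covariates`` with an ``im_label`` column.  Rows
    where theta yields no valid probability vector raise, identifying
    the rows.
    """
    X, _, keep = design_matrix(covariates, covariate_set)
    if not keep.all():
        raise ValueError(
            "covariates contain rows outside the covariate set "
            f"(e.g. Marked/Unknown rows under {covariate_set!r})"
        )
    pi = category_probs(spec, theta, X, check=False)
    bad = ~np.all(np.isfinite(pi) & (pi > 0.0), axis=1)
    if bad.any():
        raise ValueError(f"theta infeasible at rows {list(np.flatnonzero(bad)[:10])}")
    rng = np.random.default_rng(seed)
    u = rng.random(len(X))
    labels = (u[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)
    out = covariates.copy()
    out["im_label"] = [IM_LABELS[j] for j in labels]
    return out


def simulate_dataset(
    model: int = 1, n: int = 124, seed: int = 0, **overrides
) -> pd.DataFrame:
    """One synthetic study table drawn from a reference model.

    Convenience wrapper: covariates then responses, with the atrophy
    marginal matched to the model's covariate set (models 1 and 2 use
    the 5-class marginal, model 3 the restricted 3-class one).
    """
    spec, theta, covset = study_model(model)
    probs = (
        dict(DEFAULT_ATROPHY_PROBS_3)
        if covset == "tnsc+atrophy3"
        else dict(DEFAULT_ATROPHY_PROBS_5)
    )
    config = GeneratorConfig(
        n=n, atrophy_probs=probs, spec=spec, theta=theta,
        covariate_set=covset, seed=seed, **overrides,
    )
    cov = simulate_covariates(config)
    # responses get their own stream so covariate draws stay comparable
    # across models at the same seed
    return simulate_responses(spec, theta, cov, seed=seed + 500_000_000, covariate_set=covset)


def synthetic_epitoc_params(
    nc: int = NOMINAL_NC, seed: int = 0, delta_range: tuple[float, float] = (2e-5, 9e-5)
) -> EpiTOCParams:
    """A synthetic stand-in for the published clock parameter table.

    The real per-CpG de novo methylation probabilities ship with the
    published clock code and are an input file here; this fabricated
    table only mimics their role.  The delta range is chosen so that
    TNSC values up to ~2e4 stay reachable with beta values in [0, 1]
    (each probe caps TNSC contributions at 2/delta).
    """
    rng = np.random.default_rng(seed)
    delta = rng.uniform(*delta_range, size=nc)
    ids = tuple(f"cg{seed:02d}{i:06d}" for i in range(nc))
    return EpiTOCParams(ids, delta)


def simulate_beta_matrix(
    params: EpiTOCParams,
    target_tnsc,
    seed: int = 0,
    jitter: float = 0.2,
) -> pd.DataFrame:
    """Beta matrix whose TNSC equals ``target_tnsc`` to high precision.

    Base construction beta_is = target_s * delta_i / 2 reproduces the
    target exactly; mean-zero jitter is added in the weighted null space
    of the TNSC functional (so the score is untouched) and shrunk if it
    would leave [0, 1].
    """
    target = np.asarray(target_tnsc, dtype=float)
    caps = 2.0 / params.delta
    if np.any(target < 0) or np.any(target.max() > caps.min()):
        raise ValueError(
            "target TNSC not achievable with beta in [0, 1] for every probe "
            f"(max feasible {caps.min():.6g})"
        )
    base = np.outer(params.delta / 2.0, target)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(base.shape)
    z -= z.mean(axis=0, keepdims=True)  # zero weighted-TNSC contribution
    noise = (params.delta / 2.0)[:, None] * z * jitter * np.maximum(target, 1.0)
    beta = base + noise
    lo, hi = beta.min(), beta.max()
    if lo < 0.0 or hi > 1.0:
        # shrink the jitter just enough to stay inside [0, 1]
        room = np.minimum(base, 1.0 - base)
        scale = np.min(np.where(np.abs(noise) > 0, room / np.abs(noise), np.inf))
        beta = base + noise * min(1.0, 0.999 * scale)
    cols = [f"sample{j + 1}" for j in range(base.shape[1])]
    return pd.DataFrame(beta, index=list(params.cpg_ids), columns=cols)
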