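"""Candidate-model enumeration and information-criterion ranking.

With J response categories, four structures, a set of per-comparison
links and the po/npo choice, the candidate space is
|structures| x |links|^(J-1) x 2 models (128 for J = 3 with four links).
Every candidate is fitted by MLE and ranked by AIC or BIC; the grouped
view keeps, for each (structure, odds) pair, the best link combination
— the shape in which such sweeps are usually reported.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inference import fit_mle
from .links import LINK_NAMES
from .model import ModelSpec, SampleTable
from .structures import STRUCTURE_NAMES

__all__ = [
    "enumerate_candidates",
    "information_criteria",
    "select_best",
    "group_table",
]


def enumerate_candidates(
    J: int = 3,
    links: Iterable[str] = LINK_NAMES,
    structures: Iterable[str] = STRUCTURE_NAMES,
    odds: Iterable[str] = ("po", "npo"),
) -> list[ModelSpec]:
    """Full cross-product of candidate specs, in deterministic order.

    po candidates also carry one link per comparison: the proportional-
    odds restriction shares slopes, not links.
    """
    if J < 2:
        raise ValueError("J must be >= 2")
    links, structures, odds = list(links), list(structures), list(odds)
    if not links or not structures or not odds:
        raise ValueError("links, structures and odds must be non-empty")
    return [
        ModelSpec(s, combo, o)
        for s in structures
        for combo in itertools.product(links, repeat=J - 1)
        for o in odds
    ]


def information_criteria(loglik: float, p: int, n: int) -> tuple[float, float]:
    """(AIC, BIC) = (-2 l + 2p, -2 l + log(n) p)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if p < 0:
        raise ValueError("p must be >= 0")
    return -2.0 * loglik + 2.0 * p, -2.0 * loglik + np.log(n) * p


def select_best(
    data: SampleTable,
    candidates: Sequence[ModelSpec],
    criterion: str = "AIC",
    fit_options: dict | None = None,
) -> pd.DataFrame:
    """Fit every candidate and rank ascending by the criterion.

    Returns one row per candidate with columns ``structure, odds,
    link_j1..link_j{J-1}, loglik, p, AIC, BIC, converged, rank``.
    Non-converged fits are retained but ranked after all converged ones
    (dropping them silently would bias the selection); criterion ties
    break toward fewer parameters, then lexicographic spec name.
    """
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    if not candidates:
        raise ValueError("no candidate models given")
    fit_options = dict(fit_options or {})
    fit_options.setdefault("compute_vcov", False)
    rows = []
    fits = []
    for spec in candidates:
        fit = fit_mle(spec, data, **fit_options)
        fits.append(fit)
        row = {"structure": spec.structure, "odds": spec.odds}
        for j, link in enumerate(spec.links):
            row[f"link_j{j + 1}"] = link
        row.update(
            loglik=fit.loglik,
            p=fit.p,
            AIC=fit.aic,
            BIC=fit.bic,
            converged=fit.converged,
            name=spec.name,
        )
        rows.append(row)
    if not any(r["converged"] for r in rows) and not any(
        np.isfinite(r["loglik"]) for r in rows
    ):
        raise RuntimeError("every candidate fit failed")
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["converged", criterion, "p", "name"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table.attrs["criterion"] = criterion
    table.attrs["fits"] = {f.spec.name: f for f in fits}
    return table


def group_table(results: pd.DataFrame, criterion: str | None = None) -> pd.DataFrame:
    """Best link combination per (structure, odds) group, ranked.

    This mirrors the usual report shape: one row per model family with
    the winning links and their AIC/BIC; the full per-combination detail
    stays in ``results``.
    """
    criterion = criterion or results.attrs.get("criterion", "AIC")
    best = (
        results.sort_values(
            by=["converged", criterion, "p", "name"],
            ascending=[False, True, True, True],
            kind="mergesort",
        )
        .groupby(["structure", "odds"], sort=False)
        .head(1)
        .reset_index(drop=True)
    )
    best["rank"] = np.arange(1, len(best) + 1)
    return best
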