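"""Model specifications and sample containers.

A :class:`ModelSpec` names one candidate model: a response structure,
one link per non-baseline comparison, and the odds type (``po`` shares a
single slope vector across comparisons, ``npo`` gives each comparison
its own).  A :class:`SampleTable` holds the design: m covariate
settings with multinomial counts over J categories.  Individual-level
data are simply the case where every row has a single trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .links import LINK_NAMES
from .structures import STRUCTURE_NAMES

__all__ = ["ModelSpec", "SampleTable"]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate multinomial mixed-link model.

    Parameters
    ----------
    structure : str
        One of ``baseline``, ``cumulative``, ``adjacent``, ``continuation``.
    links : tuple of str
        One link name per comparison j = 1..J-1; J = len(links) + 1.
    odds : str
        ``"po"`` (proportional odds: shared slopes) or ``"npo"``
        (nonproportional: per-comparison slopes).
    d : int or None
        Number of covariates; may be left None until data are seen.
    """

    structure: str
    links: tuple[str, ...]
    odds: str = "po"
    d: int | None = None

    def __post_init__(self):
        if self.structure not in STRUCTURE_NAMES:
            raise ValueError(f"unknown structure {self.structure!r}")
        links = tuple(self.links)
        object.__setattr__(self, "links", links)
        if len(links) < 1:
            raise ValueError("need at least one link (J >= 2)")
        for name in links:
            if name not in LINK_NAMES:
                raise ValueError(f"unknown link {name!r}")
        if self.odds not in ("po", "npo"):
            raise ValueError("odds must be 'po' or 'npo'")
        if self.d is not None and self.d < 0:
            raise ValueError("d must be non-negative")

    @property
    def J(self) -> int:
        return len(self.links) + 1

    def n_params(self, d: int | None = None) -> int:
        """Parameter count p: (d+1)(J-1) for npo, d + J-1 for po."""
        d = self.d if d is None else d
        if d is None:
            raise ValueError("covariate count d is not set")
        return (d + 1) * (self.J - 1) if self.odds == "npo" else d + self.J - 1

    def with_d(self, d: int) -> "ModelSpec":
        return ModelSpec(self.structure, self.links, self.odds, d)

    @property
    def name(self) -> str:
        return f"{self.structure}-{self.odds}-" + "-".join(self.links)

    def coef_names(self, covariate_names: Sequence[str] | None = None) -> list[str]:
        """Names for the theta vector: intercepts first, then slopes."""
        d = self.d
        if d is None:
            raise ValueError("covariate count d is not set")
        cov = list(covariate_names) if covariate_names is not None else [
            f"x{k + 1}" for k in range(d)
        ]
        names = [f"intercept_{j + 1}" for j in range(self.J - 1)]
        if self.odds == "po":
            names += list(cov)
        else:
            for j in range(self.J - 1):
                names += [f"{c}_{j + 1}" for c in cov]
        return names


@dataclass
class SampleTable:
    """Covariate settings with multinomial response counts.

    Attributes
    ----------
    X : ndarray, shape (m, d)
        Covariate settings (one row per setting).
    Y : ndarray, shape (m, J)
        Non-negative integer counts per category, ordered so the last
        column is the baseline category.
    covariate_names, category_labels : lists of str
    sample_ids : optional list of identifiers, one per row.
    """

    X: np.ndarray
    Y: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    category_labels: list[str] = field(default_factory=list)
    sample_ids: list | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if self.X.shape[0] == 0:
            raise ValueError("sample table is empty")
        if np.any(self.Y < 0) or np.any(self.Y != np.round(self.Y)):
            raise ValueError("Y must contain non-negative integer counts")
        if np.any(self.Y.sum(axis=1) < 1):
            raise ValueError("every retained row needs at least one observation")
        if not self.covariate_names:
            self.covariate_names = [f"x{k + 1}" for k in range(self.d)]
        if not self.category_labels:
            self.category_labels = [f"cat{j + 1}" for j in range(self.J)]

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def J(self) -> int:
        return self.Y.shape[1]

    @property
    def n(self) -> int:
        return int(self.Y.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.Y.sum(axis=1)

    @classmethod
    def from_labels(
        cls,
        X,
        y,
        categories: Sequence | None = None,
        covariate_names: Sequence[str] | None = None,
        sample_ids: Sequence | None = None,
    ) -> "SampleTable":
        """Build an individual-level table (one trial per row) from labels.

        ``categories`` fixes the category order (last = baseline); by
        default the sorted unique labels are used.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if categories is None:
            categories = list(np.unique(y))
        categories = list(categories)
        index = {c: j for j, c in enumerate(categories)}
        bad = [i for i, lab in enumerate(y) if lab not in index]
        if bad:
            raise ValueError(f"labels outside the category set at rows {bad[:10]}")
        Y = np.zeros((len(y), len(categories)))
        Y[np.arange(len(y)), [index[lab] for lab in y]] = 1.0
        return cls(
            X,
            Y,
            covariate_names=list(covariate_names) if covariate_names else [],
            category_labels=[str(c) for c in categories],
            sample_ids=list(sample_ids) if sample_ids is not None else None,
        )

    def subset(self, rows) -> "SampleTable":
        rows = np.asarray(rows)
        return SampleTable(
            self.X[rows],
            self.Y[rows],
            covariate_names=list(self.covariate_names),
            category_labels=list(self.category_labels),
            sample_ids=[self.sample_ids[i] for i in rows]
            if self.sample_ids is not None
            else None,
        )
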