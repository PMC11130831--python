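"""Reading the study-shaped sample table and building design matrices.

The input CSV has one row per tissue sample with columns ``sample_id``
(string), ``tnsc`` (real; stem-cell divisions), ``atrophy`` (factor:
Marked / Moderate / Mild / Negative / Unknown) and ``im_label``
(ordered factor: Normal / MIM / IM).  Label strings are matched
case-insensitively and canonicalized on output.

Three covariate sets are supported; the dummy-coding baselines matter
because coefficient signs depend on them:

``tnsc``
    d = 1: the mitotic-age score only.
``tnsc+atrophy5``
    d = 5: tnsc plus dummies (mild, moderate, negative, unknown);
    all-zero dummies encode the Marked baseline.
``tnsc+atrophy3``
    d = 3: rows with Marked or Unknown atrophy are dropped (with a
    count report); tnsc plus dummies (mild, moderate); all-zero encodes
    the Negative baseline.

The response categories are ordered Normal < MIM < IM with IM (the
high-risk class) as the baseline category of the model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import SampleTable

__all__ = [
    "IM_LABELS",
    "ATROPHY_LEVELS",
    "COVARIATE_SETS",
    "design_matrix",
    "read_sample_table",
]

logger = logging.getLogger(__name__)

IM_LABELS: tuple[str, ...] = ("Normal", "MIM", "IM")
ATROPHY_LEVELS: tuple[str, ...] = ("Marked", "Moderate", "Mild", "Negative", "Unknown")
COVARIATE_SETS: tuple[str, ...] = ("tnsc", "tnsc+atrophy5", "tnsc+atrophy3")

_IM_CANON = {s.lower(): s for s in IM_LABELS}
_ATROPHY_CANON = {s.lower(): s for s in ATROPHY_LEVELS}


def _canonize(series: pd.Series, table: dict, what: str) -> pd.Series:
    vals = series.astype(str).str.strip().str.lower()
    bad = ~vals.isin(table)
    if bad.any():
        rows = list(series.index[bad][:10])
        raise ValueError(
            f"unknown {what} value(s) {sorted(set(series[bad]))[:5]} at rows {rows}"
        )
    return vals.map(table)


def design_matrix(frame: pd.DataFrame, covariate_set: str):
    """Covariate matrix for a canonicalized sample frame.

    Returns ``(X, names, keep)`` where ``keep`` is the boolean row mask
    actually used (Marked/Unknown rows are masked out for the 3-class
    set).
    """
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(
            f"unknown covariate set {covariate_set!r}; expected one of {COVARIATE_SETS}"
        )
    keep = pd.Series(True, index=frame.index)
    if covariate_set == "tnsc":
        return frame[["tnsc"]].to_numpy(dtype=float), ["tnsc"], keep

    atrophy = _canonize(frame["atrophy"], _ATROPHY_CANON, "atrophy")
    if covariate_set == "tnsc+atrophy3":
        keep = ~atrophy.isin(["Marked", "Unknown"])
        dummies = ["Mild", "Moderate"]  # Negative is the baseline
    else:
        dummies = ["Mild", "Moderate", "Negative", "Unknown"]  # Marked baseline
    cols = [frame.loc[keep, "tnsc"].to_numpy(dtype=float)]
    names = ["tnsc"]
    sub = atrophy[keep]
    for level in dummies:
        cols.append((sub == level).to_numpy(dtype=float))
        names.append(level.lower())
    return np.column_stack(cols), names, keep


def read_sample_table(source, covariate_set: str = "tnsc") -> SampleTable:
    """Load a sample CSV (or ready DataFrame) into a :class:`SampleTable`.

    Rows with labels outside the schema are rejected with their row
    numbers; for the 3-class covariate set, Marked/Unknown rows are
    dropped and the count logged.
    """
    frame = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if frame.empty:
        raise ValueError("sample table is empty")
    required = {"sample_id", "tnsc", "im_label"}
    if covariate_set != "tnsc":
        required.add("atrophy")
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"sample table lacks columns: {sorted(missing)}")

    frame = frame.reset_index(drop=True)
    labels = _canonize(frame["im_label"], _IM_CANON, "im_label")
    X, names, keep = design_matrix(frame, covariate_set)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d Marked/Unknown rows for the 3-class covariate set "
            "(%d of %d rows retained)",
            n_dropped,
            int(keep.sum()),
            len(frame),
        )
    table = SampleTable.from_labels(
        X,
        labels[keep].to_numpy(),
        categories=list(IM_LABELS),
        covariate_names=names,
        sample_ids=list(frame.loc[keep, "sample_id"]),
    )
    table.n_dropped = n_dropped
    return table
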