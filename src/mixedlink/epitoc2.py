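"""Mitotic-age (TNSC) computation from DNA-methylation beta values.

The epiTOC2 mitotic clock estimates the total number of stem-cell
divisions per stem cell (TNSC) in a tissue sample from the methylation
state of nc = 163 PRC2-marked CpG sites.  In its simplified weighted-
average form,

    TNSC(s) = (1/nc) * sum_i (2 * beta_is / delta_i),

where beta_is in [0, 1] is the methylation beta value of CpG i in
sample s and delta_i is the per-CpG probability of de novo methylation
of both strands per division.  The delta table ships with the published
epiTOC2 code and is read here from a two-column CSV (cpg_id, delta);
it is not vendored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EpiTOCParams", "load_epitoc_params", "tnsc"]

#: number of CpGs in the published clock
NOMINAL_NC = 163


@dataclass(frozen=True)
class EpiTOCParams:
    """CpG identifiers with their de novo methylation probabilities."""

    cpg_ids: tuple[str, ...]
    delta: np.ndarray

    def __post_init__(self):
        delta = np.asarray(self.delta, dtype=float)
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "cpg_ids", tuple(self.cpg_ids))
        if len(self.cpg_ids) != len(delta):
            raise ValueError("cpg_ids and delta must have the same length")
        if np.any(delta <= 0.0) or np.any(delta > 1.0):
            raise ValueError("delta values must lie in (0, 1]")

    @property
    def nc(self) -> int:
        return len(self.cpg_ids)

    @property
    def weights(self) -> np.ndarray:
        """w_i = 2 / delta_i."""
        return 2.0 / self.delta

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EpiTOCParams":
        return cls(tuple(frame["cpg_id"].astype(str)), frame["delta"].to_numpy())


def load_epitoc_params(path) -> EpiTOCParams:
    """Read a cpg_id, delta CSV."""
    frame = pd.read_csv(path)
    missing = {"cpg_id", "delta"} - set(frame.columns)
    if missing:
        raise ValueError(f"parameter table lacks columns: {sorted(missing)}")
    return EpiTOCParams.from_frame(frame)


def tnsc(
    betas: pd.DataFrame,
    params: EpiTOCParams,
    missing_policy: str = "strict",
) -> pd.DataFrame:
    """Per-sample TNSC from a CpG x sample beta-value matrix.

    Parameters
    ----------
    betas : DataFrame
        Rows indexed by CpG probe ID, one column per sample, entries in
        [0, 1] (NaN marks a missing measurement).
    params : EpiTOCParams
    missing_policy : {"strict", "intersect"}
        Under "strict" every clock CpG must be present and measured in
        every sample.  Under "intersect" the average runs over the CpGs
        actually available, with the per-sample count reported and a
        warning — subsetting the clock changes the estimand, so it never
        happens silently.

    Returns
    -------
    DataFrame with columns ``sample_id``, ``tnsc``, ``n_probes_used``.
    """
    if missing_policy not in ("strict", "intersect"):
        raise ValueError("missing_policy must be 'strict' or 'intersect'")
    present = [c for c in params.cpg_ids if c in betas.index]
    if not present:
        raise ValueError("none of the clock CpGs are present in the beta matrix")
    absent = [c for c in params.cpg_ids if c not in betas.index]
    sub = betas.loc[present]
    vals = sub.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if np.any((vals < 0.0) | (vals > 1.0), where=finite):
        raise ValueError("beta values must lie within [0, 1]")

    if missing_policy == "strict":
        if absent:
            raise ValueError(
                f"{len(absent)} clock CpGs missing from the beta matrix "
                f"(first few: {absent[:5]})"
            )
        if not finite.all():
            bad = sub.index[~finite.all(axis=1)][:5]
            raise ValueError(f"missing beta values at CpGs {list(bad)}")
    elif absent or not finite.all():
        warnings.warn(
            f"TNSC computed over a subset of the clock: {len(absent)} CpGs "
            "absent; per-sample counts are reported",
            UserWarning,
            stacklevel=2,
        )

    order = [params.cpg_ids.index(c) for c in present]
    w = params.weights[order]
    contrib = np.where(finite, vals, 0.0) * w[:, None]
    counts = finite.sum(axis=0)
    scores = contrib.sum(axis=0) / counts
    return pd.DataFrame(
        {
            "sample_id": list(betas.columns),
            "tnsc": scores,
            "n_probes_used": counts.astype(int),
        }
    )
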