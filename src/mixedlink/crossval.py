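"""k-fold cross-validated cross-entropy and paired model comparison.

A random balanced partition splits the n samples into k blocks of
nearly equal size.  For a fixed model spec, each block is predicted by
the model refitted on its complement, and the loss is the average
negative log predictive probability of the true label,

    CE(B) = -(1/n) * sum_i log pi-hat_{i, y_i}^{k(i)}.

Because a single partition is noisy, several independent partitions are
drawn and two model specs are compared by a one-sided paired t-test on
their per-partition CE values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import category_probs, fit_mle
from .model import ModelSpec, SampleTable

__all__ = [
    "Partition",
    "make_partition",
    "cross_entropy_from_probs",
    "cross_entropy_loss",
    "cv_table",
    "compare_models_ttest",
]


def cross_entropy_from_probs(probs, labels, clip: float = 1e-12) -> float:
    """Average negative log predictive probability of the true labels.

    ``probs`` has one row of category probabilities per sample and
    ``labels`` the true category indices; probabilities are clipped at
    ``clip`` before the log so the loss stays finite.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    picked = np.clip(probs[np.arange(len(labels)), labels], clip, None)
    return float(-np.mean(np.log(picked)))


@dataclass(frozen=True)
class Partition:
    """A balanced k-block partition of {0, ..., n-1}."""

    n: int
    k: int
    assignment: np.ndarray  # block label per sample, shape (n,)
    seed: int

    def block(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == label)


def make_partition(n: int, k: int, seed: int, stratify_labels=None) -> Partition:
    """Uniformly random balanced partition, reproducible from the seed.

    Block sizes differ by at most one.  By default the split is a simple
    random one; passing per-sample ``stratify_labels`` balances label
    frequencies across blocks instead (off by default because the plain
    random split is the primitive the CE loss is defined over).
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    base = np.arange(n) % k  # sizes differ by at most 1
    assignment = np.empty(n, dtype=int)
    if stratify_labels is None:
        assignment[rng.permutation(n)] = base
    else:
        labels = np.asarray(stratify_labels)
        counter = 0
        for lab in pd.unique(labels):
            idx = np.flatnonzero(labels == lab)
            perm = rng.permutation(len(idx))
            assignment[idx[perm]] = (np.arange(len(idx)) + counter) % k
            counter += len(idx)
    return Partition(n=n, k=k, assignment=assignment, seed=seed)


def cross_entropy_loss(
    spec: ModelSpec,
    data: SampleTable,
    partition: Partition,
    clip: float = 1e-12,
    fit_options: dict | None = None,
) -> float:
    """Held-out cross-entropy of ``spec`` over one partition.

    Requires individual-level data (one trial per row) so each sample
    has a single true label.  A fold whose refit does not converge is
    used anyway (best available fit) with a warning.
    """
    if np.any(data.row_totals != 1):
        raise ValueError("cross-validation needs one observation per row")
    if partition.n != data.m:
        raise ValueError("partition size does not match the data")
    fit_options = dict(fit_options or {})
    fit_options.setdefault("compute_vcov", False)
    labels = np.argmax(data.Y, axis=1)
    total = 0.0
    for b in range(partition.k):
        held = partition.block(b)
        train = np.flatnonzero(partition.assignment != b)
        fit = fit_mle(spec, data.subset(train), **fit_options)
        if not fit.converged:
            warnings.warn(
                f"fold {b}: refit of {spec.name} did not converge; "
                "using its best available fit",
                RuntimeWarning,
                stacklevel=2,
            )
        pi = category_probs(fit.spec, fit.theta, data.X[held], check=False)
        total += cross_entropy_from_probs(pi, labels[held], clip) * len(held)
    return total / data.m


def cv_table(
    specs: dict[str, ModelSpec] | list[ModelSpec],
    data: SampleTable,
    n_partitions: int = 10,
    k: int = 10,
    seed_base: int = 1,
    fit_options: dict | None = None,
) -> pd.DataFrame:
    """CE per (model, partition) for several specs on shared partitions.

    Partitions use seeds ``seed_base .. seed_base + n_partitions - 1``
    and are identical across models, so columns are paired.  Returns a
    DataFrame with one row per partition and one column per model name.
    """
    if not isinstance(specs, dict):
        specs = {s.name: s for s in specs}
    parts = [make_partition(data.m, k, seed_base + r) for r in range(n_partitions)]
    out = {
        name: [cross_entropy_loss(spec, data, part, fit_options=fit_options) for part in parts]
        for name, spec in specs.items()
    }
    table = pd.DataFrame(out, index=[p.seed for p in parts])
    table.index.name = "partition_seed"
    return table


def compare_models_ttest(ce_a, ce_b) -> float:
    """One-sided paired t-test p-value for H1: mean CE_a < mean CE_b.

    The pairs must come from the same partitions.  With zero variance of
    the differences the answer is still defined by the sign of the mean
    difference; identical vectors are degenerate and raise.
    """
    a = np.asarray(ce_a, dtype=float)
    b = np.asarray(ce_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two paired vectors of equal length >= 2")
    diff = a - b
    if np.all(diff == 0.0):
        raise ValueError("all paired differences are exactly zero")
    if np.var(diff) == 0.0:
        return 0.0 if diff.mean() < 0 else 1.0
    return float(stats.ttest_rel(a, b, alternative="less").pvalue)
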