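"""Scikit-learn estimator interface to the mixed-link models.

:class:`MultinomialMixedLink` is a classifier in the sklearn sense: it
composes with pipelines, `clone`, and model selection.  It predicts a
probability for each of J ordered response categories from a linear
predictor per non-baseline comparison, where each comparison may use
its own link function and the comparisons share slopes under the
proportional-odds assumption.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .inference import fit_mle, wald_inference
from .links import DEFAULT_EPS
from .model import ModelSpec, SampleTable

__all__ = ["MultinomialMixedLink"]


class MultinomialMixedLink(BaseEstimator, ClassifierMixin):
    """Multinomial regression with per-category links.

    Parameters
    ----------
    structure : str, default "cumulative"
        How the modelled ratios relate to category probabilities:
        "baseline", "cumulative", "adjacent", or "continuation".
    links : str or sequence of str, default "logit"
        Link per comparison j = 1..J-1 ("logit", "probit", "loglog",
        "cloglog").  A single string is broadcast to all comparisons.
    odds : str, default "po"
        "po" for shared slopes across comparisons, "npo" for
        per-comparison slopes.
    categories : sequence or None
        Fixed category order; the LAST category is the baseline.  By
        default the sorted unique labels of ``y``.
    max_iter, tol, grad_tol, clip_eps :
        Fisher-scoring controls; see :func:`mixedlink.inference.fit_mle`.

    Attributes
    ----------
    classes_ : ndarray of category labels in model order (last = baseline).
    intercept_ : ndarray, shape (J-1,)
    coef_ : ndarray, shape (d,) for po or (J-1, d) for npo
    theta_, vcov_, loglik_, aic_, bic_, converged_, n_iter_

    Examples
    --------
    >>> est = MultinomialMixedLink("cumulative", ("loglog", "logit"))
    >>> est.fit(X, y).predict_proba(X[:3])   # doctest: +SKIP
    """

    def __init__(
        self,
        structure: str = "cumulative",
        links="logit",
        odds: str = "po",
        categories=None,
        max_iter: int = 200,
        tol: float = 1e-10,
        grad_tol: float = 1e-6,
        clip_eps: float = DEFAULT_EPS,
    ):
        self.structure = structure
        self.links = links
        self.odds = odds
        self.categories = categories
        self.max_iter = max_iter
        self.tol = tol
        self.grad_tol = grad_tol
        self.clip_eps = clip_eps

    # ------------------------------------------------------------------
    def _resolve_spec(self, J: int, d: int) -> ModelSpec:
        links = self.links
        if isinstance(links, str):
            links = (links,) * (J - 1)
        links = tuple(links)
        if len(links) != J - 1:
            raise ValueError(
                f"need {J - 1} links for {J} categories, got {len(links)}"
            )
        return ModelSpec(self.structure, links, self.odds, d=d)

    def fit(self, X, y, sample_weight=None):
        """Fit by maximum likelihood.

        ``y`` may be a 1-D array of labels (one trial per row of X) or a
        2-D array of per-row multinomial counts with J columns.
        """
        if sample_weight is not None:
            raise NotImplementedError("sample_weight is not supported")
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if y.ndim == 2:
            table = SampleTable(X, y)
            self.classes_ = (
                np.asarray(list(self.categories))
                if self.categories is not None
                else np.arange(y.shape[1])
            )
        else:
            cats = list(self.categories) if self.categories is not None else None
            table = SampleTable.from_labels(X, y, categories=cats)
            self.classes_ = np.asarray(
                cats if cats is not None else list(np.unique(y))
            )
        spec = self._resolve_spec(table.J, table.d)
        result = fit_mle(
            spec,
            table,
            max_iter=self.max_iter,
            tol=self.tol,
            grad_tol=self.grad_tol,
            clip_eps=self.clip_eps,
        )
        K = spec.J - 1
        self.result_ = result
        self.spec_ = spec
        self.theta_ = result.theta
        self.intercept_ = result.theta[:K]
        if spec.odds == "po":
            self.coef_ = result.theta[K:]
        else:
            self.coef_ = result.theta[K:].reshape(K, table.d)
        self.vcov_ = result.vcov
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        self.bic_ = result.bic
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.n_features_in_ = table.d
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "result_")
        X = check_array(X, dtype=float)
        return self.result_.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def conf_int(self, coef, level: float = 0.95):
        """Wald confidence interval and p-value for one coefficient.

        ``coef`` is an index into theta or a coefficient name; returns
        (lower, upper, p_value).
        """
        check_is_fitted(self, "result_")
        return wald_inference(self.result_, coef, level)
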