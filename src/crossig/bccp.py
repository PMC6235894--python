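"""Bayesian compound covariate prediction (BCCP).

The compound covariate of a sample is the t-statistic-weighted sum of its
(standardized) signature-gene expression values, c_i = sum_j t_j x_ij.
Training fits a two-class equal-variance Gaussian model of c: class means
m1 (perturbation-like signature present) and m2 (absent), pooled within-class
SD s, and class priors (default 0.5/0.5). The posterior

    p1 = pi1 phi(c; m1, s) / (pi1 phi(c; m1, s) + pi2 phi(c; m2, s))

is computed in log space; samples are called signature-present when
p1 > cutoff (default 0.5, ties -> absent).

``BCCPClassifier`` is the scikit-learn estimator; ``train`` / ``predict`` /
``loocv`` are matrix-level wrappers working on ExpressionMatrix objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix
from .signature import CONTROL, PERTURBED, GeneSignature, SignatureSelector

logger = logging.getLogger("crossig")

ASS_PRESENT = "ASS_present"
ASS_ABSENT = "ASS_absent"


class BCCPClassifier(BaseEstimator, ClassifierMixin):
    """Compound-covariate classifier with a Gaussian Bayes posterior.

    Parameters
    ----------
    weights : optional per-feature weights t_j. When None, they are computed
        at fit time as the training pooled-variance t-statistics
        (class 1 minus class 0), the classical compound-covariate choice.
    priors : class priors (pi0, pi1); default equal priors rather than the
        empirical class frequencies.
    cutoff : posterior threshold; a sample is called class 1 when
        P(class 1 | c) > cutoff, strictly.

    Fitted attributes: ``weights_``, ``m1_`` (class-1 mean of c), ``m0_``,
    ``s_`` (pooled within-class SD of c), ``classes_``.
    """

    def __init__(self, weights=None, priors=(0.5, 0.5), cutoff: float = 0.5):
        self.weights = weights
        self.priors = priors
        self.cutoff = cutoff

    # -- core algebra ------------------------------------------------------
    def _validate(self):
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must be in (0,1)")
        p0, p1 = self.priors
        if p0 < 0 or p1 < 0 or abs(p0 + p1 - 1.0) > 1e-12:
            raise ValueError("priors must be non-negative and sum to 1")

    def compound_covariate(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights_.shape[0]:
            raise ValueError("feature count does not match weights")
        return X @ self.weights_

    def fit(self, X, y):
        self._validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("BCCP is a two-class model")
        if X.shape[1] == 0:
            raise ValueError("no signature genes to combine")
        pos = y == self.classes_[1]
        if pos.sum() < 2 or (~pos).sum() < 2:
            raise ValueError("need >=2 samples per class")
        if self.weights is None:
            from .signature import _t_vectorized

            t, _, _ = _t_vectorized(X[pos].T, X[~pos].T)
            w = np.where(np.isfinite(t), t, 0.0)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape[0] != X.shape[1]:
                raise ValueError("weights length does not match features")
        self.weights_ = w
        c = X @ w
        c1, c0 = c[pos], c[~pos]
        self.m1_ = float(c1.mean())
        self.m0_ = float(c0.mean())
        n1, n0 = len(c1), len(c0)
        sp2 = ((n1 - 1) * c1.var(ddof=1) + (n0 - 1) * c0.var(ddof=1)) / (
            n1 + n0 - 2
        )
        self.s_ = float(np.sqrt(sp2))
        if self.s_ == 0.0:
            raise ValueError(
                "degenerate training: pooled SD of the compound covariate is 0"
            )
        return self

    def posterior_from_c(self, c) -> np.ndarray:
        """P(class 1 | c) from the two-Gaussian equal-variance model."""
        check_is_fitted(self, "s_")
        c = np.asarray(c, dtype=float)
        p0, p1 = self.priors
        if p1 == 0.0:
            return np.zeros_like(c)
        if p0 == 0.0:
            return np.ones_like(c)
        # log pi_k - (c-m_k)^2 / (2 s^2); equal variances cancel the normalizer
        l1 = np.log(p1) - (c - self.m1_) ** 2 / (2.0 * self.s_**2)
        l0 = np.log(p0) - (c - self.m0_) ** 2 / (2.0 * self.s_**2)
        m = np.maximum(l1, l0)
        e1 = np.exp(l1 - m)
        e0 = np.exp(l0 - m)
        return e1 / (e1 + e0)

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.posterior_from_c(self.compound_covariate(X))
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        return self.compound_covariate(X)

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        at_cut = p1 == self.cutoff
        if at_cut.any():
            logger.info(
                "%d samples exactly at the posterior cutoff -> class 0",
                int(at_cut.sum()),
            )
        return np.where(p1 > self.cutoff, self.classes_[1], self.classes_[0])

    # -- persistence -------------------------------------------------------
    def to_dict(self, genes=None) -> dict:
        check_is_fitted(self, "s_")
        return {
            "weights": list(map(float, self.weights_)),
            "genes": list(genes) if genes is not None else None,
            "m1": self.m1_,
            "m0": self.m0_,
            "s": self.s_,
            "priors": list(self.priors),
            "cutoff": self.cutoff,
            "classes": [str(c) for c in self.classes_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BCCPClassifier":
        clf = cls(priors=tuple(d["priors"]), cutoff=d["cutoff"])
        clf.weights_ = np.asarray(d["weights"], dtype=float)
        clf.m1_ = float(d["m1"])
        clf.m0_ = float(d["m0"])
        clf.s_ = float(d["s"])
        clf.classes_ = np.asarray(d["classes"])
        clf._genes = d.get("genes")
        return clf


# ---------------------------------------------------------------------------
# matrix-level wrappers


@dataclass
class ClassCall:
    sample_id: str
    c: float
    p1: float
    label: str


def compound_covariate(sample_values: pd.Series, weights: pd.Series) -> float:
    """Weighted sum over signature genes for a single sample.

    Genes missing from the sample are dropped pairwise with a warning; zero
    overlap is an error.
    """
    common = weights.index.intersection(sample_values.index)
    if len(common) == 0:
        raise ValueError("no signature gene present in sample")
    if len(common) < len(weights):
        logger.warning(
            "%d signature genes missing; using %d",
            len(weights) - len(common),
            len(common),
        )
    return float((sample_values.loc[common] * weights.loc[common]).sum())


def _aligned_matrix(m: ExpressionMatrix, genes) -> np.ndarray:
    present = [g for g in genes if g in m.values.index]
    if not present:
        raise ValueError("no signature gene present in matrix")
    if len(present) < len(genes):
        logger.warning(
            "%d signature genes missing from matrix", len(genes) - len(present)
        )
    return m.values.loc[present].T.to_numpy(), present


def train(
    m: ExpressionMatrix,
    labels: pd.Series,
    signature: GeneSignature,
    priors=(0.5, 0.5),
    cutoff: float = 0.5,
) -> tuple[BCCPClassifier, list[str]]:
    """Fit the BCCP model on a standardized training matrix.

    Weights are the signature t-statistics; class 1 is the perturbed /
    signature-present class. Returns the fitted classifier and the gene list
    actually used (signature genes present in the matrix).
    """
    X, genes = _aligned_matrix(m, signature.genes)
    w = signature.weights.loc[genes].to_numpy()
    labels = labels.reindex(m.sample_ids)
    y = np.where(labels.isin([PERTURBED, ASS_PRESENT]), 1, 0)
    clf = BCCPClassifier(weights=w, priors=priors, cutoff=cutoff).fit(X, y)
    return clf, genes


def posterior(c, model: BCCPClassifier) -> np.ndarray:
    """P(signature present | compound covariate c)."""
    return model.posterior_from_c(c)


def predict(
    m: ExpressionMatrix, model: BCCPClassifier, genes: list[str]
) -> pd.DataFrame:
    """Per-sample compound covariate, posterior and dichotomized call."""
    X, present = _aligned_matrix(m, genes)
    if len(present) < len(genes):
        w = pd.Series(model.weights_, index=genes).loc[present].to_numpy()
        sub = BCCPClassifier(priors=model.priors, cutoff=model.cutoff)
        sub.weights_, sub.m1_, sub.m0_, sub.s_ = w, model.m1_, model.m0_, model.s_
        sub.classes_ = model.classes_
        model = sub
    c = model.compound_covariate(X)
    p1 = model.posterior_from_c(c)
    label = np.where(p1 > model.cutoff, ASS_PRESENT, ASS_ABSENT)
    return pd.DataFrame(
        {"c": c, "p1": p1, "label": label}, index=pd.Index(m.sample_ids, name="sample_id")
    )


def loocv(
    m: ExpressionMatrix,
    labels: pd.Series,
    fold: float = 1.5,
    p: float = 0.005,
    priors=(0.5, 0.5),
    cutoff: float = 0.5,
) -> dict:
    """Honest leave-one-out cross-validation.

    Each fold re-derives the signature (fold + p filters, on the log2 scale)
    AND re-trains the classifier on the n-1 remaining samples; per-gene
    standardization uses training-fold means/SDs only, applied identically to
    the held-out sample. An empty in-fold signature makes the posterior fall
    back to the prior (logged); a fold that would lose one class entirely is
    skipped with a warning. Sensitivity is the recall of the perturbed
    (signature-present) class.
    """
    if m.standardized:
        raise ValueError("LOOCV needs the unstandardized log2 matrix")
    labels = labels.reindex(m.sample_ids)
    y_all = (labels == PERTURBED).to_numpy().astype(int)
    if len(y_all) < 3 or len(np.unique(y_all)) != 2:
        raise ValueError("need >=3 samples and both classes")
    X_raw = m.values.T.to_numpy()  # samples x genes, log2
    calls = {}
    for i, sid in enumerate(m.sample_ids):
        mask = np.ones(len(y_all), dtype=bool)
        mask[i] = False
        y_tr = y_all[mask]
        if y_tr.sum() < 2 or (~y_tr.astype(bool)).sum() < 2:
            logger.warning("fold %s skipped: a class would vanish", sid)
            continue
        sel = SignatureSelector(fold=fold, p=p).fit(X_raw[mask], y_tr)
        idx = sel.selected_idx_
        if len(idx) == 0:
            logger.info("fold %s: empty in-fold signature, prior fallback", sid)
            p1 = priors[1]
        else:
            tr = X_raw[mask][:, idx]
            mu = tr.mean(axis=0)
            sd = tr.std(axis=0, ddof=1)
            sd[sd == 0.0] = 1.0
            clf = BCCPClassifier(priors=priors, cutoff=cutoff).fit(
                (tr - mu) / sd, y_tr
            )
            held = (X_raw[i : i + 1, idx] - mu) / sd
            p1 = float(clf.predict_proba(held)[0, 1])
        calls[sid] = (p1, int(p1 > cutoff), int(y_all[i]))
    if not calls:
        raise ValueError("no fold could be evaluated")
    dfc = pd.DataFrame(
        calls.values(), index=pd.Index(calls.keys(), name="sample_id"),
        columns=["p1", "call", "truth"],
    )
    tp = int(((dfc.call == 1) & (dfc.truth == 1)).sum())
    tn = int(((dfc.call == 0) & (dfc.truth == 0)).sum())
    npos = int((dfc.truth == 1).sum())
    nneg = int((dfc.truth == 0).sum())
    return {
        "misclassification_rate": 1.0 - (tp + tn) / len(dfc),
        "sensitivity": tp / npos if npos else float("nan"),
        "specificity": tn / nneg if nneg else float("nan"),
        "calls": dfc,
    }
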