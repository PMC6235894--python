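"""Concordance of the signature call with alternative molecular subtype
labels: cross-tabulation with Pearson chi-square (no continuity correction),
plus generic classifiers to produce subtype labels from user-supplied
signatures when a cohort lacks them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .bccp import BCCPClassifier
from .io import ExpressionMatrix

logger = logging.getLogger("crossig")


@dataclass
class CrossTab:
    table: pd.DataFrame  # calls as rows, subtype levels as columns
    chi2: float
    df: int
    p: float


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin; expected counts undefined")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


class CorrelationNearestCentroid(BaseEstimator, ClassifierMixin):
    """Nearest-centroid classifier with Pearson correlation similarity.

    ``fit(centroids, class_names)`` takes a (genes x classes) array; a sample
    is assigned the class whose centroid has the highest Pearson correlation
    with its signature-gene vector.
    """

    def fit(self, centroids, classes):
        centroids = np.asarray(centroids, dtype=float)
        if centroids.ndim != 2 or centroids.shape[1] != len(classes):
            raise ValueError("centroids must be genes x classes")
        self.centroids_ = centroids
        self.classes_ = np.asarray(classes)
        return self

    def _corr(self, X) -> np.ndarray:
        check_is_fitted(self, "centroids_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        xc = X - X.mean(axis=1, keepdims=True)
        cc = self.centroids_ - self.centroids_.mean(axis=0, keepdims=True)
        num = xc @ cc
        den = np.outer(
            np.sqrt((xc**2).sum(axis=1)), np.sqrt((cc**2).sum(axis=0))
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / den, 0.0)
        return r

    def predict(self, X):
        r = self._corr(X)
        return self.classes_[np.argmax(r, axis=1)]


def classify_external(
    m: ExpressionMatrix,
    ext_signature: pd.DataFrame,
    method: str = "nearest_centroid",
    min_overlap: int = 10,
) -> pd.Series:
    """Assign each sample a label from an external two-class signature.

    ``ext_signature`` is indexed by gene. For ``nearest_centroid`` its
    columns are the per-class centroids (column names become the labels).
    For ``bccp`` it must carry a ``weight`` column; the compound covariate is
    computed with those weights, split into two components (2-means on c),
    and the higher-c component is labeled with the class the positive
    weights favor (column name convention ``pos_class``/``neg_class`` in
    ``ext_signature.attrs``, defaulting to "high"/"low").
    """
    common = ext_signature.index.intersection(m.values.index)
    if len(common) < min_overlap:
        raise ValueError(
            f"only {len(common)} signature genes overlap (min {min_overlap})"
        )
    X = m.values.loc[common].T.to_numpy()
    if method == "nearest_centroid":
        cents = ext_signature.loc[common]
        clf = CorrelationNearestCentroid().fit(
            cents.to_numpy(), cents.columns.to_numpy()
        )
        labels = clf.predict(X)
    elif method == "bccp":
        w = ext_signature.loc[common, "weight"].to_numpy(dtype=float)
        c = X @ w
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(c.reshape(-1, 1))
        hi = int(np.argmax(km.cluster_centers_.ravel()))
        pos = ext_signature.attrs.get("pos_class", "high")
        neg = ext_signature.attrs.get("neg_class", "low")
        labels = np.where(km.labels_ == hi, pos, neg)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(labels, index=m.values.columns, name="label")


def rs_dichotomize(rs_scores) -> pd.Series:
    """Dichotomize a 0-100 recurrence-risk score at >50 (strict)."""
    rs = pd.Series(rs_scores, dtype=float)
    if ((rs < 0) | (rs > 100)).any():
        raise ValueError("RS scores must lie in [0,100]")
    return pd.Series(np.where(rs > 50, "high", "low"), index=rs.index, name="RS")


def concordance_report(
    calls: pd.Series, subtype_labels: pd.DataFrame
) -> dict[str, CrossTab]:
    """One cross-tabulation + chi-square per subtype column.

    Samples missing either label are dropped per column; margins always
    reconcile with the retained label counts.
    """
    if subtype_labels.shape[1] == 0:
        raise ValueError("need at least one subtype column")
    out: dict[str, CrossTab] = {}
    for col in subtype_labels.columns:
        sub = pd.DataFrame(
            {"call": calls, "subtype": subtype_labels[col]}
        ).dropna()
        tab = pd.crosstab(sub["call"], sub["subtype"])
        try:
            chi2, df, p = chi_square_test(tab.to_numpy())
        except ValueError as err:
            logger.warning("subtype %s: %s", col, err)
            continue
        out[col] = CrossTab(table=tab, chi2=chi2, df=df, p=p)
    return out
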