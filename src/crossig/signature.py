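"""Derivation of the perturbation expression signature.

The signature is the set of genes passing BOTH a fold-change filter
(|difference of log2 class means| >= log2(fold_threshold)) and a pooled-
variance two-sample t-test at p < p_threshold, with the perturbed-vs-control
direction recorded per gene. A ``shared_signature`` operation intersects
per-cohort differential gene sets requiring direction consistency.

``SignatureSelector`` exposes the same selection as a scikit-learn
transformer (fit on samples x genes, transform subsets columns);
``derive_signature`` is the matrix-level wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix

logger = logging.getLogger("crossig")

PERTURBED = "perturbed"
CONTROL = "control"


def two_sample_t(x, y, *, welch: bool = False):
    """Pooled-variance two-sample t-test (Student), two-sided.

    Returns ``(t_stat, p_value, mean_diff)`` with ``mean_diff = mean(x) -
    mean(y)``. Degenerate zero-variance inputs: equal means give t=0, p=1;
    unequal means give t=+/-inf, p=0 (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each class needs at least 2 samples")
    t, p, d = _t_vectorized(x[None, :], y[None, :], welch=welch)
    return float(t[0]), float(p[0]), float(d[0])


def _t_vectorized(xa: np.ndarray, ya: np.ndarray, *, welch: bool = False):
    """Row-wise two-sample t over (genes x samples) arrays."""
    n1, n2 = xa.shape[1], ya.shape[1]
    m1 = xa.mean(axis=1)
    m2 = ya.mean(axis=1)
    diff = m1 - m2
    v1 = xa.var(axis=1, ddof=1)
    v2 = ya.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
            t = diff / np.sqrt(se2)
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            df = np.full(diff.shape, float(n1 + n2 - 2))
            t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero_var = ~np.isfinite(t)
    if zero_var.any():
        # zero pooled variance: equal means -> t=0,p=1; unequal -> +/-inf,p=0
        t = np.where(zero_var & (diff == 0.0), 0.0, t)
        t = np.where(zero_var & (diff != 0.0), np.sign(diff) * np.inf, t)
        n_deg = int(zero_var.sum())
        logger.warning("%d genes with zero pooled variance", n_deg)
    p = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df)
    )
    p = np.where((t == 0.0) & zero_var, 1.0, p)
    return t, p, diff


@dataclass
class GeneSignature:
    """Ordered differential-expression signature.

    ``entries`` is a DataFrame indexed by gene with columns ``t``, ``diff``
    (log2 units, perturbed minus control), ``p`` and ``direction``
    (``up_in_perturbed`` / ``down_in_perturbed``), ordered by p ascending.
    """

    entries: pd.DataFrame
    fold_threshold: float = 1.5
    p_threshold: float = 0.005

    def __post_init__(self) -> None:
        if len(self.entries):
            lfc = np.log2(self.fold_threshold)
            if (np.abs(self.entries["diff"]) < lfc - 1e-12).any():
                raise ValueError("signature entry below fold threshold")
            if (self.entries["p"] >= self.p_threshold).any():
                raise ValueError("signature entry above p threshold")
            want = np.where(
                self.entries["diff"] > 0, "up_in_perturbed", "down_in_perturbed"
            )
            if (self.entries["direction"] != want).any():
                raise ValueError("direction inconsistent with sign of diff")

    @property
    def genes(self) -> list[str]:
        return self.entries.index.tolist()

    @property
    def weights(self) -> pd.Series:
        """Training t-statistics, the compound-covariate weights."""
        return self.entries["t"]

    def __len__(self) -> int:
        return len(self.entries)


class SignatureSelector(BaseEstimator, TransformerMixin):
    """Select differentially expressed features by fold change + t-test p.

    Parameters
    ----------
    fold : ratio threshold on the (geometric-mean) fold change; a feature
        passes when |mean(log2 A) - mean(log2 B)| >= log2(fold).
    p : raw two-sided p-value threshold (no multiple-testing correction).
    welch : use Welch's t instead of the pooled-variance Student t.

    After ``fit(X, y)`` (X samples x genes on the log2 scale, y binary with
    1 = perturbed), ``support_`` marks selected columns, ``stats_`` holds per
    selected feature (t, diff, p, direction) ordered by p ascending.
    """

    def __init__(self, fold: float = 1.5, p: float = 0.005, welch: bool = False):
        self.fold = fold
        self.p = p
        self.welch = welch

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("need exactly two classes")
        pos = y == classes.max() if classes.dtype.kind in "biuf" else y == classes[1]
        if pos.sum() < 2 or (~pos).sum() < 2:
            raise ValueError("need >=2 samples per class")
        t, pv, diff = _t_vectorized(X[pos].T, X[~pos].T, welch=self.welch)
        lfc = np.log2(self.fold)
        sel = (np.abs(diff) >= lfc) & (pv < self.p)
        self.n_features_in_ = X.shape[1]
        self.support_ = sel
        self.t_ = t
        self.p_values_ = pv
        self.diff_ = diff
        order = np.argsort(pv[sel], kind="stable")
        idx = np.flatnonzero(sel)[order]
        self.selected_idx_ = idx
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_idx_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return self.selected_idx_ if indices else self.support_


def derive_signature(
    m: ExpressionMatrix,
    labels: pd.Series,
    fold: float = 1.5,
    p: float = 0.005,
    *,
    welch: bool = False,
) -> GeneSignature:
    """Derive the perturbed-vs-control signature from a log2 matrix.

    ``m`` must NOT be standardized (the fold filter needs log2 units).
    Genes passing both filters are returned ordered by p ascending; an empty
    result is valid (logged as a warning).
    """
    if m.standardized:
        raise ValueError("signature derivation needs unstandardized log2 data")
    labels = labels.reindex(m.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample needs a class label")
    y = (labels == PERTURBED).to_numpy().astype(int)
    if set(labels.unique()) - {PERTURBED, CONTROL}:
        raise ValueError(f"labels must be {{{PERTURBED!r}, {CONTROL!r}}}")
    sel = SignatureSelector(fold=fold, p=p, welch=welch).fit(m.values.T.to_numpy(), y)
    idx = sel.selected_idx_
    genes = m.values.index.to_numpy()[idx]
    entries = pd.DataFrame(
        {
            "t": sel.t_[idx],
            "diff": sel.diff_[idx],
            "p": sel.p_values_[idx],
            "direction": np.where(
                sel.diff_[idx] > 0, "up_in_perturbed", "down_in_perturbed"
            ),
        },
        index=pd.Index(genes, name="gene"),
    )
    if not len(entries):
        logger.warning("no gene passed the signature filters")
    return GeneSignature(entries=entries, fold_threshold=fold, p_threshold=p)


def shared_signature(per_cohort_de: list[pd.DataFrame]) -> pd.DataFrame:
    """Intersect per-cohort DE gene sets requiring consistent direction.

    Each input frame is indexed by gene with a ``direction`` column. Returns
    the genes significant with the SAME direction in every cohort, with that
    direction.
    """
    if len(per_cohort_de) < 2:
        raise ValueError("need at least 2 cohorts")
    common = set(per_cohort_de[0].index)
    for de in per_cohort_de[1:]:
        common &= set(de.index)
    keep = []
    for g in per_cohort_de[0].index:  # preserve first-cohort order
        if g not in common:
            continue
        dirs = {de.loc[g, "direction"] for de in per_cohort_de}
        if len(dirs) == 1:
            keep.append((g, dirs.pop()))
    return pd.DataFrame(keep, columns=["gene", "direction"]).set_index("gene")
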