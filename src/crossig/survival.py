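"""Kaplan-Meier estimation, the two-group log-rank test, Cox proportional
hazards (Efron ties) and stage-restricted subgroup analysis.

KM and Cox go through lifelines; the log-rank statistic is computed directly
from risk sets (observed-minus-expected with the hypergeometric variance),
which also yields the classical identity with the Cox score test for a
binary covariate without tied event times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .io import ClinicalTable

logger = logging.getLogger("crossig")


@dataclass
class KMEstimate:
    """Product-limit survival curve.

    ``timeline`` includes t=0 with S(0)=1; events precede censorings at tied
    times (the standard right-censoring convention).
    """

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    variance: np.ndarray | None = None

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_fit(times, events) -> KMEstimate:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    table = kmf.event_table
    at_risk = table["at_risk"].to_numpy(dtype=float)
    ev = table["observed"].to_numpy(dtype=float)
    var = kmf.confidence_interval_  # Greenwood-based bounds exist; variance below
    greenwood = (
        surv**2
        * np.cumsum(np.where(at_risk > ev, ev / (at_risk * (at_risk - ev)), 0.0))
    )
    return KMEstimate(
        timeline=timeline, survival=surv, at_risk=at_risk, events=ev,
        variance=greenwood,
    )


def logrank(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test.

    Sums observed-minus-expected events for group 1 over the distinct event
    times, with the hypergeometric variance (including the multiplicity
    factor (n-d)/(n-1) at tied event times); returns the 1-df chi-square
    statistic and its p-value.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    if not ((group == 0).any() and (group == 1).any()):
        raise ValueError("both groups must be non-empty")
    if events.sum() == 0:
        raise ValueError("log-rank undefined with zero events")
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        dead = at_risk & (times == t) & (events == 1)
        d = dead.sum()
        d1 = (dead & (group == 1)).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_score_chi2(times, events, x) -> float:
    """Cox partial-likelihood score test at beta=0 for one covariate.

    With a binary covariate and no tied event times this equals the log-rank
    chi-square exactly.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    u = 0.0
    info = 0.0
    for t in np.unique(times[events == 1]):
        risk = times >= t
        xr = x[risk]
        dead = risk & (times == t) & (events == 1)
        d = int(dead.sum())
        xbar = xr.mean()
        u += x[dead].sum() - d * xbar
        info += d * (np.mean(xr**2) - xbar**2)
    if info == 0.0:
        return 0.0
    return float(u**2 / info)


@dataclass
class CoxFit:
    summary: pd.DataFrame  # per covariate: beta, HR, CI bounds, p
    log_likelihood: float
    n: int
    n_dropped: int

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "HR"])


def cox_fit(
    clinical: ClinicalTable | pd.DataFrame,
    covariates: list[str],
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional hazards via Newton-Raphson on the partial likelihood.

    Missing covariate rows are listwise-deleted and the dropped count
    reported. Wald 95% CIs.
    """
    df = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    cols = ["os_months", "os_event", *covariates]
    sub = df[cols].apply(pd.to_numeric, errors="raise")
    n0 = len(sub)
    sub = sub.dropna()
    n_dropped = n0 - len(sub)
    if n_dropped:
        logger.info("cox_fit: listwise-deleted %d rows with missing covariates", n_dropped)
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    if sub["os_event"].sum() < 1:
        raise ValueError("no events; Cox model not estimable")
    for c in covariates:
        if sub[c].nunique() < 2:
            raise ValueError(f"constant covariate {c!r} is not identifiable")
    cph = CoxPHFitter()
    cph.fit(sub, duration_col="os_months", event_col="os_event")
    s = cph.summary
    summary = pd.DataFrame(
        {
            "beta": s["coef"],
            "HR": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=len(sub),
        n_dropped=n_dropped,
    )


def subgroup_survival(
    clinical: ClinicalTable,
    calls: pd.Series,
    strata: list | None = None,
    stage_col: str = "stage",
) -> dict:
    """KM + log-rank of the signature call restricted to given stage strata.

    A stratum with fewer than 2 patients, or with one call group empty, is
    reported without a test (warning). ``strata=None`` uses the whole cohort.
    """
    df = clinical.data.copy()
    df["call"] = calls.reindex(df.index)
    if strata is not None:
        df = df[df[stage_col].isin(strata)]
    out: dict = {"n": len(df)}
    if len(df) < 2:
        logger.warning("subgroup has <2 patients; no test")
        out["logrank"] = None
        return out
    groups = df["call"].dropna().unique()
    if len(groups) < 2:
        logger.warning("one call group empty within subgroup; no test")
        out["logrank"] = None
        return out
    g = (df["call"] == sorted(groups)[1]).astype(int).to_numpy()
    chi2, p = logrank(df["os_months"].to_numpy(), df["os_event"].to_numpy(), g)
    out["logrank"] = {"chi2": chi2, "p": p}
    out["km"] = {
        lab: km_fit(
            df.loc[df["call"] == lab, "os_months"],
            df.loc[df["call"] == lab, "os_event"],
        )
        for lab in sorted(groups)
    }
    out["group_sizes"] = df["call"].value_counts().to_dict()
    return out
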