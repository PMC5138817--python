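"""Prognosis stage: signature normalization, median dichotomization, Cox
proportional-hazards models, Kaplan-Meier curves, weighted (G-rho) log-rank
tests, and cross-dataset agreement statistics (ICC, Kruskal-Wallis).

Signatures are first min-max normalized to [0, 1] WITHIN each cohort (the
two cohorts come from different scanners/protocols, so pooled normalization
would leak protocol into the signature), then split at the cohort median
into low (0) / high (1) status; the status enters the Cox model. Cox fits
use lifelines with the Efron approximation for tied event times — survival
times on a months scale tie often. Tests are two-sided and flagged
significant at p < 0.05.

The G-rho (Harrington-Fleming) family weights each event time by
S(t-)^rho, where S is the left-continuous pooled Kaplan-Meier estimate:
rho = 0 is the standard log-rank test, rho = 1 (the default here)
up-weights early survival differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats as sps

__all__ = [
    "SurvivalRecord",
    "CoxFit",
    "KMCurve",
    "normalize_01",
    "dichotomize_median",
    "cox_fit",
    "km_estimate",
    "grho_logrank",
    "icc_agreement",
    "kruskal_wallis",
    "signature_report",
]

ALPHA = 0.05  # two-sided significance threshold


@dataclass
class SurvivalRecord:
    """One subject of a survival analysis (low-level container)."""

    id: str
    time: float  # months, > 0
    event: int  # 1 = death observed, 0 = censored
    covariates: dict = field(default_factory=dict)
    signature_status: dict = field(default_factory=dict)  # name -> 0 (low) / 1 (high)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class CoxFit:
    """Per-term estimates and global statistics of a Cox PH fit."""

    terms: dict  # name -> dict(coef, hr, ci_low, ci_high, p)
    log_likelihood: float
    n: int
    n_events: int

    def hr(self, term: str) -> float:
        return self.terms[term]["hr"]

    def p(self, term: str) -> float:
        return self.terms[term]["p"]

    def significant(self, term: str) -> bool:
        return self.terms[term]["p"] < ALPHA


@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    times: np.ndarray
    survival: np.ndarray  # S(t) after each time in `times`
    at_risk: np.ndarray
    median: float  # earliest t with S(t) <= 0.5; inf = not reached
    median_ci: tuple[float, float]


def normalize_01(values) -> np.ndarray:
    """Min-max normalization (x - min) / (max - min) within one cohort."""
    x = np.asarray(values, dtype=float)
    if np.unique(x[~np.isnan(x)]).size < 2:
        raise ValueError("cannot normalize a constant signature (no spread)")
    lo, hi = np.nanmin(x), np.nanmax(x)
    return (x - lo) / (hi - lo)


def dichotomize_median(values) -> np.ndarray:
    """High/low status at the cohort median: value > median -> 1, else 0.

    The median element itself goes to the low group. A constant input yields
    all-low with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    med = np.nanmedian(x)
    status = (x > med).astype(int)
    if status.sum() == 0 and np.unique(x[~np.isnan(x)]).size == 1:
        warnings.warn("constant signature: all patients assigned low status",
                      stacklevel=2)
    return status


def cox_fit(
    data: pd.DataFrame,
    terms: list[str],
    time_col: str = "os_months",
    event_col: str = "event",
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) with Wald CIs.

    Parameters
    ----------
    data : DataFrame with time, event and covariate columns. Non-numeric
        covariates are dummy-coded (first level dropped).
    terms : model terms; one term = univariate model, more = adjusted model.
    """
    if not terms:
        raise ValueError("at least one model term is required")
    df = data[[time_col, event_col] + list(terms)].copy()
    if df[event_col].sum() < 1:
        raise ValueError("Cox model needs at least one observed event")
    for t in terms:
        col = df[t]
        if col.nunique(dropna=True) < 2:
            raise ValueError(f"term {t!r} is constant")
    df = pd.get_dummies(df, columns=[t for t in terms
                                     if not pd.api.types.is_numeric_dtype(df[t])],
                        drop_first=True, dtype=float)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation warnings -> wide CIs, kept
        cph.fit(df, duration_col=time_col, event_col=event_col)
    summary = cph.summary
    terms_out = {
        name: dict(
            coef=float(row["coef"]),
            hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
        )
        for name, row in summary.iterrows()
    }
    return CoxFit(
        terms=terms_out,
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(df)),
        n_events=int(df[event_col].sum()),
    )


def km_estimate(
    data: pd.DataFrame,
    group_col: str | None = None,
    time_col: str = "os_months",
    event_col: str = "event",
) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit curves, one per group.

    The median is the earliest time with S(t) <= 0.5; if the curve never
    drops that far the median is reported as not reached (inf).
    """
    groups = {"all": data} if group_col is None else {
        str(g): sub for g, sub in data.groupby(group_col)
    }
    out: dict[str, KMCurve] = {}
    for g, sub in groups.items():
        if len(sub) == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col])
        times = kmf.survival_function_.index.to_numpy()
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        keep = times > 0
        at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy()
        med = float(kmf.median_survival_time_)
        try:
            ci = median_survival_times(kmf.confidence_interval_)
            med_ci = (float(ci.iloc[0, 0]), float(ci.iloc[0, 1]))
        except Exception:  # degenerate CIs (tiny groups)
            med_ci = (np.nan, np.nan)
        out[g] = KMCurve(times[keep], surv[keep], at_risk[keep], med, med_ci)
    return out


def grho_logrank(
    data: pd.DataFrame,
    group_col: str,
    rho: float = 1.0,
    time_col: str = "os_months",
    event_col: str = "event",
) -> dict[str, float]:
    """Harrington-Fleming G-rho weighted log-rank test for two groups.

    Each distinct event time t contributes (observed - expected) events in
    group 1 under the hypergeometric null, weighted by S(t-)^rho with S the
    left-continuous pooled Kaplan-Meier estimate. rho = 0 reduces exactly to
    the standard log-rank test. Returns {"statistic", "p"} (chi-square, 1 df).
    """
    groups = data[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    t = data[time_col].to_numpy(dtype=float)
    e = data[event_col].to_numpy(dtype=int)
    g1 = (data[group_col] == groups[0]).to_numpy()
    if e.sum() < 1:
        raise ValueError("no observed events")

    event_times = np.unique(t[e == 1])
    # left-continuous pooled KM: S(t-) at each event time
    s_left = np.empty(event_times.size)
    s = 1.0
    for k, tk in enumerate(event_times):
        s_left[k] = s
        nk = np.sum(t >= tk)
        dk = np.sum((t == tk) & (e == 1))
        s *= 1.0 - dk / nk

    num = 0.0
    var = 0.0
    for k, tk in enumerate(event_times):
        at_risk = t >= tk
        nk = at_risk.sum()
        n1k = (at_risk & g1).sum()
        dk = np.sum((t == tk) & (e == 1))
        d1k = np.sum((t == tk) & (e == 1) & g1)
        w = s_left[k] ** rho
        num += w * (d1k - dk * n1k / nk)
        if nk > 1:
            var += (
                w**2 * dk * (n1k / nk) * (1 - n1k / nk) * (nk - dk) / (nk - 1)
            )
    if var == 0:
        return {"statistic": 0.0, "p": 1.0}
    stat = num**2 / var
    return {"statistic": float(stat), "p": float(sps.chi2.sf(stat, df=1))}


def icc_agreement(values_a, values_b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Crossed subjects x raters ANOVA decomposition:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)), k = 2 raters.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1D measurements required")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    Y = np.column_stack([a, b])
    k = 2
    if np.allclose(Y, Y.mean()):
        raise ValueError("zero total variance: ICC undefined")
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    rater_means = Y.mean(axis=0)
    msr = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((rater_means - grand) ** 2) / (k - 1)
    sse = np.sum(
        (Y - subj_means[:, None] - rater_means[None, :] + grand) ** 2
    )
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse)))


def kruskal_wallis(*groups) -> dict[str, float]:
    """Rank-based Kruskal-Wallis H test with tie correction (chi-square p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    flat = np.concatenate(arrays)
    if np.unique(flat).size == 1:
        return {"H": 0.0, "p": 1.0}
    h, p = sps.kruskal(*arrays)
    return {"H": float(h), "p": float(p)}


def signature_report(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    signatures: list[str],
    adjust: list[str] | None = None,
    events_only: bool = False,
    rho: float = 1.0,
) -> dict:
    """Full prognosis report for a set of candidate imaging signatures.

    For each signature: min-max normalize within the cohort, dichotomize at
    the median into low/high status, fit a univariate Cox model on the
    status, run the G-rho weighted log-rank test between status groups, and
    (if ``adjust`` is given) fit a multivariate Cox model with the
    adjustment covariates. ``events_only=True`` drops censored records
    before analysis (the inclusion rule of a complete-follow-up cohort).
    """
    df = clinical.join(features, how="inner")
    if events_only:
        df = df[df["event"] == 1]
    report: dict = {"n": int(len(df)), "n_events": int(df["event"].sum()),
                    "signatures": {}}
    for sig in signatures:
        norm = normalize_01(df[sig].to_numpy())
        status = dichotomize_median(norm)
        sub = df[["os_months", "event"]].copy()
        scol = f"{sig}_status"
        sub[scol] = status
        entry: dict = {}
        uni = cox_fit(sub, [scol])
        entry["univariate"] = uni.terms[scol] | {
            "significant": uni.significant(scol)
        }
        entry["grho_logrank"] = grho_logrank(sub, scol, rho=rho)
        if adjust:
            mv = sub.join(df[list(adjust)])
            fit = cox_fit(mv, [scol] + list(adjust))
            entry["multivariate"] = {
                term: vals | {"significant": vals["p"] < ALPHA}
                for term, vals in fit.terms.items()
            }
        report["signatures"][sig] = entry
    return report
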