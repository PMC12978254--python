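"""Cohort-level linear/interaction models and survival stratification.

Covers the patient-level statistics: response-specific MN associations
(Feature ~ MN x Response, extracting the nonresponder-minus-responder slope
difference), per-gene CIN x cGAS-STING interaction classification with
purity and leukocyte-fraction covariates, agreement between orthogonal CIN
scores, Kaplan-Meier / log-rank machinery, maximally-selected-rank-statistic
dichotomization with a permutation p value, nested median stratification by
CIN score then myeloid:lymphoid skew, and univariate Cox models.

Kaplan-Meier, log-rank and Cox fits are delegated to lifelines (Efron tie
handling in the Cox partial likelihood); the max-stat scan and its
permutation null are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InteractionResult",
    "MaxStatResult",
    "CoxResult",
    "response_interaction",
    "cin_cgassting_interaction",
    "cin_score_agreement",
    "km_logrank",
    "pairwise_logrank",
    "maxstat_cutpoint",
    "nested_median_stratify",
    "cox_univariate",
]


@dataclass
class InteractionResult:
    feature: str
    p_interaction: float
    slope_r: float
    slope_nr: float
    slope_diff: float  # NR - R
    n_r: int
    n_nr: int
    degenerate: bool = False


def response_interaction(
    table: pd.DataFrame,
    feature: str,
    mn_col: str = "mn_score",
    response_col: str = "response",
    classes: tuple[str, str] = ("R", "NR"),
) -> InteractionResult:
    """OLS of Feature ~ MN x Response over responder/nonresponder tumors.

    Tumors outside the two classes (e.g. intermediate regression grades) are
    excluded.  Returns per-class slopes, the interaction p value and the
    slope difference (nonresponder minus responder).  A class with constant
    MN makes the interaction unidentifiable; the result is flagged
    degenerate with NaN statistics.
    """
    import statsmodels.formula.api as smf

    sub = table[table[response_col].isin(classes)].copy()
    n_r = int((sub[response_col] == classes[0]).sum())
    n_nr = int((sub[response_col] == classes[1]).sum())
    if min(n_r, n_nr) < 3:
        raise ValueError("need >= 3 tumors per response class")
    mn_sd = sub.groupby(response_col)[mn_col].std(ddof=0)
    if (mn_sd.fillna(0.0) == 0).any():
        warnings.warn("a response class has constant MN; interaction degenerate")
        return InteractionResult(feature, np.nan, np.nan, np.nan, np.nan, n_r, n_nr, True)

    sub["_resp"] = pd.Categorical(sub[response_col], categories=list(classes))
    fit = smf.ols(f"Q('{feature}') ~ Q('{mn_col}') * _resp", sub).fit()
    inter_name = [p for p in fit.params.index if ":" in p][0]
    slope_r = float(fit.params[f"Q('{mn_col}')"])
    diff = float(fit.params[inter_name])
    return InteractionResult(
        feature,
        float(fit.pvalues[inter_name]),
        slope_r,
        slope_r + diff,
        diff,
        n_r,
        n_nr,
    )


def cin_cgassting_interaction(
    expr: pd.DataFrame,
    cin_mn: pd.Series,
    cgassting: pd.Series,
    purity: pd.Series,
    leukocyte: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Expression ~ CIN^MN x cGAS-STING + Purity + Leukocyte.

    A gene is "CIN enriched, cGAS-STING-dependent" iff the CIN^MN main term
    is significantly positive (p <= ``alpha``) AND the interaction term is
    significantly positive; the mirror rule gives "CIN depleted".  All genes
    share one design matrix, so the sweep is a single batched least-squares
    solve.
    """
    samples = expr.columns
    X = np.column_stack(
        [
            np.ones(len(samples)),
            cin_mn[samples],
            cgassting[samples],
            cin_mn[samples] * cgassting[samples],
            purity[samples],
            leukocyte[samples],
        ]
    ).astype(float)
    Y = expr.to_numpy(float).T  # samples x genes
    n, k = X.shape
    if n <= k:
        raise ValueError("more model terms than samples")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # k x genes
    resid = Y - X @ B
    s2 = (resid**2).sum(axis=0) / (n - k)
    se = np.sqrt(np.outer(np.diag(XtX_inv), s2))
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = B / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - k)

    i_cin, i_int = 1, 3
    slope_cin, p_cin = B[i_cin], pvals[i_cin]
    slope_int, p_int = B[i_int], pvals[i_int]
    klass = np.full(Y.shape[1], "none", dtype=object)
    enr = (p_cin <= alpha) & (slope_cin > 0) & (p_int <= alpha) & (slope_int > 0)
    dep = (p_cin <= alpha) & (slope_cin < 0) & (p_int <= alpha) & (slope_int < 0)
    klass[enr] = "cin_enriched_dependent"
    klass[dep] = "cin_depleted_dependent"
    return pd.DataFrame(
        {
            "slope_cin": slope_cin,
            "p_cin": p_cin,
            "slope_interaction": slope_int,
            "p_interaction": p_int,
            "class": klass,
        },
        index=expr.index,
    )


def cin_score_agreement(
    table: pd.DataFrame,
    target: str,
    cin_col: str = "cin_mn",
    purity_col: str = "purity",
    leukocyte_col: str = "leukocyte_fraction",
):
    """OLS of an orthogonal CIN score on CIN^MN + purity + leukocyte fraction.

    Returns (coefficient, p) of the CIN^MN term — the covariate-adjusted
    agreement between CIN readouts.
    """
    import statsmodels.formula.api as smf

    fit = smf.ols(
        f"Q('{target}') ~ Q('{cin_col}') + Q('{purity_col}') + Q('{leukocyte_col}')", table
    ).fit()
    term = f"Q('{cin_col}')"
    return float(fit.params[term]), float(fit.pvalues[term])


# ---------------------------------------------------------------------------
# Survival machinery
# ---------------------------------------------------------------------------

def km_logrank(times, events, groups):
    """Kaplan-Meier curves per group plus the k-group log-rank test.

    Returns ``(curves, statistic, p)`` where curves maps group label to the
    product-limit survival function (a Series indexed by time).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    curves = {}
    for g in pd.unique(groups):
        kmf = KaplanMeierFitter()
        kmf.fit(times[groups == g], events[groups == g], label=str(g))
        curves[g] = kmf.survival_function_.iloc[:, 0]
    res = multivariate_logrank_test(times, groups, events)
    return curves, float(res.test_statistic), float(res.p_value)


def pairwise_logrank(times, events, groups, reference):
    """Two-group log-rank tests of the reference group against every other."""
    from lifelines.statistics import logrank_test

    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    ref = groups == reference
    rows = []
    for g in pd.unique(groups):
        if g == reference:
            continue
        other = groups == g
        res = logrank_test(times[ref], times[other], events[ref], events[other])
        rows.append(dict(group=g, statistic=float(res.test_statistic), p=float(res.p_value)))
    return pd.DataFrame(rows)


def _logrank_z_for_cuts(score, times, events, cutpoints):
    """Standardized two-group log-rank z for each 'score > cut' split."""
    order = np.argsort(times)
    t = times[order]
    e = events[order]
    s = score[order]
    ev_times = np.unique(t[e == 1])
    R = t[:, None] >= ev_times[None, :]  # at risk
    E = (t[:, None] == ev_times[None, :]) & (e[:, None] == 1)
    d = E.sum(axis=0).astype(float)
    nt = R.sum(axis=0).astype(float)
    G = (s[None, :] > np.asarray(cutpoints)[:, None]).astype(float)  # cuts x subjects
    n1 = G @ R  # cuts x event times
    d1 = G @ E
    exp1 = d * n1 / nt
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n1 / nt) * (1 - n1 / nt) * (nt - d) / np.maximum(nt - 1, 1.0)
    U = (d1 - exp1).sum(axis=1)
    V = var.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = U / np.sqrt(V)
    return np.where(V > 0, z, 0.0)


@dataclass
class MaxStatResult:
    cutpoint: float
    statistic: float  # max |standardized log-rank z|
    p: float  # permutation p
    candidates: pd.DataFrame = field(repr=False, default=None)


def maxstat_cutpoint(
    score,
    times,
    events,
    quantile_range: tuple[float, float] = (0.10, 0.90),
    n_perm: int = 1000,
    seed: int = 0,
) -> MaxStatResult:
    """Maximally selected rank statistic dichotomization of a score.

    Every unique score value inside the quantile range is a candidate split
    ("high" = score above the cut); the selected cutpoint maximizes the
    absolute standardized log-rank statistic.  Because the maximum over
    candidates is not chi-square distributed, the p value is computed by
    permuting the score labels against the survival data (``n_perm`` draws,
    unbiased (count+1)/(B+1) estimator).
    """
    score = np.asarray(score, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    lo, hi = np.quantile(score, quantile_range)
    cand = np.unique(score[(score >= lo) & (score <= hi)])
    cand = cand[cand < score.max()]  # both groups must be non-empty
    if len(cand) == 0:
        raise ValueError("no admissible cutpoints in the quantile range")

    z = _logrank_z_for_cuts(score, times, events, cand)
    i = int(np.argmax(np.abs(z)))
    m_obs = float(np.abs(z[i]))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(score))
        zp = _logrank_z_for_cuts(score[perm], times, events, cand)
        if np.max(np.abs(zp)) >= m_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return MaxStatResult(
        cutpoint=float(cand[i]),
        statistic=m_obs,
        p=float(p),
        candidates=pd.DataFrame({"cutpoint": cand, "z": z}),
    )


def nested_median_stratify(cin_score, skew) -> pd.Series:
    """Four strata: median split on CIN score, then on skew within each half.

    Values exactly at a median go to the "low" side.  Labels are
    ``CIN_{high,low}/{My,Ly}_dom`` with skew above the within-half median
    read as myeloid-dominated.
    """
    cin = pd.Series(np.asarray(cin_score, float))
    sk = pd.Series(np.asarray(skew, float), index=cin.index)
    hi = cin > cin.median()
    labels = pd.Series(index=cin.index, dtype=object)
    for flag, tag in ((hi, "CIN_high"), (~hi, "CIN_low")):
        if flag.sum() == 0:
            continue
        m = sk[flag].median()
        labels[flag & (sk > m)] = f"{tag}/My_dom"
        labels[flag & (sk <= m)] = f"{tag}/Ly_dom"
    if hasattr(cin_score, "index"):
        labels.index = cin_score.index
    return labels


@dataclass
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_wald: float
    p_logrank: float
    converged: bool = True


def cox_univariate(group_high, times, events) -> CoxResult:
    """Univariate Cox model of a high/low indicator (Efron tie handling).

    Returns the hazard ratio of the high group with its Wald 95% CI and p,
    alongside the two-group log-rank p.  Degenerate splits (a group with no
    events) are flagged non-converged with NaN estimates.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError
    from lifelines.statistics import logrank_test

    g = np.asarray(group_high).astype(int)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    lr = logrank_test(times[g == 1], times[g == 0], events[g == 1], events[g == 0])
    p_lr = float(lr.p_value)
    if events[g == 1].sum() == 0 or events[g == 0].sum() == 0:
        warnings.warn("a group has no events; Cox fit not attempted")
        return CoxResult(np.nan, np.nan, np.nan, np.nan, p_lr, converged=False)
    df = pd.DataFrame({"time": times, "event": events, "high": g})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        warnings.warn("Cox partial likelihood failed to converge")
        return CoxResult(np.nan, np.nan, np.nan, np.nan, p_lr, converged=False)
    hr = float(np.exp(cph.params_["high"]))
    ci = cph.confidence_intervals_.loc["high"]
    return CoxResult(
        hazard_ratio=hr,
        ci_low=float(np.exp(ci.iloc[0])),
        ci_high=float(np.exp(ci.iloc[1])),
        p_wald=float(cph.summary.loc["high", "p"]),
        p_logrank=p_lr,
    )
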