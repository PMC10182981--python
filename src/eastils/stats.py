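"""Trial-style statistics for TILs cohorts.

Implements the analysis battery used to relate a TILs score to pathologic
complete response (pCR) and event-free survival (EFS): Mann–Whitney group
comparison, Pearson correlation, chi-square on dichotomized rates, ROC/AUC
with DeLong variance and the paired DeLong test, Kaplan–Meier curves with
the log-rank test, Wilcoxon matched-pairs signed-rank for pre/post change,
and multivariable logistic regression with an optional marker×treatment
interaction.  Two-sided p-values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "TestResult",
    "SeparationError",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "pearson_r",
    "chi_square_2x2",
    "roc_auc",
    "delong_paired_test",
    "km_logrank",
    "logistic_model",
    "table1_percentages",
    "pool_control_arms",
]


@dataclass
class TestResult:
    """Container for a statistical test: statistic, p, effect summary, group sizes."""

    name: str
    statistic: float
    p_value: float
    effect: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


class SeparationError(RuntimeError):
    """Logistic fit failed due to complete or quasi-complete separation."""


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def mann_whitney(group_a, group_b) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when both groups have n <= 8 and there are no ties;
    otherwise the tie-corrected normal approximation (with continuity
    correction).  Identical constant data across both groups yields p = 1
    with a ``"degenerate"`` flag.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    flags: list[str] = []
    if np.ptp(np.concatenate([a, b])) == 0:
        u = a.size * b.size / 2.0
        return TestResult("mann_whitney", u, 1.0,
                          {"median_a": float(np.median(a)), "median_b": float(np.median(b))},
                          {"n_a": a.size, "n_b": b.size}, ["degenerate"])
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if max(a.size, b.size) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
        flags.append("asymptotic")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        "mann_whitney",
        float(res.statistic),
        float(res.pvalue),
        {"median_a": float(np.median(a)), "median_b": float(np.median(b))},
        {"n_a": int(a.size), "n_b": int(b.size)},
        flags,
    )


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided signed-rank p by convolution over the 2^n sign flips.

    Handles midrank ties: ranks are scaled by 2 to integers and the null
    distribution of 2*W+ built by dynamic programming.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    support = np.arange(total + 1)
    center = total / 2.0
    dev = abs(2.0 * w_plus - center)
    return float(dist[np.abs(support - center) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(pre, post) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test on post - pre.

    Zero differences are dropped (Wilcoxon convention).  The exact null
    distribution (tie-aware, by convolution) is used for <= 15 informative
    pairs, the normal approximation above.  All-zero differences yield p = 1
    with a ``"degenerate"`` flag.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must pair up")
    d = post - pre
    informative = d[d != 0]
    if informative.size == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0,
                          {"median_change": 0.0}, {"n_pairs": int(d.size), "n_informative": 0},
                          ["degenerate"])
    ranks = sps.rankdata(np.abs(informative))
    w_plus = float(ranks[informative > 0].sum())
    w_minus = float(ranks[informative < 0].sum())
    statistic = min(w_plus, w_minus)
    if informative.size <= 15:
        p = _wilcoxon_exact_p(ranks, w_plus)
        flags = []
    else:
        res = sps.wilcoxon(pre, post, zero_method="wilcox", alternative="two-sided",
                           method="approx")
        p = float(res.pvalue)
        flags = ["asymptotic"]
    return TestResult(
        "wilcoxon_signed_rank",
        statistic,
        min(1.0, p),
        {"median_change": float(np.median(d))},
        {"n_pairs": int(d.size), "n_informative": int(informative.size)},
        flags,
    )


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return TestResult("pearson_r", float(res.statistic), float(res.pvalue), {}, {"n": int(x.size)})


def chi_square_2x2(table, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 count table (no continuity correction by default)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    res = sps.chi2_contingency(t, correction=continuity_correction)
    rates = t[:, 0] / t.sum(axis=1)
    return TestResult(
        "chi_square_2x2",
        float(res.statistic),
        float(res.pvalue),
        {"rate_row0": float(rates[0]), "rate_row1": float(rates[1])},
        {"n": int(t.sum())},
    )


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    sorter = np.argsort(x, kind="mergesort")
    xs = x[sorter]
    n = x.size
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[sorter] = ranks
    return out


def _delong_components(scores: np.ndarray, positive: np.ndarray):
    """AUC and DeLong structural components for one score vector."""
    pos = scores[positive]
    neg = scores[~positive]
    m, n = pos.size, neg.size
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # per-positive components
    v01 = 1.0 - (tz[m:] - ty) / m    # per-negative components
    return auc, v10, v01


def roc_auc(scores, outcome) -> TestResult:
    """AUC via the Mann–Whitney identity (ties count 1/2) with DeLong variance.

    ``outcome`` is boolean-like (True = event/pCR).  Returns the AUC as the
    statistic, a Wald 95% CI clipped to [0, 1], and the DeLong variance.
    The p-value tests AUC = 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome).astype(bool)
    if not y.any() or y.all():
        raise ValueError("both outcome classes must be present")
    auc, v10, v01 = _delong_components(s, y)
    m, n = int(y.sum()), int((~y).sum())
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    se = np.sqrt(var)
    lo, hi = np.clip([auc - 1.96 * se, auc + 1.96 * se], 0.0, 1.0)
    if se > 0:
        p = 2.0 * sps.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return TestResult(
        "roc_auc", float(auc), float(min(p, 1.0)),
        {"variance": float(var), "ci95": (float(lo), float(hi))},
        {"n_pos": m, "n_neg": n},
    )


def delong_paired_test(scores_a, scores_b, outcome) -> TestResult:
    """DeLong test for the difference of two correlated AUCs (same patients)."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcome).astype(bool)
    if sa.size != sb.size or sa.size != y.size:
        raise ValueError("paired scores must cover the same patients")
    if not y.any() or y.all():
        raise ValueError("both outcome classes must be present")
    auc_a, v10_a, v01_a = _delong_components(sa, y)
    auc_b, v10_b, v01_b = _delong_components(sb, y)
    m, n = int(y.sum()), int((~y).sum())
    var_a = v10_a.var(ddof=1) / m + v01_a.var(ddof=1) / n
    var_b = v10_b.var(ddof=1) / m + v01_b.var(ddof=1) / n
    cov = (np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
           + np.cov(v01_a, v01_b, ddof=1)[0, 1] / n)
    var_diff = var_a + var_b - 2.0 * cov
    diff = auc_a - auc_b
    if var_diff <= 0:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var_diff)
        p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(
        "delong_paired", float(z), float(min(p, 1.0)),
        {"auc_a": float(auc_a), "auc_b": float(auc_b), "difference": float(diff)},
        {"n_pos": m, "n_neg": n},
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_logrank(times, events, groups) -> TestResult:
    """Kaplan–Meier curves per group plus the log-rank test across groups.

    Censored subjects (event flag False) contribute follow-up until their
    last known time.  With no events at all the curves are flat at 1 and
    p = 1 by convention.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    g = np.asarray(groups)
    if (t <= 0).any():
        raise ValueError("times must be positive")
    labels = pd.unique(g)
    curves = {}
    for lab in labels:
        sel = g == lab
        if sel.sum() == 0:
            raise ValueError(f"group {lab!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], event_observed=e[sel], label=str(lab))
        sf = kmf.survival_function_
        curves[str(lab)] = {
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
        }
    if labels.size < 2:
        stat, p = 0.0, None  # curves only; the log-rank test needs >= 2 groups
    elif not e.any():
        stat, p = 0.0, 1.0
    else:
        res = multivariate_logrank_test(t, g, e)
        stat, p = float(res.test_statistic), float(res.p_value)
    return TestResult(
        "km_logrank", stat, p, {"curves": curves},
        {str(lab): int((g == lab).sum()) for lab in labels},
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def logistic_model(records: pd.DataFrame, formula: str) -> TestResult:
    """Multivariable logistic regression by IRLS (GLM-binomial).

    ``formula`` uses patsy syntax on the cohort columns, e.g.::

        "pcr ~ er_positive + arm + disease_type + eastils_percent"
        "pcr ~ eastils_high * arm"          # marker x treatment interaction

    Convergence: tolerance 1e-8, at most 50 iterations.  Complete or
    quasi-complete separation raises :class:`SeparationError` naming the
    worst covariate; rank-deficient design matrices raise ``ValueError``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(int)
    model = smf.glm(formula, data=df, family=sm.families.Binomial())
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("collinear (rank-deficient) design matrix")
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise ValueError("more terms than observations")
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with np.errstate(all="ignore"):
            res = model.fit(maxiter=50, tol=1e-8)
    except PerfectSeparationError as exc:
        raise SeparationError(str(exc)) from exc
    lin = np.asarray(res.predict(which="linear"))
    if np.abs(lin).max() > 30:  # fitted log-odds blowing up => separation
        scaled = np.abs(res.params.values[1:]) * model.exog[:, 1:].std(axis=0)
        worst = model.exog_names[1 + int(np.argmax(scaled))] if scaled.size else "intercept"
        raise SeparationError(f"complete separation suspected on term {worst!r}")
    ci = res.conf_int()
    coef = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )
    interaction_terms = [name for name in res.params.index if ":" in name]
    p_overall = float(res.pvalues.iloc[-1])
    return TestResult(
        "logistic_model",
        float(res.llf),
        min(1.0, p_overall),
        {
            "coefficients": coef,
            "interaction_p": {k: float(res.pvalues[k]) for k in interaction_terms},
            "converged": bool(res.converged),
        },
        {"n": int(model.exog.shape[0])},
    )


# ---------------------------------------------------------------------------
# cohort utilities
# ---------------------------------------------------------------------------

def table1_percentages(counts) -> np.ndarray:
    """Column percentages of a demographic table, to one decimal.

    ``counts`` is a 1-D array of category counts within one column; returns
    ``100 * count / total`` rounded to one decimal place.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("zero column total")
    return np.round(100.0 * c / total, 1)


def pool_control_arms(records: pd.DataFrame, arm_column: str = "arm") -> pd.DataFrame:
    """Collapse all non-bevacizumab arms into one control arm."""
    df = records.copy()
    df[arm_column] = np.where(
        df[arm_column].astype(str).str.contains("bev"), "chemo+bev", "chemo"
    )
    return df
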