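"""Repeated-measures statistical battery for the assay endpoints.

The assay's core contrast is within-subject: every animal is measured on a
white and then a black background, so background is a repeated measure
while dose, trial and exposure time are fixed between-subject factors.
The battery mirrors that design:

* natural-log transform of the (positive, right-skewed) endpoints,
* a split-plot mixed ANOVA — Type-III sums of squares on the
  between-subject stratum (subject means) and on the within-subject
  stratum (orthonormal contrast scores), Greenhouse-Geisser sphericity
  correction of within-subject degrees of freedom, and partial eta squared
  per effect,
* Bonferroni-adjusted pairwise comparisons of marginal means for
  significant factors,
* Pearson correlation between the human-graded coefficient and the
  image-derived percent cover.

For the two-level background factor the within-subject F is identically the
square of the paired t statistic and the Greenhouse-Geisser epsilon is
exactly 1; both identities are exercised in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def log_transform(values, offset: float = 0.0) -> np.ndarray:
    """Elementwise natural log of ``value + offset``.

    Coefficients (>= 20 by construction) use offset 0; percent cover can be
    exactly 0, so it is transformed with offset 1.
    """
    values = np.asarray(values, dtype=float)
    shifted = values + offset
    bad = np.flatnonzero(shifted <= 0)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"log transform undefined at observation {i}: value {values.flat[i]} + offset {offset} <= 0"
        )
    return np.log(shifted)


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Effect size ``SS_effect / (SS_effect + SS_error)``."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be nonnegative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("partial eta squared undefined when both SS are zero")
    return ss_effect / (ss_effect + ss_error)


def greenhouse_geisser_epsilon(within_covariance: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction from a within-subject covariance.

    The k x k covariance of the repeated measures is doubly centred and the
    correction ``eps = tr(S)^2 / ((k-1) tr(S^2))`` evaluated on it; the
    result is clipped to the admissible interval [1/(k-1), 1].  Equals 1
    exactly when k = 2 or the covariance is compound symmetric.
    """
    S = np.asarray(within_covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"covariance must be square, got shape {S.shape}")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    P = np.eye(k) - np.full((k, k), 1.0 / k)
    S = P @ S @ P
    trace = np.trace(S)
    denom = (k - 1) * np.trace(S @ S)
    if denom <= 0:
        return 1.0
    return float(np.clip(trace**2 / denom, 1.0 / (k - 1), 1.0))


def pearson(x, y) -> "CorrelationResult":
    """Pearson product-moment correlation with two-sided p and r squared."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    res = scipy.stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, p=float(res.pvalue), r_squared=r * r, n=int(x.size))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    r_squared: float
    n: int


# ---------------------------------------------------------------------------
# Split-plot mixed ANOVA
# ---------------------------------------------------------------------------

def _sum_coded_formula(response: str, factors: list[str]) -> str:
    if not factors:
        return f"{response} ~ 1"
    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    return f"{response} ~ {terms}"


def _clean_term(term: str, factors: list[str]) -> str:
    for f in factors:
        term = term.replace(f"C({f}, Sum)", f)
    return term


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) matrix with orthonormal columns, each orthogonal to the mean."""
    helmert = np.zeros((k, k - 1))
    for j in range(1, k):
        helmert[:j, j - 1] = 1.0
        helmert[j, j - 1] = -j
    return helmert / np.linalg.norm(helmert, axis=0)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: list[str] | None = None,
) -> pd.DataFrame:
    """Mixed-design (split-plot) ANOVA with one within-subject factor.

    Type-III sums of squares are used throughout (sum-to-zero coding), so
    unbalanced between-subject cells are handled.  Between-subject effects
    are tested on subject means against the subject-level error; the
    within-subject factor and its interactions with the between factors are
    tested on orthonormal contrast scores against the subject x within
    error, with Greenhouse-Geisser adjusted p-values (``p_gg``) alongside
    the uncorrected ones.

    Returns a table with one row per effect plus the two error strata:
    columns ``effect, stratum, SS, df, MS, F, p, gg_epsilon, df1_gg,
    df2_gg, p_gg, partial_eta_sq``.

    Raises
    ------
    ValueError
        If a subject misses a within level (subjects listed), a subject has
        duplicate observations for a level, a between covariate varies
        within subject, or the between design is singular.
    """
    between = list(between or [])
    for col in [dv, within, subject, *between]:
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    try:
        wide = data.pivot(index=subject, columns=within, values=dv)
    except ValueError as exc:
        raise ValueError(f"duplicate observations per subject x {within} level: {exc}") from exc
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"subjects missing a {within!r} level: {missing}")
    k = wide.shape[1]
    n = wide.shape[0]

    # between-subject covariates, one row per subject (must be constant within)
    if between:
        per_subj = data.groupby(subject, sort=False)[between].nunique()
        varying = per_subj.columns[(per_subj > 1).any()].tolist()
        if varying:
            raise ValueError(f"between-subject factors vary within subject: {varying}")
    covars = data.drop_duplicates(subject).set_index(subject).loc[wide.index, between] if between else pd.DataFrame(index=wide.index)

    rows = []

    # ---- between-subject stratum: ANOVA of subject means (SS scaled by k) ----
    frame = covars.copy()
    frame["_m"] = wide.mean(axis=1).values
    model_b = smf.ols(_sum_coded_formula("_m", between), data=frame).fit()
    if np.linalg.matrix_rank(model_b.model.exog) < model_b.model.exog.shape[1]:
        raise ValueError("singular between-subject design (empty or aliased cells)")
    df_resid_b = int(model_b.df_resid)
    if df_resid_b <= 0:
        raise ValueError("no residual degrees of freedom in the between-subject stratum")
    ss_err_b = float(model_b.ssr) * k
    if between:
        tab = anova_lm(model_b, typ=3)
        for term in tab.index:
            if term in ("Intercept", "Residual"):
                continue
            ss = float(tab.loc[term, "sum_sq"]) * k
            df = int(tab.loc[term, "df"])
            ms = ss / df
            F = ms / (ss_err_b / df_resid_b)
            p = float(scipy.stats.f.sf(F, df, df_resid_b))
            rows.append(
                dict(effect=_clean_term(term, between), stratum="between", SS=ss, df=df, MS=ms,
                     F=F, p=p, gg_epsilon=np.nan, df1_gg=np.nan, df2_gg=np.nan, p_gg=np.nan,
                     partial_eta_sq=partial_eta_squared(ss, ss_err_b))
            )
    rows.append(
        dict(effect="Error (between)", stratum="between", SS=ss_err_b, df=df_resid_b,
             MS=ss_err_b / df_resid_b, F=np.nan, p=np.nan, gg_epsilon=np.nan,
             df1_gg=np.nan, df2_gg=np.nan, p_gg=np.nan, partial_eta_sq=np.nan)
    )

    # ---- within-subject stratum: ANOVA of orthonormal contrast scores ----
    # NB: local names here leak into the patsy formula namespace; never
    # shadow patsy's C/Sum/Q helpers.
    contrast_matrix = _orthonormal_contrasts(k)
    Z = wide.values @ contrast_matrix  # n x (k-1)
    ss_terms: dict[str, float] = {}
    ss_err_w = 0.0
    resid_cols = []
    for j in range(k - 1):
        frame_j = covars.copy()
        frame_j["_z"] = Z[:, j]
        model_w = smf.ols(_sum_coded_formula("_z", between), data=frame_j).fit()
        if between:
            tab = anova_lm(model_w, typ=3)
            for term in tab.index:
                if term == "Residual":
                    continue
                ss_terms[term] = ss_terms.get(term, 0.0) + float(tab.loc[term, "sum_sq"])
        else:
            z = Z[:, j]
            ss_terms["Intercept"] = ss_terms.get("Intercept", 0.0) + n * float(z.mean()) ** 2
        ss_err_w += float(model_w.ssr)
        resid_cols.append(model_w.resid)
    df_resid_w = df_resid_b * (k - 1)
    if df_resid_w <= 0:
        raise ValueError("no residual degrees of freedom in the within-subject stratum")

    resid = np.column_stack(resid_cols)
    V = resid.T @ resid / df_resid_b  # pooled covariance of contrast scores
    trace, tr2 = float(np.trace(V)), float(np.trace(V @ V))
    epsilon = 1.0 if tr2 <= 0 else float(np.clip(trace**2 / ((k - 1) * tr2), 1.0 / (k - 1), 1.0))

    term_order = ["Intercept"] + [t for t in ss_terms if t != "Intercept"]
    for term in term_order:
        ss = ss_terms.get(term, 0.0)
        df = (k - 1) if term == "Intercept" else _between_term_df(model_b, term) * (k - 1)
        name = within if term == "Intercept" else f"{within}:{_clean_term(term, between)}"
        ms = ss / df
        F = ms / (ss_err_w / df_resid_w)
        p = float(scipy.stats.f.sf(F, df, df_resid_w))
        p_gg = float(scipy.stats.f.sf(F, df * epsilon, df_resid_w * epsilon))
        rows.append(
            dict(effect=name, stratum="within", SS=ss, df=df, MS=ms, F=F, p=p,
                 gg_epsilon=epsilon, df1_gg=df * epsilon, df2_gg=df_resid_w * epsilon,
                 p_gg=p_gg, partial_eta_sq=partial_eta_squared(ss, ss_err_w))
        )
    rows.append(
        dict(effect=f"Error ({within})", stratum="within", SS=ss_err_w, df=df_resid_w,
             MS=ss_err_w / df_resid_w, F=np.nan, p=np.nan, gg_epsilon=np.nan,
             df1_gg=np.nan, df2_gg=np.nan, p_gg=np.nan, partial_eta_sq=np.nan)
    )
    return pd.DataFrame(rows)


def _between_term_df(model_b, term: str) -> int:
    """Degrees of freedom of a between-model term, from its design columns."""
    names = model_b.model.data.design_info.term_name_slices
    sl = names[term]
    return sl.stop - sl.start


# ---------------------------------------------------------------------------
# Post hoc pairwise comparisons
# ---------------------------------------------------------------------------

def pairwise_posthoc(
    data: pd.DataFrame,
    factor: str,
    response: str,
    subject: str | None = None,
) -> pd.DataFrame:
    """All pairwise comparisons of a factor's marginal means.

    Observations are first aggregated to subject means within each level
    (when ``subject`` is given) so repeated measures are not treated as
    independent replicates.  Raw p-values come from pairwise t statistics
    on the pooled one-way error; the Bonferroni family is the number of
    pairs, ``m = k(k-1)/2``, and adjusted p = min(1, m * raw p).
    """
    df = data[[factor, response] + ([subject] if subject else [])].dropna()
    if subject:
        df = df.groupby([factor, subject], sort=False, as_index=False)[response].mean()
    levels = list(pd.unique(df[factor]))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    groups = {lev: df.loc[df[factor] == lev, response].to_numpy() for lev in levels}
    for lev, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"level {lev!r} has fewer than 2 observations")
    N = sum(v.size for v in groups.values())
    kk = len(levels)
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / (N - kk)
    df_err = N - kk
    m = kk * (kk - 1) // 2
    rows = []
    for a, b in combinations(levels, 2):
        va, vb = groups[a], groups[b]
        diff = va.mean() - vb.mean()
        se = np.sqrt(mse * (1.0 / va.size + 1.0 / vb.size))
        t = diff / se if se > 0 else np.inf * np.sign(diff) if diff else 0.0
        p_raw = float(2.0 * scipy.stats.t.sf(abs(t), df_err))
        rows.append(
            dict(level_a=a, level_b=b, mean_diff=float(diff), t=float(t),
                 p_raw=p_raw, p_bonferroni=min(1.0, m * p_raw), family_size=m)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full battery
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Everything the battery produces for one specimen table."""

    anovas: dict = field(default_factory=dict)         # response -> ANOVA table
    posthocs: dict = field(default_factory=dict)       # (response, factor) -> table
    correlations: dict = field(default_factory=dict)   # label -> CorrelationResult
    trial_subsets: dict = field(default_factory=dict)  # (response, excluded trial) -> ANOVA table
    background_shift: dict = field(default_factory=dict)  # response -> shift summary
    alpha: float = ALPHA


_OFFSETS = {"coefficient": 0.0, "percent_dark": 1.0}


def background_shift_estimate(table: pd.DataFrame, response: str, unit_cols: list[str]) -> dict:
    """Relative white-to-black change of a response, with uncertainty.

    Two summaries are returned.  ``mean_percent`` pairs each unit's white
    and black observations and averages ``100 * (black - white) / white``
    across units (with a t-based 95% CI); because 1/white is convex this
    per-unit average sits slightly above the cohort-level change.
    ``cohort_percent`` is the population-level relative increase
    ``100 * (mean black - mean white) / mean white`` — the quantity an
    "overall X% darker on black" statement refers to — with a delta-method
    standard error (``cohort_se``) that accounts for the white/black
    pairing.
    """
    wide = table.pivot_table(index=unit_cols, columns="background", values=response)
    wide = wide.dropna()
    rel = 100.0 * (wide["black"] - wide["white"]) / wide["white"]
    n = len(rel)
    mean = float(rel.mean())
    se = float(rel.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    half = scipy.stats.t.ppf(0.975, n - 1) * se if n > 1 else np.nan
    w = wide["white"].to_numpy()
    b = wide["black"].to_numpy()
    mw, mb = w.mean(), b.mean()
    cohort = float(100.0 * (mb - mw) / mw)
    if n > 1:
        var_ratio = (
            b.var(ddof=1) / mw**2
            + w.var(ddof=1) * mb**2 / mw**4
            - 2.0 * np.cov(b, w, ddof=1)[0, 1] * mb / mw**3
        ) / n
        cohort_se = float(100.0 * np.sqrt(max(var_ratio, 0.0)))
    else:
        cohort_se = np.nan
    return {
        "mean_percent": mean,
        "se": se,
        "ci95": (mean - half, mean + half),
        "cohort_percent": cohort,
        "cohort_se": cohort_se,
        "n_units": n,
    }


def analyze_dataset(
    table: pd.DataFrame,
    responses: tuple = ("coefficient", "percent_dark"),
    alpha: float = ALPHA,
) -> AnalysisReport:
    """Run the full battery on a scored specimen table.

    The table must hold one row per observation with both background levels
    per specimen x exposure time.  For each available response the values
    are natural-log transformed (offset 1 for percent cover, which can be
    0), a split-plot mixed ANOVA is fitted with background within-subject
    and concentration / trial / exposure time between, Bonferroni post hocs
    are run for every significant between-subject main effect, and the
    white-to-black shift is summarised.  The two endpoints are then
    correlated (Pearson) overall and per trial, and the ANOVAs re-fitted
    with each trial removed in turn (sequential-removal check).
    """
    table = table.copy()
    report = AnalysisReport(alpha=alpha)
    responses = [r for r in responses if r in table.columns]
    if not responses:
        raise ValueError("no analysable response columns present")

    # repeated-measures unit: specimen x exposure time (time is a fixed factor,
    # so each white/black pair at a given time is one subject unit)
    multi_time = table["exposure_time"].nunique() > 1
    table["_unit"] = (
        table["specimen_id"].astype(str) + "@" + table["exposure_time"].astype(str)
        if multi_time
        else table["specimen_id"].astype(str)
    )
    between = [
        f for f in ("concentration_ng_per_L", "trial", "exposure_time")
        if f in table.columns and table[f].nunique() > 1
    ]

    for resp in responses:
        col = f"_log_{resp}"
        table[col] = log_transform(table[resp].to_numpy(), offset=_OFFSETS.get(resp, 0.0))
        aov = mixed_anova(table, dv=col, within="background", subject="_unit", between=between)
        report.anovas[resp] = aov
        unit_cols = ["specimen_id", "exposure_time"] if multi_time else ["specimen_id"]
        report.background_shift[resp] = background_shift_estimate(table, resp, unit_cols)
        for factor in between:
            row = aov[(aov["stratum"] == "between") & (aov["effect"] == factor)]
            if not row.empty and float(row["p"].iloc[0]) < alpha:
                report.posthocs[(resp, factor)] = pairwise_posthoc(
                    table, factor=factor, response=col, subject="_unit"
                )
        if "trial" in between:
            for excluded in sorted(table["trial"].unique()):
                sub = table[table["trial"] != excluded]
                sub_between = [f for f in between if sub[f].nunique() > 1]
                report.trial_subsets[(resp, excluded)] = mixed_anova(
                    sub, dv=col, within="background", subject="_unit", between=sub_between
                )

    if len(responses) == 2:
        a, b = responses
        paired = table[[a, b, "trial"]].dropna()
        if len(paired) >= 3:
            report.correlations["all"] = pearson(paired[a], paired[b])
            for trial, sub in paired.groupby("trial"):
                if len(sub) >= 3:
                    report.correlations[f"trial_{trial}"] = pearson(sub[a], sub[b])
    return report
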