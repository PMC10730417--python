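"""Covariate-adjusted group comparison of scalar network measures,
permutation inference, multiple-testing corrections, clinical correlations
and cohort descriptive summaries.

Parametric inference is a linear model ``value ~ group + age + sex`` (a
two-sample t for two groups, an ANCOVA F with type-II sums of squares for
three or more); the matching Freedman-Lane permutation p-value is computed
alongside so both can be reported.  FDR adjustment is Benjamini-Hochberg.

Relapse tallies follow the interval-rate convention the cohort tables use:
the k-year denominator is the number of subjects followed at least k years
(after excluding short follow-up), and the numerator is the number of them
who relapsed within k years.  Percentages are reported to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sstats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "CohortSummary",
    "adjusted_group_compare",
    "permutation_pvalue",
    "fdr_adjust",
    "bonferroni_adjust",
    "spearman_clinical",
    "summarize_cohort",
]


@dataclass
class ComparisonResult:
    measure: str
    groups: tuple[str, ...]
    statistic: float
    stat_name: str  # "t" or "F"
    p_param: float
    p_perm: float | None = None
    p_adj: float | None = None
    method: str = ""
    n: int = 0
    posthoc: pd.DataFrame | None = None


@dataclass
class CohortSummary:
    demographics: pd.DataFrame  # per-group counts / means / SDs
    relapse: pd.DataFrame | None = None  # interval_years, events, at_risk, percent
    n_excluded_short_followup: int = 0


def _frame(values, groups, covariates) -> tuple[pd.DataFrame, list[str]]:
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    terms = ["C(group)"]
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            df[c] = cov[c].to_numpy()
            terms.append(f"C({c})" if not pd.api.types.is_numeric_dtype(cov[c]) else c)
    return df, terms


def adjusted_group_compare(
    values: Sequence[float],
    groups: Sequence[str],
    covariates: pd.DataFrame | Mapping | None = None,
    measure: str = "measure",
    posthoc_alpha: float = 0.05,
    anova_type: int = 2,
) -> ComparisonResult:
    """Linear model ``value ~ group (+ covariates)``: t for two groups,
    type-II ANCOVA F for three or more, with Bonferroni-adjusted pairwise
    post-hoc contrasts when the omnibus test is significant."""
    df, terms = _frame(values, groups, covariates)
    counts = df["group"].value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 subjects")
    levels = list(dict.fromkeys(df["group"].tolist()))
    formula = "value ~ " + " + ".join(terms)
    try:
        fit = smf.ols(formula, data=df).fit()
    except Exception as exc:  # statsmodels raises on singular designs
        raise ValueError(f"singular design for {measure}: {exc}") from exc
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError(f"singular design for {measure}")
    method = "ANCOVA" if covariates is not None else "ANOVA/t"
    if len(levels) == 2:
        name = next(n for n in fit.params.index if n.startswith("C(group)"))
        stat = float(fit.tvalues[name])
        p = float(fit.pvalues[name])
        return ComparisonResult(
            measure, tuple(levels), stat, "t", p, method=method, n=len(df)
        )
    table = anova_lm(fit, typ=anova_type)
    stat = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    posthoc = None
    if p < posthoc_alpha:
        rows = []
        pairs = [
            (levels[a], levels[b])
            for a in range(len(levels))
            for b in range(a + 1, len(levels))
        ]
        for ga, gb in pairs:
            cvec = np.zeros(len(fit.params))
            for g, sign in ((gb, 1.0), (ga, -1.0)):
                label = f"C(group)[T.{g}]"
                if label in fit.params.index:
                    cvec[list(fit.params.index).index(label)] += sign
            tt = fit.t_test(cvec)
            rows.append(
                {
                    "contrast": f"{gb} - {ga}",
                    "t": float(np.squeeze(tt.tvalue)),
                    "p_raw": float(np.squeeze(tt.pvalue)),
                }
            )
        posthoc = pd.DataFrame(rows)
        posthoc["p_bonferroni"] = bonferroni_adjust(
            posthoc["p_raw"].to_numpy(), m=len(rows)
        )
    return ComparisonResult(
        measure, tuple(levels), stat, "F", p, method=method, n=len(df), posthoc=posthoc
    )


def _design_arrays(groups, covariates, n):
    groups = np.asarray([str(g) for g in groups])
    levels = list(dict.fromkeys(groups.tolist()))
    cols = [np.ones(n)]
    for g in levels[1:]:
        cols.append((groups == g).astype(float))
    interest = list(range(1, len(levels)))
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            col = cov[c]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
            else:
                lv = sorted(col.unique().tolist())
                if len(lv) != 2:
                    raise ValueError(f"covariate {c!r} must be numeric or binary")
                cols.append((col == lv[1]).to_numpy(dtype=float))
    return np.column_stack(cols), interest


def permutation_pvalue(
    values: Sequence[float],
    groups: Sequence[str],
    covariates: pd.DataFrame | Mapping | None = None,
    n_perm: int = 10000,
    seed=0,
) -> float:
    """Freedman-Lane permutation p for the omnibus group effect (F statistic;
    for two groups F = t^2, so the p-value matches a two-sided t test).
    Add-one convention; deterministic per seed."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(values, dtype=float)
    X, interest = _design_arrays(groups, covariates, y.shape[0])
    n, p = X.shape
    keep = [i for i in range(p) if i not in interest]
    Z = X[:, keep]
    hz = Z @ np.linalg.pinv(Z)
    pinv = np.linalg.pinv(X)
    q = len(interest)
    df = n - p

    def f_stat(v: np.ndarray) -> float:
        resid = v - X @ (pinv @ v)
        rss_full = float(resid @ resid)
        resid_red = v - hz @ v
        rss_red = float(resid_red @ resid_red)
        if rss_full <= 0:
            return np.inf
        return ((rss_red - rss_full) / q) / (rss_full / df)

    obs = f_stat(y)
    fitted_red = hz @ y
    resid_red = y - fitted_red
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        y_star = fitted_red + resid_red[rng.permutation(n)]
        if f_stat(y_star) >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """min(1, m * p) per element; ``m`` defaults to the number of tests."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def spearman_clinical(
    values: Sequence[float],
    clinical: Sequence[float],
    m_tests: int = 1,
) -> tuple[float, float, float]:
    """Spearman rank correlation of a network measure with a clinical score:
    (rho, raw p, Bonferroni-adjusted p over ``m_tests``)."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(clinical, dtype=float)
    if x.shape != y.shape or x.size < 5:
        raise ValueError("need paired samples with at least 5 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = sstats.spearmanr(x, y)
    return float(rho), float(p), float(min(1.0, m_tests * p))


def summarize_cohort(
    metadata: pd.DataFrame,
    intervals_years: Sequence[int] = (1, 2, 3),
    min_followup_months: float = 6.0,
    followup_col: str = "followup_months",
    relapse_col: str = "relapsed",
    relapse_time_col: str = "relapse_time_months",
) -> CohortSummary:
    """Per-group demographics plus interval relapse rates.

    Subjects followed less than ``min_followup_months`` are excluded before
    tallying.  For each k-year interval, at-risk = subjects followed >= 12k
    months, events = those relapsed within 12k months; percent to 2
    decimals (NaN, flagged, when nobody is at risk).
    """
    demo_rows = []
    for g, sub in metadata.groupby("group", sort=False):
        row = {"group": g, "n": len(sub)}
        if "age" in sub.columns:
            row["age_mean"] = round(float(sub["age"].mean()), 2)
            row["age_sd"] = round(float(sub["age"].std(ddof=1)), 2)
        if "sex" in sub.columns:
            row["pct_female"] = round(100.0 * (sub["sex"] == "F").mean(), 2)
        demo_rows.append(row)
    demographics = pd.DataFrame(demo_rows)

    relapse = None
    n_excluded = 0
    if followup_col in metadata.columns and relapse_col in metadata.columns:
        cohort = metadata.dropna(subset=[followup_col])
        eligible = cohort[cohort[followup_col] >= min_followup_months]
        n_excluded = len(cohort) - len(eligible)
        rows = []
        for k in intervals_years:
            months = 12.0 * k
            at_risk = eligible[eligible[followup_col] >= months]
            events = at_risk[
                at_risk[relapse_col].astype(bool)
                & (at_risk[relapse_time_col] <= months)
            ]
            n_at_risk = len(at_risk)
            pct = round(100.0 * len(events) / n_at_risk, 2) if n_at_risk else np.nan
            rows.append(
                {
                    "interval_years": k,
                    "events": len(events),
                    "at_risk": n_at_risk,
                    "percent": pct,
                    "undefined": n_at_risk == 0,
                }
            )
        relapse = pd.DataFrame(rows)
    return CohortSummary(demographics, relapse, n_excluded)
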