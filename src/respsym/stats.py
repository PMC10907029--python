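"""Group-level statistics for the cohort analysis.

The layer deliberately delegates to established routines (scipy,
pingouin) and adds the selection logic, pairwise follow-ups and
reporting schema: a split-plot mixed ANOVA (respiratory phase as the
within-subject factor, group as the between factor, partial eta squared
per effect) for respiratory sympathetic modulation; one-way ANOVA,
Welch ANOVA or Kruskal-Wallis for group comparisons with a
Shapiro-Wilk normality pre-check and Bonferroni-adjusted follow-ups
(mean-rank comparisons after Kruskal-Wallis); chi-squared or Fisher
exact tests for proportions; and Spearman/Pearson correlation tables
relating respiratory sympathetic modulation to resting hemodynamics.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .params import AnalysisConfig

__all__ = [
    "phase_group_anova",
    "group_compare",
    "pairwise_mean_rank",
    "proportion_compare",
    "modulation_bp_correlations",
    "cohort_report",
]


def phase_group_anova(
    cohort: pd.DataFrame,
    exp_col: str,
    insp_col: str,
    group_col: str = "group",
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Mixed (split-plot) ANOVA of a per-phase metric.

    ``exp_col``/``insp_col`` hold the metric in the mid-late-expiration
    and inspiration/postinspiration phases.  Subjects with a missing
    phase value are dropped listwise.  Returns one row per effect
    (group, phase, interaction) with F, degrees of freedom, p and
    partial eta squared.
    """
    sub = cohort[[subject_col, group_col, exp_col, insp_col]].dropna()
    if sub[group_col].nunique() < 2:
        raise ValueError("need at least two groups")
    long = sub.melt(
        id_vars=[subject_col, group_col],
        value_vars=[exp_col, insp_col],
        var_name="phase",
        value_name="value",
    )
    aov = pg.mixed_anova(
        data=long,
        dv="value",
        within="phase",
        subject=subject_col,
        between=group_col,
    )
    aov = aov.rename(
        columns={"Source": "effect", "p_unc": "p", "p-unc": "p",
                 "DF1": "df1", "DF2": "df2"}
    )
    aov["effect"] = aov["effect"].replace({group_col: "group", "phase": "phase",
                                           "Interaction": "interaction"})
    return aov[["effect", "F", "df1", "df2", "p", "np2"]]


def group_compare(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    mode: str = "auto",
    config: AnalysisConfig | None = None,
) -> dict:
    """Omnibus group comparison of one variable with pairwise follow-ups.

    ``mode='auto'`` runs one-way ANOVA unless a Shapiro-Wilk pre-check
    fails in any group, in which case Kruskal-Wallis is used;
    ``'anova'``, ``'welch'`` and ``'kruskal'`` force the choice.
    Pairwise follow-ups are Bonferroni-adjusted: mean-rank (Dunn)
    comparisons after Kruskal-Wallis, two-sample t tests otherwise
    (Welch t tests in 'welch' mode).  Groups with n < 2 are excluded
    with a warning entry in the result.
    """
    config = config or AnalysisConfig()
    sub = cohort[[group_col, variable]].dropna()
    sizes = sub.groupby(group_col).size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        sub = sub[~sub[group_col].isin(small)]
    labels = sorted(sub[group_col].unique())
    if len(labels) < 2:
        raise ValueError("need at least two groups with n >= 2")
    samples = [sub.loc[sub[group_col] == g, variable].to_numpy() for g in labels]

    if mode == "auto":
        normal = all(
            stats.shapiro(s).pvalue >= config.normality_alpha
            for s in samples
            if len(s) >= 3
        )
        mode = "anova" if normal else "kruskal"

    if mode == "kruskal":
        stat, p = stats.kruskal(*samples)
        test = "kruskal"
        pairwise = pairwise_mean_rank(samples, labels)
    elif mode == "welch":
        aov = pg.welch_anova(data=sub, dv=variable, between=group_col)
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        stat, p = float(aov["F"].iloc[0]), float(aov[pcol].iloc[0])
        test = "welch"
        pairwise = _pairwise_t(samples, labels, equal_var=False)
    elif mode == "anova":
        stat, p = stats.f_oneway(*samples)
        test = "anova"
        pairwise = _pairwise_t(samples, labels, equal_var=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return {
        "variable": variable,
        "test": test,
        "statistic": float(stat),
        "p": float(p),
        "excluded_groups": small,
        "pairwise": pairwise,
    }


def pairwise_mean_rank(
    samples: list[np.ndarray], labels: list[str]
) -> pd.DataFrame:
    """Dunn-style mean-rank pairwise comparisons (Bonferroni-adjusted).

    All observations are ranked jointly; each pair of groups is compared
    by the difference of mean ranks standardized with the
    tie-corrected Kruskal-Wallis variance.
    """
    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie

    mean_ranks, sizes = [], []
    pos = 0
    for s in samples:
        mean_ranks.append(ranks[pos : pos + len(s)].mean())
        sizes.append(len(s))
        pos += len(s)

    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else np.nan
        p_unc = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            (labels[i], labels[j], z, p_unc, min(p_unc * m, 1.0))
        )
    return pd.DataFrame(rows, columns=["a", "b", "statistic", "p_unc", "p_adj"])


def _pairwise_t(
    samples: list[np.ndarray], labels: list[str], equal_var: bool
) -> pd.DataFrame:
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        t, p = stats.ttest_ind(samples[i], samples[j], equal_var=equal_var)
        rows.append((labels[i], labels[j], float(t), float(p), min(p * m, 1.0)))
    return pd.DataFrame(rows, columns=["a", "b", "statistic", "p_unc", "p_adj"])


def proportion_compare(table: np.ndarray) -> dict:
    """Group difference in a proportion from a 2 x k count table.

    Uses the Fisher exact test when any expected cell count is below 5
    and the table is 2 x 2, otherwise the chi-squared test (without
    continuity correction).  Larger sparse tables fall back to
    chi-squared with a flag.
    """
    table = np.asarray(table)
    if table.sum() == 0:
        raise ValueError("all-zero count table")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        # a zero margin (e.g. no subject in any group shows the outcome)
        # means the proportions are identical by construction
        return {"test": "degenerate", "statistic": 0.0, "p": 1.0, "sparse": True}
    chi2, p_chi, dof, expected = stats.chi2_contingency(table, correction=False)
    sparse = bool(expected.min() < 5)
    if sparse and table.shape == (2, 2):
        odds, p = stats.fisher_exact(table)
        return {"test": "fisher", "statistic": float(odds), "p": float(p),
                "sparse": True}
    return {"test": "chi2", "statistic": float(chi2), "p": float(p_chi),
            "dof": int(dof), "sparse": sparse}


def modulation_bp_correlations(
    cohort: pd.DataFrame,
    change_col: str = "dincidence_pct",
    resting_cols: tuple[str, ...] = ("sbp_mean", "dbp_mean", "map_mean",
                                     "msna_incidence"),
    group_col: str = "group",
    config: AnalysisConfig | None = None,
    min_n: int = 5,
) -> pd.DataFrame:
    """Correlations of respiratory sympathetic modulation with resting
    hemodynamics, pooled and per group.

    Pearson's r is used when both variables pass a Shapiro-Wilk
    normality pre-check in the subset at hand, Spearman's rho
    otherwise.  Subsets with fewer than ``min_n`` complete pairs are
    skipped (method 'skipped', NaN coefficient); a constant variable is
    flagged undefined.
    """
    config = config or AnalysisConfig()
    scopes = [("all", cohort)] + [
        (g, sub) for g, sub in cohort.groupby(group_col)
    ]
    rows = []
    for resting in resting_cols:
        for scope, sub in scopes:
            pair = sub[[resting, change_col]].dropna()
            n = len(pair)
            if n < min_n:
                rows.append((resting, scope, "skipped", np.nan, np.nan, n))
                continue
            x = pair[resting].to_numpy()
            y = pair[change_col].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((resting, scope, "undefined", np.nan, np.nan, n))
                continue
            normal = (
                stats.shapiro(x).pvalue >= config.normality_alpha
                and stats.shapiro(y).pvalue >= config.normality_alpha
            )
            if normal:
                r, p = stats.pearsonr(x, y)
                method = "pearson"
            else:
                r, p = stats.spearmanr(x, y)
                method = "spearman"
            rows.append((resting, scope, method, float(r), float(p), n))
    return pd.DataFrame(
        rows, columns=["resting_variable", "scope", "method", "coef", "p", "n"]
    )


_PHASE_METRICS = {
    "incidence": ("exp_incidence", "insp_incidence"),
    "frequency": ("exp_frequency", "insp_frequency"),
    "total_area_per_s": ("exp_total_area", "insp_total_area"),
    "mean_area_per_s": ("exp_mean_area", "insp_mean_area"),
}

_RESTING_VARS = [
    "msna_incidence", "msna_freq", "msna_total_area_per_s",
    "hr_mean", "sbp_mean", "dbp_mean", "pp_mean", "map_mean",
    "sbrs_occ_slope", "sbrs_area_slope",
    "breath_rate", "resp_amp_norm_mean", "resp_period_mean",
    "rsa_mean", "th_mean",
    "dincidence_abs", "dincidence_pct", "dfrequency_abs", "dfrequency_pct",
]


def cohort_report(
    cohort: pd.DataFrame, config: AnalysisConfig | None = None
) -> dict[str, pd.DataFrame]:
    """The full group-level report for one cohort table.

    Produces the mixed phase-by-group ANOVA for every per-phase MSNA
    metric, omnibus group comparisons (auto test choice) for the
    resting and change variables, proportions of subjects with a
    significant positive MSNA-TH coupling per group, and the
    modulation-vs-resting-hemodynamics correlation table.
    """
    config = config or AnalysisConfig()
    anova_rows = []
    for metric, (exp_col, insp_col) in _PHASE_METRICS.items():
        try:
            aov = phase_group_anova(cohort, exp_col, insp_col)
        except Exception:
            continue
        aov.insert(0, "metric", metric)
        anova_rows.append(aov)
    anova = (
        pd.concat(anova_rows, ignore_index=True) if anova_rows else pd.DataFrame()
    )

    cmp_rows = []
    for var in _RESTING_VARS:
        if var not in cohort.columns or cohort[var].notna().sum() < 4:
            continue
        try:
            res = group_compare(cohort, var, config=config)
        except Exception:
            continue
        cmp_rows.append(
            {"variable": var, "test": res["test"],
             "statistic": res["statistic"], "p": res["p"]}
        )
    comparisons = pd.DataFrame(cmp_rows)

    prop_rows = []
    groups = sorted(cohort["group"].dropna().unique())
    for tag in ("lag0", "lagp1", "lagm1"):
        col = f"coupling_sig_{tag}"
        if col not in cohort.columns:
            continue
        counts = []
        for g in groups:
            sub = cohort.loc[cohort["group"] == g, col].dropna()
            counts.append([int(sub.sum()), int((~sub.astype(bool)).sum())])
        table = np.asarray(counts).T
        if table.size == 0 or table.sum() == 0:
            continue
        res = proportion_compare(table)
        prop_rows.append(
            {"lag": tag, "test": res["test"], "statistic": res["statistic"],
             "p": res["p"]}
        )
    proportions = pd.DataFrame(prop_rows)

    correlations = modulation_bp_correlations(cohort, config=config)
    return {
        "anova": anova,
        "comparisons": comparisons,
        "proportions": proportions,
        "correlations": correlations,
    }
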