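"""Group inference on normative z-scores and demographic tables.

One-way ANOVA with partial eta-squared, Tukey-Kramer post-hoc tests,
Cohen's d, the two status/dosage interaction GLMs, a summary-statistic
ANOVA (for published tables that print only means/SDs/ns) and Pearson's
chi-squared test of independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
import statsmodels.api as sm


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    eta_p_sq: float
    ss_between: float = np.nan
    ss_within: float = np.nan


@dataclass
class PairwiseResult:
    pair: tuple
    mean_diff: float
    p_tukey: float
    ci_low: float
    ci_high: float
    cohens_d: float


@dataclass
class GroupStatsResult:
    feature: str
    anova: AnovaResult
    pairwise: list = field(default_factory=list)


def one_way_anova(values, groups) -> AnovaResult:
    """Standard between/within decomposition with partial eta-squared."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = [values[groups == g] for g in pd.unique(groups)]
    if len(levels) < 2 or any(len(v) < 2 for v in levels):
        raise ValueError("need >= 2 groups with >= 2 members each")
    grand = values.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in levels)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in levels)
    df1 = len(levels) - 1
    df2 = len(values) - len(levels)
    if ssw == 0:
        raise ValueError("zero within-group variance")
    F = (ssb / df1) / (ssw / df2)
    return AnovaResult(
        F=float(F),
        df1=df1,
        df2=df2,
        p=float(sst.f.sf(F, df1, df2)),
        eta_p_sq=float(ssb / (ssb + ssw)),
        ss_between=float(ssb),
        ss_within=float(ssw),
    )


def anova_from_summary(means, sds, ns) -> AnovaResult:
    """One-way ANOVA from per-group means, SDs and sizes.

    SSB is rebuilt from the means and sizes, SSW = sum (n_i - 1) s_i^2;
    identical to `one_way_anova` on raw data matching the summaries.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    if not len(means) == len(sds) == len(ns):
        raise ValueError("means, sds, ns must have equal length")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    grand = (means * ns).sum() / ns.sum()
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df1 = len(means) - 1
    df2 = int(ns.sum() - len(means))
    F = (ssb / df1) / (ssw / df2) if ssw > 0 else 0.0
    return AnovaResult(
        F=float(F),
        df1=df1,
        df2=df2,
        p=float(sst.f.sf(F, df1, df2)),
        eta_p_sq=float(ssb / (ssb + ssw)) if ssb + ssw > 0 else 0.0,
        ss_between=float(ssb),
        ss_within=float(ssw),
    )


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """eta_p^2 = F df1 / (F df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive dfs")
    return float(F * df1 / (F * df1 + df2))


def cohens_d(values_a, values_b) -> float:
    """(mean_a - mean_b) / pooled SD, with (n-1)-weighted pooling."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def tukey_hsd(values, groups, alpha: float = 0.05) -> list:
    """Tukey-Kramer pairwise comparisons (unequal n supported).

    Returns PairwiseResult records with studentized-range p-values,
    simultaneous CIs for the mean difference, and Cohen's d per pair.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    names = list(pd.unique(groups))
    samples = [values[groups == g] for g in names]
    res = sst.tukey_hsd(*samples)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out.append(
                PairwiseResult(
                    pair=(names[i], names[j]),
                    mean_diff=float(samples[i].mean() - samples[j].mean()),
                    p_tukey=float(res.pvalue[i, j]),
                    ci_low=float(ci.low[i, j]),
                    ci_high=float(ci.high[i, j]),
                    cohens_d=cohens_d(samples[i], samples[j]),
                )
            )
    return out


def group_stats(values, groups, feature: str = "") -> GroupStatsResult:
    """Omnibus ANOVA plus Tukey/Cohen's d pairwise records."""
    return GroupStatsResult(
        feature=feature,
        anova=one_way_anova(values, groups),
        pairwise=tukey_hsd(values, groups),
    )


def chi_square_independence(contingency) -> tuple:
    """Pearson chi-squared without continuity correction: (X2, df, p)."""
    table = np.asarray(contingency, float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = sst.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# Interaction GLMs
#
# Model 1: Y = b0 + b1 Status + b2 Sex + b3 Age + b4 Status*Sex + b5 Age*Status
# Model 2: as model 1 with Status replaced by gene dosage, expanded to
#          treatment-coded DEL/DUP indicators against the CTRL reference.
# Sex is coded F=0, M=1; age enters in raw years.


def _design_matrix(model_id: int, df: pd.DataFrame) -> pd.DataFrame:
    sex = (df["sex"] == "M").astype(float) if df["sex"].dtype == object else df["sex"]
    age = df["age"].astype(float)
    cols = {"Intercept": np.ones(len(df)), "Sex": sex.to_numpy(), "Age": age.to_numpy()}
    if model_id == 1:
        status = (df["group"] != "CTRL").astype(float).to_numpy()
        cols["Status"] = status
        cols["Status:Sex"] = status * cols["Sex"]
        cols["Age:Status"] = cols["Age"] * status
    elif model_id == 2:
        for g in ("DEL", "DUP"):
            ind = (df["group"] == g).astype(float).to_numpy()
            cols[g] = ind
            cols[f"{g}:Sex"] = ind * cols["Sex"]
            cols[f"Age:{g}"] = cols["Age"] * ind
    else:
        raise ValueError("model id must be 1 or 2")
    order = (
        ["Intercept", "Status", "Sex", "Age", "Status:Sex", "Age:Status"]
        if model_id == 1
        else ["Intercept", "DEL", "DUP", "Sex", "Age",
              "DEL:Sex", "DUP:Sex", "Age:DEL", "Age:DUP"]
    )
    return pd.DataFrame({k: cols[k] for k in order}, index=df.index)


def fit_glm(model_id: int, z_values, cohort: pd.DataFrame) -> pd.DataFrame:
    """OLS fit of the status (1) or dosage (2) interaction model.

    ``cohort`` provides group/sex/age per row aligned with ``z_values``.
    Raises on a rank-deficient design, naming the collinear terms.
    Returns a coefficient table (term, beta, se, t, p) plus the design
    condition number as ``.attrs["condition_number"]``.
    """
    X = _design_matrix(model_id, cohort)
    y = np.asarray(z_values, float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the scaled design
        q, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in range(len(diag))
               if diag[i] < 1e-10 * max(diag.max(), 1.0)]
        raise ValueError(f"rank-deficient design; collinear terms: {bad or 'unknown'}")
    fit = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {
            "term": X.columns,
            "beta": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    table.attrs["condition_number"] = float(np.linalg.cond(X.to_numpy()))
    return table
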