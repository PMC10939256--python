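"""Group statistics for ROI summary tables.

Two-group (WT vs ARTE10 transgenic) comparisons of per-animal ROI measures:
covariate-adjusted GLM t-tests, Benjamini-Hochberg FDR over each table's
family of measures, Cohen's d with a noncentral-t confidence interval, and
partial correlations between MRS concentrations and CEST-derived measures.

Sign conventions follow the reported tables: the mean difference is
WT − ARTE10 (adjusted), while Cohen's d standardizes ARTE10 − WT, so a
positive mean difference goes with a negative d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GROUPS = ("WT", "ARTE10")  # (reference, transgenic)


@dataclass
class ROITable:
    """Per-animal ROI measures with group labels and covariates."""

    data: pd.DataFrame
    group_col: str = "group"
    id_col: str = "animal_id"

    def __post_init__(self):
        df = self.data
        if df[self.id_col].duplicated().any():
            raise ValueError("duplicated animal_id")
        counts = df[self.group_col].value_counts()
        if len(counts) < 2 or (counts < 1).any():
            raise ValueError("need two non-empty groups")

    def group_values(self, measure: str, group: str) -> np.ndarray:
        sel = self.data[self.group_col] == group
        return self.data.loc[sel, measure].to_numpy(dtype=float)


@dataclass
class StatsResult:
    """One measure's two-group comparison."""

    measure: str
    mean_difference: float  # WT − ARTE10, adjusted
    t: float
    df: float
    p_two_sided: float
    cohens_d: float  # ARTE10 − WT, standardized
    d_ci_low: float
    d_ci_high: float
    p_fdr: float = np.nan

    def summary(self) -> str:
        return (
            f"{self.measure}: diff(WT−ARTE10) = {self.mean_difference:.4g}, "
            f"t({self.df:.0f}) = {self.t:.3f}, p = {self.p_two_sided:.4g}, "
            f"p_FDR = {self.p_fdr:.4g}, d = {self.cohens_d:.3f} "
            f"[{self.d_ci_low:.3f}, {self.d_ci_high:.3f}]"
        )


class GroupDifferenceModel:
    """GLM two-group comparison of one measure with optional covariates.

    Ordinary least squares of the measure on a group indicator
    (1 = ARTE10-like second group) plus covariates; the group coefficient's
    two-sided t-test is the reported comparison.  With no covariates this
    reproduces the classical pooled two-sample t-test exactly.
    """

    def __init__(self, y, group_indicator, covariates=None, measure="measure"):
        self.y = np.asarray(y, dtype=float)
        self.g = np.asarray(group_indicator, dtype=float)
        self.X_cov = (
            None
            if covariates is None or np.size(covariates) == 0
            else np.atleast_2d(np.asarray(covariates, dtype=float).T).T
        )
        self.measure = measure
        if self.g.min() == self.g.max():
            raise ValueError("both groups must be present")
        for v in (0.0, 1.0):
            if (self.g == v).sum() < 2:
                raise ValueError("need at least 2 animals per group")

    @classmethod
    def from_dataframe(
        cls,
        table: ROITable | pd.DataFrame,
        measure: str,
        covariates=(),
        groups=GROUPS,
    ) -> "GroupDifferenceModel":
        df = table.data if isinstance(table, ROITable) else table
        group_col = table.group_col if isinstance(table, ROITable) else "group"
        keep = df[group_col].isin(groups)
        df = df.loc[keep]
        g = (df[group_col] == groups[1]).to_numpy(dtype=float)
        cov = df[list(covariates)].to_numpy(dtype=float) if covariates else None
        if cov is not None and np.isnan(cov).any():
            raise ValueError("covariates contain missing values")
        return cls(df[measure].to_numpy(dtype=float), g, cov, measure=measure)

    def fit(self, conf: float = 0.95) -> StatsResult:
        X = self.g[:, None]
        if self.X_cov is not None:
            X = np.column_stack([X, self.X_cov])
        X = sm.add_constant(X)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "singular design: a covariate is collinear with the group "
                "indicator or another covariate"
            )
        res = sm.OLS(self.y, X).fit()
        coef = res.params[1]  # ARTE10 − WT adjusted
        a = self.y[self.g == 0]  # WT
        b = self.y[self.g == 1]  # ARTE10
        d, lo, hi = cohens_d_ci(a, b, conf=conf)
        return StatsResult(
            measure=self.measure,
            mean_difference=float(-coef),
            t=float(res.tvalues[1]),
            df=float(res.df_resid),
            p_two_sided=float(res.pvalues[1]),
            cohens_d=d,
            d_ci_low=lo,
            d_ci_high=hi,
        )


def glm_group_difference(
    table: ROITable | pd.DataFrame, measure: str, covariates=()
) -> StatsResult:
    """Covariate-adjusted two-group comparison of one measure."""
    return GroupDifferenceModel.from_dataframe(table, measure, covariates).fit()


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d_ci(
    group_a, group_b, conf: float = 0.95
) -> tuple[float, float, float]:
    """Cohen's d (mean_b − mean_a over pooled SD) with a noncentral-t CI.

    The CI inverts the noncentral-t distribution of the two-sample t
    statistic; if the inversion fails numerically the normal-approximation
    interval d ± z·SE(d) is used instead.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("pooled SD is zero")
    d = float((b.mean() - a.mean()) / np.sqrt(sp2))
    scale = np.sqrt(n1 * n2 / (n1 + n2))
    t_obs = d * scale
    alpha = 1.0 - conf
    try:
        lo = _nct_ncp(t_obs, df, 1.0 - alpha / 2) / scale
        hi = _nct_ncp(t_obs, df, alpha / 2) / scale
    except (RuntimeError, ValueError):
        se = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * df))
        z = sps.norm.ppf(1.0 - alpha / 2)
        lo, hi = d - z * se, d + z * se
    return d, float(lo), float(hi)


def _nct_ncp(t_obs: float, df: int, prob: float) -> float:
    """Noncentrality parameter ncp with nct.cdf(t_obs; df, ncp) == prob."""
    from scipy.optimize import brentq

    def f(ncp):
        v = sps.nct.cdf(t_obs, df, ncp)
        if np.isnan(v):  # scipy underflows far in the tails
            v = 0.0 if ncp > t_obs else 1.0
        return v - prob

    span = 10.0 + 5.0 * abs(t_obs)
    lo, hi = t_obs - span, t_obs + span
    for _ in range(6):
        if f(lo) * f(hi) < 0:
            return brentq(f, lo, hi, xtol=1e-12)
        lo -= span
        hi += span
    raise RuntimeError("noncentral-t inversion failed to bracket")


def partial_corr(x, y, covariates=None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (with intercept) by
    OLS; the Pearson correlation of the residuals is tested with a t
    statistic on n − 2 − k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        k = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float).T).T
        k = C.shape[1]
        X = np.column_stack([np.ones(n), C])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    if np.allclose(rx, 0) or np.allclose(ry, 0) or rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant residuals; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    r_cl = min(max(r, -0.9999999999), 0.9999999999)
    t = r_cl * np.sqrt(dof / (1.0 - r_cl * r_cl))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return r, p


def analyze_group_table(
    table: ROITable | pd.DataFrame,
    measures,
    covariates=(),
    conf: float = 0.95,
) -> pd.DataFrame:
    """Run the GLM comparison for every measure and FDR-adjust the family.

    All measures passed together form one multiple-comparison family, as in
    a single results table.  Returns a table-shaped DataFrame with columns
    mean_difference (WT − ARTE10), p, p_fdr, cohens_d, d_ci_low, d_ci_high,
    significant (p_fdr < 0.05).
    """
    results = [
        glm_group_difference(table, m, covariates) for m in measures
    ]
    p_fdr = bh_fdr([r.p_two_sided for r in results])
    rows = []
    for r, q in zip(results, p_fdr):
        r.p_fdr = float(q)
        rows.append(
            {
                "measure": r.measure,
                "mean_difference": r.mean_difference,
                "t": r.t,
                "df": r.df,
                "p": r.p_two_sided,
                "p_fdr": r.p_fdr,
                "cohens_d": r.cohens_d,
                "d_ci_low": r.d_ci_low,
                "d_ci_high": r.d_ci_high,
                "significant": r.p_fdr < 0.05,
            }
        )
    return pd.DataFrame(rows).set_index("measure")
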