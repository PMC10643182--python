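"""Survival curves, group tests, cohort-characteristics tables and FDR control.

Conventions fixed here and relied on throughout the pipeline:

* Kaplan-Meier median survival is the first event time at which S(t) <= 0.5
  (infinite when the curve never reaches 0.5).
* The chi-square test of proportions carries NO continuity correction.
* The per-drug sensitivity comparison is an unpaired two-sample rank test
  (Mann-Whitney U, exact where sample sizes permit), with Benjamini-Hochberg
  adjustment across drugs.
* Continuous covariates in the characteristics table use the pooled-variance
  two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_norm import ClinicalTable


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float
    method: str
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p": self.p,
                "method": self.method, **self.extra}


@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float  # inf if the curve never reaches 0.5

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "survival": self.survival,
            "at_risk": self.at_risk, "n_events": self.n_events,
        })


def km_estimate(surv: ClinicalTable) -> KMCurve:
    """Kaplan-Meier estimate of a clinical table's overall survival."""
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    table = kmf.event_table
    rows = table[table["observed"] > 0]
    times = rows.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    s = sf.loc[rows.index].to_numpy(dtype=float)
    at_risk = rows["at_risk"].to_numpy(dtype=int)
    n_events = rows["observed"].to_numpy(dtype=int)
    below = np.nonzero(s <= 0.5)[0]
    median = float(times[below[0]]) if below.size else float("inf")
    return KMCurve(event_times=times, survival=s, at_risk=at_risk,
                   n_events=n_events, median=median)


def logrank_test(surv: ClinicalTable, groups: pd.Series | np.ndarray) -> TestResult:
    """Two-group log-rank test (O-E chi-square with hypergeometric variance, 1 df)."""
    g = pd.Series(np.asarray(groups), index=surv.sample_ids)
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {levels}")
    a = g == levels[0]
    res = _ll_logrank(surv.time[a.to_numpy()], surv.time[~a.to_numpy()],
                      surv.event[a.to_numpy()], surv.event[~a.to_numpy()])
    return TestResult(statistic=float(res.test_statistic), df=1,
                      p=float(res.p_value), method="log-rank",
                      extra={"groups": [str(v) for v in levels]})


def chisq_test(table: np.ndarray | list) -> TestResult:
    """Pearson chi-square test of homogeneity, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("expected a 2-d contingency table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold non-negative integer counts")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("all row and column sums must be positive")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(stat), df=int(df), p=float(p),
                      method="chi-square", extra={"table": t.astype(int).tolist()})


def percentage(a: int, n: int) -> float:
    """Column percentage 100*a/n rounded to one decimal (0.0 when n == 0)."""
    if n == 0:
        return 0.0
    return round(100.0 * a / n, 1)


def cohort_characteristics(labels: pd.Series, clin: ClinicalTable,
                           covariates: list[str] | None = None) -> pd.DataFrame:
    """Per-subtype cohort-characteristics table with homogeneity p-values.

    Categorical covariates get per-level counts with column percentages and a
    chi-square p-value; numeric covariates get mean +/- SD per subtype and a
    pooled-variance t-test p-value.  Rows with missing covariate values are
    dropped per covariate.
    """
    labels = labels.loc[clin.sample_ids]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("characteristics table expects exactly 2 subtypes")
    cov = clin.covariates if covariates is None else clin.covariates[covariates]
    rows = []
    for name in cov.columns:
        col = cov[name].dropna()
        lab = labels.loc[col.index]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 6:
            a, b = col[lab == groups[0]], col[lab == groups[1]]
            _, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append({
                "characteristic": name, "level": "mean_sd",
                f"{groups[0]}": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                f"{groups[1]}": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                "p_value": float(p), "test": "t-test",
            })
        else:
            tab = pd.crosstab(col, lab).reindex(columns=groups, fill_value=0)
            tab = tab.loc[tab.sum(axis=1) > 0]
            p = chisq_test(tab.to_numpy().T).p if tab.shape[0] > 1 else float("nan")
            n_by_group = tab.sum(axis=0)
            for level, counts in tab.iterrows():
                rows.append({
                    "characteristic": name, "level": str(level),
                    f"{groups[0]}": f"{counts[groups[0]]} ({percentage(counts[groups[0]], n_by_group[groups[0]])})",
                    f"{groups[1]}": f"{counts[groups[1]]} ({percentage(counts[groups[1]], n_by_group[groups[1]])})",
                    "p_value": float(p), "test": "chi-square",
                })
    return pd.DataFrame(rows)


def bh_adjust(p_values: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_compare_aac(aac_group_a: dict[str, np.ndarray],
                     aac_group_b: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-drug unpaired rank test of drug-sensitivity (AAC) between subtypes.

    Returns a DataFrame (drug, statistic, p, p_adj) with Benjamini-Hochberg
    adjustment across drugs.  Drug keys must match between the two groups.
    """
    if set(aac_group_a) != set(aac_group_b):
        raise ValueError("drug sets differ between groups")
    drugs = sorted(aac_group_a)
    recs = []
    for d in drugs:
        a = np.asarray(aac_group_a[d], dtype=float)
        b = np.asarray(aac_group_b[d], dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError(f"empty group for drug {d!r}")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     use_continuity=False, method="auto")
        recs.append({"drug": d, "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(recs)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
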