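"""Reliability and group-comparison statistics.

The battery mirrors standard method-comparison practice in quantitative
histology: test–retest reliability via Pearson's r, the intraclass
correlation ICC(A,1) (two-way model, absolute agreement, single measure)
with its 95% F-interval, and Bland–Altman limits of agreement; method and
group comparisons via Kruskal–Wallis with post-hoc Mann–Whitney; covariate
screens via Spearman correlation under a Bonferroni-adjusted alpha
(default 0.002).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


@dataclass
class BlandAltman:
    mean_diff: float
    loa_lower: float
    loa_upper: float
    sd_diff: float


@dataclass
class ReliabilityReport:
    """Test–retest agreement for one method."""

    r: float  # Pearson; nan if undefined (zero variance)
    icc: float  # ICC(A,1)
    icc_ci: tuple[float, float]
    bland_altman: BlandAltman
    n_pairs: int


@dataclass
class GroupComparison:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    summaries: dict  # per group: median, q1, q3, n
    bonferroni_alpha: float | None = None
    significant: bool | None = None


def bland_altman(test: np.ndarray, retest: np.ndarray) -> BlandAltman:
    """Mean difference and d̄ ± 1.96·sd limits of agreement."""
    diff = np.asarray(retest, float) - np.asarray(test, float)
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    return BlandAltman(
        mean_diff=mean, loa_lower=mean - 1.96 * sd, loa_upper=mean + 1.96 * sd, sd_diff=sd
    )


def icc_absolute_single(test: np.ndarray, retest: np.ndarray) -> tuple[float, tuple[float, float]]:
    """ICC(A,1): two-way, absolute agreement, single measure, with 95% CI."""
    n = len(test)
    if n < 3:
        # too small for the F-interval machinery: ICC point estimate from
        # the two-way ANOVA mean squares directly, CI undefined
        x = np.column_stack([test, retest]).astype(float)
        k = 2
        grand = x.mean()
        rm, cm = x.mean(axis=1), x.mean(axis=0)
        msr = k * np.sum((rm - grand) ** 2) / (n - 1)
        msc = n * np.sum((cm - grand) ** 2) / (k - 1)
        mse = np.sum((x - rm[:, None] - cm[None, :] + grand) ** 2) / ((n - 1) * (k - 1))
        denom = msr + (k - 1) * mse + k / n * (msc - mse)
        icc = (msr - mse) / denom if denom != 0 else float("nan")
        return float(icc), (float("nan"), float("nan"))
    df = pd.DataFrame(
        {
            "targets": np.tile(np.arange(n), 2),
            "raters": np.repeat(["test", "retest"], n),
            "scores": np.concatenate([test, retest]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="scores", nan_policy="omit"
        )
    sel = table["Type"].isin(["ICC(A,1)", "ICC2"])  # label differs across versions
    row = table[sel].iloc[0]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    ci = row[ci_col]
    return float(row["ICC"]), (float(ci[0]), float(ci[1]))


def test_retest(pairs: list[tuple[float, float]] | np.ndarray) -> ReliabilityReport:
    """Agreement between first and repeat analyses of the same cases."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("pairs must be an (n >= 2, 2) array of (test, retest) values")
    if not np.isfinite(arr).all():
        raise ValueError("pairs must be finite")
    test, retest = arr[:, 0], arr[:, 1]
    if np.ptp(test) == 0 or np.ptp(retest) == 0:
        r = float("nan")  # undefined-flagged; ICC is still computed
    else:
        r = float(sps.pearsonr(test, retest).statistic)
    icc, ci = icc_absolute_single(test, retest)
    return ReliabilityReport(
        r=r, icc=icc, icc_ci=ci, bland_altman=bland_altman(test, retest), n_pairs=len(test)
    )


def _summaries(groups: dict[str, np.ndarray]) -> dict:
    out = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, float)
        out[name] = {
            "n": int(len(vals)),
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
        }
    return out


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact for n ≤ 8 per group, else normal
    approximation with tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and len(np.unique(np.r_[x, y])) == len(x) + len(y)) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_methods(densities: pd.DataFrame) -> list[GroupComparison]:
    """Omnibus Kruskal–Wallis across methods plus pairwise Mann–Whitney.

    ``densities`` is a wide per-case table: one column per method, one row
    per case (NaN rows for a method are dropped pairwise).
    """
    methods = list(densities.columns)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    cols = {m: densities[m].dropna().to_numpy() for m in methods}
    for m, v in cols.items():
        if len(v) < 3:
            raise ValueError(f"method {m!r} has fewer than 3 cases")
    pooled = np.concatenate(list(cols.values()))
    if np.ptp(pooled) == 0:
        omnibus = GroupComparison(
            test="kruskal-wallis", groups=tuple(methods), statistic=0.0, p_value=1.0,
            summaries=_summaries(cols),
        )
    else:
        stat, p = sps.kruskal(*cols.values())
        omnibus = GroupComparison(
            test="kruskal-wallis", groups=tuple(methods), statistic=float(stat),
            p_value=float(p), summaries=_summaries(cols),
        )
    out = [omnibus]
    for a, b in combinations(methods, 2):
        if np.ptp(np.r_[cols[a], cols[b]]) == 0:
            stat, p = float(len(cols[a]) * len(cols[b]) / 2), 1.0
        else:
            stat, p = mann_whitney(cols[a], cols[b])
        out.append(
            GroupComparison(
                test="mann-whitney", groups=(a, b), statistic=stat, p_value=p,
                summaries=_summaries({a: cols[a], b: cols[b]}),
            )
        )
    return out


def compare_groups(values: np.ndarray, labels: np.ndarray, group_a: str, group_b: str) -> GroupComparison:
    """Mann–Whitney comparison of one measurement between two case groups."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    a = values[labels == group_a]
    b = values[labels == group_b]
    stat, p = mann_whitney(a, b)
    return GroupComparison(
        test="mann-whitney", groups=(group_a, group_b), statistic=stat, p_value=p,
        summaries=_summaries({group_a: a, group_b: b}),
    )


def clinical_correlations(
    densities: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    alpha: float = 0.002,
) -> list[GroupComparison]:
    """Spearman correlation of density against each covariate.

    Significance is flagged only below the Bonferroni-adjusted alpha.
    Constant covariates yield an undefined (NaN) correlation, flagged but
    not significant.
    """
    dens = np.asarray(densities, float)
    out = []
    for name in covariates.columns:
        cov = covariates[name].to_numpy(dtype=float)
        mask = np.isfinite(cov) & np.isfinite(dens)
        if mask.sum() < 3 or np.ptp(cov[mask]) == 0:
            rho, p = float("nan"), float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sps.spearmanr(dens[mask], cov[mask])
            rho, p = float(res.statistic), float(res.pvalue)
        out.append(
            GroupComparison(
                test="spearman", groups=("density", name), statistic=rho, p_value=p,
                summaries={}, bonferroni_alpha=alpha,
                significant=bool(np.isfinite(p) and p < alpha),
            )
        )
    return out
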