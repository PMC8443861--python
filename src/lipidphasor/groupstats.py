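"""Group comparisons between cell populations.

Implements the comparison scheme used for the CM/DR cell groups:
medians compared with the two-sided Mann–Whitney U test, coefficients
of variation with the Fligner–Killeen test, and a distribution-gated
multi-group procedure — Shapiro–Wilk normality and Levene
homoscedasticity gates choosing between nonparametric tests with
Bonferroni correction and a rank-transform / Welch ANOVA / Games–Howell
route.  The executed branch is always reported, so every p-value in a
report is traceable to the test that produced it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TestResult", "GatedResult", "compare_median", "compare_cv", "gated_compare"]

_MIN_N = 3


@dataclass(frozen=True)
class TestResult:
    """One executed hypothesis test: name, statistic, p, group sizes."""

    test: str
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    note: str = ""


@dataclass
class GatedResult:
    """Outcome of the distribution-gated comparison.

    ``path`` names the branch taken; ``shapiro_p``/``levene_p`` document
    the gate decisions; ``posthoc`` holds pairwise comparisons (Bonferroni-
    corrected p-values or Games–Howell, per branch).
    """

    path: str
    normal: bool
    homoscedastic: bool
    shapiro_p: tuple[float, ...]
    levene_p: float
    omnibus: TestResult
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def _as_samples(*groups: Sequence[float], min_n: int = _MIN_N) -> list[np.ndarray]:
    out = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float).ravel()
        a = a[np.isfinite(a)]
        if a.size < min_n:
            raise ValueError(f"group {i} has n={a.size} < {min_n}")
        out.append(a)
    return out


def compare_median(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U comparison of two samples' locations.

    Uses the exact null distribution when both groups have n < 8 and no
    ties, the tie-corrected normal approximation otherwise.  Fully tied
    data carry no ordering information: p = 1 with a warning.
    """
    x, y = _as_samples(a, b)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; Mann-Whitney p set to 1", stacklevel=2)
        return TestResult("mann-whitney", float(x.size * y.size / 2), 1.0, (x.size, y.size),
                          note="all ties")
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size < 8 and y.size < 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann-whitney", float(res.statistic), float(res.pvalue),
                      (x.size, y.size), note=method)


def compare_cv(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Fligner–Killeen comparison of two samples' relative spread.

    Nonparametric test on ranked absolute deviations from the group
    medians, chi-square approximated; robust against non-normality.
    """
    x, y = _as_samples(a, b)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance group: spread comparison undefined")
    res = stats.fligner(x, y)
    return TestResult("fligner-killeen", float(res.statistic), float(res.pvalue),
                      (x.size, y.size))


def _bonferroni_pairwise(groups: list[np.ndarray]) -> pd.DataFrame:
    k = len(groups)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    rows = []
    for i, j in pairs:
        r = compare_median(groups[i], groups[j])
        rows.append({"A": i, "B": j, "test": r.test, "statistic": r.statistic,
                     "p_uncorrected": r.pvalue,
                     "p_corrected": min(1.0, r.pvalue * len(pairs))})
    return pd.DataFrame(rows)


def _rank_transform(groups: list[np.ndarray]) -> list[np.ndarray]:
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    out, start = [], 0
    for g in groups:
        out.append(ranks[start : start + g.size])
        start += g.size
    return out


def _welch_games_howell(groups: list[np.ndarray]) -> tuple[TestResult, pd.DataFrame]:
    import pingouin as pg

    df = pd.DataFrame(
        {
            "value": np.concatenate(groups),
            "group": np.concatenate([np.full(g.size, i) for i, g in enumerate(groups)]),
        }
    )
    aov = pg.welch_anova(data=df, dv="value", between="group")
    omnibus = TestResult(
        "welch-anova(ranks)",
        float(aov["F"].iloc[0]),
        float(aov["p_unc"].iloc[0]),
        tuple(g.size for g in groups),
    )
    gh = pg.pairwise_gameshowell(data=df, dv="value", between="group")
    posthoc = gh.rename(columns={"pval": "p_corrected"})[["A", "B", "T", "df", "p_corrected"]]
    posthoc = posthoc.assign(test="games-howell")
    return omnibus, posthoc


def gated_compare(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> GatedResult:
    """Distribution-gated comparison of two or more samples.

    Gates (both at ``alpha``): Shapiro–Wilk normality per group, Levene
    homogeneity of variances.  Branches:

    * non-normal + homoscedastic -> Kruskal–Wallis (Mann–Whitney for two
      groups) with Bonferroni-corrected pairwise comparisons;
    * non-normal + heteroscedastic -> rank transform, Welch ANOVA,
      Games–Howell post hoc;
    * normal -> one-way ANOVA (equal variances) or Welch ANOVA
      (unequal), Bonferroni/Games–Howell pairwise respectively.

    The taken branch is recorded in ``path``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    gs = _as_samples(*groups)
    shapiro_p = tuple(float(stats.shapiro(g).pvalue) for g in gs)
    normal = all(p >= alpha for p in shapiro_p)
    levene_p = float(stats.levene(*gs, center="median").pvalue)
    homoscedastic = levene_p >= alpha

    if not normal and homoscedastic:
        if len(gs) == 2:
            omnibus = compare_median(gs[0], gs[1])
            path = "mann-whitney+bonferroni"
        else:
            res = stats.kruskal(*gs)
            omnibus = TestResult("kruskal-wallis", float(res.statistic), float(res.pvalue),
                                 tuple(g.size for g in gs))
            path = "kruskal-wallis+bonferroni"
        posthoc = _bonferroni_pairwise(gs)
    elif not normal and not homoscedastic:
        omnibus, posthoc = _welch_games_howell(_rank_transform(gs))
        path = "rank+welch+games-howell"
    elif homoscedastic:
        res = stats.f_oneway(*gs)
        omnibus = TestResult("anova", float(res.statistic), float(res.pvalue),
                             tuple(g.size for g in gs))
        posthoc = _bonferroni_pairwise(gs)
        path = "anova+bonferroni"
    else:
        omnibus, posthoc = _welch_games_howell(gs)
        path = "welch+games-howell"

    return GatedResult(
        path=path,
        normal=normal,
        homoscedastic=homoscedastic,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        omnibus=omnibus,
        posthoc=posthoc,
    )
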