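"""Statistical harness for the group comparisons.

The metric distributions (GE, node strength, WPLI) are screened with a
one-sample Kolmogorov-Smirnov test against a fitted normal; group contrasts
use the Mann-Whitney U test, within-group stage contrasts the Kruskal-Wallis
test with a Dunn-Bonferroni post hoc, hemispheric asymmetry a paired t-test,
and the gender table a chi-squared test.  Significance stars follow the
convention *p < 0.05, **p < 0.005, ***p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ks_normality",
    "mann_whitney_u",
    "paired_t",
    "kruskal_wallis_dunn",
    "chi_squared_2x2",
    "group_comparison_suite",
    "results_frame",
    "stars",
]

STAR_LEVELS = ((0.001, "***"), (0.005, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for level, s in STAR_LEVELS:
        if p < level:
            return s
    return ""


@dataclass
class TestResult:
    """One hypothesis test with its comparison context."""

    test: str
    statistic: float
    p: float
    n: tuple
    comparison: str = ""
    band: str = ""
    stage: str = ""
    group: str = ""
    metric: str = ""
    corrected: bool = False
    correction: str = ""
    p_corrected: float | None = None

    def __post_init__(self):
        if self.p_corrected is not None and self.p_corrected < self.p - 1e-12:
            raise ValueError("corrected p cannot be below the raw p")

    @property
    def p_final(self) -> float:
        return self.p if self.p_corrected is None else self.p_corrected

    @property
    def stars(self) -> str:
        return stars(self.p_final)


def ks_normality(sample, min_n: int = 5) -> TestResult:
    """One-sample KS test of ``sample`` against N(mean, sd) fitted to it.

    The reference parameters are estimated from the same data, so the
    reported p is anti-conservative (Lilliefors caveat); here the test is a
    screen for gross non-normality before choosing nonparametric contrasts.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("sample is constant; normality test undefined")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(test="ks-normality", statistic=float(stat), p=float(p),
                      n=(x.size,))


def mann_whitney_u(x, y, **context) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact null enumeration when both samples are small (min n <= 8) and
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(test="mann-whitney-u", statistic=float(res.statistic),
                      p=float(res.pvalue), n=(x.size, y.size), **context)


def paired_t(x, y, **context) -> TestResult:
    """Two-sided paired t-test on the per-pair differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples must have equal length "
                         f"({x.size} vs {y.size})")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("difference variance is zero; t undefined")
    t, p = sps.ttest_rel(x, y)
    return TestResult(test="paired-t", statistic=float(t), p=float(p),
                      n=(x.size,), **context)


def _dunn_pairwise(groups, labels, alpha):
    """All pairwise Dunn z-tests on pooled ranks, Bonferroni-multiplied."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    pairs = list(combinations(range(len(groups)), 2))
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(TestResult(
            test="dunn", statistic=float(z), p=float(p),
            n=(sizes[a], sizes[b]),
            comparison=f"{labels[a]} vs {labels[b]}",
            corrected=True, correction="bonferroni",
            p_corrected=float(min(1.0, p * len(pairs)))))
    return out


def kruskal_wallis_dunn(groups, alpha: float = 0.05, labels=None, **context):
    """Tie-corrected Kruskal-Wallis over >= 3 groups, Dunn post hoc if
    significant at ``alpha`` (Bonferroni factor = number of group pairs).

    Returns a list of :class:`TestResult`; the omnibus result first.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis here requires >= 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    h, p = sps.kruskal(*groups)
    omnibus = TestResult(test="kruskal-wallis", statistic=float(h),
                         p=float(p), n=tuple(g.size for g in groups), **context)
    results = [omnibus]
    if p < alpha:
        for r in _dunn_pairwise(groups, labels, alpha):
            for k, v in context.items():
                setattr(r, k, v)
            results.append(r)
    return results


def chi_squared_2x2(table, correction: bool = True, **context) -> TestResult:
    """Pearson chi-squared on a 2x2 count table (Yates correction default)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("expected a 2x2 table of nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-squared undefined with a zero marginal")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=correction)
    return TestResult(test="chi-squared", statistic=float(chi2), p=float(p),
                      n=(int(t.sum()),), **context)


# ---------------------------------------------------------------------------
# the full comparison suite on a metrics table
# ---------------------------------------------------------------------------

def _collapse(df: pd.DataFrame, unit: str, value_cols) -> pd.DataFrame:
    if unit == "epoch":
        return df
    if unit == "subject":
        keys = ["subject", "group", "band", "stage"]
        return df.groupby(keys, as_index=False)[list(value_cols)].mean()
    raise ValueError(f"unknown unit {unit!r} (use 'epoch' or 'subject')")


def group_comparison_suite(metrics: pd.DataFrame, alpha: float = 0.05,
                           unit: str = "epoch",
                           strength_cols=None) -> list:
    """Run the full comparison battery on a long metrics table.

    ``metrics`` needs columns ``subject, group, band, stage, ge`` plus
    per-channel strengths (``strength_<ch>``) and hemisphere means
    (``left_strength, right_strength``).  Groups are the two values of
    ``group`` (sorted; by convention control before patient).

    Battery, mirroring the study design:

    - per (band, stage): MWU between groups on GE and on every node strength;
    - per (band, group): KW across stages on GE, Dunn-Bonferroni post hoc
      (correction family = stage pairs within that band and metric);
    - per (band, stage, group): paired t, left vs right hemisphere strength.

    Cells with missing data are skipped and reported as ``test="skipped"``.
    ``unit="subject"`` averages epochs within subject first (independent
    observations; recommended for inference), ``unit="epoch"`` pools epochs.
    """
    required = {"subject", "group", "band", "stage", "ge"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns {sorted(missing)}")
    if strength_cols is None:
        strength_cols = [c for c in metrics.columns if c.startswith("strength_")]
    value_cols = (["ge"] + list(strength_cols)
                  + [c for c in ("left_strength", "right_strength")
                     if c in metrics.columns])
    df = _collapse(metrics, unit, value_cols)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g0, g1 = groups
    results = []

    for (band, stage), cell in df.groupby(["band", "stage"], sort=True):
        x = cell.loc[cell["group"] == g1, "ge"].to_numpy()
        y = cell.loc[cell["group"] == g0, "ge"].to_numpy()
        ctx = dict(band=band, stage=stage, metric="ge",
                   comparison=f"{g1} vs {g0}")
        if x.size and y.size:
            results.append(mann_whitney_u(x, y, **ctx))
        else:
            results.append(TestResult(test="skipped", statistic=np.nan,
                                      p=np.nan, n=(x.size, y.size), **ctx))
        for col in strength_cols:
            xs = cell.loc[cell["group"] == g1, col].to_numpy()
            ys = cell.loc[cell["group"] == g0, col].to_numpy()
            ctx = dict(band=band, stage=stage, metric=col,
                       comparison=f"{g1} vs {g0}")
            if xs.size and ys.size:
                results.append(mann_whitney_u(xs, ys, **ctx))
            else:
                results.append(TestResult(test="skipped", statistic=np.nan,
                                          p=np.nan, n=(xs.size, ys.size), **ctx))

    for (band, group), cell in df.groupby(["band", "group"], sort=True):
        stage_groups = [(s, sub["ge"].to_numpy())
                        for s, sub in cell.groupby("stage", sort=True)
                        if sub.shape[0] >= 2]
        if len(stage_groups) >= 3:
            labels, arrays = zip(*stage_groups)
            results.extend(kruskal_wallis_dunn(
                arrays, alpha=alpha, labels=list(labels),
                band=band, group=group, metric="ge"))

    if {"left_strength", "right_strength"} <= set(df.columns):
        for (band, stage, group), cell in df.groupby(["band", "stage", "group"],
                                                     sort=True):
            l = cell["left_strength"].to_numpy()
            r = cell["right_strength"].to_numpy()
            ctx = dict(band=band, stage=stage, group=group,
                       metric="hemisphere_strength", comparison="left vs right")
            if l.size >= 2 and not np.allclose((l - r).std(ddof=1), 0):
                results.append(paired_t(l, r, **ctx))
            else:
                results.append(TestResult(test="skipped", statistic=np.nan,
                                          p=np.nan, n=(l.size,), **ctx))
    return results


def results_frame(results) -> pd.DataFrame:
    """Tabulate :class:`TestResult` objects (one row each, with stars)."""
    rows = []
    for r in results:
        rows.append({
            "test": r.test, "comparison": r.comparison, "band": r.band,
            "stage": r.stage, "group": r.group, "metric": r.metric,
            "statistic": r.statistic, "p_raw": r.p,
            "p_corrected": r.p_corrected if r.p_corrected is not None else r.p,
            "correction": r.correction, "n": "/".join(str(k) for k in r.n),
            "stars": r.stars if r.test != "skipped" else "",
        })
    return pd.DataFrame(rows)
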