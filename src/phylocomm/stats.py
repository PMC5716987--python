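"""Reported-statistics layer: Tukey letters, threshold t-tests, Pearson
panels and quadratic yield fits.

Group mean separation uses one-way ANOVA followed by Tukey's HSD, with a
compact letter display built by the insert-absorb algorithm: two groups
share a letter exactly when their Tukey-adjusted p-value is at or above α.
Normality (Shapiro) and homogeneity (Levene) checks are run and reported as
advisory warnings; they never block the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

log = logging.getLogger(__name__)


@dataclass
class LetterDisplay:
    """group -> (mean, sd, letters) plus the pairwise significance map."""

    table: pd.DataFrame                      # index group: mean, sd, n, letters
    reject: dict[frozenset, bool]            # pair -> significantly different
    anova_p: float
    assumption_warnings: list[str] = field(default_factory=list)

    def share_letter(self, a: str, b: str) -> bool:
        la = set(self.table.loc[a, "letters"])
        lb = set(self.table.loc[b, "letters"])
        return bool(la & lb)


def _insert_absorb(groups: list[str], reject: dict[frozenset, bool]) -> dict[str, str]:
    """Compact letter display (insert-absorb).

    Start from one column holding every group; for each significant pair
    split any column containing both; absorb columns that became subsets.
    """
    columns: list[set[str]] = [set(groups)]
    for a, b in combinations(groups, 2):
        if not reject.get(frozenset((a, b)), False):
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
            columns = [c for c in columns
                       if not any(c < other for other in columns)]
    # deduplicate, then order columns by the first member's position
    uniq = []
    for c in columns:
        if c and c not in uniq:
            uniq.append(c)
    order = {g: i for i, g in enumerate(groups)}
    uniq.sort(key=lambda c: min(order[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for k, col in enumerate(uniq):
        for g in groups:
            if g in col:
                letters[g] += alphabet[k % len(alphabet)]
    return letters


def tukey_letters(values, groups, alpha: float = 0.05) -> LetterDisplay:
    """One-way ANOVA + Tukey HSD with a compact letter display.

    Groups are ordered by decreasing mean for lettering, so 'a' marks the
    top group(s). Any group with fewer than 2 values raises.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    names, counts = np.unique(groups, return_counts=True)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    small = [n for n, c in zip(names, counts) if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 values: {small}")
    by_group = {n: values[groups == n] for n in names}

    warnings = []
    for n, v in by_group.items():
        if len(v) >= 3 and np.ptp(v) > 0:
            p_sw = sps.shapiro(v).pvalue
            if p_sw < alpha:
                warnings.append(f"normality questionable in group {n} "
                                f"(Shapiro p={p_sw:.3g})")
    if all(np.ptp(v) > 0 for v in by_group.values()):
        p_lev = sps.levene(*by_group.values()).pvalue
        if p_lev < alpha:
            warnings.append(f"variance homogeneity questionable "
                            f"(Levene p={p_lev:.3g})")
    for w in warnings:
        log.warning("tukey_letters: %s", w)

    anova_p = float(sps.f_oneway(*by_group.values()).pvalue)
    hsd = pairwise_tukeyhsd(values, groups, alpha=alpha)
    res = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    reject = {frozenset((str(r["group1"]), str(r["group2"]))): bool(r["reject"])
              for _, r in res.iterrows()}

    # letter columns assigned on mean-descending order; label ties broken
    # by group name for determinism
    ordered = sorted(names, key=lambda n: (-by_group[n].mean(), n))
    letters = _insert_absorb(ordered, reject)
    table = pd.DataFrame({
        "mean": [by_group[n].mean() for n in ordered],
        "sd": [by_group[n].std(ddof=1) for n in ordered],
        "n": [len(by_group[n]) for n in ordered],
        "letters": [letters[n] for n in ordered],
    }, index=pd.Index(ordered, name="group"))
    return LetterDisplay(table=table, reject=reject, anova_p=anova_p,
                         assumption_warnings=warnings)


@dataclass
class ThresholdTest:
    t: float
    p: float
    mean: float
    threshold: float
    verdict: str
    degenerate: bool = False


def ttest_vs_threshold(values, threshold: float) -> ThresholdTest:
    """One-sample two-tailed t-test of a set of values against a constant.

    Used for the ±2 decision rules: e.g. NRI values significantly above +2
    read "clustered beyond the null band". Zero-variance input degenerates
    to an exact mean comparison with a flagged p.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    if np.ptp(v) == 0:
        verdict = ("above" if mean > threshold else
                   "below" if mean < threshold else "equal")
        return ThresholdTest(t=float("inf") if mean != threshold else 0.0,
                             p=float("nan"), mean=mean, threshold=threshold,
                             verdict=verdict, degenerate=True)
    t, p = sps.ttest_1samp(v, popmean=threshold)
    if p < 0.05:
        verdict = "significantly above" if mean > threshold else "significantly below"
    else:
        verdict = "not significantly different"
    return ThresholdTest(t=float(t), p=float(p), mean=mean,
                         threshold=threshold, verdict=verdict)


@dataclass
class CorrelationPanel:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame

    def pair(self, a: str, b: str) -> tuple[float, float, str]:
        return (float(self.r.loc[a, b]), float(self.p.loc[a, b]),
                str(self.stars.loc[a, b]))


def _star(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_panel(data: pd.DataFrame, variables=None) -> CorrelationPanel:
    """Pairwise Pearson correlations with 0.05/0.01 significance stars.

    Pairs are computed on their complete observations; a pair with fewer
    than 3 complete rows, or with a constant variable, is reported as NaN
    and logged rather than raised.
    """
    variables = list(variables) if variables is not None else list(data.columns)
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.nan, index=variables, columns=variables)
    n = pd.DataFrame(0, index=variables, columns=variables, dtype=int)
    for a, b in combinations(variables, 2):
        sub = data[[a, b]].dropna()
        n.loc[a, b] = n.loc[b, a] = len(sub)
        if len(sub) < 3:
            log.warning("pearson_panel: <3 complete observations for %s~%s", a, b)
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        if sub[a].nunique() == 1 or sub[b].nunique() == 1:
            log.warning("pearson_panel: constant variable in pair %s~%s", a, b)
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        rr, pp = sps.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = rr
        p.loc[a, b] = p.loc[b, a] = pp
    np.fill_diagonal(n.values, len(data))
    stars = p.map(_star)
    return CorrelationPanel(r=r, p=p, n=n, stars=stars)


@dataclass
class QuadraticFit:
    intercept: float
    linear: float
    quadratic: float
    r: float
    r_linear: float
    p_model: float
    vertex: float | None  # interior optimum −b/(2c) when c < 0


def quadratic_fit(x, y) -> QuadraticFit:
    """Least-squares fit of y = a + b·x + c·x², with the linear fit nested.

    Reports the multiple correlation R = sqrt(R²), the model F-test p-value
    and the vertex −b/(2c) when the parabola opens downward (an interior
    maximum). Degenerate designs (fewer than 4 points, or x effectively
    constant) raise.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    design = np.column_stack([np.ones_like(x), x, x * x])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate design: x values do not span a quadratic")
    model = sm.OLS(y, design).fit()
    a, b, c = model.params
    lin = sm.OLS(y, design[:, :2]).fit()
    vertex = float(-b / (2 * c)) if c < 0 else None
    return QuadraticFit(intercept=float(a), linear=float(b), quadratic=float(c),
                        r=float(np.sqrt(max(model.rsquared, 0.0))),
                        r_linear=float(np.sqrt(max(lin.rsquared, 0.0))),
                        p_model=float(model.f_pvalue), vertex=vertex)
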