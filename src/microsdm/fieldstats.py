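"""Univariate group comparisons for the factor-sample table.

The analysis sequence is the one field ecologists run on plot data:
normality (Lilliefors-style Kolmogorov–Smirnov, parameters estimated from
the sample) and homogeneity of variance (Levene's test on absolute
deviations from group means), an optional natural-log transform when those
fail, then a one-way ANOVA followed by unadjusted LSD pairwise t-tests on
the pooled within-group variance. Groups are labelled with compact letter
display (CLD): groups sharing a letter do not differ at α, 'a' starts at
the largest mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import ParameterError, TransformError

__all__ = [
    "NormalityResult",
    "AnovaResult",
    "ks_normality",
    "levene",
    "anova_lsd",
    "compact_letters",
]


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def ks_normality(values) -> NormalityResult:
    """Lilliefors-style KS test against a normal with estimated mean/SD.

    P-values use the statsmodels table/approximation. Constant data cannot
    be tested and come back flagged degenerate.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ParameterError("normality test needs at least 3 values")
    if np.ptp(x) == 0:
        return NormalityResult(np.nan, np.nan, degenerate=True)
    stat, p = lilliefors(x, dist="norm")
    return NormalityResult(float(stat), float(p))


def _split_groups(values, groups):
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups)})
    out = {g: sub["value"].to_numpy() for g, sub in df.groupby("group", sort=False)}
    if len(out) < 2:
        raise ParameterError("need at least 2 groups")
    return out


def levene(values, groups) -> tuple[float, float]:
    """Levene's test (mean-centred variant) for homogeneity of variances."""
    parts = _split_groups(values, groups)
    if any(v.size < 2 for v in parts.values()):
        raise ParameterError("every group needs at least 2 values")
    stat, p = stats.levene(*parts.values(), center="mean")
    return float(stat), float(p)


def compact_letters(names: list, means: dict, different: set[frozenset]) -> dict:
    """Insert-and-absorb compact letter display.

    ``different`` holds frozensets of group pairs that differ significantly.
    Groups are processed in descending-mean order so the group with the
    largest mean carries 'a'. The result satisfies: two groups share a
    letter iff the display does not separate them, every significantly
    different pair shares no letter, and every non-different pair shares at
    least one letter.
    """
    order = sorted(names, key=lambda g: -means[g])
    # letter columns: each is a set of groups sharing that letter
    columns: list[set] = [set(order)]
    for i, g1 in enumerate(order):
        for g2 in order[i + 1:]:
            if frozenset((g1, g2)) not in different:
                continue
            for col in list(columns):
                if g1 in col and g2 in col:
                    # split the offending column into two copies
                    c1 = col - {g2}
                    c2 = col - {g1}
                    columns.remove(col)
                    for c in (c1, c2):
                        if c and not any(c <= other for other in columns):
                            columns.append(c)
                    # absorb columns that became subsets
                    columns = [c for c in columns
                               if not any(c < other for other in columns)]
    # stable letter order: first appearance of each column's top-mean group
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in names}
    for li, col in enumerate(columns):
        ch = chr(ord("a") + li)
        for g in col:
            letters[g] += ch
    return {g: "".join(sorted(letters[g])) for g in names}


@dataclass
class AnovaResult:
    """One-way ANOVA with LSD pairwise comparisons and letter groupings."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_stats: pd.DataFrame   # group, n, mean, se (on the analysed scale)
    pairwise_p: pd.DataFrame    # symmetric matrix of LSD p-values
    letters: dict
    alpha: float
    log_transformed: bool

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F({self.df_between}, {self.df_within}) = "
            f"{self.f_statistic:.3f}, p = {self.p_value:.4g}"
            + ("  [ln-transformed]" if self.log_transformed else ""),
            f"{'group':<16}{'n':>4}{'mean':>12}{'SE':>10}  letters",
        ]
        for _, r in self.group_stats.iterrows():
            lines.append(
                f"{str(r['group']):<16}{int(r['n']):>4}{r['mean']:>12.2f}"
                f"{r['se']:>10.2f}  {self.letters[r['group']]}"
            )
        return "\n".join(lines)


def anova_lsd(values, groups, alpha: float = 0.05,
              log_transform: bool = False) -> AnovaResult:
    """One-way ANOVA with LSD post-hoc letters.

    Pairwise LSD tests use the pooled within-group mean square:
    t = (x̄ᵢ − x̄ⱼ) / √(MSE·(1/nᵢ + 1/nⱼ)) on the within-group df. Letters
    come from :func:`compact_letters`; 'a' marks the largest mean.
    """
    x = np.asarray(values, dtype=float)
    if log_transform:
        if np.any(x <= 0):
            raise TransformError("log transform requires strictly positive values")
        x = np.log(x)
    parts = _split_groups(x, groups)
    names = list(parts)
    if any(v.size < 2 for v in parts.values()):
        raise ParameterError("every group needs at least 2 values for ANOVA")
    k = len(names)
    ns = {g: v.size for g, v in parts.items()}
    means = {g: float(v.mean()) for g, v in parts.items()}
    n_total = sum(ns.values())
    grand = float(x.mean())
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in names)
    ss_within = sum(float(((parts[g] - means[g]) ** 2).sum()) for g in names)
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    if mse == 0.0:
        f = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = (ss_between / df_b) / mse
        p = float(stats.f.sf(f, df_b, df_w))
    # pairwise LSD
    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    different = set()
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            if mse == 0.0:
                pij = 1.0 if means[g1] == means[g2] else 0.0
            else:
                t = (means[g1] - means[g2]) / np.sqrt(
                    mse * (1.0 / ns[g1] + 1.0 / ns[g2])
                )
                pij = float(2.0 * stats.t.sf(abs(t), df_w))
            pmat.loc[g1, g2] = pmat.loc[g2, g1] = pij
            if pij < alpha:
                different.add(frozenset((g1, g2)))
    letters = compact_letters(names, means, different)
    gstats = pd.DataFrame({
        "group": names,
        "n": [ns[g] for g in names],
        "mean": [means[g] for g in names],
        "se": [float(parts[g].std(ddof=1) / np.sqrt(ns[g])) for g in names],
    })
    return AnovaResult(float(f), df_b, df_w, p, gstats, pmat, letters,
                       alpha, log_transform)
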