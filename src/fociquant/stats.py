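"""Group comparisons: Student t-test, one-way ANOVA with Tukey HSD, and the
significance-star convention.

The two-group test is the classical two-tailed Student t-test with pooled
variance (Welch available behind a flag). Multi-group designs use one-way
ANOVA followed by Tukey's honestly-significant-difference post hoc test;
unbalanced groups get the Tukey–Kramer harmonic-mean correction (as
implemented by statsmodels' studentized-range machinery). Stars follow the
convention ns: p >= 0.05; *: p < 0.05; **: p < 0.01; ***: p < 0.001;
****: p < 0.0001.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    stars: str
    group_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def stars(p_value: float) -> str:
    """Map a p-value to its significance stars."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    if p_value < 1e-4:
        return "****"
    if p_value < 1e-3:
        return "***"
    if p_value < 1e-2:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def two_tailed_t(group_a, group_b, equal_var: bool = True) -> StatResult:
    """Two-tailed two-sample t-test (Student by default, Welch optional)."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            # Degenerate but unambiguous: identical constant groups.
            return StatResult("t", 0.0, 1.0, "ns")
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return StatResult("t" if equal_var else "welch-t", float(t), float(p), stars(float(p)))


def anova_tukey(groups: dict[str, np.ndarray],
                alpha: float = 0.05) -> list[StatResult]:
    """One-way ANOVA omnibus test plus all pairwise Tukey HSD comparisons.

    Returns the omnibus F result first, then one :class:`StatResult` per
    group pair with the Tukey-adjusted p-value. Requires >= 3 groups of
    n >= 2 each.
    """
    if len(groups) < 3:
        raise ValueError("one-way ANOVA with Tukey needs >= 3 groups")
    for name, values in groups.items():
        if np.asarray(values).size < 2:
            raise ValueError(f"group {name!r} has n < 2")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    if all(a.std(ddof=1) == 0 for a in arrays.values()) and \
            len({a.mean() for a in arrays.values()}) == 1:
        results = [StatResult("anova-F", 0.0, 1.0, "ns")]
        names = list(arrays)
        for i, gi in enumerate(names):
            for gj in names[i + 1:]:
                results.append(StatResult("tukey", 0.0, 1.0, "ns", (gi, gj)))
        return results

    f, p = sps.f_oneway(*arrays.values())
    results = [StatResult("anova-F", float(f), float(p), stars(float(p)))]

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    for (g1, g2), padj, stat in zip(
            zip(frame["group1"], frame["group2"]),
            np.asarray(tk.pvalues, dtype=float),
            np.asarray(tk.meandiffs, dtype=float)):
        padj = float(min(max(padj, 0.0), 1.0))
        results.append(StatResult("tukey", float(stat), padj, stars(padj),
                                  (str(g1), str(g2))))
    return results


def pairwise_t_unadjusted(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Unadjusted pairwise p-values from the one-way ANOVA model.

    Uses the pooled within-group mean square (all groups, df = N - k), the
    same error term Tukey HSD studentizes — so Tukey's adjusted p is always
    >= these values. Keys are group-name pairs in sorted order.
    """
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    n_total = sum(a.size for a in arrays.values())
    k = len(arrays)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    mse = sse / (n_total - k)
    out = {}
    names = sorted(arrays)
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            a, b = arrays[gi], arrays[gj]
            se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
            t = (a.mean() - b.mean()) / se
            out[(gi, gj)] = float(2.0 * sps.t.sf(abs(t), df=n_total - k))
    return out


def results_table(results: list[StatResult]) -> pd.DataFrame:
    """Flatten StatResults into the stats CSV layout."""
    rows = []
    for r in results:
        rows.append({
            "test": r.test,
            "group1": r.group_pair[0] if r.group_pair else "",
            "group2": r.group_pair[1] if r.group_pair else "",
            "statistic": r.statistic,
            "p_value": r.p_value,
            "stars": r.stars,
        })
    return pd.DataFrame(rows, columns=["test", "group1", "group2",
                                       "statistic", "p_value", "stars"])
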