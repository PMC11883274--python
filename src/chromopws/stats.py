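"""The study's statistical test battery.

Pairwise comparisons use a two-tailed unpaired t-test or a Mann-Whitney
test; families of pairwise comparisons are adjusted with the Holm-Šídák
step-down procedure; many-versus-control designs use one-way ANOVA followed
by Dunnett's test. All p-values are analytic (no permutation), keeping the
battery deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupComparison", "compare_groups", "holm_sidak"]

_METHODS = ("t", "mann-whitney", "anova-dunnett")
_ADJUSTMENTS = ("holm-sidak", "none")


@dataclass
class GroupComparison:
    """One comparison's result within a (possibly adjusted) family."""

    groups: tuple
    statistic: float
    raw_p: float
    adjusted_p: float
    method: str
    adjustment: str
    n_per_group: tuple
    degenerate: bool = False


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Šídák step-down adjusted p-values.

    Order the m raw p ascending; ``adj_i = max_{j<=i} 1 - (1-p_j)^(m-j+1)``,
    capped at 1 (so adjusted >= raw elementwise and the ordered output is
    monotone non-decreasing). Delegates to statsmodels' implementation of
    the same formula.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm-sidak")[1]


def _pairwise_p(a: np.ndarray, b: np.ndarray, method: str
                ) -> tuple[float, float, bool]:
    degenerate = (np.ptp(a) == 0 and np.ptp(b) == 0
                  and a[0] == b[0])
    if degenerate:
        # identical constant groups: no evidence of difference
        return 0.0, 1.0, True
    if method == "t":
        res = sps.ttest_ind(a, b, equal_var=True)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), False


def compare_groups(samples: dict, design: str = "pairwise",
                   method: str = "t", adjustment: str = "holm-sidak",
                   control: str | None = None,
                   pairs: list[tuple] | None = None
                   ) -> list[GroupComparison]:
    """Run the named tests over groups of observations.

    Parameters
    ----------
    samples : dict
        Group name -> 1-D array of observations (>= 2 each).
    design : "pairwise" | "many-vs-control"
        Pairwise runs the requested ``pairs`` (default: all unordered pairs)
        with the chosen method and family adjustment. Many-vs-control runs
        one-way ANOVA followed by Dunnett's test of every group against
        ``control`` (method must be "anova-dunnett").
    method : "t" | "mann-whitney" | "anova-dunnett"
    adjustment : "holm-sidak" | "none"
        Family-wise adjustment for the pairwise design (Dunnett adjusts
        internally).
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; options: {_METHODS}")
    if adjustment not in _ADJUSTMENTS:
        raise ValueError(
            f"unknown adjustment {adjustment!r}; options: {_ADJUSTMENTS}")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in samples.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs >= 2 observations")
    names = list(arrays)

    if design == "many-vs-control" or method == "anova-dunnett":
        if control is None:
            raise ValueError("many-vs-control design requires a control group")
        others = [n for n in names if n != control]
        f_res = sps.f_oneway(*arrays.values())
        dun = sps.dunnett(*(arrays[n] for n in others),
                          control=arrays[control])
        out = []
        for i, name in enumerate(others):
            out.append(GroupComparison(
                groups=(name, control),
                statistic=float(dun.statistic[i]),
                raw_p=float(dun.pvalue[i]),
                adjusted_p=float(dun.pvalue[i]),  # Dunnett is family-adjusted
                method="anova-dunnett",
                adjustment="dunnett",
                n_per_group=(arrays[name].size, arrays[control].size)))
        for c in out:
            c.anova_f = float(f_res.statistic)
            c.anova_p = float(f_res.pvalue)
        return out

    if pairs is None:
        pairs = [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names))]
    stats_raw = [_pairwise_p(arrays[a], arrays[b], method) for a, b in pairs]
    raw_p = np.array([p for _, p, _ in stats_raw])
    adj_p = holm_sidak(raw_p) if adjustment == "holm-sidak" else raw_p.copy()
    return [
        GroupComparison(groups=(a, b), statistic=s, raw_p=p,
                        adjusted_p=float(q), method=method,
                        adjustment=adjustment,
                        n_per_group=(arrays[a].size, arrays[b].size),
                        degenerate=deg)
        for (a, b), (s, p, deg), q in zip(pairs, stats_raw, adj_p)
    ]
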