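"""One-way ANOVA with the Games-Howell post-hoc test.

Games-Howell compares all group pairs without assuming equal variances:
each pair uses the Welch standard error and Welch-Satterthwaite degrees of
freedom, and refers q = |mean difference| * sqrt(2) / SE to the studentized
range distribution with k groups.  A compact-letter display is derived from
the adjusted-P matrix so that groups sharing no letter differ significantly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GamesHowellResult:
    pairwise: pd.DataFrame
    letters: dict[str, str]
    anova_F: float
    anova_p: float


def games_howell(groups: dict[str, np.ndarray], alpha: float = 0.05) -> GamesHowellResult:
    """All-pairs Games-Howell comparisons plus letter grouping.

    Parameters
    ----------
    groups
        Mapping of group name to 1-D sample of the metric; at least two
        groups with n >= 2 each.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: np.asarray(v, dtype=float).ravel() for g, v in groups.items()}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
    k = len(names)
    means = {g: v.mean() for g, v in data.items()}
    vars_ = {g: v.var(ddof=1) for g, v in data.items()}
    ns = {g: v.size for g, v in data.items()}

    F, p_anova = stats.f_oneway(*data.values())

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            va, vb = vars_[a] / ns[a], vars_[b] / ns[b]
            se = np.sqrt(va + vb)
            diff = means[a] - means[b]
            degenerate = se == 0
            if degenerate:
                # two zero-variance groups: identical -> p 1, else p 0
                df = float(ns[a] + ns[b] - 2)
                q = 0.0 if diff == 0 else np.inf
                padj = 1.0 if diff == 0 else 0.0
            else:
                denom = 0.0
                if vars_[a] > 0:
                    denom += va ** 2 / (ns[a] - 1)
                if vars_[b] > 0:
                    denom += vb ** 2 / (ns[b] - 1)
                df = (va + vb) ** 2 / denom if denom > 0 else float(ns[a] + ns[b] - 2)
                q = abs(diff) * np.sqrt(2.0) / se
                padj = float(stats.studentized_range.sf(q, k, df))
            rows.append(
                {
                    "group1": a,
                    "group2": b,
                    "mean_diff": diff,
                    "se": se,
                    "df": df,
                    "q": q,
                    "p_adj": min(1.0, padj),
                    "significant": padj < alpha,
                    "degenerate": degenerate and (vars_[a] == 0 or vars_[b] == 0),
                }
            )
    pairwise = pd.DataFrame(rows)
    letters = compact_letter_display(
        names, means, {(r["group1"], r["group2"]): r["p_adj"] for r in rows}, alpha
    )
    return GamesHowellResult(pairwise, letters, float(F), float(p_anova))


def compact_letter_display(names, means, pvals: dict, alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb letter assignment from a pairwise P matrix.

    Groups are processed by mean descending (ties by name) so the output is
    deterministic; two groups share a letter iff they are not significantly
    different at ``alpha``.
    """
    order = sorted(names, key=lambda g: (-means[g], g))

    def differ(a, b) -> bool:
        p = pvals.get((a, b), pvals.get((b, a), 1.0))
        return p < alpha

    # letter sets: list of sets of group names that may share a letter
    letter_sets: list[set] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(not differ(g, other) for other in s):
                s.add(g)
                placed = True
        if not placed:
            # insert: start a new letter with g, greedily absorbing prior
            # groups mutually compatible with every member
            new = {g}
            for h in order:
                if h != g and all(not differ(h, m) for m in new):
                    new.add(h)
            if not any(new <= s for s in letter_sets):
                letter_sets = [s for s in letter_sets if not s <= new]
                letter_sets.append(new)
    # prune non-maximal sets, order deterministically
    letter_sets = [s for s in letter_sets if not any(s < t for t in letter_sets)]
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for i, s in enumerate(letter_sets):
        for g in order:
            if g in s:
                out[g] += alphabet[i % len(alphabet)]
    return out
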