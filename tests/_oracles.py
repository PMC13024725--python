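"""Independent brute-force oracles used by the test suite.

Each routine re-derives a statistic from its definition (ranks and
concordances by enumeration, step-up FDR by the literal procedure,
mixed-ANOVA F by projection-matrix least squares) so the package's
implementations are checked against an unrelated computational path.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def average_ranks(x) -> np.ndarray:
    """Midranks computed by pairwise comparison counting."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    ranks = np.empty(n)
    for i in range(n):
        less = sum(1 for j in range(n) if x[j] < x[i])
        equal = sum(1 for j in range(n) if x[j] == x[i])
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_bruteforce(x, y) -> float:
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom) if denom else np.nan


def kendall_taub_bruteforce(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2.0
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return float((conc - disc) / denom) if denom else np.nan


def bh_stepup_bruteforce(pvals) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        adj[idx] = val
        prev = val
    return adj


def bh_rejections_bruteforce(pvals, q: float) -> int:
    """Number of step-up rejections at level q, from the definition."""
    p = np.sort(np.asarray(pvals, dtype=float))
    m = len(p)
    k = 0
    for i in range(1, m + 1):
        if p[i - 1] <= q * i / m:
            k = i
    return k


def exhaustive_permutation_p(x, y) -> float:
    """Two-sided enumeration p for |mean difference| over all splits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    obs = abs(x.mean() - y.mean())
    count = total = 0
    for idx in combinations(range(n), n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        if abs(pooled[sel].mean() - pooled[~sel].mean()) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _effect_code(labels, levels) -> np.ndarray:
    """Sum-to-zero (effect) coding: len(levels)-1 columns."""
    labels = np.asarray(labels)
    cols = []
    for lev in levels[:-1]:
        col = np.where(labels == lev, 1.0, 0.0)
        col[labels == levels[-1]] = -1.0
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(labels), 0))


def _ss_drop(y, X_full, drop_cols) -> tuple[float, float]:
    """Type-III SS for dropping ``drop_cols`` from the full design, plus the
    full-model residual SS, via least-squares projections."""
    keep = [i for i in range(X_full.shape[1]) if i not in drop_cols]
    rss_full = np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2)
    X_red = X_full[:, keep]
    rss_red = np.sum((y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]) ** 2)
    return rss_red - rss_full, rss_full


def mixed_anova_F_bruteforce(subjects, groups, conds, y,
                             group_levels, cond_levels) -> dict[str, float]:
    """F statistics of the 2-stratum mixed RM-ANOVA by projection matrices.

    Between-subjects: one-way ANOVA on subject means. Within-subjects:
    subject-centered responses regressed on effect-coded condition and
    group x condition columns; Type-III model comparisons.
    """
    subjects = np.asarray(subjects)
    groups = np.asarray(groups)
    conds = np.asarray(conds)
    y = np.asarray(y, dtype=float)
    uniq_sub = list(dict.fromkeys(subjects))
    k = len(cond_levels)
    G = len(group_levels)
    N = len(uniq_sub)

    sub_mean = {s: y[subjects == s].mean() for s in uniq_sub}
    sub_group = {s: groups[subjects == s][0] for s in uniq_sub}
    ym = np.array([sub_mean[s] for s in uniq_sub])
    g_of_sub = np.array([sub_group[s] for s in uniq_sub])
    Xb = np.column_stack([np.ones(N), _effect_code(g_of_sub, group_levels)])
    ss_a, rss_b = _ss_drop(ym, Xb, drop_cols=list(range(1, Xb.shape[1])))
    F_between = (ss_a / (G - 1)) / (rss_b / (N - G))

    centered = np.array([yy - sub_mean[s] for s, yy in zip(subjects, y)])
    Xc = _effect_code(conds, cond_levels)
    Xg = _effect_code(groups, group_levels)
    Xgc = np.column_stack([Xg[:, i:i + 1] * Xc for i in range(Xg.shape[1])])
    X_full = np.column_stack([Xc, Xgc])
    ccols = list(range(Xc.shape[1]))
    icols = list(range(Xc.shape[1], X_full.shape[1]))
    ss_c, rss_w = _ss_drop(centered, X_full, ccols)
    ss_i, _ = _ss_drop(centered, X_full, icols)
    df_err = (N - G) * (k - 1)
    F_cond = (ss_c / (k - 1)) / (rss_w / df_err)
    F_inter = (ss_i / ((G - 1) * (k - 1))) / (rss_w / df_err)
    return {"age": float(F_between), "condition": float(F_cond),
            "age x condition": float(F_inter)}
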