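"""Mixed 2 x k repeated-measures ANOVA with Greenhouse-Geisser correction,
Bonferroni pairwise follow-ups, Welch t tests, and a-priori power analysis
for the within-between interaction.

The ANOVA uses the unweighted-means (Type III) convention for unbalanced
groups: the within-subject main effect tests the *unweighted* average of
group condition profiles, matching what conventional RM-ANOVA software
reports. Within-subject sums of squares are computed on orthonormal
contrast scores, so the Greenhouse-Geisser epsilon from the pooled
within-group covariance applies directly to the degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.optimize import brentq
from scipy.stats import f as f_dist
from scipy.stats import ncf, nct
from scipy.stats import t as t_dist


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    d: float
    ci: tuple[float, float]
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_x: int
    n_y: int


def _d_ci_from_t(t: float, df: float, scale: float, conf: float = 0.95
                 ) -> tuple[float, float]:
    """Noncentral-t inversion CI for a standardized difference.

    ``scale`` converts a noncentrality parameter into d units
    (d = ncp * scale at the observed design).
    """
    alpha = 1.0 - conf

    def safe_cdf(nc: float) -> float:
        v = nct.cdf(t, df, nc)
        if np.isnan(v):  # scipy underflows to NaN deep in the tails
            return 0.0 if nc > t else 1.0
        return float(v)

    def solve(target: float) -> float:
        lo, hi = t - 50.0 - 50.0 * abs(t), t + 50.0 + 50.0 * abs(t)
        try:
            return brentq(lambda nc: safe_cdf(nc) - target, lo, hi, xtol=1e-10)
        except ValueError:
            return np.nan

    nc_lo = solve(1.0 - alpha / 2.0)
    nc_hi = solve(alpha / 2.0)
    return (nc_lo * scale, nc_hi * scale)


def welch_t(x, y, conf: float = 0.95) -> WelchResult:
    """Welch's unequal-variance t test with Cohen's d and its CI.

    The sign convention is ``mean(x) - mean(y)``; d uses the pooled SD and
    its CI comes from noncentral-t inversion at the Welch df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = (m1 - m2) / sp if sp > 0 else np.nan
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    t_d = d / scale if np.isfinite(d) else np.nan
    ci = (_d_ci_from_t(t_d, n1 + n2 - 2, scale, conf)
          if np.isfinite(t_d) else (np.nan, np.nan))
    return WelchResult(float(t), float(df), float(p), float(d), ci,
                       float(m1), float(m2), float(np.sqrt(v1)),
                       float(np.sqrt(v2)), n1, n2)


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k repeated-measures covariance."""
    k = cov.shape[0]
    C = helmert(k)  # (k-1) x k, orthonormal rows orthogonal to the unit vector
    M = C @ cov @ C.T
    eps = np.trace(M) ** 2 / ((k - 1) * np.trace(M @ M))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def partial_eta_ci(F: float, df1: float, df2: float, conf: float = 0.90
                   ) -> tuple[float, float]:
    """CI for partial eta squared by noncentral-F CDF inversion.

    The lower bound is clipped at 0 (the usual one-sided-safe convention
    when F is small).
    """
    alpha = 1.0 - conf
    fobs = F

    def solve(target: float) -> float:
        if ncf.cdf(fobs, df1, df2, 0.0) < target:
            return 0.0
        hi = 10.0
        while ncf.cdf(fobs, df1, df2, hi) > target and hi < 1e7:
            hi *= 2.0
        return brentq(lambda nc: ncf.cdf(fobs, df1, df2, nc) - target,
                      0.0, hi, xtol=1e-10)

    lam_lo = solve(1.0 - alpha / 2.0)
    lam_hi = solve(alpha / 2.0)
    to_eta = lambda lam: lam / (lam + df1 + df2 + 1.0)
    return (to_eta(lam_lo), to_eta(lam_hi))


def mixed_anova(df: pd.DataFrame, dv: str = "value", within: str = "condition",
                between: str = "group", subject: str = "participant",
                correction: str = "gg", eta_conf: float = 0.90,
                eta_ci: bool = True) -> pd.DataFrame:
    """2-group x k-condition mixed RM-ANOVA.

    Subjects missing any condition are dropped listwise. Returns one row
    per effect (between, within, interaction) with F, (epsilon-corrected)
    dfs, p, partial eta squared and its CI, and the Greenhouse-Geisser
    epsilon for within effects.
    """
    wide = (df.pivot_table(index=[subject, between], columns=within,
                           values=dv, aggfunc="mean")
            .dropna().reset_index())
    cond_levels = [c for c in wide.columns if c not in (subject, between)]
    k = len(cond_levels)
    groups = sorted(wide[between].unique())
    G = len(groups)
    if G < 2 or k < 2:
        raise ValueError("need >= 2 groups and >= 2 conditions")
    Ys = [wide.loc[wide[between] == g, cond_levels].to_numpy(dtype=float)
          for g in groups]
    ns = np.array([len(Y) for Y in Ys])
    if (ns < 2).any():
        raise ValueError("need >= 2 complete participants per group")
    N = int(ns.sum())

    # Between-subjects stratum on subject means (one-way ANOVA, scaled by k).
    sub_means = [Y.mean(axis=1) for Y in Ys]
    gmeans = np.array([sm.mean() for sm in sub_means])
    grand = np.concatenate(sub_means).mean()
    ss_between = k * float(np.sum(ns * (gmeans - grand) ** 2))
    ss_subj = k * float(sum(((sm - sm.mean()) ** 2).sum() for sm in sub_means))
    df_between, df_subj = G - 1.0, float(N - G)
    F_between = (ss_between / df_between) / (ss_subj / df_subj)

    # Within-subjects stratum on orthonormal contrast scores.
    C = helmert(k)
    Us = [Y @ C.T for Y in Ys]
    ubars = np.stack([U.mean(axis=0) for U in Us])       # G x (k-1)
    uw = np.concatenate(Us).sum(axis=0) / N              # weighted mean
    unweighted = ubars.mean(axis=0)
    ss_cond = float((unweighted ** 2).sum() * G * G / np.sum(1.0 / ns))
    ss_inter = float(sum(ns[g] * ((ubars[g] - uw) ** 2).sum()
                         for g in range(G)))
    ss_err = float(sum(((U - U.mean(axis=0)) ** 2).sum() for U in Us))
    df_cond, df_inter = k - 1.0, (G - 1.0) * (k - 1.0)
    df_err = (N - G) * (k - 1.0)
    F_cond = (ss_cond / df_cond) / (ss_err / df_err)
    F_inter = (ss_inter / df_inter) / (ss_err / df_err)

    # Pooled within-group covariance -> sphericity correction.
    S_pool = sum((ns[g] - 1) * np.cov(Ys[g], rowvar=False)
                 for g in range(G)) / (N - G)
    eps = gg_epsilon(S_pool) if correction == "gg" else 1.0

    rows = []
    for effect, F, d1, d2, use_eps in (
            ("age", F_between, df_between, df_subj, False),
            ("condition", F_cond, df_cond, df_err, True),
            ("age x condition", F_inter, df_inter, df_err, True)):
        e = eps if use_eps else 1.0
        d1c, d2c = d1 * e, d2 * e
        p = float(f_dist.sf(F, d1c, d2c))
        eta = d1c * F / (d1c * F + d2c)
        ci = partial_eta_ci(F, d1c, d2c, eta_conf) if eta_ci else (np.nan, np.nan)
        rows.append({"effect": effect, "F": float(F), "df1": d1c, "df2": d2c,
                     "p": p, "eta_p2": float(eta), "eta_ci_lo": ci[0],
                     "eta_ci_hi": ci[1], "epsilon": e if use_eps else np.nan})
    return pd.DataFrame(rows)


def bonferroni_pairwise(df: pd.DataFrame, dv: str = "value",
                        within: str = "condition", subject: str = "participant",
                        between: str = "group", group: str | None = None,
                        m: int | None = None, d_method: str = "diff",
                        conf: float = 0.95) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise condition contrasts.

    Contrast t statistics use difference scores with the variance pooled
    across both groups (error df = N - G), the conventional follow-up for a
    mixed design; with a single group present this reduces to the ordinary
    paired t. ``group`` restricts the contrasted means to one group while
    still pooling the error. ``d_method`` is "diff" (difference-score SD)
    or "cell" (average cell SD).
    """
    wide = (df.pivot_table(index=[subject] + ([between] if between in df else []),
                           columns=within, values=dv, aggfunc="mean")
            .dropna().reset_index())
    conds = [c for c in wide.columns if c not in (subject, between)]
    has_groups = between in wide.columns
    if has_groups:
        groups = sorted(wide[between].unique())
    else:
        groups = ["all"]
        wide[between] = "all"
    G = len(groups)
    N = len(wide)
    pairs = [(conds[i], conds[j]) for i in range(len(conds))
             for j in range(i + 1, len(conds))]
    m = m if m is not None else len(pairs)

    rows = []
    for a, b in pairs:
        diffs = {g: (wide.loc[wide[between] == g, a] -
                     wide.loc[wide[between] == g, b]).to_numpy()
                 for g in groups}
        pooled_var = sum((len(d) - 1) * d.var(ddof=1) for d in diffs.values())
        df_err = N - G
        pooled_var /= df_err
        if group is not None:
            dsel = diffs[group]
        else:
            dsel = np.concatenate(list(diffs.values()))
        n_eff = len(dsel)
        mean_diff = float(np.mean([d.mean() for d in diffs.values()])
                          if group is None else dsel.mean())
        t = mean_diff / np.sqrt(pooled_var / n_eff)
        p = 2.0 * t_dist.sf(abs(t), df_err)
        if d_method == "diff":
            sd_eff = np.sqrt(pooled_var)
        else:
            sub = wide if group is None else wide[wide[between] == group]
            sd_eff = np.sqrt((sub[a].var(ddof=1) + sub[b].var(ddof=1)) / 2.0)
        d_val = mean_diff / sd_eff if sd_eff > 0 else np.nan
        # ncp-to-d scale: d = (t / sqrt(n)) * (sd_diff / sd_eff).
        scale = (np.sqrt(pooled_var) / sd_eff) / np.sqrt(n_eff) if sd_eff > 0 else np.nan
        ci = (_d_ci_from_t(t, df_err, scale, conf)
              if np.isfinite(d_val) else (np.nan, np.nan))
        rows.append({"contrast": f"{a} - {b}", "group": group or "all",
                     "mean_diff": mean_diff, "t": float(t), "df": float(df_err),
                     "p": float(p), "p_bonf": float(min(1.0, m * p)),
                     "d": float(d_val), "d_ci_lo": ci[0], "d_ci_hi": ci[1]})
    return pd.DataFrame(rows)


def power_rm_interaction(n_total: int, f: float = 0.25, alpha: float = 0.05,
                         n_groups: int = 2, n_measurements: int = 3,
                         rho_rm: float = 0.5, epsilon: float = 1.0) -> float:
    """Power of the within-between interaction F test at total N.

    Noncentrality lambda = N * m * f^2 * epsilon / (1 - rho_rm) with
    numerator df (g-1)(m-1)epsilon and denominator df (N-g)(m-1)epsilon —
    the conventional a-priori repeated-measures convention (G*Power with
    its default effect-size parameterization).
    """
    g, m = n_groups, n_measurements
    lam = n_total * m * f * f * epsilon / (1.0 - rho_rm)
    df1 = (g - 1) * (m - 1) * epsilon
    df2 = (n_total - g) * (m - 1) * epsilon
    crit = f_dist.ppf(1.0 - alpha, df1, df2)
    return float(ncf.sf(crit, df1, df2, lam))


def required_n_rm_interaction(f: float = 0.25, alpha: float = 0.05,
                              power: float = 0.95, n_groups: int = 2,
                              n_measurements: int = 3, rho_rm: float = 0.5,
                              epsilon: float = 1.0, n_max: int = 10 ** 6) -> int:
    """Smallest total N (equal group allocation) reaching the power target."""
    if not 0.0 < alpha < power < 1.0:
        raise ValueError("need 0 < alpha < power < 1")
    if f <= 0.0 or not 0.0 <= rho_rm < 1.0:
        raise ValueError("need f > 0 and rho_rm in [0, 1)")
    g = n_groups
    n = g * 2  # at least two subjects per group
    while n <= n_max:
        if power_rm_interaction(n, f, alpha, g, n_measurements, rho_rm,
                                epsilon) >= power:
            return n
        n += g
    raise ValueError(f"power target unreachable within N <= {n_max}")
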