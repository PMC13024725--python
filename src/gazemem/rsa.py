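"""Eye-memory representational similarity analysis.

For each participant, the 3x3 choice-proportion matrix (chosen category x
true condition) and each gaze metric's 3x3 matrix (AOI x condition) are
vectorized with the same column-wise rule and rank-correlated; the Fisher
r-to-z transform of that correlation is the participant's eye-memory
similarity. Three inference schemes operate on the z values:

* primary — Welch t per metric, Benjamini-Hochberg FDR across the six
  metrics;
* estimator robustness — Kendall tau-b similarity with a label-permutation
  test (add-one smoothed two-sided p), FDR across metrics;
* trial-level bootstrap — choice trials paired with gaze trials by triad
  identity within participant and condition, fixed-size resampling with
  replacement within condition, both matrices rebuilt per resample, and
  the participant's estimate is the mean Fisher z over resamples.

Perfect 9-pair correlations are common, so |rho| is clamped at 1 - 1e-6
before atanh; zero-variance vectors make the rank correlation undefined
and the participant-metric pair is excluded with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, spearmanr
from statsmodels.stats.multitest import multipletests

from .gazemetrics import METRICS
from .groupstats import welch_t
from .synthdata import CONDITIONS

RHO_CLAMP = 1.0 - 1e-6


class DegenerateInputError(ValueError):
    """Raised when a similarity is undefined (zero-variance vector)."""


def fisher_z(rho: float, clamp: float = RHO_CLAMP) -> float:
    """Fisher r-to-z (atanh) with |rho| clamped below 1 for finiteness."""
    return float(np.arctanh(np.clip(rho, -clamp, clamp)))


def vectorize_matrix(mat) -> np.ndarray:
    """Column-wise vectorization: top-to-bottom within columns, left-to-right
    across columns — the same fixed rule for both representational spaces."""
    if isinstance(mat, pd.DataFrame):
        mat = mat.loc[list(CONDITIONS), list(CONDITIONS)].to_numpy()
    return np.asarray(mat, dtype=float).ravel(order="F")


def similarity(mem_vec, eye_vec, estimator: str = "spearman"
               ) -> tuple[float, float]:
    """Rank correlation between the two 9-vectors, plus its Fisher z.

    Spearman uses average ranks on ties; Kendall is tau-b. Raises
    :class:`DegenerateInputError` if either vector has zero variance or
    missing entries.
    """
    x = np.asarray(mem_vec, dtype=float)
    y = np.asarray(eye_vec, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateInputError("missing values in representational vector")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateInputError("zero-variance representational vector")
    if estimator == "spearman":
        rho = spearmanr(x, y).statistic
    elif estimator == "kendall":
        rho = kendalltau(x, y).statistic
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if not np.isfinite(rho):
        raise DegenerateInputError("rank correlation undefined")
    return float(rho), fisher_z(rho)


def build_eye_matrix(cond_df: pd.DataFrame, participant: str, metric: str
                     ) -> pd.DataFrame | None:
    """3x3 (AOI rows x condition columns) matrix of one participant's
    condition-level metric values; None if any cell is missing."""
    sub = cond_df[(cond_df["participant"] == participant) &
                  (cond_df["metric"] == metric)]
    if len(sub) == 0:
        return None
    mat = sub.pivot_table(index="aoi", columns="condition", values="value")
    try:
        mat = mat.loc[list(CONDITIONS), list(CONDITIONS)]
    except KeyError:
        return None
    if mat.isna().any().any():
        return None
    mat.index.name = "aoi"
    return mat


def participant_similarities(choice_mats: dict[str, pd.DataFrame],
                             cond_df: pd.DataFrame,
                             estimator: str = "spearman",
                             metrics=METRICS
                             ) -> tuple[pd.DataFrame, list[dict]]:
    """Per participant x metric similarity records plus an exclusion log.

    Participants whose choice matrix has an empty column are excluded from
    all metrics (incomplete condition information); participant-metric
    pairs with incomplete eye matrices or degenerate vectors are excluded
    individually.
    """
    groups = (cond_df[["participant", "age_group"]].drop_duplicates()
              .set_index("participant")["age_group"].to_dict())
    # One pivot for all participants and metrics, then cheap slicing.
    pt = cond_df.pivot_table(index=["participant", "metric", "aoi"],
                             columns="condition", values="value")
    emats = {key: sub.droplevel([0, 1]) for key, sub in pt.groupby(level=[0, 1])}
    conds = list(CONDITIONS)
    rows, exclusions = [], []
    for pid, cmat in choice_mats.items():
        if cmat.isna().any().any():
            exclusions.append({"participant": pid, "metric": "*",
                               "reason": "incomplete choice matrix"})
            continue
        mem_vec = vectorize_matrix(cmat)
        for metric in metrics:
            emat = emats.get((pid, metric))
            if emat is not None:
                emat = emat.reindex(index=conds, columns=conds)
            if emat is None or emat.isna().to_numpy().any():
                exclusions.append({"participant": pid, "metric": metric,
                                   "reason": "incomplete eye matrix"})
                continue
            try:
                rho, z = similarity(mem_vec, emat.to_numpy().ravel(order="F"),
                                    estimator)
            except DegenerateInputError as err:
                exclusions.append({"participant": pid, "metric": metric,
                                   "reason": str(err)})
                continue
            rows.append({"participant": pid, "age_group": groups.get(pid),
                         "metric": metric, "estimator": estimator,
                         "rho": rho, "z": z})
    return pd.DataFrame(rows, columns=["participant", "age_group", "metric",
                                       "estimator", "rho", "z"]), exclusions


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def group_inference(sim_df: pd.DataFrame, young: str = "YA", older: str = "OA",
                    metrics=METRICS) -> pd.DataFrame:
    """Welch t comparison of Fisher-z similarity between age groups, with
    BH-FDR across the metric family and Cohen's d with 95% CI."""
    rows = []
    for metric in metrics:
        sub = sim_df[sim_df["metric"] == metric]
        zy = sub[sub["age_group"] == young]["z"].to_numpy()
        zo = sub[sub["age_group"] == older]["z"].to_numpy()
        if len(zy) < 2 or len(zo) < 2:
            continue
        res = welch_t(zy, zo)
        rows.append({"metric": metric, "n_young": res.n_x, "n_older": res.n_y,
                     "mean_z_young": res.mean_x, "mean_z_older": res.mean_y,
                     "sd_z_young": res.sd_x, "sd_z_older": res.sd_y,
                     "t": res.t, "df": res.df, "p": res.p, "d": res.d,
                     "d_ci_lo": res.ci[0], "d_ci_hi": res.ci[1]})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = bh_adjust(out["p"])
    return out


def permutation_test(x, y, n_perm: int = 10_000, seed: int | None = None,
                     exact: bool = False) -> float:
    """Two-sided permutation p for the group mean difference.

    Random label shuffles with add-one smoothing by default; ``exact=True``
    enumerates all group assignments (feasible for small samples) and
    returns the unsmoothed enumeration p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    obs = abs(x.mean() - y.mean())
    if exact:
        count = total = 0
        for idx in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += stat >= obs - 1e-12
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    order = rng.random((n_perm, n)).argsort(axis=1)
    shuffled = pooled[order]
    total = pooled.sum()
    m1 = shuffled[:, :n1].mean(axis=1)
    m2 = (total - shuffled[:, :n1].sum(axis=1)) / (n - n1)
    count = int(np.sum(np.abs(m1 - m2) >= obs - 1e-12))
    return (count + 1.0) / (n_perm + 1.0)


def permutation_inference(sim_df: pd.DataFrame, n_perm: int = 10_000,
                          seed: int | None = None, young: str = "YA",
                          older: str = "OA", metrics=METRICS) -> pd.DataFrame:
    """Permutation p per metric (single RNG stream), BH-FDR across metrics."""
    rng = np.random.default_rng(seed)
    rows = []
    for metric in metrics:
        sub = sim_df[sim_df["metric"] == metric]
        zy = sub[sub["age_group"] == young]["z"].to_numpy()
        zo = sub[sub["age_group"] == older]["z"].to_numpy()
        if len(zy) < 2 or len(zo) < 2:
            continue
        p = permutation_test(zy, zo, n_perm=n_perm,
                             seed=int(rng.integers(2 ** 31)))
        rows.append({"metric": metric, "mean_z_young": zy.mean(),
                     "mean_z_older": zo.mean(), "p_perm": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_perm_fdr"] = bh_adjust(out["p_perm"])
    return out


@dataclass(frozen=True)
class BootstrapSpec:
    """Trial-level bootstrap settings.

    ``resample_size`` None applies the median rule: the median number of
    quality-controlled paired trials across participants x conditions x
    metrics (the rule that fixes the within-condition draw size).
    """
    n_boot: int = 100
    resample_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.resample_size is not None and self.resample_size < 1:
            raise ValueError("resample_size must be >= 1")


def pair_trials(trials_df: pd.DataFrame, trial_metric_df: pd.DataFrame
                ) -> pd.DataFrame:
    """Pair memory-choice trials with gaze trials by triad identity.

    Inner join on (participant, condition, group_id); each paired trial
    carries the chosen category and the metric's three AOI values, wide by
    AOI; pairs missing any eye-movement value for a metric are removed for
    that metric. QC-failing gaze trials never enter.
    """
    from .memory import selection_trials
    gaze = trial_metric_df
    if "qc_pass" in gaze.columns:
        gaze = gaze[gaze["qc_pass"].astype(bool)]
    long = gaze.melt(id_vars=["participant", "trial", "condition", "group_id",
                              "aoi"],
                     value_vars=list(METRICS), var_name="metric",
                     value_name="value")
    wide = long.pivot_table(index=["participant", "condition", "group_id",
                                   "metric"],
                            columns="aoi", values="value").reset_index()
    wide = wide.dropna(subset=list(CONDITIONS))
    sel = selection_trials(trials_df)[["participant", "condition", "group_id",
                                       "choice", "age_group"]]
    return sel.merge(wide, on=["participant", "condition", "group_id"],
                     how="inner")


def median_resample_size(paired: pd.DataFrame) -> int:
    """Median paired-trial count across participants x conditions x metrics."""
    counts = paired.groupby(["participant", "condition", "metric"]).size()
    return max(1, int(np.median(counts)))


def bootstrap_rsa(paired: pd.DataFrame, spec: BootstrapSpec = BootstrapSpec(),
                  metrics=METRICS) -> tuple[pd.DataFrame, list[dict]]:
    """Trial-level bootstrap similarity estimates.

    For each participant and metric: draw ``resample_size`` paired trials
    with replacement within each condition (regardless of how many pairs
    that condition actually has — the deficit is logged), rebuild the 3x3
    choice and eye matrices from the resample, correlate (Spearman) and
    Fisher-transform; the estimate is the mean z over ``n_boot`` resamples.
    Degenerate resamples (zero-variance vectors) are dropped from the mean;
    participant-metric pairs with a condition lacking pairs entirely, or
    with no valid resample, are excluded with a reason.
    """
    size = spec.resample_size or median_resample_size(paired)
    cond_idx = {c: i for i, c in enumerate(CONDITIONS)}
    pids = sorted(paired["participant"].unique())
    groups = (paired[["participant", "age_group"]].drop_duplicates()
              .set_index("participant")["age_group"].to_dict())
    rows, exclusions = [], []
    for p_i, pid in enumerate(pids):
        psub = paired[paired["participant"] == pid]
        for m_i, metric in enumerate(metrics):
            msub = psub[psub["metric"] == metric]
            pools = {}
            for cond in CONDITIONS:
                csub = msub[msub["condition"] == cond]
                if len(csub) == 0:
                    pools = None
                    break
                pools[cond] = (
                    np.array([cond_idx[c] for c in csub["choice"]]),
                    csub[list(CONDITIONS)].to_numpy(dtype=float))
            if pools is None:
                exclusions.append({"participant": pid, "metric": metric,
                                   "reason": "condition with zero paired trials"})
                continue
            deficit = {c: size - len(v[0]) for c, v in pools.items()
                       if len(v[0]) < size}
            rng = np.random.default_rng([spec.seed, p_i, m_i])
            zs = []
            for _ in range(spec.n_boot):
                cmat = np.empty((3, 3))
                emat = np.empty((3, 3))
                for cond, (ch, eye) in pools.items():
                    draw = rng.integers(0, len(ch), size=size)
                    j = cond_idx[cond]
                    cmat[:, j] = np.bincount(ch[draw], minlength=3) / size
                    emat[:, j] = eye[draw].mean(axis=0)
                try:
                    _, z = similarity(cmat.ravel(order="F"),
                                      emat.ravel(order="F"))
                except DegenerateInputError:
                    continue
                zs.append(z)
            if not zs:
                exclusions.append({"participant": pid, "metric": metric,
                                   "reason": "all resamples degenerate"})
                continue
            rows.append({"participant": pid, "age_group": groups.get(pid),
                         "metric": metric, "z": float(np.mean(zs)),
                         "n_valid_resamples": len(zs),
                         "resample_size": size,
                         "deficit": sum(deficit.values())})
    return pd.DataFrame(rows, columns=["participant", "age_group", "metric",
                                       "z", "n_valid_resamples",
                                       "resample_size", "deficit"]), exclusions


def bootstrap_inference(boot_df: pd.DataFrame, young: str = "YA",
                        older: str = "OA", metrics=METRICS) -> pd.DataFrame:
    """Welch t + BH-FDR on the participant-level bootstrap-mean z values."""
    return group_inference(boot_df, young=young, older=older, metrics=metrics)
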