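"""Trial x AOI eye-movement metrics and their condition-level aggregation.

Six metrics are computed per retained trial for each of the three AOIs
(NR/RR/UR); the trial's *target* AOI is the one whose label matches the
trial condition:

* ``viewing_prop`` — AOI fixation time / total fixation time within the
  three AOIs (the three proportions form a composition summing to 1);
* ``early_target`` — per-AOI indicator: 1 iff the first AOI-landing
  fixation of the trial is in that AOI (so the target-AOI column is the
  early target viewing proportion after averaging);
* ``first_fix_latency`` — onset of the first fixation in the AOI minus the
  trial-onset marker time (ms);
* ``first_fix_dur`` — duration of that first fixation (ms);
* ``mean_fix_dur`` — mean fixation duration in the AOI (ms);
* ``revisits`` — number of entries into the AOI minus one (an entry is a
  maximal run of consecutive fixations with that AOI label), floored at 0.

Unvisited AOIs yield missing values for the time-based metrics (never
zero-filled; zeros would inject spurious structure into the downstream
representational matrices), while ``revisits`` is 0 and ``viewing_prop`` is
0 for an unvisited AOI whenever the trial has at least one AOI fixation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthdata import CONDITIONS

METRICS = ("viewing_prop", "early_target", "first_fix_latency",
           "first_fix_dur", "mean_fix_dur", "revisits")

#: Fraction of a condition's trials that must survive QC for the
#: participant to be retained (participants below this in any condition
#: are flagged for exclusion).
MIN_RETAINED_FRACTION = 0.30


def trial_metrics(fix_df: pd.DataFrame) -> pd.DataFrame:
    """Compute the six metrics at the trial x AOI level.

    ``fix_df`` is the preprocessed fixation table (one row per retained
    fixation, temporally ordered within trial, with ``aoi``, ``target``,
    ``trial_onset_ms`` and ``duration_ms`` columns). Returns a long frame
    with one row per (participant, trial, aoi).
    """
    df = fix_df.sort_values(["participant", "trial", "t_on_ms"],
                            kind="stable").reset_index(drop=True)
    key = ["participant", "trial"]

    on_aoi = df[df["aoi"] != "none"].copy()
    # Dwell time per AOI and per trial (AOI-fixation time only).
    dwell = (on_aoi.groupby(key + ["aoi"], sort=False)["duration_ms"].sum()
             .rename("dwell").reset_index())
    total = dwell.groupby(key, sort=False)["dwell"].sum().rename("total")
    dwell = dwell.merge(total.reset_index(), on=key)

    # First fixation per (trial, aoi): latency and duration.
    firsts = on_aoi.groupby(key + ["aoi"], sort=False).agg(
        first_t_on=("t_on_ms", "first"), first_fix_dur=("duration_ms", "first"),
        mean_fix_dur=("duration_ms", "mean"),
        trial_onset_ms=("trial_onset_ms", "first")).reset_index()
    firsts["first_fix_latency"] = firsts["first_t_on"] - firsts["trial_onset_ms"]

    # Entries: a fixation starts an entry when its AOI label differs from the
    # previous fixation's label within the same trial (full sequence,
    # off-AOI fixations break a run).
    prev_aoi = df.groupby(key, sort=False)["aoi"].shift()
    entry = (df["aoi"] != "none") & (df["aoi"] != prev_aoi)
    entries = (df.assign(_entry=entry.astype(int))
               [df["aoi"] != "none"]
               .groupby(key + ["aoi"], sort=False)["_entry"].sum()
               .rename("n_entries").reset_index())
    entries["revisits"] = np.maximum(entries["n_entries"] - 1, 0)

    # First AOI-landing fixation of the trial; the per-AOI early-viewing
    # indicator is 1 for the AOI it landed in and 0 for the other two, so
    # the target-AOI column is the early target viewing proportion and the
    # full 3x3 is the early-orienting distribution.
    first_landing = on_aoi.groupby(key, sort=False).agg(
        _first_aoi=("aoi", "first"), target=("target", "first")).reset_index()

    # Assemble the full trial x AOI grid for trials with >= 1 AOI fixation.
    trials = first_landing[key + ["target", "_first_aoi"]]
    grid = trials.loc[trials.index.repeat(3)].reset_index(drop=True)
    grid["aoi"] = np.tile(np.asarray(CONDITIONS), len(trials))
    grid["early_target"] = (grid["aoi"] == grid["_first_aoi"]).astype(float)
    grid = grid.drop(columns="_first_aoi")

    grid = grid.merge(dwell, on=key + ["aoi"], how="left")
    # "total" is NaN on rows for unvisited AOIs; recover it from the trial.
    tot = grid.groupby(key, sort=False)["total"].transform("max")
    grid["viewing_prop"] = grid["dwell"].fillna(0.0) / tot

    grid = grid.merge(firsts[key + ["aoi", "first_fix_latency", "first_fix_dur",
                                    "mean_fix_dur"]], on=key + ["aoi"], how="left")
    grid = grid.merge(entries[key + ["aoi", "revisits"]], on=key + ["aoi"],
                      how="left")
    grid["revisits"] = grid["revisits"].fillna(0.0)

    meta_cols = [c for c in ("condition", "age_group", "qc_pass", "group_id")
                 if c in fix_df.columns]
    if meta_cols:
        meta = fix_df.groupby(key, sort=False)[meta_cols].first().reset_index()
        grid = grid.merge(meta, on=key, how="left")
    return grid.drop(columns=["dwell", "total"])


def aggregate(trial_df: pd.DataFrame, qc_only: bool = True) -> pd.DataFrame:
    """Average trial x AOI metrics to participant x condition x AOI level.

    Means are taken over QC-passing trials; cells with no contributing
    trials are absent (missing, never zero-filled). Returns a tidy long
    frame: participant, age_group, metric, condition, aoi, value, n_trials.
    """
    df = trial_df
    if qc_only and "qc_pass" in df.columns:
        df = df[df["qc_pass"].astype(bool)]
    long = df.melt(
        id_vars=[c for c in ("participant", "age_group", "condition", "aoi")
                 if c in df.columns],
        value_vars=list(METRICS), var_name="metric", value_name="value")
    long = long.dropna(subset=["value"])
    out = (long.groupby(["participant", "age_group", "metric", "condition",
                         "aoi"], sort=False, dropna=False)
           .agg(value=("value", "mean"), n_trials=("value", "size"))
           .reset_index())
    return out


def target_metrics(cond_df: pd.DataFrame) -> pd.DataFrame:
    """Extract the target-AOI column (condition == AOI) for RM-ANOVA use."""
    return cond_df[cond_df["condition"] == cond_df["aoi"]].copy()


def flag_low_retention(qc: pd.DataFrame, trials_per_condition: int,
                       min_fraction: float = MIN_RETAINED_FRACTION
                       ) -> pd.DataFrame:
    """Participants whose retained-trial fraction falls below the threshold
    in any condition (flagged for exclusion from group analyses)."""
    counts = (qc[qc["qc_pass"]].groupby(["participant", "condition"])
              .size().rename("n_retained").reset_index())
    full = pd.MultiIndex.from_product(
        [qc["participant"].unique(), list(CONDITIONS)],
        names=["participant", "condition"]).to_frame(index=False)
    counts = full.merge(counts, on=["participant", "condition"], how="left")
    counts["n_retained"] = counts["n_retained"].fillna(0).astype(int)
    counts["fraction"] = counts["n_retained"] / trials_per_condition
    counts["flagged"] = counts["fraction"] < min_fraction
    return (counts.groupby("participant")
            .agg(min_fraction=("fraction", "min"), flagged=("flagged", "any"))
            .reset_index())
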