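"""Memory scoring: cue d', true object memory, the schema-based
false-memory decomposition, and the 3x3 choice-proportion matrix.

Old/new cue judgments are scored with the signal-detection index
d' = Z(hit rate) - Z(false-alarm rate). Object selection (3AFC) trials —
old-cue trials the participant correctly judged "old" — are scored per
condition: *true object memory* is the fraction of selections matching the
studied condition; for restructured targets (RR/UR) the errors decompose
into *schema-consistent* false memory (choosing the typical NR lure) and
*schema-inconsistent* false memory (choosing the other restructured lure).

The choice-proportion matrix collects, per participant, the empirical
distribution of chosen categories (rows) within each true condition
(columns); columns are exactly stochastic and the diagonal equals true
object memory per condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .synthdata import CONDITIONS

DPRIME_CORRECTIONS = ("loglinear", "none", "half")


def dprime(hits: int, misses: int, fas: int, crs: int,
           correction: str = "loglinear") -> float:
    """Signal-detection d' from response counts.

    ``correction`` handles extreme rates: ``"loglinear"`` (default) adds
    0.5 to each cell and 1 to each denominator; ``"half"`` replaces rates of
    0 and 1 by 1/(2N) and 1 - 1/(2N); ``"none"`` applies no correction and
    returns +/-inf on perfect rates.
    """
    n_old, n_new = hits + misses, fas + crs
    if n_old < 1 or n_new < 1:
        raise ValueError("need at least one old and one new trial")
    if correction == "loglinear":
        hr = (hits + 0.5) / (n_old + 1.0)
        far = (fas + 0.5) / (n_new + 1.0)
    elif correction == "half":
        hr = min(max(hits / n_old, 1.0 / (2 * n_old)), 1.0 - 1.0 / (2 * n_old))
        far = min(max(fas / n_new, 1.0 / (2 * n_new)), 1.0 - 1.0 / (2 * n_new))
    elif correction == "none":
        hr, far = hits / n_old, fas / n_new
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(ndtri(hr) - ndtri(far))


def true_object_memory(choices, condition: str) -> float:
    """Fraction of selection trials where the studied category was chosen."""
    choices = np.asarray(choices, dtype=object)
    if len(choices) == 0:
        return float("nan")
    return float(np.mean(choices == condition))


def false_memory_decomposition(choices, condition: str
                               ) -> tuple[float, float]:
    """Schema-consistent and schema-inconsistent false-memory proportions.

    Defined only for restructured conditions: schema-consistent errors pick
    the NR lure; schema-inconsistent errors pick the other restructured
    category (UR in RR trials, RR in UR trials). Both are proportions of
    the condition's selection-trial count.
    """
    if condition not in ("RR", "UR"):
        raise ValueError("false-memory decomposition is defined for RR/UR only")
    choices = np.asarray(choices, dtype=object)
    n = len(choices)
    if n == 0:
        return float("nan"), float("nan")
    other = "UR" if condition == "RR" else "RR"
    return (float(np.sum(choices == "NR")) / n,
            float(np.sum(choices == other)) / n)


def selection_trials(trials_df: pd.DataFrame) -> pd.DataFrame:
    """Object-selection trials: old cues the participant judged "old"."""
    return trials_df[(trials_df["cue_status"] == "old") &
                     (trials_df["cue_resp"] == "old")]


def score_memory(trials_df: pd.DataFrame, correction: str = "loglinear"
                 ) -> pd.DataFrame:
    """Per participant x condition memory scores.

    Returns one row per (participant, condition) with d' (condition-wise
    hit rate against the participant's pooled false-alarm rate), true
    object memory, the false-memory decomposition (NaN in the NR
    condition, where it is undefined) and the selection-trial count.
    """
    rows = []
    for (pid, grp_lab), part in trials_df.groupby(["participant", "age_group"],
                                                  sort=False):
        new = part[part["cue_status"] == "new"]
        fas = int((new["cue_resp"] == "old").sum())
        crs = int((new["cue_resp"] == "new").sum())
        for cond in CONDITIONS:
            old = part[(part["cue_status"] == "old") & (part["condition"] == cond)]
            hits = int((old["cue_resp"] == "old").sum())
            misses = int((old["cue_resp"] == "new").sum())
            sel = old[old["cue_resp"] == "old"]["choice"].to_numpy()
            if cond in ("RR", "UR"):
                fm_c, fm_i = false_memory_decomposition(sel, cond)
            else:
                fm_c = fm_i = float("nan")
            rows.append({
                "participant": pid, "age_group": grp_lab, "condition": cond,
                "dprime": dprime(hits, misses, fas, crs, correction)
                if (hits + misses and fas + crs) else float("nan"),
                "true_mem": true_object_memory(sel, cond),
                "fm_schema_consistent": fm_c, "fm_schema_inconsistent": fm_i,
                "n_selection_trials": len(sel),
            })
    return pd.DataFrame(rows)


def choice_matrix(trials_df: pd.DataFrame) -> pd.DataFrame:
    """3x3 choice-proportion matrix for one participant's selection trials.

    Rows are chosen categories, columns true conditions; each column with
    at least one selection trial is an exact probability distribution.
    Columns without trials are NaN.
    """
    sel = selection_trials(trials_df)
    mat = pd.DataFrame(np.nan, index=list(CONDITIONS), columns=list(CONDITIONS))
    for cond in CONDITIONS:
        ch = sel[sel["condition"] == cond]["choice"]
        if len(ch):
            counts = ch.value_counts()
            mat[cond] = [counts.get(lab, 0) / len(ch) for lab in CONDITIONS]
    mat.index.name = "chosen"
    mat.columns.name = "condition"
    return mat


def choice_matrices(trials_df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-participant choice matrices, keyed by participant id."""
    return {pid: choice_matrix(part)
            for pid, part in trials_df.groupby("participant", sort=False)}
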