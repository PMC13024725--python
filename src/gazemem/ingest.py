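"""Fixation-report ingestion: trial segmentation, eye selection, filtering,
coordinate mapping, AOI assignment and trial-level quality control.

The input is a documented TSV fixation report (one row per fixation event or
experiment message) plus a behavioral trial CSV and an AOI JSON, as written
by :mod:`gazemem.synthdata` or exported from real recordings in the same
schema. All stages operate on pandas DataFrames and are pure functions of
their inputs, so re-running any stage on already-processed data is a no-op.

Conventions fixed here (each the package's default, switchable where noted):

* a fixation belongs to the trial whose ``TRIALID``/``TRIAL_RESULT`` window
  contains its *onset* time (a fixation straddling the trial end is kept);
* fixations strictly shorter than ``min_dur`` (default 60 ms) are removed,
  60 ms exactly is kept;
* AOI containment is half-open, ``[xmin, xmax) x [ymin, ymax)``, so the
  three rectangles partition the plane without double counting;
* quality control runs after the short-fixation filter (switchable).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import CONDITIONS


class MalformedRecordingError(ValueError):
    """Raised when trial demarcation messages are not well nested."""


class ParticipantDataError(ValueError):
    """Raised when a participant has no usable gaze data."""


class AOIConfigError(ValueError):
    """Raised when per-trial AOI rectangles overlap or are mislabeled."""


_TRIALID = re.compile(r"^TRIALID\s+(\d+)$")
_TRIALRESULT = re.compile(r"^TRIAL_RESULT\s+(\d+)$")


def read_fixation_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_aois(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        payload = json.load(fh)
    records = payload["aois"] if isinstance(payload, dict) else payload
    return pd.DataFrame(records)


def _parse_windows(grp: pd.DataFrame, pid: str) -> tuple[list, list, list]:
    """Extract well-nested (trial id, start, end) windows for one participant."""
    starts, ends, trial_ids = [], [], []
    open_trial = None
    markers = grp[grp["msg"] != "FIX"]
    for msg, t in zip(markers["msg"], markers["t_on_ms"]):
        m = _TRIALID.match(msg)
        if m:
            if open_trial is not None:
                raise MalformedRecordingError(
                    f"{pid}: TRIALID {m.group(1)} opened before trial "
                    f"{open_trial[0]} was closed")
            open_trial = (int(m.group(1)), float(t))
            continue
        m = _TRIALRESULT.match(msg)
        if m:
            tid = int(m.group(1))
            if open_trial is None or open_trial[0] != tid:
                raise MalformedRecordingError(f"{pid}: unmatched TRIAL_RESULT {tid}")
            trial_ids.append(tid)
            starts.append(open_trial[1])
            ends.append(float(t))
            open_trial = None
    if open_trial is not None:
        raise MalformedRecordingError(f"{pid}: TRIALID {open_trial[0]} never closed")
    return trial_ids, starts, ends


def trial_windows(fix_df: pd.DataFrame) -> pd.DataFrame:
    """All demarcated trial windows (including trials with no fixations)."""
    rows = []
    for pid, grp in fix_df.groupby("participant", sort=False):
        grp = grp.sort_values("t_on_ms", kind="stable")
        ids, starts, ends = _parse_windows(grp, pid)
        rows.extend({"participant": pid, "trial": tid, "t_start_ms": s,
                     "t_end_ms": e} for tid, s, e in zip(ids, starts, ends))
    return pd.DataFrame(rows, columns=["participant", "trial", "t_start_ms",
                                       "t_end_ms"])


def segment_trials(fix_df: pd.DataFrame) -> pd.DataFrame:
    """Assign fixations to trials delimited by TRIALID / TRIAL_RESULT.

    Returns only fixation rows (``msg == "FIX"``) whose *onset* falls inside
    a trial window, with ``trial``, ``trial_onset_ms`` and ``duration_ms``
    columns added; fixations outside any trial are discarded. Raises
    :class:`MalformedRecordingError` if any TRIALID lacks a matching
    TRIAL_RESULT (or vice versa), naming the offending trial.
    """
    out = []
    for pid, grp in fix_df.groupby("participant", sort=False):
        grp = grp.sort_values("t_on_ms", kind="stable")
        trial_ids, starts, ends = _parse_windows(grp, pid)
        fixes = grp[grp["msg"] == "FIX"].copy()
        if not len(starts):
            continue
        starts_a = np.asarray(starts)
        ends_a = np.asarray(ends)
        order = np.argsort(starts_a, kind="stable")
        starts_a, ends_a = starts_a[order], ends_a[order]
        ids_a = np.asarray(trial_ids)[order]
        idx = np.searchsorted(starts_a, fixes["t_on_ms"].to_numpy(), side="right") - 1
        inside = (idx >= 0) & (fixes["t_on_ms"].to_numpy() > starts_a[idx.clip(0)]) & (
            fixes["t_on_ms"].to_numpy() < ends_a[idx.clip(0)])
        fixes = fixes[inside]
        fixes["trial"] = ids_a[idx[inside]]
        fixes["trial_onset_ms"] = starts_a[idx[inside]]
        out.append(fixes)
    if not out:
        return fix_df.iloc[0:0].assign(trial=pd.Series(dtype=int),
                                       trial_onset_ms=pd.Series(dtype=float),
                                       duration_ms=pd.Series(dtype=float))
    res = pd.concat(out, ignore_index=True)
    res["duration_ms"] = res["t_off_ms"] - res["t_on_ms"]
    return res


def select_eye(fix_df: pd.DataFrame, priority: tuple[str, ...] = ("R", "L")
               ) -> pd.DataFrame:
    """Keep exactly one eye per participant, chosen by a fixed priority rule.

    The priority is applied at the participant level (right eye first, per
    the recording default); trials recorded only with the other eye are
    dropped for that participant.
    """
    kept = []
    for pid, grp in fix_df.groupby("participant", sort=False):
        present = set(grp["eye"].unique())
        eye = next((e for e in priority if e in present), None)
        if eye is None:
            raise ParticipantDataError(f"{pid}: no events for any eye in {priority}")
        kept.append(grp[grp["eye"] == eye])
    return pd.concat(kept, ignore_index=True)


def filter_short_fixations(fix_df: pd.DataFrame, min_dur: float = 60.0
                           ) -> pd.DataFrame:
    """Drop fixations strictly shorter than ``min_dur`` ms; order preserved."""
    if "duration_ms" not in fix_df.columns:
        fix_df = fix_df.assign(duration_ms=fix_df["t_off_ms"] - fix_df["t_on_ms"])
    return fix_df[fix_df["duration_ms"] >= min_dur].reset_index(drop=True)


def map_to_stimulus_space(fix_df: pd.DataFrame, screen: tuple[int, int],
                          stim: tuple[int, int]) -> pd.DataFrame:
    """Map screen coordinates to stimulus space (centered, unscaled).

    Adds ``x_stim``/``y_stim`` and an ``on_stimulus`` flag for coordinates
    inside ``[0, stim_w) x [0, stim_h)``.
    """
    (sw, sh), (tw, th) = screen, stim
    if tw > sw or th > sh:
        raise AOIConfigError("stimulus dimensions exceed screen dimensions")
    offx, offy = (sw - tw) / 2.0, (sh - th) / 2.0
    out = fix_df.copy()
    out["x_stim"] = out["x_px"] - offx
    out["y_stim"] = out["y_px"] - offy
    out["on_stimulus"] = ((out["x_stim"] >= 0) & (out["x_stim"] < tw) &
                          (out["y_stim"] >= 0) & (out["y_stim"] < th))
    return out


def _check_disjoint(aois: pd.DataFrame) -> None:
    for trial, grp in aois.groupby("trial"):
        rects = grp[["xmin", "xmax", "ymin", "ymax"]].to_numpy(dtype=float)
        labels = grp["label"].tolist()
        if sorted(labels) != sorted(CONDITIONS):
            raise AOIConfigError(
                f"trial {trial}: AOI labels {labels} != {list(CONDITIONS)}")
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                a, b = rects[i], rects[j]
                if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                    raise AOIConfigError(
                        f"trial {trial}: AOIs {labels[i]} and {labels[j]} overlap")


def assign_aoi(fix_df: pd.DataFrame, aois: pd.DataFrame) -> pd.DataFrame:
    """Label each fixation with its containing AOI (half-open rects) or "none".

    Containment is evaluated in stimulus space; overlapping rectangles raise
    :class:`AOIConfigError` rather than being tie-broken silently.
    """
    _check_disjoint(aois)
    out = fix_df.copy()
    out["_row"] = np.arange(len(out))
    merged = out.merge(aois, on="trial", how="left")
    hit = ((merged["x_stim"] >= merged["xmin"]) & (merged["x_stim"] < merged["xmax"]) &
           (merged["y_stim"] >= merged["ymin"]) & (merged["y_stim"] < merged["ymax"]))
    hits = merged[hit].set_index("_row")["label"]
    out["aoi"] = out["_row"].map(hits).fillna("none")
    return out.drop(columns="_row")


def qc_trials(fix_df: pd.DataFrame, threshold: float = 0.50,
              trials: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-trial quality control on the fraction of on-stimulus gaze.

    A trial passes iff both the proportion of fixations and the proportion
    of total fixation time landing on the stimulus are >= ``threshold``
    (inclusive). Trials with zero fixations fail; pass ``trials`` (a frame
    with participant/trial rows, e.g. from :func:`trial_windows`) to report
    demarcated trials that retained no fixations at all.
    """
    tmp = fix_df.assign(
        _on=fix_df["on_stimulus"].astype(float),
        _t_on=fix_df["duration_ms"] * fix_df["on_stimulus"])
    agg = tmp.groupby(["participant", "trial"], sort=False).agg(
        n_fix=("_on", "size"), _on_sum=("_on", "sum"),
        _t_on=("_t_on", "sum"), _t_all=("duration_ms", "sum")).reset_index()
    rep = agg.assign(
        frac_fix=np.where(agg["n_fix"] > 0, agg["_on_sum"] / agg["n_fix"], 0.0),
        frac_time=np.where(agg["_t_all"] > 0, agg["_t_on"] / agg["_t_all"], 0.0),
    ).drop(columns=["_on_sum", "_t_on", "_t_all"])
    if trials is not None:
        rep = trials[["participant", "trial"]].drop_duplicates().merge(
            rep, on=["participant", "trial"], how="left")
        rep[["n_fix", "frac_fix", "frac_time"]] = rep[
            ["n_fix", "frac_fix", "frac_time"]].fillna(0.0)
        rep["n_fix"] = rep["n_fix"].astype(int)
    rep["qc_pass"] = (rep["frac_fix"] >= threshold) & (rep["frac_time"] >= threshold)
    return rep


def preprocess(fix_df: pd.DataFrame, trials_df: pd.DataFrame, aois: pd.DataFrame,
               screen: tuple[int, int], stim: tuple[int, int],
               min_dur: float = 60.0, qc_threshold: float = 0.50,
               qc_before_filter: bool = False,
               eye_priority: tuple[str, ...] = ("R", "L")
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full ingest chain: segment, select eye, filter, map, assign, QC.

    Returns ``(fixations, qc_report)`` where ``fixations`` carries trial,
    condition, AOI label, stimulus coordinates and QC verdict per fixation,
    restricted to retrieval-phase trials present in ``trials_df``.
    """
    windows = trial_windows(fix_df)[["participant", "trial"]]
    seg = segment_trials(fix_df)
    seg = select_eye(seg, eye_priority)
    if qc_before_filter:
        mapped = map_to_stimulus_space(seg, screen, stim)
        qc = qc_trials(mapped, qc_threshold, trials=windows)
        seg = filter_short_fixations(seg, min_dur)
    else:
        seg = filter_short_fixations(seg, min_dur)
        mapped = map_to_stimulus_space(seg, screen, stim)
        qc = qc_trials(mapped, qc_threshold, trials=windows)
    mapped = map_to_stimulus_space(seg, screen, stim)
    labeled = assign_aoi(mapped, aois)

    meta_cols = ["participant", "trial", "condition", "age_group", "cue_status",
                 "cue_resp", "choice", "group_id"]
    meta = trials_df[trials_df["phase"] == "retrieval"][meta_cols]
    labeled = labeled.merge(meta, on=["participant", "trial"], how="inner")
    labeled["target"] = labeled["condition"]
    labeled = labeled.merge(qc[["participant", "trial", "qc_pass"]],
                            on=["participant", "trial"], how="left")
    qc = qc.merge(meta[["participant", "trial", "condition"]],
                  on=["participant", "trial"], how="left")
    return labeled, qc
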