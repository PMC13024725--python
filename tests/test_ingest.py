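"""Ingest rules on constructed fixation streams: segmentation boundaries,
eye priority, the 60 ms filter, coordinate mapping, half-open AOI
containment and the >= 0.50 quality-control rule."""

import numpy as np
import pandas as pd
import pytest

from gazemem import ingest
from gazemem.ingest import (AOIConfigError, MalformedRecordingError,
                            ParticipantDataError, assign_aoi,
                            filter_short_fixations, map_to_stimulus_space,
                            qc_trials, segment_trials, select_eye,
                            trial_windows)


def _stream(fix_builder):
    rows = [("TRIALID 1", 0, 0, np.nan, np.nan)]
    rows += [("FIX", 100 + 200 * i, 250 + 200 * i, 50, 50) for i in range(5)]
    rows += [("TRIAL_RESULT 1", 1200, 1200, np.nan, np.nan),
             ("TRIALID 2", 2000, 2000, np.nan, np.nan)]
    rows += [("FIX", 2100 + 200 * i, 2250 + 200 * i, 60, 60) for i in range(5)]
    rows += [("TRIAL_RESULT 2", 3200, 3200, np.nan, np.nan)]
    return fix_builder(rows)


def test_segmentation_counts_and_onsets(fix_builder):
    seg = segment_trials(_stream(fix_builder))
    assert seg.groupby("trial").size().to_dict() == {1: 5, 2: 5}
    assert set(seg["trial_onset_ms"]) == {0.0, 2000.0}


def test_straddling_fixation_assigned_by_onset(fix_builder):
    # Onset before TRIAL_RESULT, offset after: belongs to the trial.
    df = fix_builder([("TRIALID 7", 0, 0, np.nan, np.nan),
                      ("FIX", 100, 300, 10, 10),
                      ("FIX", 450, 900, 10, 10),  # straddles the end marker
                      ("TRIAL_RESULT 7", 500, 500, np.nan, np.nan),
                      ("FIX", 600, 700, 10, 10)])  # outside any trial
    seg = segment_trials(df)
    assert list(seg["t_on_ms"]) == [100.0, 450.0]
    assert (seg["trial"] == 7).all()


def test_empty_trial_fails_qc(fix_builder):
    df = fix_builder([("TRIALID 3", 0, 0, np.nan, np.nan),
                      ("TRIAL_RESULT 3", 500, 500, np.nan, np.nan)])
    windows = trial_windows(df)
    seg = segment_trials(df)
    assert len(seg) == 0
    mapped = seg.assign(duration_ms=[], on_stimulus=[])
    qc = qc_trials(mapped, trials=windows)
    assert len(qc) == 1 and not qc["qc_pass"].iloc[0]


def test_unmatched_markers_raise(fix_builder):
    df = fix_builder([("TRIALID 5", 0, 0, np.nan, np.nan),
                      ("FIX", 100, 200, 1, 1)])
    with pytest.raises(MalformedRecordingError, match="5"):
        segment_trials(df)
    df2 = fix_builder([("TRIAL_RESULT 9", 50, 50, np.nan, np.nan)])
    with pytest.raises(MalformedRecordingError, match="9"):
        segment_trials(df2)


def test_eye_priority(fix_builder):
    df = _stream(fix_builder)
    both = pd.concat([df, df.assign(eye="L")], ignore_index=True)
    assert set(select_eye(both)["eye"]) == {"R"}
    only_l = df.assign(eye="L")
    assert set(select_eye(only_l)["eye"]) == {"L"}
    with pytest.raises(ParticipantDataError):
        select_eye(df.assign(eye="X"))


def test_eye_priority_applied_at_participant_level(fix_builder):
    # Trial 1 recorded with both eyes, trial 2 only with L: the participant
    # is analyzed with R, so trial 2's fixations drop.
    df = segment_trials(_stream(fix_builder))
    df.loc[df["trial"] == 2, "eye"] = "L"
    extra_l = df[df["trial"] == 1].assign(eye="L")
    mixed = pd.concat([df, extra_l], ignore_index=True)
    out = select_eye(mixed)
    assert set(out["eye"]) == {"R"}
    assert set(out["trial"]) == {1}
    assert len(out) == 5


@pytest.mark.parametrize("durations,expected", [
    ([59, 60, 200], [60, 200]),
    ([60, 61, 1000], [60, 61, 1000]),   # all at/above threshold: identity
    ([10, 59.9], []),                    # everything removed
])
def test_short_fixation_filter(fix_builder, durations, expected):
    rows = [("FIX", 1000 * i, 1000 * i + d, 0, 0)
            for i, d in enumerate(durations)]
    out = filter_short_fixations(fix_builder(rows))
    assert list(out["duration_ms"]) == expected


def test_coordinate_mapping(fix_builder):
    df = fix_builder([("FIX", 0, 100, 960, 540)])
    out = map_to_stimulus_space(df, (1920, 1080), (1720, 880))
    assert (out["x_stim"].iloc[0], out["y_stim"].iloc[0]) == (860.0, 440.0)
    assert out["on_stimulus"].iloc[0]
    ident = map_to_stimulus_space(fix_builder([("FIX", 0, 100, 100, 100)]),
                                  (1920, 1080), (1920, 1080))
    assert (ident["x_stim"].iloc[0], ident["y_stim"].iloc[0]) == (100.0, 100.0)
    off = map_to_stimulus_space(fix_builder([("FIX", 0, 100, 99, 100)]),
                                (1920, 1080), (1720, 880))
    assert off["x_stim"].iloc[0] == -1.0 and not off["on_stimulus"].iloc[0]


def _aois():
    return pd.DataFrame([
        {"trial": 1, "label": "NR", "xmin": 0, "xmax": 100, "ymin": 0, "ymax": 100},
        {"trial": 1, "label": "RR", "xmin": 200, "xmax": 300, "ymin": 0, "ymax": 100},
        {"trial": 1, "label": "UR", "xmin": 400, "xmax": 500, "ymin": 0, "ymax": 100},
    ])


def _mapped(fix_builder, points):
    rows = [("FIX", 100 * i, 100 * i + 80, x, y) for i, (x, y) in enumerate(points)]
    df = fix_builder(rows).assign(trial=1)
    df["x_stim"] = df["x_px"]
    df["y_stim"] = df["y_px"]
    return df


def test_aoi_assignment_half_open(fix_builder):
    pts = [(50, 50),     # inside NR
           (100, 50),    # at NR xmax -> half-open -> none
           (150, 50),    # between rects, on stimulus -> none
           (200, 0)]     # RR corner (closed-left) -> RR
    out = assign_aoi(_mapped(fix_builder, pts), _aois())
    assert list(out["aoi"]) == ["NR", "none", "none", "RR"]


def test_overlapping_aois_rejected(fix_builder):
    bad = _aois()
    bad.loc[1, "xmin"] = 50  # RR now overlaps NR
    with pytest.raises(AOIConfigError):
        assign_aoi(_mapped(fix_builder, [(10, 10)]), bad)
    mislabeled = _aois()
    mislabeled.loc[2, "label"] = "RR"
    with pytest.raises(AOIConfigError):
        assign_aoi(_mapped(fix_builder, [(10, 10)]), mislabeled)


def test_qc_verdicts(fix_builder):
    # 4 fixations: three 100 ms on-stimulus, one 700 ms off-stimulus.
    # frac_fix = 0.75 passes but frac_time = 0.3 fails.
    df = fix_builder([("FIX", 0, 100, 1, 1), ("FIX", 200, 300, 1, 1),
                      ("FIX", 400, 500, 1, 1), ("FIX", 600, 1300, -5, 1)])
    df = df.assign(trial=1, duration_ms=df["t_off_ms"] - df["t_on_ms"],
                   on_stimulus=[True, True, True, False])
    rep = qc_trials(df)
    assert rep["frac_fix"].iloc[0] == 0.75
    assert rep["frac_time"].iloc[0] == pytest.approx(0.3)
    assert not rep["qc_pass"].iloc[0]
    # Exactly 0.50 on both criteria is retained (inclusive rule).
    df2 = fix_builder([("FIX", 0, 100, 1, 1), ("FIX", 200, 300, -5, 1)])
    df2 = df2.assign(trial=1, duration_ms=[100.0, 100.0],
                     on_stimulus=[True, False])
    assert qc_trials(df2)["qc_pass"].iloc[0]
    # All on stimulus passes trivially.
    df3 = df2.assign(on_stimulus=[True, True])
    assert qc_trials(df3)["qc_pass"].iloc[0]


def test_pipeline_stages_idempotent(clean_study):
    cfg = clean_study.config
    seg = segment_trials(clean_study.fixations)
    seg = select_eye(seg)
    filt = filter_short_fixations(seg)
    again = filter_short_fixations(filt)
    pd.testing.assert_frame_equal(filt, again)
    mapped = map_to_stimulus_space(filt, (cfg.screen_w, cfg.screen_h),
                                   (cfg.stim_w, cfg.stim_h))
    remapped = map_to_stimulus_space(
        mapped.drop(columns=["x_stim", "y_stim", "on_stimulus"]),
        (cfg.screen_w, cfg.screen_h), (cfg.stim_w, cfg.stim_h))
    pd.testing.assert_frame_equal(mapped, remapped)
    lab = assign_aoi(mapped, clean_study.aois)
    relab = assign_aoi(lab.drop(columns="aoi"), clean_study.aois)
    pd.testing.assert_frame_equal(lab, relab)


def test_fixation_count_conservation(small_study):
    """Input fixations = assigned + short-dropped + outside-trial."""
    fix = small_study.fixations
    n_input = int((fix["msg"] == "FIX").sum())
    seg = segment_trials(fix)
    n_outside = n_input - len(seg)
    filt = filter_short_fixations(seg)
    n_short = len(seg) - len(filt)
    assert n_input == len(filt) + n_short + n_outside
    assert n_outside == 0  # the generator emits fixations only inside trials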