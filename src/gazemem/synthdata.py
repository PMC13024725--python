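"""Synthetic study generator for a 3AFC restructured-object memory experiment.

Emulates the trial structure of a two-group (young/older adults) retrieval
experiment with three object conditions — NR (non-restructured,
schema-consistent), RR (reasonably restructured) and UR (unreasonably
restructured) — in which each old-cue trial ends with a three-alternative
forced choice among the NR/RR/UR variants of one stimulus triad while gaze
is recorded.

The generator produces three artifacts per study:

* a behavioral trial table (one row per retrieval trial),
* a fixation-event stream with ``TRIALID n`` / ``TRIAL_RESULT n``
  demarcation messages, mimicking an EyeLink fixation report, and
* per-trial AOI rectangles in stimulus-pixel space.

The gaze–choice coupling parameter ``kappa`` controls how strongly each
trial's fixation-time allocation concentrates on the AOI of the object the
participant is about to choose; it is the generative counterpart of the
eye–memory representational similarity the analysis measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

CONDITIONS = ("NR", "RR", "UR")
AGE_GROUPS = ("YA", "OA")

TRIALS_SCHEMA = "gazemem/trials-v1"
FIXATIONS_SCHEMA = "gazemem/fixations-v1"
AOI_SCHEMA = "gazemem/aoi-v1"


class ConfigurationError(ValueError):
    """Raised when a study configuration is internally inconsistent."""


@dataclass(frozen=True)
class StudyConfig:
    """Sizes and geometry of one simulated study.

    ``n_groups`` is the number of stimulus triads; every old cue comes from
    one triad and each triad is studied once, so ``3 * trials_per_condition``
    old trials are drawn from ``n_groups`` triads. ``n_new_cues`` unstudied
    foil cues are mixed into retrieval (the real study does not report this
    count; it is a free parameter here).
    """

    n_young: int = 26
    n_older: int = 29
    n_groups: int = 60
    trials_per_condition: int = 20
    n_new_cues: int = 30
    screen_w: int = 1920
    screen_h: int = 1080
    stim_w: int = 1720
    stim_h: int = 880
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_young", "n_older", "n_groups", "trials_per_condition"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_new_cues < 0:
            raise ConfigurationError("n_new_cues must be >= 0")
        if self.stim_w > self.screen_w or self.stim_h > self.screen_h:
            raise ConfigurationError("stimulus must fit on the screen")
        if 3 * self.trials_per_condition > 3 * self.n_groups:
            raise ConfigurationError("not enough stimulus triads for the trial count")

    @property
    def n_old_trials(self) -> int:
        return 3 * self.trials_per_condition

    @property
    def n_trials(self) -> int:
        return self.n_old_trials + self.n_new_cues


@dataclass(frozen=True)
class CellChoice:
    """Choice/judgment probabilities for one (age group, condition) cell.

    ``p_target`` is the probability of picking the studied object on a
    selection trial; ``p_schema_consistent`` of picking the NR lure (for NR
    targets: the RR lure); ``p_schema_inconsistent`` of picking the remaining
    restructured lure. The three must sum to 1. ``p_cue_hit``/``p_cue_fa``
    drive the old/new cue judgment.
    """

    p_target: float
    p_schema_consistent: float
    p_schema_inconsistent: float
    p_cue_hit: float
    p_cue_fa: float

    def __post_init__(self) -> None:
        probs = (self.p_target, self.p_schema_consistent, self.p_schema_inconsistent,
                 self.p_cue_hit, self.p_cue_fa)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("choice probabilities must lie in [0, 1]")
        total = self.p_target + self.p_schema_consistent + self.p_schema_inconsistent
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(
                f"choice probabilities must sum to 1 (got {total!r})")

    def chosen_label_probs(self, condition: str) -> dict[str, float]:
        """Map the cell probabilities onto chosen-category labels."""
        if condition == "NR":
            # No schema-consistent lure exists for an NR target; the two
            # error probabilities fall on the RR and UR lures respectively.
            return {"NR": self.p_target, "RR": self.p_schema_consistent,
                    "UR": self.p_schema_inconsistent}
        other = "UR" if condition == "RR" else "RR"
        return {condition: self.p_target, "NR": self.p_schema_consistent,
                other: self.p_schema_inconsistent}


@dataclass(frozen=True)
class CellGaze:
    """Gaze-stream parameters for one (age group, condition) cell.

    Units are ms and probabilities. ``kappa`` is the gaze–choice coupling:
    the per-trial AOI allocation is Dirichlet(1 + kappa on the to-be-chosen
    AOI), and per-fixation duration means scale with the allocation, so
    kappa = 0 decouples gaze from choice entirely. ``early_bias`` is the
    probability that the first AOI-landing fixation falls on the to-be-chosen
    AOI. ``p_offstim`` is the per-fixation probability of landing outside
    the stimulus area.
    """

    latency_mean: float = 600.0
    latency_sd: float = 250.0
    dwell_mean: float = 300.0
    dwell_sd: float = 60.0
    min_fix_dur: float = 60.0
    kappa: float = 1.0
    early_bias: float = 0.5
    p_offstim: float = 0.05
    n_fix_mean: float = 8.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ConfigurationError("kappa must be >= 0")
        if not 0.0 <= self.early_bias <= 1.0 or not 0.0 <= self.p_offstim <= 1.0:
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.dwell_mean <= self.min_fix_dur:
            raise ConfigurationError("dwell_mean must exceed min_fix_dur")
        if self.n_fix_mean < 1.0:
            raise ConfigurationError("n_fix_mean must be >= 1")


@dataclass(frozen=True)
class ChoiceModel:
    cells: dict[tuple[str, str], CellChoice]

    def cell(self, age_group: str, condition: str) -> CellChoice:
        return self.cells[(age_group, condition)]

    @classmethod
    def reference(cls) -> "ChoiceModel":
        """Presets built from the study's reported choice proportions.

        True-memory / schema-consistent / schema-inconsistent splits follow
        the published group descriptives (e.g. older adults in RR:
        0.84 / 0.14 / 0.02). Cue hit/false-alarm rates are free parameters
        chosen to give realistic d' of ~2.9 (young) and ~1.9 (older).
        """
        ya = {"NR": (0.99, 0.005, 0.005), "RR": (0.96, 0.04, 0.0),
              "UR": (0.92, 0.07, 0.01)}
        oa = {"NR": (0.91, 0.045, 0.045), "RR": (0.84, 0.14, 0.02),
              "UR": (0.76, 0.16, 0.08)}
        cue = {"YA": (0.95, 0.10), "OA": (0.88, 0.25)}
        cells = {}
        for grp, table in (("YA", ya), ("OA", oa)):
            hit, fa = cue[grp]
            for cond, (pt, pc, pi) in table.items():
                cells[(grp, cond)] = CellChoice(pt, pc, pi, hit, fa)
        return cls(cells)

    @classmethod
    def uniform(cls, p_cue_hit: float = 0.9, p_cue_fa: float = 0.1) -> "ChoiceModel":
        third = 1.0 / 3.0
        return cls({(g, c): CellChoice(third, third, 1 - 2 * third, p_cue_hit, p_cue_fa)
                    for g in AGE_GROUPS for c in CONDITIONS})

    @classmethod
    def deterministic(cls, p_cue_hit: float = 1.0, p_cue_fa: float = 0.0) -> "ChoiceModel":
        return cls({(g, c): CellChoice(1.0, 0.0, 0.0, p_cue_hit, p_cue_fa)
                    for g in AGE_GROUPS for c in CONDITIONS})


@dataclass(frozen=True)
class GazeModel:
    cells: dict[tuple[str, str], CellGaze]

    def cell(self, age_group: str, condition: str) -> CellGaze:
        return self.cells[(age_group, condition)]

    @classmethod
    def reference(cls, kappa_young: float = 3.0, kappa_older: float = 0.5,
                  p_offstim: float = 0.05) -> "GazeModel":
        """Presets anchored to the study's reported gaze descriptives.

        First-fixation latency and mean-fixation-duration means/SDs follow
        the published group x condition values; ``early_bias`` follows the
        published early-target-viewing proportions. The default coupling
        contrast (kappa 3.0 vs 0.5) encodes the study's central finding that
        gaze sampling tracks retrieval choices more tightly in young adults.
        """
        lat = {("YA", "NR"): (567.0, 276.0), ("YA", "RR"): (336.0, 112.0),
               ("YA", "UR"): (774.0, 128.0), ("OA", "NR"): (892.0, 335.0),
               ("OA", "RR"): (660.0, 333.0), ("OA", "UR"): (1387.0, 325.0)}
        dur = {("YA", "NR"): (303.0, 52.0), ("YA", "RR"): (306.0, 66.0),
               ("YA", "UR"): (389.0, 82.0), ("OA", "NR"): (293.0, 54.0),
               ("OA", "RR"): (279.0, 43.0), ("OA", "UR"): (301.0, 69.0)}
        early = {("YA", "NR"): 0.43, ("YA", "RR"): 0.66, ("YA", "UR"): 0.48,
                 ("OA", "NR"): 0.45, ("OA", "RR"): 0.56, ("OA", "UR"): 0.25}
        cells = {}
        for key in lat:
            grp = key[0]
            kappa = kappa_young if grp == "YA" else kappa_older
            cells[key] = CellGaze(latency_mean=lat[key][0], latency_sd=lat[key][1],
                                  dwell_mean=dur[key][0], dwell_sd=dur[key][1],
                                  kappa=kappa, early_bias=early[key],
                                  p_offstim=p_offstim)
        return cls(cells)

    @classmethod
    def constant(cls, **kwargs) -> "GazeModel":
        cell = CellGaze(**kwargs)
        return cls({(g, c): cell for g in AGE_GROUPS for c in CONDITIONS})

    def with_kappa(self, kappa_young: float, kappa_older: float) -> "GazeModel":
        cells = {k: replace(v, kappa=kappa_young if k[0] == "YA" else kappa_older)
                 for k, v in self.cells.items()}
        return GazeModel(cells)


@dataclass
class Study:
    """One simulated study: trial table, fixation stream and AOI layout."""

    trials: pd.DataFrame
    fixations: pd.DataFrame
    aois: pd.DataFrame
    config: StudyConfig


def aoi_layout(config: StudyConfig, n_trials: int | None = None) -> pd.DataFrame:
    """Per-trial AOI rectangles (stimulus-pixel space), counterbalanced.

    Three equal slots span the stimulus horizontally; the assignment of
    NR/RR/UR labels to slots is a seeded permutation per trial number,
    shared by all participants, so label position is counterbalanced across
    trials but identical layouts can be reconstructed from the seed.
    """
    if n_trials is None:
        n_trials = config.n_trials
    sw = config.stim_w // 5
    sh = config.stim_h // 2
    y0 = config.stim_h // 4
    xcenters = [round(config.stim_w * (2 * k + 1) / 6) for k in range(3)]
    rng = np.random.default_rng([config.seed, 982451653])
    rows = []
    for trial in range(1, n_trials + 1):
        perm = rng.permutation(3)
        for slot, lab_idx in enumerate(perm):
            x0 = xcenters[slot] - sw // 2
            rows.append({"trial": trial, "label": CONDITIONS[lab_idx],
                         "xmin": x0, "xmax": x0 + sw,
                         "ymin": y0, "ymax": y0 + sh})
    return pd.DataFrame(rows)


def simulate_choices(rng: np.random.Generator, cell: CellChoice, condition: str,
                     n: int) -> np.ndarray:
    """Draw ``n`` 3AFC chosen-category labels for one condition cell."""
    probs = cell.chosen_label_probs(condition)
    labels = np.array(list(probs))
    p = np.array([probs[l] for l in labels])
    return labels[rng.choice(3, size=n, p=p)]


def _lognormal_ms(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Lognormal draws parameterized by the target mean and SD in ms."""
    var = sd * sd
    sigma2 = np.log(1.0 + var / (mean * mean))
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _truncnorm_ms(rng: np.random.Generator, mean: np.ndarray, sd: float,
                  lower: float) -> np.ndarray:
    """Normal draws truncated below at ``lower`` via inverse-CDF sampling."""
    from scipy.special import ndtr
    a = ndtr((lower - mean) / sd)
    u = rng.uniform(a, 1.0)
    return mean + sd * ndtri(np.clip(u, 1e-12, 1 - 1e-12))


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    # One child stream per participant: adding participants never perturbs
    # previously generated ones.
    return np.random.default_rng([seed, index])


def generate_study(config: StudyConfig, choice: ChoiceModel | None = None,
                   gaze: GazeModel | None = None) -> Study:
    """Simulate a complete retrieval-phase study.

    Returns the behavioral trial table, the fixation stream (with TRIALID /
    TRIAL_RESULT messages; gaze is emitted only for trials that reach the
    object-selection display) and the AOI layout.
    """
    choice = choice or ChoiceModel.reference()
    gaze = gaze or GazeModel.reference()
    if any(cell.p_offstim > 0 for cell in gaze.cells.values()) and (
            config.stim_w == config.screen_w and config.stim_h == config.screen_h):
        raise ConfigurationError(
            "p_offstim > 0 requires the stimulus to be smaller than the screen")

    aois = aoi_layout(config)
    offx = (config.screen_w - config.stim_w) // 2
    offy = (config.screen_h - config.stim_h) // 2
    # Screen-space AOI rects indexed by (trial, label) for fast lookup.
    rect_lookup: dict[tuple[int, str], tuple[float, float, float, float]] = {}
    for row in aois.itertuples(index=False):
        rect_lookup[(row.trial, row.label)] = (
            row.xmin + offx, row.xmax + offx, row.ymin + offy, row.ymax + offy)

    trial_frames: list[pd.DataFrame] = []
    fix_frames: list[pd.DataFrame] = []
    # Stream indices are cohort-fixed (OA offset by a constant) so growing
    # either cohort never perturbs already-generated participants.
    participants = ([("YA", f"YA{i + 1:03d}", i) for i in range(config.n_young)] +
                    [("OA", f"OA{i + 1:03d}", 1_000_000 + i)
                     for i in range(config.n_older)])

    for age_group, pid, pidx in participants:
        rng = _participant_rng(config.seed, pidx)
        trials = _participant_trials(rng, config, choice, age_group, pid)
        trial_frames.append(trials)
        fix_frames.append(_participant_fixations(
            rng, config, gaze, age_group, pid, trials, rect_lookup, offx, offy))

    trials_df = pd.concat(trial_frames, ignore_index=True)
    fix_df = pd.concat(fix_frames, ignore_index=True)
    return Study(trials=trials_df, fixations=fix_df, aois=aois, config=config)


def _participant_trials(rng: np.random.Generator, config: StudyConfig,
                        choice: ChoiceModel, age_group: str, pid: str) -> pd.DataFrame:
    tpc = config.trials_per_condition
    # Conditions are assigned uniformly at random per triad; only the first
    # 3*tpc of the shuffled triads are studied.
    triads = rng.permutation(config.n_groups)[:3 * tpc] + 1
    conds = np.repeat(CONDITIONS, tpc)
    old_groups = triads
    new_groups = config.n_groups + np.arange(config.n_new_cues) + 1
    # New cues carry a nominal condition label (they feed only the shared
    # false-alarm pool of the per-condition d' analysis).
    new_conds = np.asarray(CONDITIONS)[rng.integers(0, 3, size=config.n_new_cues)]

    group_id = np.concatenate([old_groups, new_groups])
    condition = np.concatenate([conds, new_conds])
    cue_status = np.array(["old"] * len(old_groups) + ["new"] * len(new_groups))
    order = rng.permutation(len(group_id))
    group_id, condition, cue_status = group_id[order], condition[order], cue_status[order]

    n = len(group_id)
    p_yes = np.empty(n)
    for cond in CONDITIONS:
        cell = choice.cell(age_group, cond)
        mask = condition == cond
        p_yes[mask & (cue_status == "old")] = cell.p_cue_hit
        p_yes[mask & (cue_status == "new")] = cell.p_cue_fa
    cue_resp = np.where(rng.random(n) < p_yes, "old", "new")

    chosen = np.full(n, "none", dtype=object)
    sel = (cue_status == "old") & (cue_resp == "old")
    for cond in CONDITIONS:
        mask = sel & (condition == cond)
        if mask.any():
            chosen[mask] = simulate_choices(rng, choice.cell(age_group, cond),
                                            cond, int(mask.sum()))

    rt_scale = 1.2 if age_group == "YA" else 2.4
    cue_rt = rng.lognormal(np.log(rt_scale), 0.35, size=n)
    obj_rt = np.where(sel, rng.lognormal(np.log(1.5 * rt_scale), 0.35, size=n), np.nan)

    return pd.DataFrame({
        "participant": pid, "age_group": age_group, "phase": "retrieval",
        "trial": np.arange(1, n + 1), "group_id": group_id,
        "condition": condition, "cue_status": cue_status, "cue_resp": cue_resp,
        "choice": chosen, "cue_rt_s": np.round(cue_rt, 3),
        "obj_rt_s": np.round(obj_rt, 3),
    })


def _participant_fixations(rng: np.random.Generator, config: StudyConfig,
                           gaze: GazeModel, age_group: str, pid: str,
                           trials: pd.DataFrame, rect_lookup, offx: int,
                           offy: int) -> pd.DataFrame:
    msgs: list[str] = []
    t_on: list[float] = []
    t_off: list[float] = []
    xs: list[float] = []
    ys: list[float] = []

    clock = 0.0
    sel = trials[trials["choice"] != "none"]
    sel_rows = {int(r.trial): r for r in sel.itertuples(index=False)}

    for trial_no in trials["trial"]:
        trial_no = int(trial_no)
        row = sel_rows.get(trial_no)
        if row is None:
            continue  # no selection display -> no gaze stream for this trial
        cell = gaze.cell(age_group, row.condition)
        t0 = clock
        msgs.append(f"TRIALID {trial_no}")
        t_on.append(t0)
        t_off.append(t0)
        xs.append(np.nan)
        ys.append(np.nan)

        n_fix = 1 + rng.poisson(max(cell.n_fix_mean - 1.0, 0.0))
        # Per-trial AOI allocation, concentrated on the to-be-chosen AOI.
        alpha = np.ones(3)
        alpha[CONDITIONS.index(row.choice)] += cell.kappa
        g = rng.gamma(alpha)
        w = g / g.sum()

        offstim = rng.random(n_fix) < cell.p_offstim
        labels = np.asarray(CONDITIONS)[
            np.searchsorted(np.cumsum(w), rng.random(n_fix)).clip(0, 2)]
        on_idx = np.flatnonzero(~offstim)
        if on_idx.size:
            first = on_idx[0]
            if rng.random() < cell.early_bias:
                labels[first] = row.choice
            else:
                others = [c for c in CONDITIONS if c != row.choice]
                labels[first] = others[int(rng.integers(0, 2))]

        dur_mean = cell.dwell_mean * 3.0 * w[
            [CONDITIONS.index(l) for l in labels]]
        durs = np.round(_truncnorm_ms(rng, dur_mean, cell.dwell_sd,
                                      cell.min_fix_dur))
        durs = np.maximum(durs, cell.min_fix_dur)

        latency = float(_lognormal_ms(rng, cell.latency_mean, cell.latency_sd, 1)[0])
        starts = np.round(t0 + latency + np.concatenate(
            [[0.0], np.cumsum(durs[:-1] + 30.0)]))  # ~30 ms saccade gaps
        for i in range(n_fix):
            if offstim[i]:
                # Land in the horizontal (or vertical) off-stimulus margin.
                if offx > 0:
                    x = rng.uniform(0, offx)
                    y = rng.uniform(0, config.screen_h)
                else:
                    x = rng.uniform(0, config.screen_w)
                    y = rng.uniform(0, offy)
            else:
                x0, x1, y0, y1 = rect_lookup[(trial_no, labels[i])]
                x = rng.uniform(x0, x1)
                y = rng.uniform(y0, y1)
            msgs.append("FIX")
            t_on.append(float(starts[i]))
            t_off.append(float(starts[i] + durs[i]))
            xs.append(round(x, 1))
            ys.append(round(y, 1))

        t_end = t_off[-1] + 100.0
        msgs.append(f"TRIAL_RESULT {trial_no}")
        t_on.append(t_end)
        t_off.append(t_end)
        xs.append(np.nan)
        ys.append(np.nan)
        clock = t_end + 500.0

    return pd.DataFrame({
        "participant": pid, "msg": msgs, "eye": "R",
        "t_on_ms": np.asarray(t_on, dtype=float),
        "t_off_ms": np.asarray(t_off, dtype=float),
        "x_px": xs, "y_px": ys,
    })


def write_fixture_bundle(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Write the trial CSV, fixation TSV and AOI JSON; byte-stable per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"trials": out / "trials.csv", "fixations": out / "fixations.tsv",
             "aois": out / "aois.json"}
    with open(paths["trials"], "w") as fh:
        fh.write(f"# schema: {TRIALS_SCHEMA}\n")
        study.trials.to_csv(fh, index=False, float_format="%.3f", lineterminator="\n")
    with open(paths["fixations"], "w") as fh:
        fh.write(f"# schema: {FIXATIONS_SCHEMA}\n")
        study.fixations.to_csv(fh, index=False, sep="\t", float_format="%.1f",
                               lineterminator="\n")
    payload = {"schema": AOI_SCHEMA,
               "aois": study.aois.to_dict(orient="records")}
    with open(paths["aois"], "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    return paths
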