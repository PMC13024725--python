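"""Representational similarity machinery: vectorization, rank-correlation
and FDR brute-force oracles, permutation inference, and the trial-level
bootstrap."""

import numpy as np
import pandas as pd
import pytest

from gazemem import rsa
from gazemem.rsa import (BootstrapSpec, DegenerateInputError, bh_adjust,
                         bootstrap_rsa, fisher_z, group_inference,
                         pair_trials, permutation_test, similarity,
                         vectorize_matrix)
from gazemem.synthdata import CONDITIONS

from _oracles import (bh_rejections_bruteforce, bh_stepup_bruteforce,
                      exhaustive_permutation_p, kendall_taub_bruteforce,
                      spearman_bruteforce)


class TestVectorize:
    def test_column_wise_order(self):
        m = np.array([[1, 4, 7], [2, 5, 8], [3, 6, 9]])
        np.testing.assert_array_equal(vectorize_matrix(m), np.arange(1, 10))

    def test_identity_matrix(self):
        np.testing.assert_array_equal(
            vectorize_matrix(np.eye(3)),
            [1, 0, 0, 0, 1, 0, 0, 0, 1])

    def test_round_trip(self, rng):
        m = rng.random((3, 3))
        np.testing.assert_array_equal(
            vectorize_matrix(m).reshape(3, 3, order="F"), m)

    def test_dataframe_uses_fixed_label_order(self):
        df = pd.DataFrame(np.arange(9).reshape(3, 3),
                          index=["UR", "NR", "RR"], columns=["RR", "NR", "UR"])
        v = vectorize_matrix(df)
        # First column must be the NR condition, rows NR, RR, UR.
        assert list(v[:3]) == [df.loc["NR", "NR"], df.loc["RR", "NR"],
                               df.loc["UR", "NR"]]


class TestSimilarity:
    def test_identical_vectors(self, rng):
        x = rng.random(9)
        rho, z = similarity(x, x)
        assert rho == 1.0
        assert z == pytest.approx(np.arctanh(1 - 1e-6))

    def test_reversed_ranks(self):
        x = np.arange(9.0)
        rho, z = similarity(x, x[::-1])
        assert rho == -1.0
        assert z == pytest.approx(-np.arctanh(1 - 1e-6))

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            similarity(np.ones(9), np.arange(9.0))
        with pytest.raises(DegenerateInputError):
            similarity(np.r_[np.arange(8.0), np.nan], np.arange(9.0))

    @pytest.mark.parametrize("estimator,oracle", [
        ("spearman", spearman_bruteforce),
        ("kendall", kendall_taub_bruteforce)])
    def test_matches_bruteforce_oracle(self, estimator, oracle, rng):
        for _ in range(50):
            x = rng.integers(0, 5, size=9).astype(float)  # ties likely
            y = rng.random(9)
            if np.ptp(x) == 0:
                continue
            rho, _ = similarity(x, y, estimator)
            assert rho == pytest.approx(oracle(x, y), abs=1e-12)

    def test_invariance_to_monotone_transforms(self, rng):
        x, y = rng.random(9), rng.random(9)
        rho, _ = similarity(x, y)
        rho2, _ = similarity(np.exp(3 * x), y ** 3 + 5 * y, "spearman")
        assert rho2 == pytest.approx(rho)
        perm = rng.permutation(9)
        rho3, _ = similarity(x[perm], y[perm])
        assert rho3 == pytest.approx(rho)


def test_build_eye_matrix_completeness():
    cond = pd.DataFrame([
        {"participant": "P01", "age_group": "YA", "metric": "mean_fix_dur",
         "condition": c, "aoi": a, "value": 300.0, "n_trials": 5}
        for c in CONDITIONS for a in CONDITIONS])
    mat = rsa.build_eye_matrix(cond, "P01", "mean_fix_dur")
    assert (mat.to_numpy() == 300.0).all()
    with pytest.raises(DegenerateInputError):
        similarity(np.arange(9.0), vectorize_matrix(mat))
    # missing UR-condition cells -> incomplete -> None
    incomplete = cond[cond["condition"] != "UR"]
    assert rsa.build_eye_matrix(incomplete, "P01", "mean_fix_dur") is None
    assert rsa.build_eye_matrix(cond, "P01", "revisits") is None


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=9, max_size=9),
       st.lists(st.floats(-100, 100), min_size=9, max_size=9))
def test_similarity_invariant_to_common_permutation(xs, ys):
    x, y = np.asarray(xs), np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    rho, _ = similarity(x, y)
    perm = np.random.default_rng(0).permutation(9)
    rho_p, _ = similarity(x[perm], y[perm])
    assert rho_p == pytest.approx(rho, abs=1e-12)


def test_fisher_z_is_odd_increasing_and_clamped():
    rhos = np.linspace(-1, 1, 41)
    zs = np.array([fisher_z(r) for r in rhos])
    assert np.all(np.diff(zs) >= 0)
    np.testing.assert_allclose(zs, -zs[::-1], atol=1e-12)
    assert abs(fisher_z(1.0)) <= np.arctanh(1 - 1e-6)


def test_bh_adjust_matches_bruteforce(rng):
    for _ in range(50):
        p = rng.random(rng.integers(2, 12))
        np.testing.assert_allclose(bh_adjust(p), bh_stepup_bruteforce(p),
                                   atol=1e-12)


def test_bh_on_reference_p_family():
    """Structural check on a reference six-metric p family: adjustment
    preserves order and never shrinks a p value."""
    p = np.array([0.009, 0.0005, 0.004, 0.779, 0.137, 0.559])
    adj = bh_adjust(p)
    assert np.all(adj >= p)
    assert np.all(np.argsort(adj, kind="stable") == np.argsort(p, kind="stable"))
    q = 0.05
    assert (adj <= q).sum() == bh_rejections_bruteforce(p, q)


class TestPermutation:
    def test_identical_groups_give_p_one(self):
        x = np.arange(8.0)
        assert permutation_test(x, x, n_perm=500, seed=1) > 0.99

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            x, y = rng.random(4), rng.random(4)
            assert permutation_test(x, y, exact=True) == pytest.approx(
                exhaustive_permutation_p(x, y))

    def test_deterministic_per_seed(self, rng):
        x, y = rng.random(10), rng.random(10) + 0.3
        p1 = permutation_test(x, y, n_perm=999, seed=42)
        p2 = permutation_test(x, y, n_perm=999, seed=42)
        assert p1 == p2
        assert 0 < p1 <= 1


def test_group_inference_identical_groups():
    sim = pd.DataFrame({
        "participant": [f"P{i}" for i in range(8)],
        "age_group": ["YA"] * 4 + ["OA"] * 4,
        "metric": ["viewing_prop"] * 8,
        "estimator": "spearman",
        "rho": [0.1, 0.2, 0.3, 0.4] * 2,
        "z": [0.1, 0.2, 0.3, 0.4] * 2,
    })
    out = group_inference(sim, metrics=("viewing_prop",))
    assert out["t"].iloc[0] == pytest.approx(0.0)
    assert out["p"].iloc[0] == pytest.approx(1.0)


def _paired_set(study, config):
    from gazemem.gazemetrics import trial_metrics
    from gazemem.ingest import preprocess
    fix, _ = preprocess(study.fixations, study.trials, study.aois,
                        (config.screen_w, config.screen_h),
                        (config.stim_w, config.stim_h))
    return pair_trials(study.trials, trial_metrics(fix))


def test_pair_trials_joins_on_triad_identity(clean_study):
    paired = _paired_set(clean_study, clean_study.config)
    # every pair's triad must exist in both sources with matching condition
    sel = clean_study.trials[(clean_study.trials["cue_status"] == "old") &
                             (clean_study.trials["cue_resp"] == "old")]
    key = set(map(tuple, sel[["participant", "condition", "group_id"]]
                  .to_numpy()))
    got = set(map(tuple, paired[["participant", "condition", "group_id"]]
                  .drop_duplicates().to_numpy()))
    assert got <= key
    # viewing_prop has no missing AOI values, so it pairs every trial
    vp = paired[paired["metric"] == "viewing_prop"]
    assert len(vp) == len(key)


def test_bootstrap_deterministic_per_seed(clean_study):
    paired = _paired_set(clean_study, clean_study.config)
    spec = BootstrapSpec(n_boot=20, resample_size=6, seed=9)
    b1, _ = bootstrap_rsa(paired, spec)
    b2, _ = bootstrap_rsa(paired, spec)
    pd.testing.assert_frame_equal(b1, b2)


def test_bootstrap_excludes_empty_conditions(clean_study):
    paired = _paired_set(clean_study, clean_study.config)
    pid = paired["participant"].iloc[0]
    broken = paired[~((paired["participant"] == pid) &
                      (paired["condition"] == "UR"))]
    out, excl = bootstrap_rsa(broken, BootstrapSpec(n_boot=5, resample_size=4,
                                                    seed=2))
    reasons = {(e["participant"], e["metric"]): e["reason"] for e in excl}
    assert any(p == pid and "zero paired trials" in r
               for (p, _), r in reasons.items())
    assert not ((out["participant"] == pid) &
                (out["metric"] == "viewing_prop")).any()


def test_bootstrap_converges_to_plugin(small_study):
    """As resample size and the number of resamples grow, the bootstrap
    estimate approaches the plug-in similarity computed from the full data."""
    from gazemem.gazemetrics import aggregate, trial_metrics
    from gazemem.ingest import preprocess
    from gazemem.memory import choice_matrices
    cfg = small_study.config
    fix, _ = preprocess(small_study.fixations, small_study.trials,
                        small_study.aois, (cfg.screen_w, cfg.screen_h),
                        (cfg.stim_w, cfg.stim_h))
    tm = trial_metrics(fix)
    cond = aggregate(tm)
    cmats = choice_matrices(small_study.trials)
    sim, _ = rsa.participant_similarities(cmats, cond, "spearman")
    paired = pair_trials(small_study.trials, tm)
    pid = "YA001"
    plug = sim[(sim["participant"] == pid) &
               (sim["metric"] == "viewing_prop")]["z"].iloc[0]
    biases = []
    for size, boot in ((8, 100), (32, 400), (128, 1600)):
        est, _ = bootstrap_rsa(paired[paired["participant"] == pid],
                               BootstrapSpec(n_boot=boot, resample_size=size,
                                             seed=5),
                               metrics=("viewing_prop",))
        biases.append(abs(est["z"].iloc[0] - plug))
    assert biases[2] < biases[0]
    assert biases[2] < 0.1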