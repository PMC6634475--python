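"""Trial-table IO, category collapsing, exclusions, descriptives, kappa, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from veracue.data import (
    DISFLUENCY_FLAGS,
    TrialTableError,
    apply_exclusions,
    cohens_kappa,
    collapse_categories,
    descriptives,
    read_trials,
    speech_rate_composite,
    write_trials,
)
from veracue.simulate import GeneratorConfig, generate_dataset

from conftest import make_trial_row, make_trials


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

class TestTrialIO:
    def test_three_row_fixture_round_trips(self, tmp_path):
        df = make_trials([make_trial_row(trial_index=i + 1) for i in range(3)])
        p = tmp_path / "trials.csv"
        write_trials(df, p)
        back = read_trials(p)
        assert len(back) == 3
        pd.testing.assert_frame_equal(back, df, check_dtype=False)

    def test_tab_delimited_autodetected(self, tmp_path):
        df = make_trials([make_trial_row()])
        p = tmp_path / "trials.tsv"
        write_trials(df, p, sep="\t")
        assert len(read_trials(p)) == 1

    def test_invalid_veracity_names_allowed_levels(self, tmp_path):
        df = pd.DataFrame([make_trial_row(), make_trial_row(veracity="maybe")])
        p = tmp_path / "trials.csv"
        df.to_csv(p, index=False)
        with pytest.raises(TrialTableError, match=r"row 2.*truth, lie"):
            read_trials(p)

    def test_missing_column_is_configuration_error(self, tmp_path):
        df = pd.DataFrame([make_trial_row()]).drop(columns=["response"])
        p = tmp_path / "trials.csv"
        df.to_csv(p, index=False)
        with pytest.raises(TrialTableError, match="response"):
            read_trials(p)

    def test_synthetic_export_reread_equal(self, tmp_path):
        trials, _, _ = generate_dataset(GeneratorConfig(generate_cursor=False, seed=9))
        p = tmp_path / "synthetic.csv"
        write_trials(trials, p)
        back = read_trials(p)
        assert len(back) == 24 * 48
        num = trials.select_dtypes("number").columns
        assert np.allclose(back[num].to_numpy(float), trials[num].to_numpy(float),
                           equal_nan=True)
        obj = [c for c in trials.columns if c not in num]
        assert (back[obj].to_numpy() == trials[obj].to_numpy()).all()


# ---------------------------------------------------------------------------
# category collapsing
# ---------------------------------------------------------------------------

class TestCollapse:
    @pytest.mark.parametrize(
        "flags, expected",
        [
            # a filled pause alone makes the pause category, not repairs
            ({"filled_pause": 1}, {"pauses": 1, "repetitions": 0, "repairs": 0, "prolongations": 0}),
            # a substitution alone is a repair
            ({"substitution": 1}, {"pauses": 0, "repetitions": 0, "repairs": 1, "prolongations": 0}),
            ({}, {"pauses": 0, "repetitions": 0, "repairs": 0, "prolongations": 0}),
            ({"silent_pause": 1, "restart": 1}, {"pauses": 1, "repetitions": 0, "repairs": 1, "prolongations": 0}),
            ({"repetition": 1, "prolongation": 1}, {"pauses": 0, "repetitions": 1, "repairs": 0, "prolongations": 1}),
            ({"addition": 1}, {"pauses": 0, "repetitions": 0, "repairs": 1, "prolongations": 0}),
        ],
    )
    def test_mapping(self, flags, expected):
        df = make_trials([make_trial_row(**flags)])
        out = collapse_categories(df).iloc[0]
        for cat, v in expected.items():
            assert out[cat] == v

    def test_gesture_categories_copied_not_derived(self):
        # a hand movement annotated as an illustrator must not become an adaptor
        df = make_trials([make_trial_row(gest_hand=1, illustrator=1)])
        out = collapse_categories(df).iloc[0]
        assert out["illustrator"] == 1 and out["adaptor"] == 0

    @given(flags=st.lists(st.booleans(), min_size=7, max_size=7),
           extra=st.integers(0, 6))
    @settings(max_examples=60, deadline=None)
    def test_collapsing_is_monotone(self, flags, extra):
        base = dict(zip(DISFLUENCY_FLAGS, map(int, flags)))
        raised = dict(base)
        raised[DISFLUENCY_FLAGS[extra]] = 1
        a = collapse_categories(make_trials([make_trial_row(**base)])).iloc[0]
        b = collapse_categories(make_trials([make_trial_row(**raised)])).iloc[0]
        for cat in ("pauses", "repetitions", "repairs", "prolongations"):
            assert b[cat] >= a[cat]


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

class TestExclusions:
    def test_inconsistent_commitment_dropped_for_cue_models(self):
        rows = [make_trial_row(trial_index=i + 1) for i in range(10)]
        rows[3]["consistent_commitment"] = 0
        included, log = apply_exclusions(make_trials(rows), "cue_models")
        assert len(included) == 9
        assert list(log["rule"]) == ["inconsistent_commitment"]

    def test_missing_disambiguation_excluded_from_mouse_only(self):
        rows = [
            make_trial_row(trial_index=1),
            make_trial_row(trial_index=2, disambiguation_ms=np.nan),
        ]
        df = make_trials(rows)
        cue_inc, _ = apply_exclusions(df, "cue_models")
        mouse_inc, log = apply_exclusions(df, "mouse_pause")
        assert len(cue_inc) == 2
        assert len(mouse_inc) == 1
        assert "no_disambiguation_point" in set(log["rule"])

    def test_post_disambiguation_pause_trials_dropped(self):
        # 525 pause trials, 28 with the pause starting after disambiguation
        rows = []
        for i in range(525):
            onset = 2000.0 if i < 28 else 500.0  # disambiguation at 1500 ms
            rows.append(make_trial_row(trial_index=i + 1, filled_pause=1,
                                       pause_onset_ms=onset))
        included, log = apply_exclusions(make_trials(rows), "mouse_pause")
        assert len(included) == 497
        n_dropped = (log["rule"] == "cue_post_disambiguation").sum()
        assert n_dropped == 28
        assert round(100.0 * n_dropped / 525, 1) == 5.3

    def test_rules_order_independent(self):
        rows = [
            make_trial_row(trial_index=1, consistent_commitment=0,
                           disambiguation_ms=np.nan),
            make_trial_row(trial_index=2, filled_pause=1, pause_onset_ms=2000.0),
            make_trial_row(trial_index=3),
        ]
        df = make_trials(rows)
        inc_fwd, _ = apply_exclusions(df, "mouse_pause")
        inc_rev, _ = apply_exclusions(df.iloc[::-1], "mouse_pause")
        assert set(inc_fwd["trial_index"]) == set(inc_rev["trial_index"]) == {3}

    def test_unknown_analysis_rejected(self):
        with pytest.raises(ValueError, match="unknown analysis"):
            apply_exclusions(make_trials([make_trial_row()]), "everything")

    def test_no_video_excluded_from_affect_analysis(self):
        rows = [make_trial_row(trial_index=1, gesture_data_present=0),
                make_trial_row(trial_index=2)]
        included, log = apply_exclusions(make_trials(rows), "mouse_affect")
        assert list(included["trial_index"]) == [2]
        assert "no_gesture_data" in set(log["rule"])


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

class TestDescriptives:
    def test_degenerate_all_truth(self):
        df = make_trials([make_trial_row(trial_index=i + 1) for i in range(4)])
        d = descriptives(df)
        assert d.truth_rate == 100.0
        assert d.accuracy_overall == 100.0

    def test_hand_count_four_trials(self):
        # 2 truths judged {truth, lie}; 2 lies judged {truth, truth}
        rows = [
            make_trial_row(trial_index=1, veracity="truth", response="truth"),
            make_trial_row(trial_index=2, veracity="truth", response="lie"),
            make_trial_row(trial_index=3, veracity="lie", response="truth"),
            make_trial_row(trial_index=4, veracity="lie", response="truth"),
        ]
        d = descriptives(make_trials(rows))
        assert d.truth_rate == 50.0
        assert d.accuracy_overall == 25.0
        assert d.accuracy_given_truth == 50.0
        assert d.accuracy_given_lie == 0.0

    def test_study_rates_recompose(self):
        # conditional accuracies recomposing to the overall rate
        overall = 0.539 * 0.535 + (1 - 0.539) * 0.417
        assert round(100 * overall, 1) == 48.1  # printed 48.0 under rounding of inputs
        assert abs(100 * overall - 48.0) < 0.2

    def test_decomposition_identity_on_generated_data(self, default_trials):
        d = descriptives(default_trials)
        p_t = d.truth_rate / 100
        lhs = d.accuracy_overall / 100
        rhs = p_t * d.accuracy_given_truth / 100 + (1 - p_t) * d.accuracy_given_lie / 100
        assert abs(lhs - rhs) < 1e-12

    def test_empty_rejected(self):
        df = make_trials([make_trial_row()])
        with pytest.raises(ValueError):
            descriptives(df.iloc[0:0])


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

class TestKappa:
    def test_perfect_agreement(self):
        r = cohens_kappa([1, 1, 0, 0, 1], [1, 1, 0, 0, 1])
        assert r.kappa == pytest.approx(1.0)
        assert r.observed_agreement == 1.0

    def test_chance_level_symmetry(self):
        r = cohens_kappa((1, 1, 0, 0), (1, 0, 1, 0))
        assert r.kappa == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_hand_computation(self):
        # counts: both=1: 40, a-only: 5, b-only: 5, both=0: 50
        a = [1] * 45 + [0] * 55
        b = [1] * 40 + [0] * 5 + [1] * 5 + [0] * 50
        r = cohens_kappa(a, b)
        p_o = 90 / 100
        p_e = 0.45 * 0.45 + 0.55 * 0.55
        assert r.observed_agreement == pytest.approx(p_o)
        assert r.expected_agreement == pytest.approx(p_e)
        assert r.kappa == pytest.approx((p_o - p_e) / (1 - p_e))
        # independent implementation
        assert r.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        assert cohens_kappa(a, b).kappa == pytest.approx(
            cohens_kappa(1 - a, 1 - b).kappa
        )

    def test_constant_identical_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_kappa([1, 1, 1], [1, 1, 1])


# ---------------------------------------------------------------------------
# PCA speech-rate composite
# ---------------------------------------------------------------------------

class TestSpeechRateComposite:
    def test_rank_one_limit(self):
        x = np.linspace(1, 2, 50)
        r = speech_rate_composite(x, 2 * x, -3 * x)
        assert r.eigenvalue == pytest.approx(3.0, abs=1e-10)
        assert r.variance_share == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalues_sum_to_three(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((200, 3))
        from veracue.data import SpeechRateComposite

        est = SpeechRateComposite().fit(M)
        assert est.eigenvalues_.sum() == pytest.approx(3.0, abs=1e-8)
        assert est.variance_share_ == pytest.approx(est.eigenvalue_ / 3.0)

    def test_printed_identity(self):
        # a leading eigenvalue of 2.19 on three standardized variables
        assert round(100 * 2.19 / 3) == 73

    def test_sign_convention_and_scores(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(300)
        dur = 3000 + 800 * base + 50 * rng.standard_normal(300)
        pause = 600 + 300 * base + 40 * rng.standard_normal(300)
        rate = 3.8 - 1.2 * base + 0.05 * rng.standard_normal(300)
        r = speech_rate_composite(dur, pause, rate)
        assert r.loadings[2] > 0  # syllable rate loads positively
        # higher score = faster speech => negatively related to duration
        assert np.corrcoef(r.scores, dur)[0, 1] < 0

    def test_constant_column_named(self):
        x = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="silent_pause_duration_ms"):
            speech_rate_composite(x, np.ones(10), x)

    def test_generator_eigenvalue_matches_large_sample_oracle(self, default_trials):
        """The default-n composite eigenvalue agrees with the generator's
        population value, estimated independently from a much larger draw."""
        big, _, _ = generate_dataset(
            GeneratorConfig(n_dyads=400, generate_cursor=False, seed=77)
        )
        M = big[["utterance_duration_ms", "silent_pause_duration_ms", "syllable_rate"]]
        lam_pop = np.linalg.eigvalsh(np.corrcoef(M.to_numpy(float), rowvar=False))[-1]
        r = speech_rate_composite(
            default_trials["utterance_duration_ms"],
            default_trials["silent_pause_duration_ms"],
            default_trials["syllable_rate"],
        )
        assert r.eigenvalue == pytest.approx(lam_pop, abs=0.1)
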