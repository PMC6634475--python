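"""Trajectory binning, proportions, e-logit DV and the time-locked model."""

import numpy as np
import pandas as pd
import pytest

from veracue.data import collapse_categories
from veracue.mousetrace import (
    CursorTrack,
    assemble_tracks,
    bin_track,
    elogit_difference,
    trajectory_analysis,
)
from veracue.simulate import (
    GeneratorConfig,
    ResponseModel,
    TrajectoryModel,
    generate_dataset,
)


def track_from_xs(xs, referent_side="right", dt=20.0, disamb=0.0, ys=None):
    xs = np.asarray(xs, dtype=float)
    t = np.arange(len(xs)) * dt
    ys = np.zeros_like(xs) if ys is None else np.asarray(ys, float)
    return CursorTrack(("d1", 1), t, xs, ys, referent_side, disamb)


class TestBinning:
    def test_pure_approach_gives_unit_proportion(self):
        # monotone leftward motion with the referent on the left
        tr = track_from_xs([0, -10, -25, -40, -80], referent_side="left")
        b = bin_track(tr)
        moved = b.cum_total > 0
        assert moved.any()
        assert np.allclose(b.p_ref[moved], 1.0)
        assert np.allclose(b.p_dist[moved], 0.0)

    def test_overshoot_hand_computation(self):
        # 100 px toward the referent then 50 px back: final p_ref = 2/3
        tr = track_from_xs([0, 50, 100, 75, 50])
        b = bin_track(tr)
        assert b.cum_total[-1] == pytest.approx(150.0)
        assert b.p_ref[-1] == pytest.approx(2.0 / 3.0)
        assert b.p_dist[-1] == pytest.approx(1.0 / 3.0)

    def test_stationary_pointer_flagged(self):
        tr = track_from_xs([0, 0, 0, 0])
        b = bin_track(tr)
        assert np.all(b.zero_movement)
        assert np.all(b.d_ref == 0) and np.all(b.d_dist == 0)
        assert np.all(np.isnan(b.p_ref))

    def test_distance_conservation(self):
        rng = np.random.default_rng(3)
        xs = np.cumsum(rng.normal(0, 15, 120))
        tr = track_from_xs(xs, disamb=400.0)
        b = bin_track(tr)
        assert (b.d_ref + b.d_dist).sum() == pytest.approx(
            np.abs(np.diff(xs)).sum(), abs=1e-9
        )

    def test_bins_relative_to_disambiguation(self):
        tr = track_from_xs([0, 10, 20, 30, 40], disamb=40.0)
        b = bin_track(tr)
        # samples at 20,40,60,80 ms; displacement into the 40 ms sample is
        # the last pre-disambiguation movement => bin index -1
        assert b.time_rel[0] == -40.0 or b.time_rel[0] == -20.0
        assert 0.0 in b.time_rel

    def test_proportions_scale_invariant(self):
        rng = np.random.default_rng(5)
        xs = np.cumsum(rng.normal(0, 10, 60))
        a = bin_track(track_from_xs(xs))
        b = bin_track(track_from_xs(3.7 * xs))
        moved = a.cum_total > 0
        assert np.allclose(a.p_ref[moved], b.p_ref[moved])

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(6)
        xs = np.cumsum(rng.normal(0, 10, 60))
        a = bin_track(track_from_xs(xs, referent_side="right"))
        m = bin_track(track_from_xs(-xs, referent_side="left"))
        assert np.allclose(a.d_ref, m.d_ref)
        assert np.allclose(a.d_dist, m.d_dist)
        assert np.allclose(
            elogit_difference(a), elogit_difference(m), atol=1e-12
        )

    def test_unordered_timestamps_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            CursorTrack(("d1", 1), [0, 20, 20], [0, 1, 2], [0, 0, 0], "left", 0.0)

    def test_disambiguation_outside_range_rejected(self):
        tr = track_from_xs([0, 5, 10])
        tr.disambiguation_ms = 10_000.0
        with pytest.raises(ValueError, match="outside sampled range"):
            bin_track(tr)

    def test_xy_denominator_dilutes_proportions(self):
        xs = [0, 50, 100]
        ys = [0, 120, 240]
        bx = bin_track(track_from_xs(xs, ys=None))
        bxy = bin_track(track_from_xs(xs, ys=ys), denominator="xy")
        assert bxy.cum_total[-1] > bx.cum_total[-1]
        assert bxy.p_ref[-1] < bx.p_ref[-1]


class TestElogit:
    def test_symmetric_movement_gives_zero(self):
        tr = track_from_xs([0, 50, 0])  # 50 px out, 50 px back
        b = bin_track(tr)
        dv = elogit_difference(b)
        assert dv[-1] == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        # cumulative 100 px toward referent, 50 toward distractor, c = 0.5
        tr = track_from_xs([0, 100, 50])
        b = bin_track(tr)
        expected = np.log(100.5 / 50.5) - np.log(50.5 / 100.5)
        assert dvlast(b) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(8)
        xs = np.cumsum(rng.normal(0, 12, 50))
        a = bin_track(track_from_xs(xs, referent_side="right"))
        b = bin_track(track_from_xs(xs, referent_side="left"))
        moved = ~a.zero_movement
        assert np.allclose(elogit_difference(a)[moved], -elogit_difference(b)[moved])

    def test_invalid_smoothing_rejected(self):
        b = bin_track(track_from_xs([0, 10, 20]))
        with pytest.raises(ValueError, match="positive"):
            elogit_difference(b, c=0.0)

    def test_zero_mode_drop_gives_nan(self):
        b = bin_track(track_from_xs([0, 0, 10]))
        dv = elogit_difference(b, zero_mode="drop")
        assert np.isnan(dv[b.zero_movement]).all()


def dvlast(b):
    return elogit_difference(b)[-1]


@pytest.fixture(scope="module")
def analysed(default_dataset):
    trials, cursor, _ = default_dataset
    tracks = assemble_tracks(cursor, trials)
    return trials, tracks


class TestTrajectoryAnalysis:
    def test_pause_effect_negative_on_default_data(self, analysed):
        trials, tracks = analysed
        ana = trajectory_analysis(tracks, trials, cue="pause")
        coef = dict(zip(ana.fit.terms, ana.fit.estimates))
        assert coef["time:cue"] < 0

    def test_affect_effect_positive_on_default_data(self, analysed):
        trials, tracks = analysed
        ana = trajectory_analysis(tracks, trials, cue="affect_display")
        coef = dict(zip(ana.fit.terms, ana.fit.estimates))
        assert coef["time:cue"] > 0

    def test_curves_cover_conditions_to_4000ms(self, analysed):
        trials, tracks = analysed
        ana = trajectory_analysis(tracks, trials, cue="pause")
        assert set(ana.curves["cue"]) == {0, 1}
        # capped at 4000 ms; synthetic trials end at the click, so coverage
        # runs to the longest track but always past the 800 ms model window
        assert ana.curves["time_rel"].max() <= 4000.0
        assert ana.curves["time_rel"].max() >= 1200.0
        early = ana.curves[ana.curves["time_rel"] <= 800]
        assert {"p_ref", "p_dist", "se_ref", "se_dist"} <= set(early.columns)

    def test_identical_trajectories_give_zero_interaction(self):
        """If every trial has the same track, time x cue must be exactly 0."""
        rows = []
        tracks = {}
        xs = np.concatenate([np.zeros(10), np.linspace(0, 300, 60)])
        for i in range(40):
            from conftest import make_trial_row

            pause = i % 2
            rows.append(make_trial_row(
                dyad_id=f"d{i % 4}", trial_index=i + 1, item_id=f"item{i % 10}",
                target_side="right", veracity="truth", response="truth",
                filled_pause=pause,
                pause_onset_ms=200.0 if pause else np.nan,
                disambiguation_ms=200.0,
            ))
            tracks[(f"d{i % 4}", i + 1)] = CursorTrack(
                (f"d{i % 4}", i + 1), np.arange(len(xs)) * 20.0, xs,
                np.zeros_like(xs), "right", 200.0,
            )
        from conftest import make_trials

        trials = collapse_categories(make_trials(rows))
        ana = trajectory_analysis(tracks, trials, cue="pause")
        coef = dict(zip(ana.fit.terms, ana.fit.estimates))
        assert coef["time:cue"] == pytest.approx(0.0, abs=1e-8)
        assert coef["cue"] == pytest.approx(0.0, abs=1e-8)

    def test_too_few_trials_per_level_rejected(self, analysed):
        trials, tracks = analysed
        no_pause = trials[(trials["filled_pause"] == 0) & (trials["silent_pause"] == 0)]
        with pytest.raises(ValueError, match="at least 2 trials"):
            trajectory_analysis(tracks, no_pause, cue="pause")

    def test_null_generator_interaction_sign_balanced(self):
        """With both the drift lag and the response pathway zeroed the
        interaction estimate has no systematic sign and is small relative
        to the injected condition."""
        tm = TrajectoryModel(pause_lag_ms=0.0, affect_absent_lag_ms=0.0)
        rm = ResponseModel(coef={})
        betas = []
        for seed in range(12):
            cfg = GeneratorConfig(n_dyads=8, trials_per_dyad=24,
                                  trajectory_model=tm, response_model=rm, seed=seed)
            trials, cursor, _ = generate_dataset(cfg)
            trials = collapse_categories(trials)
            tracks = assemble_tracks(cursor, trials)
            ana = trajectory_analysis(tracks, trials, cue="pause")
            betas.append(dict(zip(ana.fit.terms, ana.fit.estimates))["time:cue"])
        betas = np.asarray(betas)
        assert (betas < 0).sum() < len(betas)  # not all negative
        assert (betas > 0).sum() < len(betas)  # not all positive
        assert np.abs(np.mean(betas)) < 0.15
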