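"""Trial protocol, outcome classification and the analysis surface."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saccadebg.colliculus import SaccadeEvent
from saccadebg.config import ExperimentConfig, ModelConfig
from saccadebg.tasks import (OUTCOMES, TaskSpec, build_trial,
                             classify_outcome, performance_curve,
                             run_experiment, srt_histogram, srt_mode,
                             weight_map_summary)


@pytest.fixture(scope="module")
def cfg():
    return ModelConfig.reduced()


class TestBuildTrial:
    def test_layout_contract(self, cfg, rng):
        for kind in ("spatial", "color", "conjunction"):
            spec = TaskSpec(kind)
            for _ in range(20):
                sched = build_trial(spec, cfg, rng)
                sides = sorted(c.side for c in sched.cues)
                assert sides == [-1, 1]
                colors = sorted(c.color for c in sched.cues)
                assert colors == ["green", "red"]
                intens = sorted(c.intensity for c in sched.cues)
                assert intens == [0.95, 1.0]
                assert 150.0 <= sched.gap <= 250.0

    def test_conjunction_cases_both_occur(self, cfg, rng):
        spec = TaskSpec("conjunction")
        flags = {build_trial(spec, cfg, rng).conj_present for _ in range(40)}
        assert flags == {True, False}

    def test_fixed_seed_reproduces_schedule(self, cfg):
        spec = TaskSpec("spatial")
        a = build_trial(spec, cfg, np.random.default_rng(9))
        b = build_trial(spec, cfg, np.random.default_rng(9))
        assert a.gap == b.gap
        assert [(c.side, c.color, c.intensity) for c in a.cues] == \
            [(c.side, c.color, c.intensity) for c in b.cues]

    def test_timeline_phases_ordered(self, cfg, rng):
        sched = build_trial(TaskSpec("spatial"), cfg, rng)
        starts = [p[0] for p in sched.phases]
        ends = [p[1] for p in sched.phases]
        assert starts == sorted(starts)
        assert all(e > s for s, e in zip(starts, ends))
        assert sched.phases[0][1] - sched.phases[0][0] == 50.0
        assert sched.phases[1][1] - sched.phases[1][0] == 800.0

    def test_scene_lookup(self, cfg, rng):
        sched = build_trial(TaskSpec("spatial"), cfg, rng)
        assert sched.scene_at(-10.0).lum.max() == 0.0
        assert sched.scene_at(25.0).lum.max() == 0.0  # black screen
        assert sched.scene_at(100.0).lum.max() > 0.0  # fixation cue
        assert sched.scene_at(sched.t_cue_on + 1.0).lum.max() > 0.0


class TestClassification:
    @settings(max_examples=200, deadline=None)
    @given(st.floats(-25, 25), st.floats(-25, 25), st.booleans(),
           st.sampled_from(["spatial", "color", "conjunction"]),
           st.booleans())
    def test_exhaustive_and_exclusive(self, lx, ly, saccade, kind,
                                      red_right):
        cfg = ModelConfig.reduced()
        spec = TaskSpec(kind)
        rng = np.random.default_rng(abs(hash((red_right,))) % 2 ** 31)
        sched = build_trial(spec, cfg, rng)
        event = SaccadeEvent(150.0, math.hypot(lx, ly), 0.0, (lx, ly)) \
            if saccade else None
        eye = (lx, ly) if saccade else (0.1, 0.0)
        outcome, reward = classify_outcome(spec, sched, event, eye, 2.5)
        assert outcome in OUTCOMES
        assert reward in (0.0, 1.0)

    def test_known_cases(self, cfg, rng):
        spec = TaskSpec("spatial")
        sched = build_trial(spec, cfg, rng)
        right = next(c for c in sched.cues if c.side == 1)
        ev = SaccadeEvent(150.0, 10.0, 0.0, (right.x, 0.0))
        outcome, reward = classify_outcome(spec, sched, ev,
                                           (right.x, 0.0), 2.5)
        assert outcome == "correct" and reward == 1.0
        ev = SaccadeEvent(150.0, 10.0, 180.0, (-right.x, 0.0))
        outcome, reward = classify_outcome(spec, sched, ev,
                                           (-right.x, 0.0), 2.5)
        assert outcome == "spatial_error" and reward == 0.0
        ev = SaccadeEvent(150.0, 5.0, 37.0, (4.0, 3.0))
        outcome, reward = classify_outcome(spec, sched, ev, (4.0, 3.0), 2.5)
        assert outcome == "bad_saccade" and reward == 0.0

    def test_fixation_hold_rewarded_only_without_conjunction(self, cfg, rng):
        spec = TaskSpec("conjunction")
        for _ in range(30):
            sched = build_trial(spec, cfg, rng)
            outcome, reward = classify_outcome(spec, sched, None,
                                               (0.2, 0.0), 2.5)
            if sched.conj_present:
                assert outcome == "no_saccade" and reward == 0.0
            else:
                assert outcome == "good_average" and reward == 1.0


class TestHistograms:
    def test_single_latency_single_mode(self):
        counts, edges, modes = srt_histogram(np.full(50, 100.0))
        assert len(modes) == 1
        assert abs(modes[0] - 100.0) <= 8.0

    def test_bimodal_mixture_recovers_both_modes(self, rng):
        srts = np.concatenate([rng.normal(88, 4, 150),
                               rng.normal(200, 10, 100)])
        counts, edges, modes = srt_histogram(srts)
        assert any(abs(m - 88) <= 10 for m in modes)
        assert any(abs(m - 200) <= 14 for m in modes)

    def test_srt_mode_picks_dominant_cluster(self, rng):
        srts = np.concatenate([rng.normal(88, 3, 200),
                               rng.normal(200, 10, 50)])
        assert abs(srt_mode(srts) - 88) < 8

    def test_empty_input(self):
        counts, edges, modes = srt_histogram([])
        assert len(counts) == 0 and modes == []
        assert math.isnan(srt_mode([np.nan]))


class TestPerformanceCurve:
    def make_df(self, outcomes):
        rows = []
        for s, outs in enumerate(outcomes):
            for t, o in enumerate(outs):
                rows.append({"session": s, "run": 0, "trial": t,
                             "outcome": o,
                             "reward": 1.0 if o == "correct" else 0.0})
        return pd.DataFrame(rows)

    def test_all_correct_is_flat_one(self):
        df = self.make_df([["correct"] * 4] * 3)
        curve = performance_curve(df)
        assert (curve["reward"] == 1.0).all()
        assert (curve["correct"] == 1.0).all()

    def test_fractions_sum_to_one(self):
        df = self.make_df([["correct", "spatial_error", "no_saccade",
                            "bad_saccade"]] * 2)
        curve = performance_curve(df)
        totals = curve[list(OUTCOMES)].sum(axis=1)
        np.testing.assert_allclose(totals.values, 1.0)


class TestWeightMapSummary:
    def test_identity_gives_uniform_ones(self):
        from saccadebg.learning import ActorState
        from saccadebg.config import LearningConfig
        m = 5
        actor = ActorState.init(4 * m * m, LearningConfig(), 0.1)
        maps = weight_map_summary(actor, m)
        assert maps["sc"] == pytest.approx(np.ones((2, m, m)))
        assert maps["fef"] == pytest.approx(np.ones((2, m, m)))

    def test_boosted_column_appears_as_hot_unit(self):
        from saccadebg.learning import ActorState
        from saccadebg.config import LearningConfig
        m = 5
        n = 4 * m * m
        actor = ActorState.init(n, LearningConfig(), 0.1)
        actor.w[3, 7] += 4.0  # input unit 7 of the collicular portion
        maps = weight_map_summary(actor, m)
        hot = np.unravel_index(np.argmax(maps["sc"]), (2, m, m))
        assert hot == np.unravel_index(7, (2, m, m))
        assert maps["sc"].max() == pytest.approx(5.0)
        assert maps["fef"].max() == pytest.approx(1.0)


class TestRunExperiment:
    def test_record_counting(self, cfg):
        exp = ExperimentConfig(runs=1, sessions=2, trials_per_session=12,
                               scale="reduced")
        df = run_experiment(exp, TaskSpec("spatial"), cfg=cfg, seed=0)
        assert len(df) == 24
        assert set(df.session.unique()) == {0, 1}
        assert df.outcome.isin(OUTCOMES).all()

    def test_fixed_seed_identical_logs(self, cfg):
        exp = ExperimentConfig(runs=1, sessions=1, trials_per_session=6,
                               scale="reduced")
        a = run_experiment(exp, TaskSpec("color"), cfg=cfg, seed=4)
        b = run_experiment(exp, TaskSpec("color"), cfg=cfg, seed=4)
        pd.testing.assert_frame_equal(a, b)
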