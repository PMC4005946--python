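"""Whole-model properties: latencies, gating, rest stability, determinism."""

import numpy as np
import pytest

from saccadebg.config import ModelConfig
from saccadebg.model import SaccadeModel
from saccadebg.retinotopy import (VisualTarget, pyramid_reduce,
                                  render_stimulus)
from saccadebg.tasks import TaskSpec, build_trial, run_trial


def step_scene(model, cfg, scene, empty, n_steps, probe=None):
    """Step the model with a scene switched on at t=0 (latencies apply)."""
    lat = cfg.dynamics
    for t in range(n_steps):
        def at(latency):
            return scene if t >= latency else empty
        model.step(at(lat.latency_scs).lum, at(lat.latency_fef).lum,
                   at(lat.latency_it).color)
        if probe is not None:
            probe(t, model)


@pytest.fixture(scope="module")
def cfg():
    return ModelConfig.reduced()


@pytest.fixture
def model(cfg):
    return SaccadeModel(cfg, rng=np.random.default_rng(0), learning=False)


class TestLatencyOrdering:
    def test_pathway_departures_follow_the_anatomical_delays(self, cfg, model):
        scene = render_stimulus([VisualTarget(10.0, 0.0, "red", 1.0)],
                                cfg.retinotopy)
        empty = render_stimulus([], cfg.retinotopy)
        first = {}

        base = {"scs": model.sc.scs.max(),
                "fef": model.fef_loop.fef_in.max(),
                "it": 0.0}

        def probe(t, m):
            vals = {"scs": m.sc.scs.max(), "fef": m.fef_loop.fef_in.max(),
                    "it": float(m._u3_prev.max()) if m._u3_prev is not None
                    else 0.0}
            for k, v in vals.items():
                if k not in first and v > base[k] + 0.05:
                    first[k] = t

        step_scene(model, cfg, scene, empty, 170, probe)
        # departures track the 41 / 91 / 122 ms input latencies
        assert 41 <= first["scs"] <= 55
        assert 91 <= first["fef"] <= 105
        assert 122 <= first["it"] <= 136
        assert first["fef"] - first["scs"] >= 30
        assert first["it"] - first["fef"] >= 25

    def test_color_loop_departs_after_fef(self, cfg, model):
        # the feature pathway is the slowest of the three
        scene = render_stimulus([VisualTarget(10.0, 0.0, "red", 1.0)],
                                cfg.retinotopy)
        empty = render_stimulus([], cfg.retinotopy)
        it_dep, fef_dep = [], []

        def probe(t, m):
            if not fef_dep and m.fef_loop.fef_in.max() > 0.05:
                fef_dep.append(t)
            if not it_dep and m.color_loop.it_out.max() > 0.15:
                it_dep.append(t)

        step_scene(model, cfg, scene, empty, 220, probe)
        assert fef_dep and it_dep
        assert it_dep[0] - fef_dep[0] >= 31


class TestRestAndGating:
    def test_no_structure_self_ignites_at_rest(self, cfg, model):
        empty = render_stimulus([], cfg.retinotopy)
        model.reset_trial()
        for _ in range(1000):
            model.step(empty.lum, empty.lum, empty.color)
        assert model.sc.sci_out.max() < 0.1
        assert model.fef_loop.fef_out.max() < 0.1
        assert model.sc.motor.max() < 0.01
        assert model._disinhib_sp.max() < 0.1
        assert np.hypot(*model.sbg.eye) < 0.01

    def test_saccade_signal_gates_all_feedforward_input(self, cfg, model):
        scene = render_stimulus([VisualTarget(10.0, 0.0, "red", 1.0)],
                                cfg.retinotopy)
        model.reset_trial()
        model.cfg.sc_motor.w_sg_scs = 1.0
        model.cfg.loops.w_sg_inhib = 1.0
        try:
            for _ in range(200):
                model.sbg.sat = 1.0  # saccade in full execution
                model.step(scene.lum, scene.lum, scene.color)
            assert model.sc.scs.max() < 0.05
            assert model.fef_loop.fef_in.max() < 0.05
        finally:
            model.cfg.sc_motor.w_sg_scs = ModelConfig().sc_motor.w_sg_scs


class TestFusedKernelEquivalence:
    def test_fused_step_matches_modular_structures(self, cfg, rng):
        """The jit kernel and the modular map updates are the same math."""
        from saccadebg._kernels import fused_map_step
        from saccadebg.colliculus import SCState
        from saccadebg.loops import SpatialLoop

        n = cfg.retinotopy.n
        model = SaccadeModel(cfg, rng=np.random.default_rng(1),
                             learning=False)
        sc_ref = SCState(cfg.sc_motor, n, 1.0)
        fef_ref = SpatialLoop(cfg.loops, n, 1.0)
        scc = cfg.sc_motor
        for _ in range(40):
            retina = rng.random((2, n, n))
            fefvis = rng.random((2, n, n))
            v4 = rng.random((2, n, n)) * 0.5
            dmap = rng.random((2, n, n)) * 0.8
            sg = float(rng.random() * 0.5)
            sat, opn = float(rng.random()), float(rng.random())
            trn_sc, trn_fef = sc_ref.trn, fef_ref.trn

            # modular reference (motor first: it reads the previous-step
            # SCi, matching the synchronous update of the fused kernel)
            fef_out_prev = fef_ref.fef_out.copy()
            sc_ref.step_motor(dmap, sat, opn, cfg.bg_spatial.gpi_rest)
            sc_ref.step_visual(retina, fef_out_prev, v4, dmap, sg)
            sc_ref.trn = trn_sc  # TRN handled outside the fused kernel
            fef_ref.step(fefvis, dmap, sg)
            fef_ref.trn = trn_fef

            # fused kernel on the model's arrays (state synchronised)
            gate_sc = max(0.0, 1.0 - scc.w_sg_scs * sg)
            gate_sci = max(0.0, 1.0 - scc.w_sg_sci * sg)
            gate_fef = max(0.0, 1.0 - cfg.loops.w_sg_inhib * sg)
            f = model._flat
            fused_map_step(
                f[0], f[1], f[2], f[3], f[4], f[5], f[6],
                retina.reshape(-1), fefvis.reshape(-1), v4.reshape(-1),
                dmap.reshape(-1), model._vec_x, model._vec_y,
                gate_sc, gate_sci, gate_fef, trn_sc, trn_fef, sat, opn,
                cfg.bg_spatial.gpi_rest, model._p)

            np.testing.assert_allclose(model.sc.scs, sc_ref.scs, atol=1e-12)
            np.testing.assert_allclose(model.sc.sci_out, sc_ref.sci_out,
                                       atol=1e-12)
            np.testing.assert_allclose(model.sc.th, sc_ref.th, atol=1e-12)
            np.testing.assert_allclose(model.sc.motor, sc_ref.motor,
                                       atol=1e-12)
            np.testing.assert_allclose(model.fef_loop.fef_in, fef_ref.fef_in,
                                       atol=1e-12)
            np.testing.assert_allclose(model.fef_loop.fef_out,
                                       fef_ref.fef_out, atol=1e-12)
            np.testing.assert_allclose(model.fef_loop.th, fef_ref.th,
                                       atol=1e-12)


class TestLearningNeutralityAndDeterminism:
    def test_identity_start_matches_learning_free_model(self, cfg):
        """Before any reward, behaviour equals a learning-free model."""
        spec = TaskSpec("spatial")
        recs = []
        for learn in (True, False):
            rng = np.random.default_rng(7)
            model = SaccadeModel(cfg, rng=rng, learning=learn)
            sched = build_trial(spec, cfg, rng)
            recs.append(run_trial(model, spec, sched))
        assert recs[0]["srt"] == recs[1]["srt"] or (
            np.isnan(recs[0]["srt"]) and np.isnan(recs[1]["srt"]))
        assert recs[0]["landing_x"] == pytest.approx(recs[1]["landing_x"])
        assert recs[0]["outcome"] == recs[1]["outcome"]

    def test_trial_is_bit_reproducible(self, cfg):
        spec = TaskSpec("color")
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(3)
            model = SaccadeModel(cfg, rng=rng)
            sched = build_trial(spec, cfg, rng)
            rec = run_trial(model, spec, sched)
            outs.append((rec["srt"], rec["landing_x"], rec["outcome"],
                         model.critic_spatial.w.sum(),
                         model.actor_color.w.sum()))
        assert outs[0] == outs[1]


def test_lesion_is_reversible(cfg):
    spec = TaskSpec("spatial")

    def run_once(lesion_cycle):
        rng = np.random.default_rng(5)
        model = SaccadeModel(cfg, rng=rng, learning=False)
        if lesion_cycle:
            model.apply_lesion("fef_inactivation")
            model.apply_lesion("none")
        sched = build_trial(spec, cfg, rng)
        return run_trial(model, spec, sched)

    a, b = run_once(False), run_once(True)
    assert a["srt"] == b["srt"] or (np.isnan(a["srt"]) and np.isnan(b["srt"]))
    assert a["landing_x"] == pytest.approx(b["landing_x"])


def test_pre_visual_fef_burst_with_strong_spatial_weights():
    """With strong learned collicular weights, FEF output departs its
    baseline before the 91 ms visual input could drive it (resonance
    through the shared spatial circuit)."""
    cfg = ModelConfig.full()
    model = SaccadeModel(cfg, rng=np.random.default_rng(0), learning=False)
    sc = render_stimulus([VisualTarget(10.0, 0.0, "white", 1.0)],
                         cfg.retinotopy)
    coarse = pyramid_reduce(sc.lum) * model.reduce_gain
    prof = coarse.reshape(-1) / coarse.max()
    rows = np.nonzero(prof > 0.8)[0]
    c = 4.5 / max(len(rows), 1)
    for k in rows:
        model.actor_spatial.w[k, :model.n_coarse] += c * prof
    model.actor_spatial.touched[:] = True
    model.actor_spatial.touched_idx = np.arange(model.n_learn)
    model._refresh_actor_cache()

    scene = render_stimulus([VisualTarget(10.0, 0.0, "red", 1.0)],
                            cfg.retinotopy)
    empty = render_stimulus([], cfg.retinotopy)
    lat = cfg.dynamics

    def departure_time(feed_fef_visual):
        model.reset_trial()
        baseline, departure = None, None
        for t in range(150):
            def at(latency):
                return scene if t >= latency else empty
            fef_vis = at(lat.latency_fef).lum if feed_fef_visual \
                else empty.lum
            model.step(at(lat.latency_scs).lum, fef_vis,
                       at(lat.latency_it).color)
            if t == 30:
                baseline = model.fef_loop.fef_out.max()
            if baseline is not None and departure is None \
                    and model.fef_loop.fef_out.max() > baseline + 0.03:
                departure = t
        return departure

    dep = departure_time(True)
    dep_blind = departure_time(False)
    assert dep is not None and dep_blind is not None
    # the burst departs before the frontal visual volley could lift the
    # output (input arrives at 91 ms and passes one integration stage)
    assert dep < lat.latency_fef + 10
    # and it is not caused by that volley: removing the frontal visual
    # input entirely leaves the departure time unchanged
    assert abs(dep - dep_blind) <= 3
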