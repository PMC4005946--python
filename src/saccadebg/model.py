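"""Full saccade-selection model: three loops, two learners, one eye.

Wiring (per 1 ms step, all structures updated from the previous step's
values):

  retina --41ms--> SCs --+
  retina --91ms--> FEF_in -> FEF_out ----+--> SCi --> motor --> SBG --> eye
  retina --122ms-> V4 -> IT channels -> V4_out -+        ^
                                                         |
  spatial BG (shared by FEF and SC loops): salience =    |
      merge(actor . [reduce(Th_SC); reduce(FEF_in)]) + raw FEF term
      -> GPi|SNr -> expanded disinhibition gates FEF/Th, SCi and motor
  colour BG: salience = actor . colour-sums + IT_out feedback
      -> gates the IT thalamo-cortical amplification

The saturating burst terminator of the saccade generators is fed back as
SG_inhib to every visual input.  Learning (actor-critic per module) runs
continuously; reward is delivered as an impulse at trial end by the task
runner.

The seven map sheets are integrated by one fused kernel
(:mod:`saccadebg._kernels`); the modular implementations in
:mod:`saccadebg.loops` / :mod:`saccadebg.colliculus` define the reference
semantics and the test-suite holds the two paths together.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from ._kernels import fused_map_step
from .basal_ganglia import BGCircuit
from .colliculus import SCState, SaccadeGenerator
from .config import ModelConfig
from .learning import ActorState, CriticState, TrialAccumulator
from .loops import (ColorLoop, SpatialLoop, color_backproject,
                    color_channel_sum, merge_sigmoid)
from .retinotopy import (PyramidOps, blob_mass, coarse_n, diffuse_norm,
                         reduction_gain)

__all__ = ["SaccadeModel"]


class SaccadeModel:
    """The assembled model; owns all dynamic state and learned weights."""

    def __init__(self, config: Optional[ModelConfig] = None,
                 rng: Optional[np.random.Generator] = None,
                 learning: bool = True):
        self.cfg = config or ModelConfig.full()
        self.cfg.validate()
        rng = rng or np.random.default_rng()
        ret = self.cfg.retinotopy
        self.n = ret.n
        self.m = coarse_n(ret.n)
        self.n_coarse = 2 * self.m * self.m       # spatial BG channels
        self.n_learn = 2 * self.n_coarse           # concatenated input
        self.reduce_gain = reduction_gain(ret)
        self.input_gain_sc = self.reduce_gain * self.cfg.loops.w_learn_sc
        self.input_gain_fef = self.reduce_gain * self.cfg.loops.w_learn_fef
        self._blob_mass = blob_mass(ret)
        self._pyr = PyramidOps(ret.n)
        dt = self.cfg.dynamics.dt

        bg_sp_cfg = dataclasses.replace(self.cfg.bg_spatial,
                                        diffuse_norm=diffuse_norm(ret),
                                        variant="subcortical")
        self.bg_spatial = BGCircuit(self.n_coarse, bg_sp_cfg, dt)
        self.bg_color = BGCircuit(3, self.cfg.bg_color, dt)
        self.color_loop = ColorLoop(self.cfg.loops, dt)
        self.fef_loop = SpatialLoop(self.cfg.loops, self.n, dt)
        self.sc = SCState(self.cfg.sc_motor, self.n, dt)
        self.sbg = SaccadeGenerator(self.cfg.sc_motor, ret, dt)

        lc = self.cfg.learning
        self.actor_spatial = ActorState.init(self.n_learn, lc, lc.eta_spatial)
        self.actor_color = ActorState.init(3, lc, lc.eta_color)
        self.actor_color.w_max = lc.w_max_color
        self.critic_spatial = CriticState.init(
            self.n_learn, lc, lc.eta_critic_spatial, rng)
        self.critic_color = CriticState.init(3, lc, lc.eta_critic_color, rng)
        self._acc_spatial = TrialAccumulator(self.actor_spatial)
        self._acc_color = TrialAccumulator(self.actor_color)
        self.learning = learning

        #: colour-channel normalisation so one full blob sums to ~1
        self.color_norm = self.cfg.loops.color_sum_gain / self._blob_mass

        # kernel plumbing: flat views and packed gains
        self._flat = tuple(a.reshape(-1) for a in (
            self.sc.scs, self.sc.sci_out, self.sc.th, self.sc.motor,
            self.fef_loop.fef_in, self.fef_loop.fef_out, self.fef_loop.th))
        self._vec_x = np.ascontiguousarray(self.sbg.vec[..., 0].reshape(-1))
        self._vec_y = np.ascontiguousarray(self.sbg.vec[..., 1].reshape(-1))
        self._zero_map = np.zeros(2 * self.n * self.n)
        lcf, scc, dyn = self.cfg.loops, self.cfg.sc_motor, self.cfg.dynamics
        self._p = np.array([
            dyn.dt, scc.tau, scc.tau_scs, scc.tau_motor,
            scc.w_scs_sci, scc.w_fef_sci, scc.w_v4_sci, scc.w_sci_in,
            scc.w_bgamp_sci, scc.w_sciout_th, scc.w_gpi_th_sc,
            scc.w_trn_th_sc, scc.i_th, scc.w_bginhib_sci, scc.w_sat_mot,
            scc.w_opn_mot, lcf.w_fefin_fefout, lcf.w_th_fefout,
            lcf.w_fefout_th, lcf.w_gpi_th_fef, lcf.w_trn_th_fef, lcf.i_th,
            scc.w_sat_stop, lcf.tau])

        self._disinhib_sp = np.zeros(self.n_coarse)
        self._disinhib_fine = np.zeros(2 * self.n * self.n)
        self._sal_sp = np.zeros(self.n_coarse)
        self._sal_col = np.zeros(3)
        self._u_prev: Optional[np.ndarray] = None
        self._u3_prev: Optional[np.ndarray] = None
        self._credit_prev = np.zeros(self.n_learn)
        self._credit3_prev = np.zeros(3)
        self._w_sp = self.actor_spatial.w
        self._w_col = self.actor_color.w
        self._refresh_actor_cache()
        self._th_sc_max = 0.0
        self._th_fef_max = 0.0
        self._fef_in_max = 0.0
        self.probe: Optional[dict] = None

    def _refresh_actor_cache(self) -> None:
        idx = self.actor_spatial.touched_idx
        self._w_sp_idx = idx
        self._w_sp_active = (self.actor_spatial.w[idx].copy()
                             if idx.size else None)

    # ------------------------------------------------------------------
    def reset_trial(self) -> None:
        """Reset all dynamic state (a fresh fixation); weights persist.

        Thalamic maps and their reticular units start at the tonic-drive
        fixed point rather than zero, so a trial does not open with a
        map-wide thalamic transient.
        """
        self.bg_spatial.reset()
        self.bg_color.reset()
        self.color_loop.reset()
        self.fef_loop.reset()
        self.sc.reset()
        self.sbg.reset()
        scc, lcf = self.cfg.sc_motor, self.cfg.loops
        th_sc0 = scc.i_th / (1.0 + scc.w_trn_th_sc * scc.w_th_trn_sc)
        self.sc.th[:] = th_sc0
        self.sc.trn = scc.w_th_trn_sc * th_sc0
        th_f0 = lcf.i_th / (1.0 + lcf.w_trn_th_fef * lcf.w_th_trn_fef)
        self.fef_loop.th[:] = th_f0
        self.fef_loop.trn = lcf.w_th_trn_fef * th_f0
        th_c0 = lcf.i_th / (1.0 + lcf.w_trn_th_it * lcf.w_th_trn_it)
        self.color_loop.th[:] = th_c0
        self.color_loop.trn = lcf.w_th_trn_it * th_c0
        self._th_sc_max = th_sc0
        self._th_fef_max = th_f0
        self.critic_spatial.reset_trial()
        self.critic_color.reset_trial()
        self.actor_spatial.reset_trial()
        self.actor_color.reset_trial()
        self._acc_spatial.reset()
        self._acc_color.reset()
        self._disinhib_sp[:] = 0.0
        self._disinhib_fine[:] = 0.0
        self._sal_sp[:] = 0.0
        self._sal_col[:] = 0.0
        self._u_prev = None
        self._u3_prev = None
        self._credit_prev[:] = 0.0
        self._credit3_prev[:] = 0.0
        self._w_sp = self.actor_spatial.w
        self._w_col = self.actor_color.w
        self._refresh_actor_cache()
        self._th_sc_max = 0.0
        self._th_fef_max = 0.0
        self._fef_in_max = 0.0

    def apply_lesion(self, lesion: str) -> None:
        if lesion in ("fef", "fef_inactivation"):
            self.fef_loop.lesioned = True
            self.fef_loop.fef_out[:] = 0.0
        elif lesion == "none":
            self.fef_loop.lesioned = False
        else:
            raise ValueError(f"unknown lesion {lesion!r}")

    # ------------------------------------------------------------------
    def step(self, retina: np.ndarray, fef_visual: np.ndarray,
             v4_maps: np.ndarray, reward: float = 0.0) -> None:
        """Advance the whole model one integration step.

        The three visual arguments are the luminance map delayed by the
        SCs latency, the luminance map delayed by the FEF latency, and the
        per-colour maps delayed by the IT latency.  ``reward`` is the
        scalar reinforcement for this step (an impulse at trial end).
        """
        cfg = self.cfg
        lcf = cfg.loops
        sg = self.sbg.sg_inhib
        rest_sp = self.bg_spatial.gpi_rest
        rest_col = self.bg_color.gpi_rest

        # ---- colour pathway (previous-step cortical state) -----------
        it_out_prev = self.color_loop.it_out.copy()
        it_in = color_channel_sum(v4_maps, self.color_norm)
        if it_out_prev.max() > 1e-9:
            v4_out = color_backproject(v4_maps, it_out_prev).reshape(-1)
        else:
            v4_out = self._zero_map

        # ---- learning inputs / BG saliences from previous maps -------
        u_sc = self._pyr.reduce(self.sc.th).reshape(-1) * self.input_gain_sc
        if self._fef_in_max > 1e-9:
            u_fef = (self._pyr.reduce(self.fef_loop.fef_in).reshape(-1)
                     * self.input_gain_fef)
        else:
            u_fef = np.zeros(self.n_coarse)
        u = np.concatenate([u_sc, u_fef])
        u -= lcf.u_threshold
        np.clip(u, 0.0, None, out=u)
        u_fef = u[self.n_coarse:]
        # actor apply exploiting identity + touched-row structure
        a = u.copy()
        if self._w_sp_active is not None:
            a[self._w_sp_idx] = self._w_sp_active @ u
        merged = merge_sigmoid(a[:self.n_coarse] + a[self.n_coarse:],
                               lcf.merge_slope, lcf.merge_threshold)
        salience_sp = merged + lcf.w_raw_spatial * u_fef
        a3 = self._w_col @ it_in
        salience_col = a3 + lcf.w_itout_bg * it_out_prev
        # divisive normalisation at the colour-striatal input: the circuit
        # always competes relative saliences at its calibrated range
        peak = salience_col.max()
        if peak > 1.0:
            salience_col = salience_col / peak

        trn_sc_prev = self.sc.trn
        trn_fef_prev = self.fef_loop.trn
        th_sc_max = self._th_sc_max
        th_fef_max = self._th_fef_max

        # ---- colour loop (3-channel, modular) ------------------------
        self.color_loop.step(it_in, self.bg_color.gpi, rest_col, sg)

        # ---- BG circuits ---------------------------------------------
        # cortico-striatal integration: the BG track a low-passed salience
        dt = cfg.dynamics.dt
        self._sal_sp += dt / lcf.tau_salience * (salience_sp - self._sal_sp)
        self._sal_col += dt / lcf.tau_salience_color * (
            salience_col - self._sal_col)
        self.bg_spatial.step(self._sal_sp)
        self.bg_color.step(self._sal_col)

        # ---- fused map update ----------------------------------------
        gate_sc = max(0.0, 1.0 - cfg.sc_motor.w_sg_scs * sg)
        gate_sci = max(0.0, 1.0 - cfg.sc_motor.w_sg_sci * sg)
        gate_fef = max(0.0, 1.0 - lcf.w_sg_inhib * sg)
        f = self._flat
        motor_sum, bx, by, self._th_sc_max, self._th_fef_max, \
            self._fef_in_max = fused_map_step(
            f[0], f[1], f[2], f[3], f[4], f[5], f[6],
            retina.reshape(-1), fef_visual.reshape(-1), v4_out,
            self._disinhib_fine, self._vec_x, self._vec_y,
            gate_sc, gate_sci, gate_fef, trn_sc_prev, trn_fef_prev,
            self.sbg.sat, self.sbg.opn, rest_sp, self._p)
        if self.fef_loop.lesioned:
            self.fef_loop.fef_out[:] = 0.0

        # global reticular units (driven by the previous thalamic peaks)
        scc = cfg.sc_motor
        dt = cfg.dynamics.dt
        trn_sc = trn_sc_prev + dt / (2.0 * scc.tau) * (
            scc.w_th_trn_sc * th_sc_max - trn_sc_prev)
        self.sc.trn = min(max(trn_sc, 0.0), 1.0)
        trn_fef = trn_fef_prev + dt / lcf.tau_trn * (
            lcf.w_th_trn_fef * th_fef_max - trn_fef_prev)
        self.fef_loop.trn = min(max(trn_fef, 0.0), 1.0)

        # ---- burst generators / eye ----------------------------------
        self.sbg.step_from_sums(motor_sum, bx, by)

        # ---- selection state for the next step -----------------------
        np.clip(1.0 - self.bg_spatial.gpi / rest_sp, 0.0, 1.0,
                out=self._disinhib_sp)
        d_peak = self._disinhib_sp.max()
        if d_peak > 1e-9:
            fine = self._pyr.expand(
                self._disinhib_sp.reshape(2, self.m, self.m)).reshape(-1)
            # renormalise: expansion smooths an isolated selected channel
            # well below 1; the gates downstream read the selection
            # amplitude, so restore the coarse peak
            fp = fine.max()
            if fp > 1e-12:
                fine *= 1.4 * d_peak / fp
                np.clip(fine, 0.0, 1.0, out=fine)
            self._disinhib_fine = fine
        else:
            self._disinhib_fine = np.zeros(2 * self.n * self.n)
        disinhib_col = self.bg_color.selection_state()

        # ---- actor-critic --------------------------------------------
        if self.learning:
            self._learn_step(u, it_in, reward, disinhib_col)
        else:
            self._u_prev = self._critic_input(u)
            self._u3_prev = self._critic_input(it_in)
            self._store_credit(disinhib_col)

        if self.probe is not None:
            self._record_probe(it_in, salience_sp, v4_out)

    # ------------------------------------------------------------------
    def _credit_vectors(self, disinhib_col: np.ndarray):
        if self.cfg.learning.credit == "disinhibition":
            # credit flows to committed selections; transient partial dips
            # of the output nuclei during the competition carry none
            floor = 0.75
            d = np.clip((self._disinhib_sp - floor) / (1.0 - floor), 0.0, 1.0)
            cr_sp = np.tile(d, 2)
            cr_col = np.clip((disinhib_col - floor) / (1.0 - floor), 0.0, 1.0)
        else:  # literal pallidal output
            cr_sp = np.tile(self.bg_spatial.gpi, 2)
            cr_col = self.bg_color.gpi.copy()
        return cr_sp, cr_col

    def _store_credit(self, disinhib_col: np.ndarray) -> None:
        self._credit_prev, self._credit3_prev = self._credit_vectors(
            disinhib_col)

    @staticmethod
    def _critic_input(u: np.ndarray) -> np.ndarray:
        # peak-normalised copy: the value estimate stays calibrated as
        # learning amplifies the raw input scale
        peak = u.max()
        return u / peak if peak > 1.0 else u

    def _learn_step(self, u: np.ndarray, u3: np.ndarray, reward: float,
                    disinhib_col: np.ndarray) -> None:
        lc = self.cfg.learning
        u = self._critic_input(u)
        u3 = self._critic_input(u3)
        for critic, acc, u_now, u_prev, credit_prev in (
                (self.critic_spatial, self._acc_spatial, u, self._u_prev,
                 self._credit_prev),
                (self.critic_color, self._acc_color, u3, self._u3_prev,
                 self._credit3_prev)):
            v_now = critic.value(u_now)
            delta = reward + lc.gamma * v_now - critic.v_prev
            delta = min(max(delta, -lc.delta_clip), lc.delta_clip)
            if u_prev is not None:
                critic.e *= critic.lam
                critic.e += u_prev
                critic.w += critic.eta * delta * critic.e
                acc.record(u_prev, credit_prev, delta)
            critic.v_prev = v_now
        self._u_prev, self._u3_prev = u, u3
        self._store_credit(disinhib_col)

    def end_trial(self, reward: float) -> None:
        """Terminal learning update: reward impulse, commit, trace reset.

        The reward is delivered on the first step after the trial ends,
        against a terminal value of zero.
        """
        if self.learning and self._u_prev is not None:
            for critic, acc, u_prev, credit_prev in (
                    (self.critic_spatial, self._acc_spatial, self._u_prev,
                     self._credit_prev),
                    (self.critic_color, self._acc_color, self._u3_prev,
                     self._credit3_prev)):
                lc = self.cfg.learning
                delta = reward - critic.v_prev
                delta = min(max(delta, -lc.delta_clip), lc.delta_clip)
                critic.e *= critic.lam
                critic.e += u_prev
                critic.w += critic.eta * delta * critic.e
                acc.record(u_prev, credit_prev, delta)
                acc.commit()

    # ------------------------------------------------------------------
    def _record_probe(self, it_in, salience_sp, v4_out) -> None:
        p = self.probe
        p.setdefault("scs", []).append(float(self.sc.scs.max()))
        p.setdefault("fef_in", []).append(float(self.fef_loop.fef_in.max()))
        p.setdefault("fef_out", []).append(float(self.fef_loop.fef_out.max()))
        p.setdefault("it_in", []).append(float(np.max(it_in)))
        p.setdefault("it_out", []).append(float(self.color_loop.it_out.max()))
        p.setdefault("v4_out", []).append(float(np.max(v4_out)))
        p.setdefault("th_sc", []).append(float(self.sc.th.max()))
        p.setdefault("sci", []).append(float(self.sc.sci_out.max()))
        p.setdefault("motor", []).append(float(self.sc.motor.sum()))
        p.setdefault("salience", []).append(float(np.max(salience_sp)))
        p.setdefault("disinhib", []).append(float(self._disinhib_sp.max()))
        p.setdefault("sat", []).append(self.sbg.sat)
        p.setdefault("opn", []).append(self.sbg.opn)
        p.setdefault("eye_x", []).append(float(self.sbg.eye[0]))
        p.setdefault("eye_y", []).append(float(self.sbg.eye[1]))
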