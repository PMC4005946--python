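"""Trial protocol, tasks, experiment runner and analysis surface.

A trial follows a fixed timeline: 50 ms black screen, 800 ms central
fixation cue, a random 150-250 ms gap with no stimuli, then two lateral
cues (one red, one green, sides randomised) for at most 600 ms.  Perceptual
noise makes one cue slightly more salient than the other (amplitudes 1.0
and 0.95, randomly assigned) -- the only source of exploration for the
learner.  A saccade is detected when the eye leaves a 2.5 degree circle
around the centre; the trial then runs a short tail so the burst can
finish, reward is delivered according to the task rule, and the learning
modules commit.

Three tasks share this protocol and differ only in the reward rule:
``spatial`` (saccade to the designated side, any colour), ``color``
(saccade to the designated colour, any side) and ``conjunction`` (saccade
to the designated colour at the designated side; when that conjunction is
absent, reward for keeping the eyes within the central circle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .colliculus import SaccadeEvent
from .config import ConfigurationError, ExperimentConfig, ModelConfig, TaskConfig
from .model import SaccadeModel
from .retinotopy import RenderedScene, VisualTarget, render_stimulus

logger = logging.getLogger(__name__)

OUTCOMES = ("correct", "spatial_error", "color_error", "good_average",
            "bad_average", "bad_saccade", "no_saccade")


@dataclass
class TaskSpec:
    """Which cue is rewarded."""

    kind: str = "spatial"  # spatial | color | conjunction
    rewarded_side: int = +1  # +1 right, -1 left
    rewarded_color: str = "red"

    def __post_init__(self):
        if self.kind not in ("spatial", "color", "conjunction"):
            raise ConfigurationError(f"unknown task kind {self.kind!r}")


@dataclass
class Cue:
    side: int
    color: str
    intensity: float
    x: float
    y: float = 0.0


@dataclass
class TrialSchedule:
    """Pre-rendered, time-indexed scene plus trial metadata."""

    cfg: TaskConfig
    gap: float
    cues: list[Cue]
    conj_present: bool
    t_cue_on: float
    phases: list[tuple[float, float, RenderedScene]]
    empty: RenderedScene

    def scene_at(self, t: float) -> RenderedScene:
        """Scene visible at time t (ms from trial start); empty before 0."""
        if t < 0:
            return self.empty
        for t0, t1, scene in self.phases:
            if t0 <= t < t1:
                return scene
        return self.empty


def build_trial(spec: TaskSpec, cfg: ModelConfig,
                rng: np.random.Generator) -> TrialSchedule:
    """Draw one trial: gap duration, cue layout and noise assignment."""
    tc = cfg.task
    gap = float(rng.uniform(tc.gap_min, tc.gap_max))
    # one red and one green cue; sides and noise independently randomised
    red_side = 1 if rng.random() < 0.5 else -1
    high_side = 1 if rng.random() < 0.5 else -1
    cues = []
    for side in (-1, +1):
        color = "red" if side == red_side else "green"
        inten = tc.noise_high if side == high_side else tc.noise_low
        cues.append(Cue(side=side, color=color, intensity=inten,
                        x=side * tc.cue_eccentricity))
    conj_present = any(c.side == spec.rewarded_side
                       and c.color == spec.rewarded_color for c in cues)

    ret = cfg.retinotopy
    empty = render_stimulus([], ret)
    fix = render_stimulus(
        [VisualTarget(0.0, 0.0, "white", tc.fixation_intensity)], ret)
    cue_scene = render_stimulus(
        [VisualTarget(c.x, c.y, c.color, c.intensity) for c in cues], ret)
    t_fix_on = tc.t_black
    t_fix_off = t_fix_on + tc.t_fixation
    t_cue_on = t_fix_off + gap
    phases = [(0.0, t_fix_on, empty),
              (t_fix_on, t_fix_off, fix),
              (t_fix_off, t_cue_on, empty),
              (t_cue_on, t_cue_on + tc.t_cue_max, cue_scene)]
    return TrialSchedule(cfg=tc, gap=gap, cues=cues,
                         conj_present=conj_present, t_cue_on=t_cue_on,
                         phases=phases, empty=empty)


# ---------------------------------------------------------------------------
# outcome classification and reward
# ---------------------------------------------------------------------------

def classify_outcome(spec: TaskSpec, schedule: TrialSchedule,
                     event: Optional[SaccadeEvent],
                     final_eye: tuple[float, float],
                     radius: float) -> tuple[str, float]:
    """Map a trial's motor outcome to an outcome class and its reward.

    Classes are mutually exclusive and exhaustive: a detected saccade is
    attributed to the cue (or the centre circle) its landing point falls
    in; anywhere else is a bad saccade.  Without a detected saccade the
    trial is a no-saccade (rewarded as a "good average" in the
    no-conjunction case if the eye stayed central).
    """
    dist_centre = math.hypot(*final_eye)
    if event is None:
        if spec.kind == "conjunction" and not schedule.conj_present \
                and dist_centre <= radius:
            return "good_average", 1.0
        return "no_saccade", 0.0

    lx, ly = event.landing
    chosen = None
    for cue in schedule.cues:
        if math.hypot(lx - cue.x, ly - cue.y) <= radius:
            chosen = cue
            break
    if chosen is None:
        if dist_centre <= radius:
            if spec.kind == "conjunction":
                if schedule.conj_present:
                    return "bad_average", 0.0
                return "good_average", 1.0
            return "bad_average", 0.0
        return "bad_saccade", 0.0

    if spec.kind == "spatial":
        if chosen.side == spec.rewarded_side:
            return "correct", 1.0
        return "spatial_error", 0.0
    if spec.kind == "color":
        if chosen.color == spec.rewarded_color:
            return "correct", 1.0
        return "color_error", 0.0
    # conjunction
    side_ok = chosen.side == spec.rewarded_side
    color_ok = chosen.color == spec.rewarded_color
    if schedule.conj_present:
        if side_ok and color_ok:
            return "correct", 1.0
        if side_ok:
            return "color_error", 0.0
        return "spatial_error", 0.0
    # no-conjunction case: any saccade to a cue is an error
    if side_ok:
        return "color_error", 0.0
    return "spatial_error", 0.0


# ---------------------------------------------------------------------------
# trial and experiment runners
# ---------------------------------------------------------------------------

def run_trial(model: SaccadeModel, spec: TaskSpec,
              schedule: TrialSchedule) -> dict:
    """Simulate one full trial; returns a flat record dict.

    Steps the model at dt through black/fixation/gap/cue phases, feeding
    each pathway the scene as it was one pathway-latency ago, detects the
    choice saccade, classifies it, and delivers the terminal reward.
    """
    cfg = model.cfg
    dt = cfg.dynamics.dt
    lat = cfg.dynamics
    tc = schedule.cfg
    radius = cfg.sc_motor.detection_radius
    model.reset_trial()

    t = 0.0
    t_end = schedule.t_cue_on + tc.t_cue_max
    event: Optional[SaccadeEvent] = None
    onset_t: Optional[float] = None
    t_stop = t_end
    learning = model.learning
    while t < t_stop:
        s_scs = schedule.scene_at(t - lat.latency_scs)
        s_fef = schedule.scene_at(t - lat.latency_fef)
        s_it = schedule.scene_at(t - lat.latency_it)
        model.step(s_scs.lum, s_fef.lum, s_it.color)
        t += dt
        if onset_t is None and t > schedule.t_cue_on:
            ex, ey = model.sbg.eye
            if math.hypot(ex, ey) > radius:
                onset_t = t
                t_stop = min(t_end, t + tc.t_post)
                # the choice is made: outcome reinforcement applies to the
                # eligibility accumulated up to this point, not to the
                # saccadic tail where the gated inputs collapse
                model.learning = False
        if not np.isfinite(model.sbg.eye).all():
            raise FloatingPointError("simulation diverged (NaN eye position)")
    model.learning = learning

    final_eye = (float(model.sbg.eye[0]), float(model.sbg.eye[1]))
    if onset_t is not None:
        amp = math.hypot(*final_eye)
        event = SaccadeEvent(
            srt=onset_t - schedule.t_cue_on, amplitude=amp,
            direction=math.degrees(math.atan2(final_eye[1], final_eye[0])),
            landing=final_eye)
    outcome, reward = classify_outcome(spec, schedule, event, final_eye,
                                       radius)
    model.end_trial(reward)

    high_cue = next(c for c in schedule.cues
                    if c.intensity >= schedule.cfg.noise_high)
    wrong_cues = [c for c in schedule.cues
                  if (spec.kind == "color" and c.color != spec.rewarded_color)]
    return {
        "outcome": outcome,
        "reward": reward,
        "srt": event.srt if event else math.nan,
        "landing_x": final_eye[0],
        "landing_y": final_eye[1],
        "amplitude": event.amplitude if event else 0.0,
        "gap": schedule.gap,
        "conj_present": schedule.conj_present,
        "high_side": high_cue.side,
        "distractor_high": bool(wrong_cues
                                and wrong_cues[0].side == high_cue.side),
    }


def run_experiment(exp: ExperimentConfig, spec: TaskSpec,
                   cfg: Optional[ModelConfig] = None, seed: int = 0,
                   keep_models: bool = False):
    """Run ``runs`` independent learning experiments of the given task.

    Each run starts from fresh weights (critic initialisation drawn from
    the run's RNG) and loops ``sessions`` x ``trials_per_session`` trials.
    Returns a tidy DataFrame of trial records (and the trained models if
    ``keep_models``).  Fully reproducible given ``seed``.
    """
    cfg = cfg or ModelConfig.preset(exp.scale)
    records = []
    models = []
    for run in range(exp.runs):
        rng = np.random.default_rng((seed, run))
        model = SaccadeModel(cfg, rng=rng)
        if exp.lesion != "none":
            model.apply_lesion(exp.lesion)
        for session in range(exp.sessions):
            for trial in range(exp.trials_per_session):
                schedule = build_trial(spec, cfg, rng)
                rec = run_trial(model, spec, schedule)
                rec.update(run=run, session=session, trial=trial,
                           task=spec.kind, lesion=exp.lesion)
                records.append(rec)
            logger.debug("run %d session %d done", run, session)
        if keep_models:
            models.append(model)
    df = pd.DataFrame.from_records(records)
    if keep_models:
        return df, models
    return df


def apply_lesion(model: SaccadeModel, lesion: str = "fef_inactivation"
                 ) -> SaccadeModel:
    """Clamp FEF output to zero (reversible with lesion='none')."""
    model.apply_lesion(lesion)
    return model


# ---------------------------------------------------------------------------
# analysis surface
# ---------------------------------------------------------------------------

def srt_histogram(srts, bin_width: float = 8.0,
                  min_frac: float = 0.05):
    """Histogram SRTs and locate modes (local maxima above a threshold).

    Returns (counts, bin_edges, modes) where ``modes`` is the list of bin
    centres that are local maxima with at least ``min_frac`` of the total
    count, sorted by latency.
    """
    srts = np.asarray([s for s in np.ravel(srts) if np.isfinite(s)])
    if srts.size == 0:
        return np.array([]), np.array([]), []
    lo = math.floor(srts.min() / bin_width) * bin_width
    hi = math.ceil(srts.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(srts, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    thresh = max(1.0, min_frac * counts.sum())
    modes = []
    padded = np.concatenate([[0], counts, [0]])
    for i in range(len(counts)):
        if counts[i] >= thresh and padded[i] <= counts[i] >= padded[i + 2]:
            # merge plateaus: keep only the first bin of equal neighbours
            if modes and abs(modes[-1] - centres[i]) <= bin_width and \
                    counts[i] == counts[int((modes[-1] - lo) // bin_width)]:
                continue
            modes.append(float(centres[i]))
    return counts, edges, modes


def srt_mode(srts, bin_width: float = 8.0) -> float:
    """Location of the highest-count SRT bin (refined by local mean)."""
    srts = np.asarray([s for s in np.ravel(srts) if np.isfinite(s)])
    if srts.size == 0:
        return math.nan
    counts, edges = np.histogram(
        srts, bins=np.arange(srts.min() - bin_width,
                             srts.max() + 2 * bin_width, bin_width))
    i = int(np.argmax(counts))
    in_bin = srts[(srts >= edges[i]) & (srts < edges[i + 1])]
    return float(in_bin.mean())


def performance_curve(df: pd.DataFrame) -> pd.DataFrame:
    """Per-session fraction of each outcome class, averaged over runs.

    Returns a DataFrame indexed by session with one column per outcome
    class plus ``reward`` (fraction of rewarded trials); fractions sum to
    one per session.
    """
    rows = []
    for session, grp in df.groupby("session"):
        per_run = []
        for _, g in grp.groupby("run"):
            frac = {o: float((g["outcome"] == o).mean()) for o in OUTCOMES}
            frac["reward"] = float(g["reward"].mean())
            per_run.append(frac)
        mean = {k: float(np.mean([r[k] for r in per_run]))
                for k in per_run[0]}
        mean["session"] = session
        rows.append(mean)
    return pd.DataFrame(rows).set_index("session")


def weight_map_summary(actor, m: int) -> dict[str, np.ndarray]:
    """Per-unit summed input weights, split into SC and FEF portions.

    For each coarse unit the sum of all actor weights in its input column
    (the quantity plotted as a learned-weight map); identity weights give
    uniform maps of 1.  Returns maps of shape (2, m, m).
    """
    w = actor.w
    n_half = w.shape[1] // 2
    col_sums = w.sum(axis=0)
    return {
        "sc": col_sums[:n_half].reshape(2, m, m),
        "fef": col_sums[n_half:].reshape(2, m, m),
    }
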