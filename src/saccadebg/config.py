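"""Model configuration.

Every tunable quantity of the model lives here, grouped by subsystem, with
the defaults used throughout the test-suite and the experiments.  Configs are
plain dataclasses; they can be round-tripped through YAML so an experiment is
fully described by one file plus a seed.

Two presets are provided: ``full`` (70x70 maps per hemifield, the resolution
used for reaction-time analyses) and ``reduced`` (36x36 maps, used for
desk-scale learning experiments).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a parameter value makes the model ill-defined."""


@dataclass
class DynamicsConfig:
    """Integration step and sensory pathway latencies (ms)."""

    dt: float = 1.0
    #: default membrane time constant for map units (ms)
    tau: float = 10.0
    #: retina -> superficial superior colliculus latency
    latency_scs: float = 41.0
    #: retina -> frontal eye field latency
    latency_fef: float = 91.0
    #: retina -> V4/IT (colour pathway) latency
    latency_it: float = 122.0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")


@dataclass
class RetinotopyConfig:
    """Complex-log mapping of the visual hemifield onto an n x n grid.

    The mapping constants follow the macaque collicular fit (shear A in
    degrees, scales Bx/By in map millimetres); the grid covers eccentricities
    up to ``r_max`` degrees.
    """

    n: int = 70
    A: float = 3.0
    Bx: float = 1.4
    By: float = 1.8
    r_max: float = 45.0
    #: Gaussian stimulus spread in grid cells (~100 units above 1% of peak
    #: on the 70x70 grid).  Fixed in cells, not in degrees, so the blob
    #: geometry seen by the coarse selection channels is the same at every
    #: grid resolution.
    sigma: float = 1.9
    #: eccentricity (deg) at which the channel-path gain is calibrated;
    #: matches the task cue eccentricity
    calib_eccentricity: float = 10.0
    #: gain applied after pyramid reduction on basal-ganglia input paths,
    #: calibrated so a full-intensity blob keeps a coarse peak of ~1
    #: (amplitude-based selection thresholds then apply across scales);
    #: None = calibrate automatically from the blob shape
    reduce_gain: float | None = None

    @property
    def u_max(self) -> float:
        import math

        r, a = self.r_max, self.A
        return self.Bx * math.log(math.sqrt(r * r + 2 * a * r + a * a) / a)

    @property
    def v_max(self) -> float:
        import math

        return self.By * math.pi / 2.0

    def validate(self) -> None:
        if self.n < 8:
            raise ConfigurationError("grid too small")
        if self.A <= 0 or self.Bx <= 0 or self.By <= 0:
            raise ConfigurationError("mapping constants must be positive")


@dataclass
class BGConfig:
    """Gains of one basal-ganglia selection circuit.

    The circuit competes ``n_channels`` options through focused striatal
    inhibition of GPi/SNr against diffuse subthalamic excitation.  The same
    structure is instantiated twice: once over coarse spatial channels and
    once over the three colour channels (which uses a larger diffuse gain,
    see :mod:`saccadebg.basal_ganglia`).
    """

    # cortex/thalamus -> striatum / STN
    w_in_d1: float = 3.065
    w_in_d2: float = 4.0
    w_in_fs: float = 6.0
    w_in_stn: float = 0.555
    # fast-spiking interneuron feedforward inhibition
    w_fs_d1: float = 1.158
    w_fs_d2: float = 1.8
    # subthalamo-pallidal diffuse excitation (one-to-all)
    w_stn_gpi: float = 2.939
    w_stn_gpe: float = 0.172
    # pallidal feedback
    w_gpe_stn: float = 0.409
    w_gpe_gpi: float = 0.360
    # focused (one-to-one) striatal inhibition
    w_d1_gpi: float = 3.630
    w_d2_gpe: float = 1.0
    # tonic drives
    i_gpe: float = 0.3
    i_gpi: float = 0.599
    #: multiplier on the summed STN output feeding the diffuse projections;
    #: set at model build so the diffuse drive per stimulus is independent
    #: of the grid resolution (1 for the reference grid / colour channels)
    diffuse_norm: float = 1.0
    #: saturation of the summed subthalamic drive: pathological all-out
    #: co-activation cannot push the output nuclei into a global collapse
    stn_sum_max: float = 2.5
    # saturation bounds
    d1_max: float = 4.0
    d2_max: float = 2.0
    stn_max: float = 1.0
    fs_max: float = 1.0
    gpe_max: float = 1.0
    gpi_max: float = 2.0
    # time constants (ms)
    tau: float = 8.0
    #: cortical loops close through thalamus on the output side, the
    #: subcortical loop receives its input through thalamus (wiring flag
    #: carried by the owning loop; kept here for introspection)
    variant: str = "cortical"

    @property
    def gpe_rest(self) -> float:
        return min(max(self.i_gpe, 0.0), self.gpe_max)

    @property
    def gpi_rest(self) -> float:
        rest = self.i_gpi - self.w_gpe_gpi * self.gpe_rest
        return min(max(rest, 0.0), self.gpi_max)

    def validate(self) -> None:
        if self.gpi_rest <= 0:
            raise ConfigurationError("BG rest inhibition must be positive")


@dataclass
class LoopsConfig:
    """Gains of the cortico-thalamic colour (V4|IT) and spatial (FEF) loops."""

    # ---- colour loop -------------------------------------------------
    w_itin_itout: float = 0.25
    w_th_itout: float = 0.8
    w_itout_th: float = 0.35
    w_gpi_th_it: float = 1.1
    w_trn_th_it: float = 0.6
    w_th_trn_it: float = 0.5
    #: colour-channel normalisation: one full-intensity blob sums to ~1
    #: (set at run time from the blob mass; this is a multiplier on that)
    color_sum_gain: float = 1.0
    #: weight of the IT_out feedback term in the colour BG salience
    w_itout_bg: float = 0.12
    # ---- spatial FEF loop --------------------------------------------
    w_fefin_fefout: float = 0.3
    w_th_fefout: float = 0.8
    w_fefout_th: float = 0.35
    w_gpi_th_fef: float = 1.1
    w_trn_th_fef: float = 0.6
    w_th_trn_fef: float = 0.5
    # ---- shared -------------------------------------------------------
    i_th: float = 0.08
    w_sg_inhib: float = 1.0
    #: merge sigmoid (minimal-salience threshold non-linearity)
    merge_slope: float = 15.0
    merge_threshold: float = 0.95
    #: gains on the two halves of the concatenated learning input
    #: (relative to the calibrated unit-peak coarse maps); < 1 so an
    #: untrained (identity-actor) model selects only once several pathways
    #: are active
    w_learn_sc: float = 1.2
    w_learn_fef: float = 0.5
    #: activation threshold on the learning input (striatal input stage):
    #: tonic map baselines carry no salience and no eligibility
    u_threshold: float = 0.05
    #: cortico-striatal input integration (ms): the BG see a low-pass
    #: filtered salience, which makes selection latency fall steeply with
    #: salience (the substrate of the express/regular latency contrast).
    #: The colour circuit has its own constant (3 channels, no spatial
    #: grid, hence no resolution correction).
    tau_salience: float = 30.0
    tau_salience_color: float = 20.0
    #: cortical map integration (ms); the colour channels keep their own
    tau_color: float = 9.0
    #: raw (unlearned) input paths feeding the BG alongside the merged
    #: actor-weighted maps, so that an untrained model still selects
    w_raw_spatial: float = 0.25
    tau: float = 9.0
    tau_trn: float = 15.0


@dataclass
class SCMotorConfig:
    """Deep superior colliculus, motor map and saccade burst generators."""

    # afferents onto SCi (Eq-level gains)
    w_scs_sci: float = 0.65
    w_fef_sci: float = 0.8
    w_v4_sci: float = 1.8
    #: baseline transmission and BG-controlled amplification of SCi
    w_sci_in: float = 0.3
    w_bgamp_sci: float = 2.0
    # thalamic loop of the subcortical circuit (low tonic baseline: the
    # subcortical thalamus is driven by SCi, not by its own resonance)
    i_th: float = 0.01
    w_sciout_th: float = 1.2
    w_gpi_th_sc: float = 1.1
    w_trn_th_sc: float = 0.6
    w_th_trn_sc: float = 0.3
    #: saccade-execution gating of the retinal and SCi drives (the motor
    #: projection has its own Sat gate, so these are partial to avoid a
    #: compound choke that would truncate the burst mid-flight)
    w_sg_scs: float = 0.5
    w_sg_sci: float = 0.5
    # motor-layer drive
    w_bginhib_sci: float = 2.0
    #: subtractive stop on the motor map once the saturating terminator is
    #: engaged (cuts the post-saccadic motor tail)
    w_sat_stop: float = 3.0
    w_sat_mot: float = 1.0
    w_opn_mot: float = 0.6
    # omnipause latch
    i_opn: float = 1.0
    w_mot_opn: float = 8.0
    tau_opn: float = 5.0
    # saturating burst terminator (integration rate per unit motor mass)
    sat_rate: float = 0.2
    tau_sat_decay: float = 40.0
    #: displacement calibration: eye velocity is burst_cal * sat_rate /
    #: blob_mass per unit of (motor activity x encoded vector), which makes
    #: total displacement track the population vector independently of
    #: burst intensity (see colliculus module docstring)
    burst_cal: float = 1.7
    tau: float = 9.0
    tau_motor: float = 6.0
    tau_scs: float = 3.0
    #: saccade detection radius (deg from centre)
    detection_radius: float = 2.5

    def validate(self) -> None:
        if self.detection_radius <= 0:
            raise ConfigurationError("detection radius must be positive")


@dataclass
class LearningConfig:
    """Actor-critic TD(lambda) hyper-parameters.

    gamma/lambda/alpha are per-millisecond-step factors; they are close to 1
    so that eligibility bridges the ~500 ms between cue onset and reward.
    """

    gamma: float = 1.0
    lam: float = 0.99
    #: actor trace decay; defaults to lam (no separate value is defined)
    alpha: float = 0.99
    eta_spatial: float = 0.002
    eta_color: float = 0.001
    eta_critic_spatial: float = 0.0001
    eta_critic_color: float = 0.0003
    #: floor on the actor diagonal: the model must never lose the ability
    #: to trigger saccades
    w_min_diag: float = 0.6
    #: saturation bound on actor weights (synaptic ceiling; safely above
    #: the learned-weight scale the tasks produce); the colour module has
    #: a near-identity ceiling, matching the scale its learned weights
    #: settle at
    w_max: float = 8.0
    w_max_color: float = 1.6
    #: credit signal fed to the actor trace: "disinhibition" (1 - GPi/rest,
    #: credit flows to selected channels) or "gpi" (raw pallidal output)
    credit: str = "disinhibition"
    #: TD error is clipped to this magnitude (numerical guard against
    #: runaway value feedback)
    delta_clip: float = 10.0
    #: critic weights start uniform in [0, critic_init]
    critic_init: float = 0.01

    def validate(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ConfigurationError("gamma must be in (0, 1]")
        if self.credit not in ("disinhibition", "gpi"):
            raise ConfigurationError("credit must be 'disinhibition' or 'gpi'")


@dataclass
class TaskConfig:
    """Trial protocol timing (ms) and geometry (deg)."""

    t_black: float = 50.0
    t_fixation: float = 800.0
    gap_min: float = 150.0
    gap_max: float = 250.0
    t_cue_max: float = 600.0
    #: extra simulated time after saccade detection, letting the burst finish
    t_post: float = 80.0
    cue_eccentricity: float = 10.0
    fixation_intensity: float = 0.7
    noise_high: float = 1.0
    noise_low: float = 0.95


@dataclass
class ExperimentConfig:
    runs: int = 10
    sessions: int = 40
    trials_per_session: int = 12
    lesion: str = "none"  # none | fef_inactivation
    scale: str = "full"  # full | reduced


@dataclass
class ModelConfig:
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    retinotopy: RetinotopyConfig = field(default_factory=RetinotopyConfig)
    bg_spatial: BGConfig = field(default_factory=BGConfig)
    bg_color: BGConfig = field(default_factory=lambda: BGConfig(
        w_stn_gpi=5.578, w_stn_gpe=0.269, variant="cortical"))
    loops: LoopsConfig = field(default_factory=LoopsConfig)
    sc_motor: SCMotorConfig = field(default_factory=SCMotorConfig)
    learning: LearningConfig = field(default_factory=LearningConfig)
    task: TaskConfig = field(default_factory=TaskConfig)

    def validate(self) -> None:
        self.dynamics.validate()
        self.retinotopy.validate()
        self.bg_spatial.validate()
        self.bg_color.validate()
        self.sc_motor.validate()
        self.learning.validate()

    # ---- presets ------------------------------------------------------
    @classmethod
    def full(cls) -> "ModelConfig":
        return cls()

    @classmethod
    def reduced(cls) -> "ModelConfig":
        cfg = cls()
        cfg.retinotopy.n = 36
        # resolution calibrations: the coarser selection grid commits
        # earlier for the same inputs (longer cortico-striatal integration
        # restores the latency law), and credit concentrates on ~4x fewer
        # channels (per-weight learning rates scaled down accordingly)
        cfg.loops.tau_salience = 52.0
        cfg.loops.tau_salience_color = 24.0
        cfg.learning.eta_spatial /= 8.0
        cfg.learning.eta_critic_spatial /= 1.7
        return cfg

    @classmethod
    def preset(cls, name: str) -> "ModelConfig":
        if name == "full":
            return cls.full()
        if name == "reduced":
            return cls.reduced()
        raise ConfigurationError(f"unknown preset {name!r}")

    # ---- (de)serialisation -------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        cfg = cls()
        for section_name, section in d.items():
            target = getattr(cfg, section_name, None)
            if target is None:
                raise ConfigurationError(f"unknown config section {section_name!r}")
            for key, value in section.items():
                if not hasattr(target, key):
                    raise ConfigurationError(
                        f"unknown key {key!r} in section {section_name!r}")
                setattr(target, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
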