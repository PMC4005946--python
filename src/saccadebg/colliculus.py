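"""Deep superior colliculus, motor map and saccade burst generators.

The intermediate-layer visual map (SCi) sums its three afferent streams --
retinal input relayed by the superficial layers (SCs), FEF output and the
colour-selected V4 output -- and passes them through a multiplicative gate
controlled by the spatial basal ganglia: a small base transmission plus a
strong disinhibition-controlled amplification.  Its thalamic relay closes
the subcortical selection loop (the spatial BG circuit is shared with the
FEF loop).

The motor map receives the SCi activity through a second multiplicative
chain: residual nigral inhibition, the saturating burst terminator (Sat)
and a subtractive omnipause (OPN) veto.  OPN behaves as a latch: tonically
active, it collapses once summed motor activity breaks through, which
releases the full burst.  Each motor unit encodes the displacement vector
of its map position (inverse complex-log mapping); the burst generators
integrate the population drive into eye velocity (the spatio-temporal
transformation), while Sat integrates total motor activity and chokes the
burst after a fixed integrated mass -- making saccade amplitude depend on
*where* the burst sits on the map, not on how intense it is.  Sat is also
exported as the ascending saccade-execution signal (SG_inhib) that gates
every visual input during the movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import RetinotopyConfig, SCMotorConfig
from .dynamics import lpds_step_
from .retinotopy import blob_mass, efferent_vectors

__all__ = ["SCState", "SaccadeGenerator", "SaccadeEvent", "detect_saccade"]


@dataclass
class SaccadeEvent:
    """One detected saccade: onset (ms from cue onset), metrics, landing."""

    srt: float
    amplitude: float
    direction: float
    landing: tuple[float, float]


@dataclass
class SCState:
    """SCi visual map, subcortical thalamic relay and motor map."""

    cfg: SCMotorConfig
    n: int = 70
    dt: float = 1.0
    scs: np.ndarray = field(default=None)  # type: ignore[assignment]
    sci_out: np.ndarray = field(default=None)  # type: ignore[assignment]
    th: np.ndarray = field(default=None)  # type: ignore[assignment]
    trn: float = 0.0
    motor: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        shape = (2, self.n, self.n)
        for name in ("scs", "sci_out", "th", "motor"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(shape))

    def reset(self) -> None:
        for name in ("scs", "sci_out", "th", "motor"):
            getattr(self, name)[:] = 0.0
        self.trn = 0.0

    def step_visual(self, retina: np.ndarray, fef_out: np.ndarray,
                    v4_out: np.ndarray, disinhib_map: np.ndarray,
                    sg_inhib: float) -> None:
        """Advance SCs, SCi and the collicular thalamus one step.

        ``retina`` is the luminance map delayed by the retino-collicular
        latency; ``disinhib_map`` the expanded spatial BG release (2,n,n).
        """
        c, dt = self.cfg, self.dt
        gate = max(0.0, 1.0 - c.w_sg_scs * sg_inhib)
        gate_sci = max(0.0, 1.0 - c.w_sg_sci * sg_inhib)
        scs_prev = self.scs.copy()
        sci_prev = self.sci_out.copy()
        th_prev = self.th.copy()
        trn_prev = self.trn

        lpds_step_(self.scs, retina * gate, c.tau_scs, dt)

        afferent = (c.w_scs_sci * scs_prev + c.w_fef_sci * fef_out
                    + c.w_v4_sci * v4_out)
        amplif = c.w_sci_in + c.w_bgamp_sci * disinhib_map
        lpds_step_(self.sci_out, afferent * amplif * gate_sci, c.tau, dt)

        drive_th = (sci_prev * (c.w_sciout_th + c.w_gpi_th_sc * disinhib_map)
                    - c.w_trn_th_sc * trn_prev + c.i_th)
        lpds_step_(self.th, drive_th, c.tau, dt)
        self.trn = float(np.clip(
            trn_prev + dt / (2.0 * c.tau)
            * (c.w_th_trn_sc * th_prev.max() - trn_prev), 0.0, 1.0))

    def step_motor(self, disinhib_map: np.ndarray, sat: float,
                   opn: float, gpi_rest: float) -> None:
        """Advance the motor map given the burst-control signals."""
        c = self.cfg
        snr = gpi_rest * (1.0 - disinhib_map)
        drive = (self.sci_out * (1.0 - c.w_bginhib_sci * snr)
                 * (1.0 - c.w_sat_mot * sat)
                 - c.w_opn_mot * opn - c.w_sat_stop * sat * sat)
        lpds_step_(self.motor, drive, c.tau_motor, self.dt)


class SaccadeGenerator:
    """Burst generators, omnipause latch and the integrate-saturate stop.

    Decodes the motor map into eye displacement: velocity is the
    activity-weighted sum of per-unit displacement vectors (both colliculi
    summed), scaled by ``burst_gain``; Sat integrates total motor activity
    (normalised by the mass of a standard blob) and both terminates the
    burst and reports saccade execution to the visual structures.
    """

    def __init__(self, cfg: SCMotorConfig, ret: RetinotopyConfig,
                 dt: float = 1.0):
        self.cfg = cfg
        self.dt = dt
        self.vec = efferent_vectors(ret)  # (2, n, n, 2)
        self._vec_flat = self.vec.reshape(-1, 2)
        self._mass = blob_mass(ret)
        #: deg of displacement per (motor x vector) unit: scaling by
        #: sat_rate/mass cancels the burst-mass integral, so amplitude
        #: depends on map position only
        self.burst_gain = cfg.burst_cal * cfg.sat_rate / self._mass
        self.opn = 1.0
        self.sat = 0.0
        self.eye = np.zeros(2)
        self.velocity = np.zeros(2)

    def reset(self) -> None:
        self.opn = 1.0
        self.sat = 0.0
        self.eye[:] = 0.0
        self.velocity[:] = 0.0

    @property
    def sg_inhib(self) -> float:
        """Ascending saccade-execution signal (= Sat)."""
        return self.sat

    def step(self, motor: np.ndarray) -> np.ndarray:
        drive = motor.reshape(-1) @ self._vec_flat
        self.step_from_sums(float(motor.sum()), float(drive[0]),
                            float(drive[1]))
        return self.eye

    def step_from_sums(self, motor_sum: float, burst_x: float,
                       burst_y: float) -> None:
        """Advance OPN, eye and Sat from precomputed motor-map sums."""
        c, dt = self.cfg, self.dt
        norm_mass = motor_sum / self._mass

        # omnipause latch
        opn = self.opn + dt / c.tau_opn * (
            c.i_opn - c.w_mot_opn * norm_mass - self.opn)
        self.opn = min(max(opn, 0.0), 1.0)

        # burst: population drive -> eye velocity
        self.velocity = self.burst_gain * np.array([burst_x, burst_y])
        self.eye = self.eye + self.velocity * dt

        # integrate-saturate burst terminator
        if norm_mass > 1e-6:
            self.sat = min(1.0, self.sat + dt * c.sat_rate * norm_mass)
        else:
            self.sat = max(0.0, self.sat - dt * self.sat / c.tau_sat_decay)


def detect_saccade(eye_trace: np.ndarray, dt: float = 1.0,
                   threshold: float = 2.5,
                   t_end: Optional[float] = None) -> Optional[SaccadeEvent]:
    """Find the first saccade in an eye trace sampled at ``dt``.

    ``eye_trace`` has shape (T, 2), in degrees relative to the centre; the
    onset is the first sample beyond ``threshold`` degrees from centre and
    the landing position is read at the end of the trace (the caller ends
    a trial once the burst has terminated).  Returns ``None`` if the trace
    never leaves the threshold circle (no-saccade outcome).
    """
    trace = np.asarray(eye_trace, float)
    if trace.ndim != 2 or trace.shape[1] != 2:
        raise ValueError("eye_trace must have shape (T, 2)")
    dist = np.hypot(trace[:, 0], trace[:, 1])
    over = np.nonzero(dist > threshold)[0]
    if over.size == 0:
        return None
    onset = int(over[0])
    if t_end is not None and onset * dt > t_end:
        return None
    landing = trace[-1]
    amp = float(np.hypot(*landing))
    direction = float(np.degrees(np.arctan2(landing[1], landing[0])))
    return SaccadeEvent(srt=onset * dt, amplitude=amp, direction=direction,
                        landing=(float(landing[0]), float(landing[1])))
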