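"""The basal-ganglia selection circuit.

One circuit competes N channels (coarse map locations for the spatial loop,
colours for the feature loop).  Selection works by opposing a focused
(one-to-one) striatal D1 inhibition of GPi/SNr against a diffuse
(one-to-all) subthalamic excitation:

* cortical/thalamic salience excites D1 and D2 striatum, the fast-spiking
  interneuron pool (FS) and STN;
* FS provides feedforward inhibition, giving the striatal projection
  neurons their activation threshold;
* the winning channel's D1 drive pulls its GPi/SNr output below the tonic
  rest level (disinhibition of the targeted circuit), while STN excitation,
  summed over every active channel, pushes all other channels at or above
  rest;
* D2 -> GPe -> (STN, GPi) closes the regulatory indirect/pallidal feedback.

With no input every population relaxes to rest and GPi/SNr outputs the
tonic level ``gpi_rest`` on all channels.  Gains are tuned so that a lone
Gaussian target with amplitude in [0.6, 1] is selected, a 0.1 target is
not, distractors up to ~0.85 do not disturb a full-amplitude winner, and
two targets are co-selected only when their amplitudes are within a few
percent of each other (the perceptual-noise difference of 5% is resolved).

Dopamine is fixed at its normal operating point (folded into the striatal
gains).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import BGConfig, ConfigurationError
from .dynamics import disinhibition

__all__ = ["BGCircuit"]


class BGCircuit:
    """N-channel selection circuit (D1/D2/FS striatum, STN, GPe, GPi|SNr)."""

    def __init__(self, n_channels: int, cfg: BGConfig, dt: float = 1.0):
        if n_channels < 1:
            raise ConfigurationError("need at least one channel")
        cfg.validate()
        self.n = n_channels
        self.cfg = cfg
        self.dt = dt
        # populations stacked as rows (d1, d2, stn, gpe, gpi); the named
        # attributes are views into this array
        self._pops = np.zeros((5, n_channels))
        self._maxv = np.array([cfg.d1_max, cfg.d2_max, cfg.stn_max,
                               cfg.gpe_max, cfg.gpi_max])
        self._p = np.array([
            dt, cfg.tau, cfg.w_in_d1, cfg.w_fs_d1, cfg.w_in_d2, cfg.w_fs_d2,
            cfg.w_in_stn, cfg.w_gpe_stn, cfg.i_gpe, cfg.w_stn_gpe,
            cfg.w_d2_gpe, cfg.i_gpi, cfg.w_stn_gpi, cfg.w_d1_gpi,
            cfg.w_gpe_gpi, cfg.w_in_fs, cfg.fs_max, cfg.diffuse_norm,
            cfg.stn_sum_max])
        self.d1 = self._pops[0]
        self.d2 = self._pops[1]
        self.stn = self._pops[2]
        self.gpe = self._pops[3]
        self.gpi = self._pops[4]
        self.gpe[:] = cfg.gpe_rest
        self.gpi[:] = cfg.gpi_rest
        self.fs = 0.0
        self._stepped = False

    # -----------------------------------------------------------------
    @property
    def gpi_rest(self) -> float:
        return self.cfg.gpi_rest

    def reset(self) -> None:
        self._pops[:3] = 0.0
        self.gpe[:] = self.cfg.gpe_rest
        self.gpi[:] = self.cfg.gpi_rest
        self.fs = 0.0
        self._stepped = False

    def step(self, salience: np.ndarray) -> np.ndarray:
        """Advance all populations one step; returns the GPi|SNr output.

        ``salience`` is the per-channel input vector (values in [0, 1+eps]).
        All populations update synchronously from the previous step's
        values (Jacobi scheme), so the result does not depend on any
        within-step ordering.
        """
        s = np.asarray(salience, dtype=float)
        if s.shape != (self.n,):
            raise ConfigurationError(
                f"salience shape {s.shape} != ({self.n},)")
        self.fs = _bg_step(self._pops, s, self._maxv, self._p, self.fs)
        self._stepped = True
        return self.gpi

    def step_reference(self, salience: np.ndarray) -> np.ndarray:
        """Pure-numpy form of :meth:`step` (reference semantics)."""
        s = np.asarray(salience, dtype=float)
        if s.shape != (self.n,):
            raise ConfigurationError(
                f"salience shape {s.shape} != ({self.n},)")
        c, dt = self.cfg, self.dt
        fs_prev = self.fs
        stn_sum = min(float(self.stn.sum()) * c.diffuse_norm, c.stn_sum_max)
        gpe_mean = float(self.gpe.mean())
        drive = np.empty_like(self._pops)
        drive[0] = c.w_in_d1 * s - c.w_fs_d1 * fs_prev
        drive[1] = c.w_in_d2 * s - c.w_fs_d2 * fs_prev
        drive[2] = c.w_in_stn * s - c.w_gpe_stn * self.gpe
        drive[3] = c.i_gpe + c.w_stn_gpe * stn_sum - c.w_d2_gpe * self.d2
        drive[4] = (c.i_gpi + c.w_stn_gpi * stn_sum
                    - c.w_d1_gpi * self.d1 - c.w_gpe_gpi * gpe_mean)
        fs = fs_prev + dt / c.tau * (c.w_in_fs * float(s.sum()) - fs_prev)
        self.fs = min(max(fs, 0.0), c.fs_max)
        pops = self._pops
        pops += (dt / c.tau) * (drive - pops)
        np.maximum(pops, 0.0, out=pops)
        np.minimum(pops, self._maxv.reshape(-1, 1), out=pops)
        self._stepped = True
        return self.gpi

    def run(self, salience: np.ndarray, n_steps: int = 300) -> np.ndarray:
        """Step a constant salience to (approximate) convergence."""
        for _ in range(n_steps):
            out = self.step(salience)
        return out

    def selection_state(self) -> np.ndarray:
        """Per-channel disinhibition readout in [0, 1].

        0 = fully inhibited (GPi at or above rest), 1 = fully disinhibited.
        """
        if not self._stepped:
            raise ConfigurationError("circuit has not been stepped yet")
        return disinhibition(self.gpi, self.cfg.gpi_rest)

    def selected(self, threshold: float = 0.9) -> np.ndarray:
        """Boolean mask of channels whose disinhibition exceeds threshold."""
        return self.selection_state() > threshold


@njit(cache=True)
def _bg_step(pops, s, maxv, p, fs_prev):
    (dt, tau, w_in_d1, w_fs_d1, w_in_d2, w_fs_d2, w_in_stn, w_gpe_stn,
     i_gpe, w_stn_gpe, w_d2_gpe, i_gpi, w_stn_gpi, w_d1_gpi, w_gpe_gpi,
     w_in_fs, fs_max, diffuse_norm, stn_sum_max) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10],
        p[11], p[12], p[13], p[14], p[15], p[16], p[17], p[18])
    n = s.shape[0]
    stn_sum = 0.0
    gpe_sum = 0.0
    s_sum = 0.0
    for i in range(n):
        stn_sum += pops[2, i]
        gpe_sum += pops[3, i]
        s_sum += s[i]
    stn_sum *= diffuse_norm
    if stn_sum > stn_sum_max:
        stn_sum = stn_sum_max
    gpe_mean = gpe_sum / n
    k = dt / tau
    gpe_base = i_gpe + w_stn_gpe * stn_sum
    gpi_base = i_gpi + w_stn_gpi * stn_sum - w_gpe_gpi * gpe_mean
    for i in range(n):
        d1 = pops[0, i]
        d2 = pops[1, i]
        stn = pops[2, i]
        gpe = pops[3, i]
        gpi = pops[4, i]
        x = d1 + k * (w_in_d1 * s[i] - w_fs_d1 * fs_prev - d1)
        pops[0, i] = min(max(x, 0.0), maxv[0])
        x = d2 + k * (w_in_d2 * s[i] - w_fs_d2 * fs_prev - d2)
        pops[1, i] = min(max(x, 0.0), maxv[1])
        x = stn + k * (w_in_stn * s[i] - w_gpe_stn * gpe - stn)
        pops[2, i] = min(max(x, 0.0), maxv[2])
        x = gpe + k * (gpe_base - w_d2_gpe * d2 - gpe)
        pops[3, i] = min(max(x, 0.0), maxv[3])
        x = gpi + k * (gpi_base - w_d1_gpi * d1 - gpi)
        pops[4, i] = min(max(x, 0.0), maxv[4])
    fs = fs_prev + k * (w_in_fs * s_sum - fs_prev)
    return min(max(fs, 0.0), fs_max)
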