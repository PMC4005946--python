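"""Cortico-basal loops: the V4|IT colour loop and the FEF spatial loop.

Both loops share one motif: a cortical output layer is driven partly by its
(delayed, saccade-gated) visual input and partly by a thalamic relay; the
thalamic drive is the cortical output times a base gain plus a gain
controlled by basal-ganglia disinhibition, minus a diffuse reticular
(TRN) inhibition, plus a small tonic drive.  Once the BG release a channel,
the thalamo-cortical gain exceeds one and the channel's activity is
amplified to saturation (closed-loop selection-amplification); at rest the
gain is below one and the tonic drive only sustains a faint baseline.

The colour loop runs over three scalar channels (red, green, blue): each
V4 colour map is summed into one channel, selection happens in this
non-spatial channel space, and the selected channel is projected back onto
the V4 map layout (spatial-colour transformation).  The FEF loop runs over
full retinotopic maps.  Their actor-weighted inputs feed the respective BG
circuits; the two spatial learning streams (collicular thalamus and FEF
input) are merged by a steep sigmoid that imposes a minimal salience
threshold before spatial selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LoopsConfig
from .dynamics import lpds_step_  # noqa: F401  (SpatialLoop reference path)

__all__ = [
    "merge_sigmoid",
    "color_channel_sum",
    "color_backproject",
    "ColorLoop",
    "SpatialLoop",
]


def merge_sigmoid(x, slope: float = 15.0, threshold: float = 0.95):
    """Minimal-salience non-linearity f(x) = 1 / (1 + exp(slope*(threshold-x)))."""
    return 1.0 / (1.0 + np.exp(slope * (threshold - np.asarray(x, float))))


def color_channel_sum(v4_maps: np.ndarray, norm: float) -> np.ndarray:
    """Collapse per-colour maps (3, 2, n, n) into 3 channel saliences.

    ``norm`` is the normalisation constant (1 / mass of a full-intensity
    blob) chosen so that one full blob yields a salience of ~1; two blobs
    of the same colour sum towards ~2 and are clipped downstream by the
    unit saturations.
    """
    return v4_maps.sum(axis=(1, 2, 3)) * norm


def color_backproject(v4_maps: np.ndarray, it_out: np.ndarray) -> np.ndarray:
    """Project selected colour channels back onto the map layout.

    Each colour's input map is normalised by its own maximum (zero maps
    stay zero) and scaled by the channel's output activity, then the
    colours are summed: spatial layout from V4, amplitude from the
    selected colour.  Returns a (2, n, n) map.
    """
    out = np.zeros(v4_maps.shape[1:])
    for c in range(v4_maps.shape[0]):
        peak = v4_maps[c].max()
        if peak > 1e-12 and it_out[c] > 0:
            out += v4_maps[c] * (it_out[c] / peak)
    return np.clip(out, 0.0, 1.0, out=out)


@dataclass
class ColorLoop:
    """IT-BG-Th selection loop over the three colour channels."""

    cfg: LoopsConfig
    dt: float = 1.0
    it_out: np.ndarray = field(default=None)  # type: ignore[assignment]
    th: np.ndarray = field(default=None)  # type: ignore[assignment]
    trn: float = 0.0

    def __post_init__(self):
        if self.it_out is None:
            self.it_out = np.zeros(3)
        if self.th is None:
            self.th = np.zeros(3)

    def reset(self) -> None:
        self.it_out[:] = 0.0
        self.th[:] = 0.0
        self.trn = 0.0

    def step(self, it_in: np.ndarray, gpi: np.ndarray, gpi_rest: float,
             sg_inhib: float) -> None:
        """One step of the output and thalamic channels.

        ``it_in`` are the raw colour-channel saliences (visual drive,
        already delayed), ``gpi`` the colour BG output.
        """
        c, dt = self.cfg, self.dt
        it_prev = self.it_out.copy()
        th_prev = self.th.copy()
        trn_prev = self.trn
        gate = max(0.0, 1.0 - c.w_sg_inhib * sg_inhib)
        disinhib = 1.0 - gpi / gpi_rest
        np.clip(disinhib, 0.0, 1.0, out=disinhib)

        k = dt / c.tau_color
        it = self.it_out
        it += k * (c.w_itin_itout * gate * it_in
                   + c.w_th_itout * th_prev - it)
        np.clip(it, 0.0, 1.0, out=it)

        th = self.th
        th += k * (it_prev * (c.w_itout_th + c.w_gpi_th_it * disinhib)
                   - c.w_trn_th_it * trn_prev + c.i_th - th)
        np.clip(th, 0.0, 1.0, out=th)

        trn = trn_prev + dt / c.tau_trn * (
            c.w_th_trn_it * float(th_prev.max()) - trn_prev)
        self.trn = min(max(trn, 0.0), 1.0)


@dataclass
class SpatialLoop:
    """FEF-BG-Th selection-amplification loop over retinotopic maps."""

    cfg: LoopsConfig
    n: int = 70
    dt: float = 1.0
    fef_in: np.ndarray = field(default=None)  # type: ignore[assignment]
    fef_out: np.ndarray = field(default=None)  # type: ignore[assignment]
    th: np.ndarray = field(default=None)  # type: ignore[assignment]
    trn: float = 0.0
    #: lesion switch: clamps FEF output at zero (inactivation experiments)
    lesioned: bool = False

    def __post_init__(self):
        shape = (2, self.n, self.n)
        if self.fef_in is None:
            self.fef_in = np.zeros(shape)
        if self.fef_out is None:
            self.fef_out = np.zeros(shape)
        if self.th is None:
            self.th = np.zeros(shape)

    def reset(self) -> None:
        self.fef_in[:] = 0.0
        self.fef_out[:] = 0.0
        self.th[:] = 0.0
        self.trn = 0.0

    def step(self, visual: np.ndarray, disinhib_map: np.ndarray,
             sg_inhib: float) -> None:
        """One step of FEF input/output maps and the thalamic map.

        ``visual`` is the luminance map delayed by the FEF latency;
        ``disinhib_map`` the expanded spatial-BG release map (2, n, n).
        """
        c, dt = self.cfg, self.dt
        gate = max(0.0, 1.0 - c.w_sg_inhib * sg_inhib)
        in_prev = self.fef_in.copy()
        out_prev = self.fef_out.copy()
        th_prev = self.th.copy()
        trn_prev = self.trn

        lpds_step_(self.fef_in, visual * gate, c.tau, dt)
        drive_out = (c.w_fefin_fefout * in_prev * gate
                     + c.w_th_fefout * th_prev)
        lpds_step_(self.fef_out, drive_out, c.tau, dt)
        if self.lesioned:
            self.fef_out[:] = 0.0
        drive_th = (out_prev * (c.w_fefout_th + c.w_gpi_th_fef * disinhib_map)
                    - c.w_trn_th_fef * trn_prev + c.i_th)
        lpds_step_(self.th, drive_th, c.tau, dt)

        self.trn = float(np.clip(
            trn_prev + dt / c.tau_trn
            * (c.w_th_trn_fef * th_prev.max() - trn_prev), 0.0, 1.0))
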