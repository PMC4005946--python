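"""Retinotopy: complex-log visual maps and the Gaussian-pyramid channel scale.

The visual hemifield is mapped onto each collicular/cortical sheet with the
complex-logarithmic transform fitted on the macaque superior colliculus:

    u = Bx * ln( sqrt(R^2 + 2*A*R*cos(theta) + A^2) / A )
    v = By * atan2( R*sin(theta), R*cos(theta) + A )

where (R, theta) are eccentricity (deg) and direction, A is the foveal shear
(deg) and Bx/By scale map millimetres.  The fovea lands on the map origin
and equal-size stimuli occupy roughly equal map areas across eccentricity
(cortical magnification).

Targets are rendered as Gaussian activity blobs spreading over about a
hundred units on the 70x70 grids.  The n x n maps talk to the coarse
basal-ganglia channel arrays through a two-stage Gaussian pyramid (5x5
normalized kernel followed by 2x2 average binning, applied twice: a factor
4 per dimension); the opposite, amplitude-preserving expansion upsamples
coarse pallidal output back to map resolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import correlate1d

from .config import ConfigurationError, RetinotopyConfig

logger = logging.getLogger(__name__)

COLORS = ("red", "green", "blue")

#: normalized 5-tap binomial kernel (the standard Gaussian-pyramid kernel)
_KERNEL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


# ---------------------------------------------------------------------------
# scene description
# ---------------------------------------------------------------------------

@dataclass
class VisualTarget:
    """One stimulus: position in gaze-centred degrees, colour, salience.

    ``color`` may be one of red/green/blue, or "white" for a pure-luminance
    stimulus (e.g. the fixation cue) that drives the retinal and FEF maps
    but none of the colour maps.
    """

    x: float
    y: float
    color: str = "white"
    intensity: float = 1.0

    @classmethod
    def from_polar(cls, R: float, theta_deg: float, color: str = "white",
                   intensity: float = 1.0) -> "VisualTarget":
        th = math.radians(theta_deg)
        return cls(R * math.cos(th), R * math.sin(th), color, intensity)

    @property
    def R(self) -> float:
        return math.hypot(self.x, self.y)


# ---------------------------------------------------------------------------
# afferent mapping
# ---------------------------------------------------------------------------

def afferent_map(R: float, theta_deg: float, cfg: RetinotopyConfig) -> tuple[float, float]:
    """Map a hemifield position (R deg, theta deg) to (u, v) map coordinates.

    ``theta`` is measured from the horizontal meridian of the hemifield the
    map represents; the fovea (R=0) maps to (0, 0).  Units are the map
    millimetres of the mapping constants.
    """
    if R < 0:
        raise ConfigurationError("eccentricity must be non-negative")
    a = cfg.A
    th = math.radians(theta_deg)
    u = cfg.Bx * math.log(
        math.sqrt(R * R + 2 * a * R * math.cos(th) + a * a) / a)
    v = cfg.By * math.atan2(R * math.sin(th), R * math.cos(th) + a)
    return u, v


def inverse_map(u: float, v: float, cfg: RetinotopyConfig) -> tuple[float, float]:
    """Inverse of :func:`afferent_map`: map coordinates -> (x, y) degrees."""
    z = cfg.A * (np.exp(u / cfg.Bx + 1j * v / cfg.By) - 1.0)
    return float(z.real), float(z.imag)


def map_to_grid(u: float, v: float, cfg: RetinotopyConfig) -> tuple[float, float]:
    """Convert map millimetres to fractional (row, col) grid indices."""
    col = u / cfg.u_max * (cfg.n - 1)
    row = (v + cfg.v_max) / (2 * cfg.v_max) * (cfg.n - 1)
    return row, col


def grid_to_map(row: float, col: float, cfg: RetinotopyConfig) -> tuple[float, float]:
    u = col / (cfg.n - 1) * cfg.u_max
    v = row / (cfg.n - 1) * (2 * cfg.v_max) - cfg.v_max
    return u, v


def efferent_vectors(cfg: RetinotopyConfig) -> np.ndarray:
    """Displacement vector (deg) encoded by each motor-map unit.

    Returns an array of shape (2, n, n, 2): hemifield, row, col, (dx, dy).
    Left-hemifield units encode leftward (negative x) displacements.
    """
    n = cfg.n
    rows = np.arange(n)
    cols = np.arange(n)
    u = cols / (n - 1) * cfg.u_max
    v = rows / (n - 1) * (2 * cfg.v_max) - cfg.v_max
    z = cfg.A * (np.exp(u[None, :] / cfg.Bx + 1j * v[:, None] / cfg.By) - 1.0)
    vec = np.zeros((2, n, n, 2))
    vec[1, :, :, 0] = z.real
    vec[1, :, :, 1] = z.imag
    vec[0, :, :, 0] = -z.real
    vec[0, :, :, 1] = z.imag
    return vec


# ---------------------------------------------------------------------------
# stimulus rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedScene:
    """Per-colour and luminance activity maps for a fixed set of targets."""

    color: np.ndarray  # (3, 2, n, n)
    lum: np.ndarray  # (2, n, n)
    targets: list = field(default_factory=list)


def _blob(n: int, row_c: float, col_c: float, sigma: float,
          amplitude: float) -> np.ndarray:
    rows = np.arange(n)[:, None]
    cols = np.arange(n)[None, :]
    d2 = (rows - row_c) ** 2 + (cols - col_c) ** 2
    return amplitude * np.exp(-d2 / (2.0 * sigma * sigma))


def render_stimulus(targets: Iterable[VisualTarget],
                    cfg: RetinotopyConfig) -> RenderedScene:
    """Render targets as Gaussian blobs on the colour and luminance maps.

    Each target lands on the hemifield map of its azimuth sign (a foveal
    target is shared by both hemifields at half intensity); blobs add and
    saturate at 1.
    """
    n = cfg.n
    color = np.zeros((3, 2, n, n))
    lum = np.zeros((2, n, n))
    targets = list(targets)
    for tgt in targets:
        if tgt.R > cfg.r_max:
            logger.warning("target at R=%.1f deg outside mapped range; dropped",
                           tgt.R)
            continue
        if abs(tgt.x) < 1e-9 and tgt.R < 1e-9:
            placements = [(0, 0.0, 0.5), (1, 0.0, 0.5)]
        elif tgt.x >= 0:
            placements = [(1, math.degrees(math.atan2(tgt.y, tgt.x)), 1.0)]
        else:
            placements = [(0, math.degrees(math.atan2(tgt.y, -tgt.x)), 1.0)]
        for hemi, theta, frac in placements:
            u, v = afferent_map(tgt.R, theta, cfg)
            row, col = map_to_grid(u, v, cfg)
            blob = _blob(n, row, col, cfg.sigma, tgt.intensity * frac)
            lum[hemi] += blob
            if tgt.color in COLORS:
                color[COLORS.index(tgt.color), hemi] += blob
            elif tgt.color != "white":
                raise ConfigurationError(f"unknown colour {tgt.color!r}")
    np.clip(color, 0.0, 1.0, out=color)
    np.clip(lum, 0.0, 1.0, out=lum)
    return RenderedScene(color=color, lum=lum, targets=targets)


def blob_mass(cfg: RetinotopyConfig) -> float:
    """Total map activity of one full-intensity blob (normalisation oracle)."""
    scene = render_stimulus(
        [VisualTarget(cfg.r_max / 4.0, 0.0, "red", 1.0)], cfg)
    return float(scene.color[0].sum())


def reduction_gain(cfg: RetinotopyConfig) -> float:
    """Gain restoring a unit coarse peak for a standard full-intensity blob.

    Pyramid reduction smooths a task-sized blob below its fine-map peak;
    basal-ganglia selection thresholds are amplitude-based, so inputs on the
    channel paths are rescaled by this constant (config override:
    ``cfg.reduce_gain``).
    """
    if cfg.reduce_gain is not None:
        return cfg.reduce_gain
    scene = render_stimulus(
        [VisualTarget(cfg.calib_eccentricity, 0.0, "white", 1.0)], cfg)
    peak = pyramid_reduce(scene.lum).max()
    return float(1.0 / peak)


# ---------------------------------------------------------------------------
# Gaussian pyramid
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray) -> np.ndarray:
    """Separable normalized 5x5 Gaussian over the last two axes."""
    out = correlate1d(x, _KERNEL5, axis=-1, mode="constant")
    return correlate1d(out, _KERNEL5, axis=-2, mode="constant")


def _padded_n(n: int) -> int:
    return int(math.ceil(n / 4.0)) * 4


def coarse_n(n: int) -> int:
    """Coarse channel grid side for an n x n map (two factor-2 stages)."""
    return _padded_n(n) // 4


def pyramid_reduce(m: np.ndarray) -> np.ndarray:
    """Reduce the last two axes by 4: twice (5x5 Gaussian, then 2x2 mean bin).

    Binning averages, so salience *amplitudes* are preserved across scales
    (a constant map stays constant away from the boundary).  Maps whose side
    is not a multiple of 4 are zero-padded symmetrically first (70 -> 72).
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[-1]
    np_ = _padded_n(n)
    if np_ != n:
        pad = np_ - n
        lo, hi = pad // 2, pad - pad // 2
        width = [(0, 0)] * (m.ndim - 2) + [(lo, hi), (lo, hi)]
        m = np.pad(m, width)
    for _ in range(2):
        m = _smooth(m)
        s = m.shape
        half = s[-1] // 2
        m = m.reshape(s[:-2] + (half, 2, half, 2)).mean(axis=(-3, -1))
    return m


def pyramid_expand(m: np.ndarray, n_out: int) -> np.ndarray:
    """Expand coarse channels back to an ``n_out`` x ``n_out`` map.

    Adjoint-style operator of :func:`pyramid_reduce` rescaled to preserve
    amplitudes: each stage replicates 2x2 and smooths with the same kernel,
    so a constant coarse map expands to the same constant and a one-hot
    channel becomes a smooth blob centred on its cell block.
    """
    m = np.asarray(m, dtype=float)
    for _ in range(2):
        m = np.repeat(np.repeat(m, 2, axis=-1), 2, axis=-2)
        m = _smooth(m)
    np_ = m.shape[-1]
    if np_ != n_out:
        pad = np_ - n_out
        lo = pad // 2
        m = m[..., lo:lo + n_out, lo:lo + n_out]
    return m


def diffuse_norm(cfg: RetinotopyConfig, n_ref: int = 70) -> float:
    """Resolution correction for the diffuse subthalamic drive.

    The one-to-all STN projection sums over all active channels, so its
    drive per stimulus scales with the coarse-grid mass of a blob, which
    depends on the grid resolution.  Returns the ratio of the calibration
    blob's coarse mass on the reference ``n_ref`` grid to its mass on this
    config's grid (1.0 for the reference grid itself).
    """
    import dataclasses as _dc

    def _mass(c: RetinotopyConfig) -> float:
        scene = render_stimulus(
            [VisualTarget(c.calib_eccentricity, 0.0, "white", 1.0)], c)
        return float(pyramid_reduce(scene.lum).sum() * reduction_gain(c))

    if cfg.n == n_ref:
        return 1.0
    ref = _dc.replace(cfg, n=n_ref)
    return _mass(ref) / _mass(cfg)


def flatten_channels(coarse: np.ndarray) -> np.ndarray:
    """(2, m, m) coarse map -> flat channel vector (2*m*m,)."""
    return np.ascontiguousarray(coarse).reshape(-1)


# ---------------------------------------------------------------------------
# precompiled sparse pyramid operators (hot-loop equivalents)
# ---------------------------------------------------------------------------

def _smooth1d_op(n: int):
    from scipy import sparse

    k = sparse.diags([_KERNEL5[2 + o] * np.ones(n - abs(o))
                      for o in (-2, -1, 0, 1, 2)],
                     offsets=[-2, -1, 0, 1, 2], format="csr")
    return k


def _bin1d_op(n: int):
    from scipy import sparse

    half = n // 2
    rows = np.repeat(np.arange(half), 2)
    cols = np.arange(n)
    return sparse.csr_matrix((np.full(n, 0.5), (rows, cols)),
                             shape=(half, n))


def _pad1d_op(n: int, n_pad: int):
    from scipy import sparse

    lo = (n_pad - n) // 2
    rows = np.arange(lo, lo + n)
    return sparse.csr_matrix((np.ones(n), (rows, np.arange(n))),
                             shape=(n_pad, n))


def _rep1d_op(n: int):
    from scipy import sparse

    rows = np.arange(2 * n)
    cols = np.repeat(np.arange(n), 2)
    return sparse.csr_matrix((np.ones(2 * n), (rows, cols)),
                             shape=(2 * n, n))


class PyramidOps:
    """Sparse-matrix forms of :func:`pyramid_reduce` / :func:`pyramid_expand`.

    Identical linear maps, precompiled for the per-millisecond loop.  The
    operators act per hemifield on flattened (n, n) sheets.
    """

    def __init__(self, n: int):
        from scipy import sparse

        self.n = n
        np_ = _padded_n(n)
        self.m = np_ // 4

        def kron2(a):
            return sparse.kron(a, a, format="csr")

        pad = kron2(_pad1d_op(n, np_))
        s1 = kron2(_smooth1d_op(np_))
        b1 = kron2(_bin1d_op(np_))
        s2 = kron2(_smooth1d_op(np_ // 2))
        b2 = kron2(_bin1d_op(np_ // 2))
        self.R = (b2 @ s2 @ b1 @ s1 @ pad).tocsr()

        r1 = kron2(_rep1d_op(self.m))
        r2 = kron2(_rep1d_op(np_ // 2))
        crop = kron2(_pad1d_op(n, np_)).T.tocsr()
        self.E = (crop @ s1 @ r2 @ s2 @ r1).tocsr()

    def reduce(self, fine: np.ndarray) -> np.ndarray:
        """(2, n, n) -> (2, m, m)."""
        flat = fine.reshape(2, -1)
        out = np.empty((2, self.m * self.m))
        out[0] = self.R @ flat[0]
        out[1] = self.R @ flat[1]
        return out.reshape(2, self.m, self.m)

    def expand(self, coarse: np.ndarray) -> np.ndarray:
        """(2, m, m) -> (2, n, n)."""
        flat = coarse.reshape(2, -1)
        out = np.empty((2, self.n * self.n))
        out[0] = self.E @ flat[0]
        out[1] = self.E @ flat[1]
        return out.reshape(2, self.n, self.n)


def unflatten_channels(vec: np.ndarray, m: int) -> np.ndarray:
    """Flat channel vector -> (2, m, m) coarse map."""
    return np.asarray(vec).reshape(2, m, m)
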