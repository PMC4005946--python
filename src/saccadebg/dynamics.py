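"""Rate-unit dynamics shared by every structure of the model.

All populations are leaky rate units whose derivative is projected back into
a bounded box ("locally projected dynamical system"): the update

    x(t+dt) = clip(x(t) + dt/tau * (I(t) - x(t)), 0, max)

keeps activities in [0, max] for any bounded input and makes the coupled
system contracting (two trajectories of the same unit under the same input
can only get closer).  The module also provides the modulatory-inhibition
contract used by every basal-ganglia projection, explicit sensory delay
lines, and small typed containers for maps and projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import ConfigurationError

__all__ = [
    "lpds_step",
    "gated_drive",
    "DelayLine",
    "SimulationClock",
    "UnitState",
    "MapGrid",
    "Projection",
]


def lpds_step(x, I, tau: float, dt: float, x_max: float = 1.0):
    """One Euler step of a projected leaky integrator.

    Works elementwise on scalars or arrays.  The fixed point of repeated
    application under constant drive ``I`` is ``clip(I, 0, x_max)``.
    """
    if tau <= 0 or dt <= 0:
        raise ConfigurationError("tau and dt must be positive")
    return np.clip(x + (dt / tau) * (np.asarray(I) - x), 0.0, x_max)


def lpds_step_(x: np.ndarray, I, tau: float, dt: float, x_max: float = 1.0) -> np.ndarray:
    """In-place variant of :func:`lpds_step` for hot loops (no validation)."""
    x += (dt / tau) * (I - x)
    np.maximum(x, 0.0, out=x)
    np.minimum(x, x_max, out=x)
    return x


def gated_drive(I_E, gpi, gpi_rest: float, w_E: float):
    """Excitatory drive modulated by basal-ganglia inhibitory output.

    Returns ``w_E * I_E * (1 - gpi/gpi_rest)``: zero at the tonic rest level
    of GPi/SNr, full gain under complete disinhibition.  The modulation
    factor is clamped to [0, 1]; inhibition above rest cannot reverse the
    sign of an excitatory input.
    """
    if gpi_rest <= 0:
        raise ConfigurationError("gpi_rest must be positive")
    factor = np.clip(1.0 - np.asarray(gpi) / gpi_rest, 0.0, 1.0)
    return w_E * np.asarray(I_E) * factor


def disinhibition(gpi, gpi_rest: float):
    """Per-channel release signal 1 - GPi/GPi_rest, clamped to [0, 1]."""
    if gpi_rest <= 0:
        raise ConfigurationError("gpi_rest must be positive")
    return np.clip(1.0 - np.asarray(gpi) / gpi_rest, 0.0, 1.0)


class DelayLine:
    """Fixed-latency transmission line.

    ``step(value)`` records the input for the current time step and returns
    the input from ``latency`` ms ago (zeros before one full latency has
    elapsed).  ``value`` may be a scalar or an array of the shape given at
    construction.
    """

    def __init__(self, latency: float, dt: float, shape: tuple = ()):
        if dt <= 0:
            raise ConfigurationError("dt must be positive")
        if latency < 0:
            raise ConfigurationError("latency must be non-negative")
        self.latency = latency
        self.dt = dt
        self.depth = int(round(latency / dt))
        self._buf = np.zeros((self.depth + 1,) + tuple(shape))
        self._i = 0

    def step(self, value):
        size = self.depth + 1
        self._buf[self._i % size] = value
        out = self._buf[(self._i - self.depth) % size]
        self._i += 1
        return out.copy() if out.ndim else float(out)

    def reset(self) -> None:
        self._buf[:] = 0.0
        self._i = 0


@dataclass
class SimulationClock:
    """Monotonic simulation time in ms, advanced by a fixed dt."""

    dt: float = 1.0
    t: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")

    def advance(self) -> float:
        self.t += self.dt
        return self.t


@dataclass
class UnitState:
    """A single rate unit: activity, time constant and saturation bound."""

    x: float = 0.0
    tau: float = 10.0
    x_max: float = 1.0

    def step(self, I: float, dt: float) -> float:
        self.x = float(lpds_step(self.x, I, self.tau, dt, self.x_max))
        return self.x


@dataclass
class MapGrid:
    """A 2D field of rate units, one n x n sheet per hemifield.

    ``data`` has shape (2, n, n); index 0 is the left visual hemifield.
    """

    n: int
    name: str = ""
    tau: float = 10.0
    x_max: float = 1.0
    data: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.data is None:
            self.data = np.zeros((2, self.n, self.n))
        else:
            self.data = np.asarray(self.data, dtype=float)
            if self.data.shape != (2, self.n, self.n):
                raise ConfigurationError(
                    f"MapGrid {self.name!r}: data shape {self.data.shape} "
                    f"!= (2, {self.n}, {self.n})")

    def step(self, I, dt: float) -> np.ndarray:
        lpds_step_(self.data, I, self.tau, dt, self.x_max)
        return self.data

    def reset(self) -> None:
        self.data[:] = 0.0

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class Projection:
    """Declarative description of one pathway between two structures."""

    source: str
    target: str
    gain: float
    topology: str = "one-to-one"  # one-to-one | one-to-all
    sign: str = "excitatory"  # excitatory | inhibitory
    modulatory: bool = False
    source_channels: Optional[int] = None
    target_channels: Optional[int] = None

    def __post_init__(self):
        if self.topology not in ("one-to-one", "one-to-all"):
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ConfigurationError(f"unknown sign {self.sign!r}")
        if (self.topology == "one-to-one"
                and self.source_channels is not None
                and self.target_channels is not None
                and self.source_channels != self.target_channels):
            raise ConfigurationError(
                "one-to-one projection requires matching channel counts")
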