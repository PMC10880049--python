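"""Core containers: single frames and trajectories of membrane inclusions.

Positions are in-plane (2D) centres of mass, in nm, in a square periodic
box.  A :class:`Trajectory` carries both wrapped coordinates (for distance
and cluster analysis under the minimum-image convention) and unwrapped
coordinates (for displacement/MSD analysis), plus optional per-inclusion
axis orientation unit vectors (membrane normal along z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = ["Configuration", "Trajectory", "wrap_positions", "min_image_displacement"]


def wrap_positions(positions: np.ndarray, box_length: float) -> np.ndarray:
    """Wrap coordinates into [0, box_length)."""
    return np.mod(positions, box_length)


def min_image_displacement(delta: np.ndarray, box_length: float) -> np.ndarray:
    """Minimum-image displacement vectors for a square periodic box."""
    return delta - box_length * np.round(delta / box_length)


@dataclass
class Configuration:
    """One frame of inclusion positions in a periodic 2D box.

    Parameters
    ----------
    positions
        Array of shape (n, 2), wrapped into [0, box_length), nm.
    box_length
        Side length of the square periodic box, nm.
    time
        Frame time, ns.
    """

    positions: np.ndarray
    box_length: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        if np.any(self.positions < 0) or np.any(self.positions >= self.box_length):
            raise ValueError("positions must be wrapped into [0, box_length)")

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Time series of inclusion configurations.

    ``wrapped`` and ``unwrapped`` have shape (n_frames, n, 2) and must agree
    modulo the box length.  ``orientations``, if present, has shape
    (n_frames, n, 3) with unit-norm rows.
    """

    times: np.ndarray
    wrapped: np.ndarray
    unwrapped: np.ndarray
    box_length: float
    orientations: Optional[np.ndarray] = None
    params: Optional[object] = None
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wrapped = np.asarray(self.wrapped, dtype=float)
        self.unwrapped = np.asarray(self.unwrapped, dtype=float)
        if self.wrapped.ndim != 3 or self.wrapped.shape[2] != 2:
            raise ValueError("wrapped must have shape (n_frames, n, 2)")
        if self.wrapped.shape != self.unwrapped.shape:
            raise ValueError("wrapped and unwrapped shapes differ")
        if self.times.shape[0] != self.wrapped.shape[0]:
            raise ValueError("times length does not match number of frames")
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        if self._validate:
            self.validate()

    def validate(self) -> None:
        if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        # wrapped and unwrapped must agree modulo L; the residual is either
        # ~0 or ~L for points sitting numerically on the boundary.
        resid = np.mod(self.unwrapped - self.wrapped, self.box_length)
        resid = np.minimum(resid, self.box_length - resid)
        if resid.size and float(np.max(resid)) > 1e-6:
            raise ValueError("wrapped and unwrapped positions disagree modulo box_length")
        if np.any(self.wrapped < 0) or np.any(self.wrapped >= self.box_length):
            raise ValueError("wrapped positions outside [0, box_length)")
        if self.orientations is not None:
            ori = np.asarray(self.orientations, dtype=float)
            if ori.shape != (self.n_frames, self.n, 3):
                raise ValueError("orientations must have shape (n_frames, n, 3)")
            norms = np.linalg.norm(ori, axis=-1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("orientation vectors must have unit norm (tol 1e-9)")
            self.orientations = ori

    @property
    def n_frames(self) -> int:
        return self.wrapped.shape[0]

    @property
    def n(self) -> int:
        return self.wrapped.shape[1]

    def frame(self, i: int) -> Configuration:
        return Configuration(self.wrapped[i], self.box_length, time=float(self.times[i]))

    def frames(self) -> Iterator[Configuration]:
        for i in range(self.n_frames):
            yield self.frame(i)
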