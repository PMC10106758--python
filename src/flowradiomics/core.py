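"""Shared containers for time-resolved velocity data.

Conventions used throughout the package:

* spatial coordinates and grid spacings are physical millimetres,
* velocities are metres per second, vorticity is 1/s,
* grids are cell-centred and voxel indices are 0-based,
* time is indexed by cardiac timeframe; the cycle is normalised to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VelocityField"]


@dataclass
class VelocityField:
    """Time-resolved 3-component velocity field on a regular voxel grid.

    Attributes
    ----------
    velocity
        Array of shape ``(n_timeframes, nx, ny, nz, 3)`` in m/s. The last
        axis holds the (x, y, z) velocity components in the physical frame.
    spacing
        Voxel spacing (mm), length-3.
    origin
        Physical position (mm) of the centre of voxel (0, 0, 0).
    frame_duration_ms
        Duration of one timeframe in milliseconds.
    venc
        Velocity encoding limit in cm/s, or ``None`` when unknown.
    """

    velocity: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    frame_duration_ms: float
    venc: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValueError(
                "velocity must have shape (t, nx, ny, nz, 3), got "
                f"{self.velocity.shape}"
            )

    @property
    def n_timeframes(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[1:4]

    @property
    def frame_times(self) -> np.ndarray:
        """Normalised cycle fraction of each frame, in [0, 1)."""
        n = self.n_timeframes
        return np.arange(n) / n

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Convert physical mm coordinates to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing
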