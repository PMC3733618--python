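"""Hexagonal detector-array geometry.

The photodiode array used for optical imaging of cortex is a hexagonal
lattice; the flow-detection stage works on a small analysis patch, one
detector plus its six nearest neighbors (the "ring").  Positions are in mm,
channel 0 is always the ring center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArrayGeometry", "hex_array"]

_DIST_TOL = 1e-6


@dataclass(frozen=True)
class ArrayGeometry:
    """Detector positions on a hexagonal lattice.

    Parameters
    ----------
    positions
        (n_channels, 2) array of x/y coordinates in mm.
    spacing
        Nearest-neighbor distance in mm.
    ring_channels
        Channel ids of the analysis patch: the center detector first,
        followed by its six neighbors in angular order.
    """

    positions: np.ndarray
    spacing: float
    ring_channels: tuple = field(default=None)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        object.__setattr__(self, "positions", pos)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.ring_channels is None:
            object.__setattr__(self, "ring_channels", tuple(range(min(7, len(pos)))))
        ring = tuple(int(c) for c in self.ring_channels)
        object.__setattr__(self, "ring_channels", ring)
        if len(ring) != 7:
            raise ValueError("ring_channels must name a center plus 6 neighbors")
        center = pos[ring[0]]
        d = np.linalg.norm(pos[list(ring[1:])] - center, axis=1)
        if not np.allclose(d, self.spacing, atol=1e-6 * self.spacing):
            raise ValueError("ring neighbors are not at one spacing from the center")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def center(self) -> np.ndarray:
        """Position of the ring-center detector (mm)."""
        return self.positions[self.ring_channels[0]]

    def neighbor_pairs(self, channels=None):
        """All unordered nearest-neighbor pairs (i, j) with i < j.

        Restricted to `channels` when given (defaults to the whole array).
        """
        if channels is None:
            channels = range(self.n_channels)
        chans = sorted(int(c) for c in channels)
        pairs = []
        for a_idx, i in enumerate(chans):
            for j in chans[a_idx + 1:]:
                d = np.linalg.norm(self.positions[j] - self.positions[i])
                if abs(d - self.spacing) <= _DIST_TOL + 1e-6 * self.spacing:
                    pairs.append((i, j))
        return pairs


# cube-coordinate unit steps around a hexagonal ring
_CUBE_DIRS = [(1, -1, 0), (1, 0, -1), (0, 1, -1), (-1, 1, 0), (-1, 0, 1), (0, -1, 1)]


def _cube_to_xy(q: int, r: int, spacing: float) -> tuple:
    # axial (q, r) -> cartesian, pointy-top lattice
    x = spacing * (q + r / 2.0)
    y = spacing * (np.sqrt(3.0) / 2.0) * r
    return x, y


def hex_array(spacing: float = 0.5, n_rings: int = 2) -> ArrayGeometry:
    """Build a hexagonal array of `n_rings` rings around a center detector.

    n_rings=2 (default) gives 19 channels; the analysis ring is channel 0
    plus the 6 first-ring neighbors (channels 1-6).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if n_rings < 1:
        raise ValueError("need at least one ring")
    coords = [(0, 0, 0)]
    for ring in range(1, n_rings + 1):
        # start `ring` steps along direction 4 and walk the perimeter
        c = (-ring, 0, ring)
        for d in _CUBE_DIRS:
            for _ in range(ring):
                coords.append(c)
                c = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
    xy = np.array([_cube_to_xy(c[0], c[2], spacing) for c in coords])
    return ArrayGeometry(positions=xy, spacing=spacing, ring_channels=tuple(range(7)))
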