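"""Room and net geometry, and the zone-labelling rule.

The colony room is a box (default 2.7 x 2.3 x 2.6 m) with two landing nets
mounted near the ceiling in opposite corners: a large net (80 x 40 cm) and a
small net (40 x 40 cm).  A food-bowl region sits on the floor near the room
centre.  Zone labelling is a pure function of 3D position and the configured
geometry: identical positions always receive identical labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ZONE_LARGE = "large_net"
ZONE_SMALL = "small_net"
ZONE_BOWL = "food_bowl_region"
ZONE_ROOM = "room"


@dataclass(frozen=True)
class NetSpec:
    """Axis-aligned rectangular landing net at height ``z``.

    ``origin`` is the room-frame (x, y) of the net corner; net-local
    coordinates are (x - origin_x, y - origin_y), so a bat on the net has
    local coordinates in [0, width] x [0, height].
    """

    name: str
    origin: tuple[float, float]
    width: float
    height: float
    z: float = 2.4

    def contains_xy(self, x, y):
        ox, oy = self.origin
        return (x >= ox) & (x <= ox + self.width) & (y >= oy) & (y <= oy + self.height)

    def to_local(self, xy: np.ndarray) -> np.ndarray:
        """Map room-frame (..., 2) xy to net-local coordinates."""
        return np.asarray(xy, dtype=float) - np.asarray(self.origin, dtype=float)

    def center_local(self) -> np.ndarray:
        return np.array([self.width / 2.0, self.height / 2.0])

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))


@dataclass(frozen=True)
class RoomGeometry:
    """Room box, two nets, food-bowl region and the tracking frame rate."""

    room_size: tuple[float, float, float] = (2.7, 2.3, 2.6)
    large_net: NetSpec = field(
        default_factory=lambda: NetSpec(ZONE_LARGE, (0.0, 0.0), 0.80, 0.40, z=2.4)
    )
    small_net: NetSpec = field(
        default_factory=lambda: NetSpec(ZONE_SMALL, (2.3, 1.9), 0.40, 0.40, z=2.4)
    )
    bowl_center: tuple[float, float] = (1.35, 1.15)
    bowl_radius: float = 0.20
    bowl_z_max: float = 0.5
    net_z_min: float = 2.0
    frame_rate: float = 25.0

    def net(self, name: str) -> NetSpec:
        if name == self.large_net.name:
            return self.large_net
        if name == self.small_net.name:
            return self.small_net
        raise KeyError(name)

    def zone_of(self, positions: np.ndarray) -> np.ndarray:
        """Label (..., 3) positions; NaN positions get the empty label ''."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        x, y, z = pos[..., 0], pos[..., 1], pos[..., 2]
        zones = np.full(x.shape, ZONE_ROOM, dtype=object)
        on_large = self.large_net.contains_xy(x, y) & (z >= self.net_z_min)
        on_small = self.small_net.contains_xy(x, y) & (z >= self.net_z_min)
        bx, by = self.bowl_center
        on_bowl = (np.hypot(x - bx, y - by) <= self.bowl_radius) & (z <= self.bowl_z_max)
        zones[on_bowl] = ZONE_BOWL
        zones[on_small] = ZONE_SMALL
        zones[on_large] = ZONE_LARGE
        zones[np.isnan(x)] = ""
        if np.ndim(positions) == 1:
            return zones[0]
        return zones


DEFAULT_GEOMETRY = RoomGeometry()
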