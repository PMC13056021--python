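"""Angle conventions shared project-wide.

Allocentric head direction: degrees in [0, 360), 0 along the room +x axis.
Egocentric bearing of a conspecific: degrees in [-180, 180), 0 directly
ahead of the observer's head direction, positive to the left; the front
hemicircle is |angle| < 90.
"""

from __future__ import annotations

import numpy as np


def wrap_signed(deg):
    """Wrap angle(s) in degrees into [-180, 180)."""
    return (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_positive(deg):
    """Wrap angle(s) in degrees into [0, 360)."""
    return np.asarray(deg, dtype=float) % 360.0


def egocentric_angle(host_xy, host_hd_deg, target_xy):
    """Bearing of target from host, relative to host head direction.

    Parameters are broadcastable arrays: host/target positions (..., 2) in
    any common planar frame, head direction in allocentric degrees.
    Returns degrees in [-180, 180).
    """
    host_xy = np.asarray(host_xy, dtype=float)
    target_xy = np.asarray(target_xy, dtype=float)
    d = target_xy - host_xy
    bearing = np.degrees(np.arctan2(d[..., 1], d[..., 0]))
    return wrap_signed(bearing - np.asarray(host_hd_deg, dtype=float))


def circular_mean_deg(deg, axis=None):
    """Circular mean of signed angles in degrees (NaN-propagating)."""
    rad = np.radians(np.asarray(deg, dtype=float))
    s = np.mean(np.sin(rad), axis=axis)
    c = np.mean(np.cos(rad), axis=axis)
    return wrap_signed(np.degrees(np.arctan2(s, c)))
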