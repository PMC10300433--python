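"""Branch and tip geometry measurements.

Widths are maximal chords on 2D maximum projections, cleft angle/depth
are triangulated from three landmarks, branch lengths ride on geodesic
fields, elongation rates are finite differences, and sphericity is the
standard isoperimetric ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import EpithelialMask, InputError, ParameterError
from .geometry import geodesic_distance_field

__all__ = [
    "measure_tip_width",
    "cleft_metrics",
    "CleftGeometry",
    "elongation_series",
    "branch_length",
    "sphericity",
]


def measure_tip_width(
    mask: EpithelialMask,
    axis: tuple[float, float],
    tip_region: tuple[tuple[float, float], tuple[float, float]] | None = None,
    projection_axis: int = 0,
) -> float:
    """Maximal foreground chord perpendicular to the branch axis.

    The mask is max-projected along ``projection_axis`` (default z) and
    every foreground pixel is projected onto the direction perpendicular
    to ``axis`` (an in-plane (x, y) unit direction); the width is the
    extent of that projection plus one pixel (pixels have finite size).
    ``tip_region`` optionally restricts to an axis-aligned ((x0,x1),(y0,y1))
    µm window.
    """
    ax = np.asarray(axis, dtype=float)
    if np.linalg.norm(ax) == 0:
        raise ParameterError("axis must be non-zero")
    ax = ax / np.linalg.norm(ax)
    perp = np.array([-ax[1], ax[0]])
    proj = mask.data.max(axis=projection_axis)  # (y, x) for z-projection
    if projection_axis != 0:
        raise ParameterError("only z-projection (projection_axis=0) is supported")
    vy, vx = mask.voxel_size[1], mask.voxel_size[2]
    oy, ox = mask.origin[1], mask.origin[2]
    yy, xx = np.nonzero(proj)
    if len(xx) == 0:
        raise InputError("projection is empty")
    pts = np.column_stack([xx * vx + ox, yy * vy + oy])
    if tip_region is not None:
        (x0, x1), (y0, y1) = tip_region
        sel = (
            (pts[:, 0] >= x0) & (pts[:, 0] <= x1) & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
        )
        pts = pts[sel]
        if len(pts) == 0:
            raise InputError("tip region contains no foreground")
    s = pts @ perp
    # add one pixel footprint so a one-pixel-wide line has nonzero width
    return float(s.max() - s.min() + min(vx, vy))


@dataclass
class CleftGeometry:
    frame: int
    angle_deg: float
    depth_um: float
    tip_a: np.ndarray
    tip_b: np.ndarray
    cleft: np.ndarray

    def __post_init__(self):
        if not 0.0 < self.angle_deg <= 180.0:
            raise ParameterError("angle must lie in (0, 180]")
        if self.depth_um < 0:
            raise ParameterError("depth must be >= 0")


def cleft_metrics(
    tip_a, tip_b, cleft, frame: int = 0
) -> CleftGeometry:
    """Cleft opening angle and ingression depth from three landmarks.

    The angle is measured at the cleft point between the vectors to the
    two daughter tips; the depth is the perpendicular distance from the
    cleft point to the chord joining the tips.  A cleft lying on the
    chord gives angle 180° and depth 0 (boundary case, not an error).
    """
    a = np.asarray(tip_a, dtype=float)
    b = np.asarray(tip_b, dtype=float)
    c = np.asarray(cleft, dtype=float)
    if np.allclose(a, b) or np.allclose(a, c) or np.allclose(b, c):
        raise InputError("the three landmarks must be distinct")
    va, vb = a - c, b - c
    cosang = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    ab = b - a
    t = float((c - a) @ ab / (ab @ ab))
    foot = a + t * ab
    depth = float(np.linalg.norm(c - foot))
    if depth < 1e-12:
        angle, depth = 180.0, 0.0
    return CleftGeometry(frame=frame, angle_deg=angle, depth_um=depth,
                         tip_a=a, tip_b=b, cleft=c)


def elongation_series(
    lengths: np.ndarray, frame_interval_min: float, frames: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-interval elongation rate (Δ length / Δ time, µm/h)."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < 2:
        raise InputError("need lengths at >= 2 frames")
    if frames is None:
        frames = np.arange(lengths.size)
    frames = np.asarray(frames, dtype=float)
    if np.any(np.diff(frames) <= 0):
        raise InputError("frames must be strictly increasing")
    dt_h = np.diff(frames) * frame_interval_min / 60.0
    rate = np.diff(lengths) / dt_h
    return pd.DataFrame(
        {
            "frame_from": frames[:-1].astype(int),
            "frame_to": frames[1:].astype(int),
            "length_from": lengths[:-1],
            "length_to": lengths[1:],
            "rate_um_per_h": rate,
        }
    )


def branch_length(
    mask: EpithelialMask,
    tip_landmark,
    origin_landmark,
    connectivity: int = 26,
) -> float:
    """Geodesic branch length (µm): origin landmark to tip, inside the mask."""
    tip = np.asarray(tip_landmark, dtype=float)
    origin = np.asarray(origin_landmark, dtype=float)
    if np.allclose(tip, origin):
        return 0.0
    field = geodesic_distance_field(mask, tuple(tip), connectivity=connectivity)
    val = field.sample([origin])[0]
    if not np.isfinite(val):
        raise InputError("landmarks are not geodesically connected in the mask")
    return float(val)


def sphericity(volume: float, surface_area: float) -> float:
    """Isoperimetric sphericity: π^(1/3) (6V)^(2/3) / A; 1 for a ball."""
    if volume <= 0 or surface_area <= 0:
        raise ParameterError("volume and surface area must be > 0")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area)
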