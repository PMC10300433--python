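"""Epithelial masks and the two distance fields that anchor spatial labels.

Two fields drive every spatial classification downstream:

* **surface distance** — distance (µm) from each epithelial voxel to the
  nearest background voxel (the rendered tissue surface); computed with
  an exact Euclidean transform by default, with a chamfer <3,4,5>-style
  option retained for parity with classic tooling (max relative error
  about 8% versus exact).
* **geodesic distance** — shortest path length (µm) from a named landmark
  constrained to run inside the mask; computed by geometric minimal-cost
  path propagation on the voxel grid (26-connected).

Cells are labelled basal/inner by thresholding the surface field at 6 µm
and assigned tip / duct / branch-point domains from landmark geodesics
(tip within 100 µm of the leading edge; centers within 50-100 µm).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import (
    CELL_COLUMNS,
    EpithelialMask,
    InputError,
    LandmarkSet,
    ParameterError,
    ScalarField,
    validate_cell_table,
)

__all__ = [
    "resample_isotropic",
    "mask_from_points",
    "surface_distance_field",
    "geodesic_distance_field",
    "classify_compartment",
    "assign_domains",
    "estimate_tip_boundary",
]

BASAL_THRESHOLD_UM = 6.0
TIP_EXTENT_UM = 100.0


# --------------------------------------------------------------------------
# resampling and mask construction
# --------------------------------------------------------------------------


def resample_isotropic(obj, target_voxel: float):
    """Resample a mask or stack volume onto a cubic-voxel grid.

    Masks use nearest-neighbour interpolation, intensities linear.
    Physical extents are preserved to within one voxel per axis.
    """
    if target_voxel <= 0:
        raise ParameterError("target_voxel must be > 0")
    if isinstance(obj, EpithelialMask):
        vz, vy, vx = obj.voxel_size
        if obj.is_isotropic and abs(vz - target_voxel) < 1e-12:
            return obj
        zoom = (vz / target_voxel, vy / target_voxel, vx / target_voxel)
        data = ndimage.zoom(obj.data.astype(np.uint8), zoom, order=0, grid_mode=True, mode="grid-constant")
        return EpithelialMask(
            data.astype(bool), (target_voxel,) * 3, frame=obj.frame, origin=obj.origin
        )
    raise InputError(f"cannot resample object of type {type(obj).__name__}")


def resample_volume(
    volume: np.ndarray, voxel_size: tuple[float, float, float], target_voxel: float
) -> np.ndarray:
    """Linearly resample an intensity volume onto a cubic grid."""
    if target_voxel <= 0:
        raise ParameterError("target_voxel must be > 0")
    vz, vy, vx = voxel_size
    zoom = (vz / target_voxel, vy / target_voxel, vx / target_voxel)
    return ndimage.zoom(
        np.asarray(volume, dtype=float), zoom, order=1, grid_mode=True, mode="grid-constant"
    )


def mask_from_points(
    points: np.ndarray,
    radius: float,
    voxel_size: float,
    closing_radius: float = 7.0,
    pad: float | None = None,
    frame: int = 0,
) -> EpithelialMask:
    """Union of balls around nuclei positions, morphologically closed.

    The closing (default structuring radius 7 µm, about one nucleus
    diameter) removes spurious internal gaps between neighbouring nuclei
    so the rendered tissue is solid.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise InputError("need at least one point")
    if radius <= 0 or voxel_size <= 0:
        raise ParameterError("radius and voxel_size must be > 0")
    if pad is None:
        pad = radius + closing_radius + 2 * voxel_size
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    nx, ny, nz = (np.ceil((hi - lo) / voxel_size).astype(int) + 1).tolist()
    seeds = np.zeros((nz, ny, nx), dtype=bool)
    iz = np.round((points[:, 2] - lo[2]) / voxel_size).astype(int)
    iy = np.round((points[:, 1] - lo[1]) / voxel_size).astype(int)
    ix = np.round((points[:, 0] - lo[0]) / voxel_size).astype(int)
    seeds[iz, iy, ix] = True
    dist = ndimage.distance_transform_edt(~seeds, sampling=(voxel_size,) * 3)
    grid = dist <= radius
    if closing_radius > 0:
        r_vox = int(np.ceil(closing_radius / voxel_size))
        if r_vox >= 1:
            zz, yy, xx = np.mgrid[-r_vox : r_vox + 1, -r_vox : r_vox + 1, -r_vox : r_vox + 1]
            ball = (zz**2 + yy**2 + xx**2) <= r_vox**2
            grid = ndimage.binary_closing(grid, structure=ball)
            grid[iz, iy, ix] = True  # closing never removes seeds, but be explicit
    return EpithelialMask(
        grid,
        (voxel_size,) * 3,
        frame=frame,
        origin=(float(lo[2]), float(lo[1]), float(lo[0])),
    )


# --------------------------------------------------------------------------
# distance fields
# --------------------------------------------------------------------------

# chamfer <3,4,5> local steps: (dz,dy,dx) offsets with integer weights
_CHAMFER_STEPS = [
    (dz, dy, dx, {1: 3, 2: 4, 3: 5}[abs(dz) + abs(dy) + abs(dx)])
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


#: normalization for <3,4,5> chamfer weights.  The metric's per-unit cost
#: along a direction (a>=b>=c>=0) is (3a+b+c)/|(a,b,c)|, which peaks at
#: sqrt(11) in the (3,1,1) direction and bottoms out at 2*sqrt(2) on face
#: diagonals; scaling by the midpoint balances the error to +/-7.94%,
#: inside the documented 8% bound (the naive /3 scaling overshoots to
#: +10.5%).
_CHAMFER_SCALE = (np.sqrt(11.0) + 2.0 * np.sqrt(2.0)) / 2.0


def _chamfer_distance(mask: np.ndarray, voxel: float) -> np.ndarray:
    """<3,4,5> chamfer distance to background by iterated relaxation.

    Vectorized Bellman–Ford over the 26 chamfer steps; converges in a few
    sweeps on the compact shapes used here.
    """
    big = np.float64(1e30)
    d = np.where(mask, big, 0.0)
    # background adjacency seeds: a foreground voxel next to background
    # starts at the corresponding step weight
    changed = True
    it = 0
    while changed and it < 10 * max(mask.shape):
        changed = False
        it += 1
        for dz, dy, dx, w in _CHAMFER_STEPS:
            shifted = np.full_like(d, big)
            src = d[
                max(dz, 0) or None : d.shape[0] + min(dz, 0) or None,
                max(dy, 0) or None : d.shape[1] + min(dy, 0) or None,
                max(dx, 0) or None : d.shape[2] + min(dx, 0) or None,
            ]
            shifted[
                max(-dz, 0) or None : d.shape[0] + min(-dz, 0) or None,
                max(-dy, 0) or None : d.shape[1] + min(-dy, 0) or None,
                max(-dx, 0) or None : d.shape[2] + min(-dx, 0) or None,
            ] = src
            cand = shifted + w
            better = cand < d
            if better.any():
                d = np.where(better, cand, d)
                changed = True
    return d * (voxel / _CHAMFER_SCALE)


def surface_distance_field(
    mask: EpithelialMask, method: str = "exact"
) -> ScalarField:
    """Distance (µm) from each foreground voxel to the nearest background.

    ``method="exact"`` uses the Euclidean distance transform;
    ``method="chamfer"`` uses integer <3,4,5> weights (max relative error
    ~8% vs exact).  Background voxels hold ``+inf``.
    """
    if not (~mask.data).any():
        raise InputError("mask has no background; surface undefined")
    if method == "exact":
        d = ndimage.distance_transform_edt(mask.data, sampling=mask.voxel_size)
    elif method == "chamfer":
        if not mask.is_isotropic:
            raise ParameterError("chamfer method requires an isotropic mask")
        d = _chamfer_distance(mask.data, mask.voxel_size[0])
    else:
        raise ParameterError(f"unknown method {method!r}")
    out = np.where(mask.data, d, np.inf)
    return ScalarField(
        out,
        mask.voxel_size,
        kind="surface_distance",
        mask=mask,
        source=method,
        origin=mask.origin,
    )


def geodesic_distance_field(
    mask: EpithelialMask,
    seed: tuple[float, float, float],
    snap_radius: float = 10.0,
    connectivity: int = 26,
) -> ScalarField:
    """Shortest within-mask path length (µm) from a seed point.

    Uses geometric minimal-cost-path propagation (equivalent to Dijkstra
    on the 26-connected voxel graph with Euclidean edge weights).
    Unreachable foreground voxels and background hold ``+inf``.  Seeds in
    the background are snapped to the nearest foreground voxel within
    ``snap_radius`` µm.
    """
    from skimage.graph import MCP_Geometric

    if connectivity not in (6, 26):
        raise ParameterError("connectivity must be 6 or 26")
    seed = np.asarray(seed, dtype=float)
    idx = mask.voxel_indices(seed)[0]
    shape = np.array(mask.data.shape)
    inside_grid = np.all(idx >= 0) and np.all(idx < shape)
    if not inside_grid or not mask.data[tuple(idx)]:
        fg = np.argwhere(mask.data)
        scale = np.array(mask.voxel_size)
        origin = np.array(mask.origin)
        centers = fg * scale + origin  # (z, y, x) µm
        dists = np.linalg.norm(centers - seed[::-1], axis=1)
        j = int(np.argmin(dists))
        if dists[j] > snap_radius:
            raise InputError(
                f"seed is {dists[j]:.1f} µm outside the mask (> snap_radius)"
            )
        idx = fg[j]
    costs = np.where(mask.data, 1.0, np.inf)
    mcp = MCP_Geometric(
        costs,
        sampling=mask.voxel_size,
        fully_connected=(connectivity == 26),
    )
    cum, _ = mcp.find_costs([tuple(idx)])
    out = np.where(mask.data & np.isfinite(cum), cum, np.inf)
    return ScalarField(
        out,
        mask.voxel_size,
        kind="geodesic_distance",
        mask=mask,
        source=f"seed={tuple(np.round(seed, 3))}",
        origin=mask.origin,
    )


# --------------------------------------------------------------------------
# per-cell classification
# --------------------------------------------------------------------------


def classify_compartment(
    cells: pd.DataFrame,
    field: ScalarField,
    threshold: float = BASAL_THRESHOLD_UM,
) -> pd.DataFrame:
    """Label each cell basal (surface distance <= threshold) or inner.

    Returns the table with ``compartment`` and ``surface_distance``
    columns added; cells falling outside the mask are labelled
    ``"unassigned"`` with a warning.
    """
    validate_cell_table(cells)
    if field.kind != "surface_distance":
        raise InputError("classify_compartment needs a surface_distance field")
    vals = field.sample(cells[["x", "y", "z"]].to_numpy())
    out = cells.copy()
    out["surface_distance"] = vals
    lab = np.where(vals <= threshold, "basal", "inner")
    bad = ~np.isfinite(vals)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} cells fall outside the mask", stacklevel=2)
    out["compartment"] = np.where(bad, "unassigned", lab)
    return out


def assign_domains(
    cells: pd.DataFrame,
    landmarks: LandmarkSet,
    fields: dict[str, ScalarField],
    frame: int | None = None,
    tip_extent: float = TIP_EXTENT_UM,
    center_radius: float = 75.0,
    split_bifurcating_tip: bool = False,
) -> pd.DataFrame:
    """Assign each cell a spatial domain from landmark geodesic fields.

    ``fields`` maps landmark names (``"leading_edge"``, ``"duct_center"``,
    ``"branch_point"``, and for tip splitting ``"cleft"``,
    ``"daughter_tip_A"``, ``"daughter_tip_B"``) to geodesic fields seeded
    at those landmarks.  Precedence when regions overlap:
    tip > branch_point > duct.  With ``split_bifurcating_tip`` the tip
    cohort is re-labelled ``daughter_tip`` vs ``cleft_region`` by whichever
    landmark is nearer (ties go to ``daughter_tip``).
    """
    validate_cell_table(cells)
    if not 50.0 <= center_radius <= 100.0:
        raise ParameterError("center_radius must lie in [50, 100] µm")
    out = cells.copy()
    n = len(out)
    pos = out[["x", "y", "z"]].to_numpy()
    domain = np.full(n, "unassigned", dtype=object)

    def _dist(name: str) -> np.ndarray | None:
        f = fields.get(name)
        if f is None:
            warnings.warn(f"landmark field {name!r} missing; domain skipped", stacklevel=2)
            return None
        return f.sample(pos)

    d_duct = _dist("duct_center")
    if d_duct is not None:
        domain[np.nan_to_num(d_duct, nan=np.inf) <= center_radius] = "duct"
    d_bp = _dist("branch_point") if "branch_point" in fields else None
    if d_bp is not None:
        domain[np.nan_to_num(d_bp, nan=np.inf) <= center_radius] = "branch_point"
    d_tip = _dist("leading_edge")
    in_tip = None
    if d_tip is not None:
        in_tip = np.nan_to_num(d_tip, nan=np.inf) <= tip_extent
        domain[in_tip] = "tip"

    if split_bifurcating_tip and in_tip is not None:
        d_cleft = _dist("cleft")
        d_a = _dist("daughter_tip_A")
        d_b = _dist("daughter_tip_B")
        if d_cleft is not None and d_a is not None and d_b is not None:
            d_daughter = np.fmin(
                np.nan_to_num(d_a, nan=np.inf), np.nan_to_num(d_b, nan=np.inf)
            )
            d_c = np.nan_to_num(d_cleft, nan=np.inf)
            cleft_side = in_tip & (d_c < d_daughter)
            tip_side = in_tip & (d_daughter <= d_c)  # ties -> daughter_tip
            domain[cleft_side] = "cleft_region"
            domain[tip_side] = "daughter_tip"

    out["domain"] = domain
    out["tip_extent_used"] = tip_extent
    out["center_radius_used"] = center_radius
    return out


def estimate_tip_boundary(
    cells: pd.DataFrame,
    field: ScalarField,
    window: float = 20.0,
    step: float = 10.0,
    min_cells: int = 30,
    flat_epsilon: float = 0.1,
    fallback: float = TIP_EXTENT_UM,
) -> float:
    """Estimate where tip-level cycling gives way to the trailing duct.

    Slides a window of width ``window`` (step ``step``) along the geodesic
    distance-to-leading-edge axis, computes the green fraction per window,
    and returns the largest distance at which the profile still exceeds
    the midpoint between the front-window maximum and the distal baseline
    (mean of the last quartile of windows).  Flat profiles fall back to
    ``fallback``.
    """
    validate_cell_table(cells, require_cls=True)
    if len(cells) < min_cells:
        raise InputError(f"need at least {min_cells} cells")
    d = field.sample(cells[["x", "y", "z"]].to_numpy())
    ok = np.isfinite(d)
    d = d[ok]
    green = (cells["cls"].to_numpy() == "green")[ok]
    if d.size < min_cells:
        raise InputError("too few cells sampled inside the mask")
    starts = np.arange(0.0, d.max() - window + step, step)
    if len(starts) < 2:
        raise InputError("profile spans fewer than two windows")
    fracs, centers = [], []
    for s in starts:
        sel = (d >= s) & (d < s + window)
        if sel.sum() >= 3:
            fracs.append(green[sel].mean())
            centers.append(s + window / 2.0)
    if len(fracs) < 2:
        raise InputError("too few populated windows")
    fracs = np.array(fracs)
    centers = np.array(centers)
    front_max = fracs[: max(1, len(fracs) // 4)].max()
    baseline = fracs[-max(1, len(fracs) // 4) :].mean()
    if front_max - baseline < flat_epsilon:
        return float(fallback)
    cut = (front_max + baseline) / 2.0
    above = np.where(fracs >= cut)[0]
    return float(centers[above.max()])
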