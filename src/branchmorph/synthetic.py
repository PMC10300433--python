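"""Ground-truthed synthetic branching scenes.

Generates agent trajectories inside an advancing capsule-shaped branch
(optionally bifurcating into two daughter branches), together with binary
masks, named landmarks and fully known cycle-class labels, and can render
the result into a noisy two-channel voxel stack.  Every downstream stage
of the package can therefore be tested against exact truth.

Geometry
--------
The branch grows along +x.  An elongating branch is the set of points
within ``tube_radius`` of the axis segment ``(0,0,0) -> (L(t),0,0)``; the
"leading edge" landmark sits at the capsule apex ``(L(t)+tip_radius, 0, 0)``.
A bifurcating branch keeps the parent capsule up to the branch base and
adds two daughter capsules diverging symmetrically in the xy-plane.

Dynamics
--------
Agent speed decays with distance ``d`` to the leading edge:
``s(d) = speed_at_edge * exp(-d / speed_decay_length)``.  Headings are von
Mises about the local branch axis in the xy-plane with a small independent
z jitter; agents reflect back inside the tissue rather than leave it.  The
tissue front advances kinematically at the mean speed of the front cohort
(agents with ``d <= tip_extent``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    GREEN,
    RED,
    EpithelialMask,
    InputError,
    LandmarkSet,
    ParameterError,
    VoxelStack,
)

__all__ = [
    "ScenarioParams",
    "BifurcationParams",
    "ImagingParams",
    "GroundTruth",
    "generate_elongation_scenario",
    "generate_bifurcation_scenario",
    "render_stack",
]


@dataclass
class BifurcationParams:
    t0_frame: int
    widening_frames: int = 5
    cleft_speed: float = 5.0  # µm/h
    branchpoint_speed_factor: float = 0.3
    branchpoint_cycle_factor: float = 0.3
    daughter_angle: float = 60.0  # degrees, full angle between daughters


@dataclass
class ScenarioParams:
    """All knobs of a synthetic scenario.

    The defaults are deliberately round numbers: the source imaging gives
    no quantitative speeds, so nothing here is presented as measured.
    """

    branch_axis_length: float = 200.0  # µm, initial axis length
    tube_radius: float = 25.0  # µm
    tip_radius: float = 25.0  # µm (capsule cap radius)
    n_cells: int = 300
    basal_shell_depth: float = 6.0  # µm, used by shell placement helpers
    tip_cycle_fraction: float = 0.5
    duct_cycle_fraction: float = 0.15
    tip_extent: float = 100.0  # µm
    speed_at_edge: float = 20.0  # µm/h
    speed_decay_length: float = 50.0  # µm
    directional_kappa: float = 2.0
    z_jitter_sd: float = 0.5  # µm per step
    frame_interval: float = 20.0  # min
    n_frames: int = 30
    bifurcation: Optional[BifurcationParams] = None
    seed: int = 0

    def validate(self, require_time: bool = True) -> None:
        for name in (
            "branch_axis_length",
            "tube_radius",
            "tip_radius",
            "tip_extent",
            "speed_decay_length",
            "frame_interval",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("tip_cycle_fraction", "duct_cycle_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0,1]")
        if self.speed_at_edge < 0 or self.directional_kappa < 0:
            raise ParameterError("speed_at_edge and directional_kappa must be >= 0")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if require_time and self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2 for a time-lapse")
        if self.bifurcation is not None:
            b = self.bifurcation
            if not 0 <= b.t0_frame < self.n_frames:
                raise ParameterError("t0_frame must lie in [0, n_frames)")
            if not 0.0 <= b.branchpoint_cycle_factor <= 1.0:
                raise ParameterError("branchpoint_cycle_factor must be in [0,1]")
            if b.branchpoint_speed_factor < 0:
                raise ParameterError("branchpoint_speed_factor must be >= 0")
            if not 0 < b.daughter_angle < 180:
                raise ParameterError("daughter_angle must be in (0,180)")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class ImagingParams:
    voxel_size: tuple[float, float, float] = (2.0, 0.7, 0.7)  # (z,y,x) µm
    nucleus_sigma: float = 2.0  # µm
    photon_scale: float = 50.0
    gaussian_noise_sd: float = 2.0
    bit_depth: int = 16
    poisson: bool = True  # disable for fully deterministic renders

    def validate(self) -> None:
        if min(self.voxel_size) <= 0:
            raise ParameterError("voxel sizes must be > 0")
        if self.nucleus_sigma <= 0:
            raise ParameterError("nucleus_sigma must be > 0")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")


# --------------------------------------------------------------------------
# capsule geometry helpers
# --------------------------------------------------------------------------


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each (x,y,z) point to segment a->b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


@dataclass
class _Shape:
    """Union of capsules: list of (a, b, radius)."""

    segments: list[tuple[np.ndarray, np.ndarray, float]]

    def distance_inside(self, points: np.ndarray) -> np.ndarray:
        """Signed clearance: radius - distance-to-axis, max over capsules."""
        points = np.atleast_2d(points)
        best = np.full(len(points), -np.inf)
        for a, b, r in self.segments:
            best = np.maximum(best, r - _segment_distance(points, a, b))
        return best

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        return self.distance_inside(points) >= margin

    def rasterize(self, voxel_size: float, pad: float = 6.0) -> EpithelialMask:
        los = np.min([np.minimum(a, b) - r for a, b, r in self.segments], axis=0)
        his = np.max([np.maximum(a, b) + r for a, b, r in self.segments], axis=0)
        lo = los - pad
        hi = his + pad
        nx, ny, nz = (np.ceil((hi - lo) / voxel_size).astype(int) + 1).tolist()
        xs = lo[0] + voxel_size * np.arange(nx)
        ys = lo[1] + voxel_size * np.arange(ny)
        zs = lo[2] + voxel_size * np.arange(nz)
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        # include voxels whose center is within half a voxel diagonal of the
        # continuous shape, so every interior point maps to foreground
        margin = -0.5 * np.sqrt(3.0) * voxel_size
        grid = self.contains(pts, margin=margin).reshape(nz, ny, nx)
        return EpithelialMask(
            grid, (voxel_size,) * 3, origin=(float(lo[2]), float(lo[1]), float(lo[0]))
        )


# --------------------------------------------------------------------------
# ground truth container
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything a downstream test needs to know about a synthetic scene."""

    cells: pd.DataFrame  # frame, id, x, y, z, cls, speed, dist_to_edge
    landmarks: LandmarkSet
    params: ScenarioParams
    mask_voxel_size: float = 2.0
    _shapes: list[_Shape] = field(default_factory=list, repr=False)

    @property
    def n_frames(self) -> int:
        return int(self.cells["frame"].max()) + 1

    def cells_at(self, frame: int) -> pd.DataFrame:
        return self.cells[self.cells["frame"] == frame].reset_index(drop=True)

    def mask_at(self, frame: int, voxel_size: float | None = None) -> EpithelialMask:
        m = self._shapes[frame].rasterize(voxel_size or self.mask_voxel_size)
        m.frame = frame
        return m

    def tracks(self) -> pd.DataFrame:
        """True trajectories, ordered by (id, frame)."""
        return self.cells.sort_values(["id", "frame"]).reset_index(drop=True)

    def to_csv(self, cells_path, landmarks_path, params_path=None) -> None:
        self.cells.to_csv(cells_path, index=False)
        self.landmarks.table.to_csv(landmarks_path, index=False)
        if params_path is not None:
            with open(params_path, "w") as fh:
                fh.write(self.params.to_json())


# --------------------------------------------------------------------------
# scenario generation
# --------------------------------------------------------------------------


def _sample_inside(shape: _Shape, n: int, rng: np.random.Generator, margin: float) -> np.ndarray:
    """Uniform rejection sampling inside a capsule union."""
    los = np.min([np.minimum(a, b) - r for a, b, r in shape.segments], axis=0)
    his = np.max([np.maximum(a, b) + r for a, b, r in shape.segments], axis=0)
    out = np.empty((0, 3))
    while len(out) < n:
        cand = rng.uniform(los, his, size=(4 * n, 3))
        cand = cand[shape.contains(cand, margin=margin)]
        out = np.vstack([out, cand])
    return out[:n]


def _speed(d: np.ndarray, p: ScenarioParams) -> np.ndarray:
    return p.speed_at_edge * np.exp(-np.asarray(d, dtype=float) / p.speed_decay_length)


def _step_directions(
    axes: np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit step directions: von Mises about each xy-plane axis angle."""
    base = np.arctan2(axes[:, 1], axes[:, 0])
    if kappa > 0:
        dtheta = rng.vonmises(0.0, kappa, size=len(axes))
    else:
        dtheta = rng.uniform(-np.pi, np.pi, size=len(axes))
    theta = base + dtheta
    return np.column_stack([np.cos(theta), np.sin(theta)])


def _reflect_inside(pos: np.ndarray, shape: _Shape, rng: np.random.Generator) -> np.ndarray:
    """Pull any escaped agent back to the nearest interior point.

    Projection onto the capsule axis keeps containment exact without a
    mechanical model; a tiny random inward offset avoids degenerate
    stacking on the axis surface.
    """
    outside = ~shape.contains(pos, margin=0.0)
    if not outside.any():
        return pos
    fixed = pos.copy()
    bad = pos[outside]
    # move each escaped point towards the nearest capsule axis until inside
    best_d = np.full(len(bad), np.inf)
    target = np.zeros_like(bad)
    for a, b, r in shape.segments:
        ab = b - a
        denom = float(ab @ ab)
        t = np.zeros(len(bad)) if denom == 0 else np.clip((bad - a) @ ab / denom, 0, 1)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(bad - proj, axis=1) - r
        closer = d < best_d
        best_d = np.where(closer, d, best_d)
        # point just inside the capsule surface along the inward radial
        radial = bad - proj
        norm = np.linalg.norm(radial, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        inward = proj + radial / norm * (r * 0.9)
        target[closer] = inward[closer]
    fixed[outside] = target
    return fixed


def _elongation_shape(L: float, p: ScenarioParams) -> _Shape:
    a = np.array([0.0, 0.0, 0.0])
    b = np.array([max(L, 1e-6), 0.0, 0.0])
    return _Shape([(a, b, p.tube_radius)])


def _bifurcation_shape(
    L_parent: float, daughter_len: float, p: ScenarioParams
) -> _Shape:
    b = p.bifurcation
    assert b is not None
    half = np.deg2rad(b.daughter_angle / 2.0)
    base = np.array([max(L_parent, 1e-6), 0.0, 0.0])
    segs: list[tuple[np.ndarray, np.ndarray, float]] = [
        (np.array([0.0, 0.0, 0.0]), base, p.tube_radius)
    ]
    if daughter_len > 0:
        for s in (+1.0, -1.0):
            u = np.array([np.cos(half), s * np.sin(half), 0.0])
            segs.append((base, base + daughter_len * u, p.tip_radius))
    return _Shape(segs)


def _leading_edge(shape_tip_axis_end: np.ndarray, direction: np.ndarray, radius: float) -> np.ndarray:
    return shape_tip_axis_end + direction * radius


def generate_elongation_scenario(params: ScenarioParams) -> GroundTruth:
    """Simulate an elongating branch; see module docstring for the model."""
    params.validate()
    if params.bifurcation is not None:
        raise ParameterError("elongation scenario must not define bifurcation")
    return _simulate(params)


def generate_bifurcation_scenario(params: ScenarioParams) -> GroundTruth:
    """Simulate a branch that widens and splits into two daughter tips."""
    params.validate()
    if params.bifurcation is None:
        raise ParameterError("bifurcation scenario requires the bifurcation field")
    return _simulate(params)


def _simulate(p: ScenarioParams) -> GroundTruth:
    rng = np.random.default_rng(p.seed)
    bif = p.bifurcation
    dt_h = p.frame_interval / 60.0

    L = float(p.branch_axis_length)
    daughter_len = 0.0
    half = np.deg2rad(bif.daughter_angle / 2.0) if bif else 0.0
    widen_start = (bif.t0_frame - bif.widening_frames) if bif else None

    shape = _elongation_shape(L, p)
    pos = _sample_inside(shape, p.n_cells, rng, margin=0.5)

    edge = _leading_edge(np.array([L, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]), p.tube_radius)
    dist_edge = np.maximum(edge[0] - pos[:, 0], 0.0)

    # fixed per-agent cycle class from the initial distance to the edge
    in_tip0 = dist_edge <= p.tip_extent
    prob = np.where(in_tip0, p.tip_cycle_fraction, p.duct_cycle_fraction)
    is_green = rng.uniform(size=p.n_cells) < prob
    reassigned = np.zeros(p.n_cells, dtype=bool)

    rows: list[pd.DataFrame] = []
    lm_records: list[tuple[int, str, float, float, float]] = []
    shapes: list[_Shape] = []
    cleft_pos: np.ndarray | None = None
    branch_base_x = None  # frozen parent length at widening start

    for f in range(p.n_frames):
        widening = bif is not None and f >= widen_start
        post_t0 = bif is not None and f >= bif.t0_frame
        if widening and branch_base_x is None:
            branch_base_x = L

        if bif is not None and widening:
            shape = _bifurcation_shape(branch_base_x, daughter_len, p)
            base = np.array([branch_base_x, 0.0, 0.0])
            uA = np.array([np.cos(half), np.sin(half), 0.0])
            uB = np.array([np.cos(half), -np.sin(half), 0.0])
            tipA = _leading_edge(base + daughter_len * uA, uA, p.tip_radius)
            tipB = _leading_edge(base + daughter_len * uB, uB, p.tip_radius)
            front = base + np.array([daughter_len * np.cos(half) + p.tip_radius, 0.0, 0.0])
            if post_t0 and cleft_pos is None:
                cleft_pos = front.copy()
            edge = (tipA + tipB) / 2.0 if not post_t0 else front
            # distance to edge ~ axial distance to the daughter front
            dist_edge = np.maximum(tipA[0] - pos[:, 0], 0.0)
        else:
            shape = _elongation_shape(L, p)
            edge = _leading_edge(
                np.array([L, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]), p.tube_radius
            )
            dist_edge = np.maximum(edge[0] - pos[:, 0], 0.0)

        # --- cleft proximity, speed/cycle modulation -----------------------
        speed_factor = np.ones(p.n_cells)
        near_cleft = np.zeros(p.n_cells, dtype=bool)
        if post_t0:
            dc = np.linalg.norm(pos - cleft_pos, axis=1)
            dA = np.linalg.norm(pos - tipA, axis=1)
            dB = np.linalg.norm(pos - tipB, axis=1)
            in_tip = dist_edge <= p.tip_extent
            near_cleft = in_tip & (dc < np.minimum(dA, dB))
            speed_factor[near_cleft] = bif.branchpoint_speed_factor
            # cycle repression: an agent entering cleft proximity has its
            # class redrawn once at the repressed probability (a single
            # one-way transition; classes are otherwise fixed)
            newly = near_cleft & ~reassigned
            if newly.any():
                p_green = p.tip_cycle_fraction * bif.branchpoint_cycle_factor
                redraw = rng.uniform(size=p.n_cells) < p_green
                is_green = np.where(newly, redraw, is_green)
                reassigned |= newly

        speed = _speed(dist_edge, p) * speed_factor

        # --- record this frame --------------------------------------------
        rows.append(
            pd.DataFrame(
                {
                    "frame": f,
                    "id": np.arange(p.n_cells),
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "z": pos[:, 2],
                    "cls": np.where(is_green, GREEN, RED),
                    "speed": speed,
                    "dist_to_edge": dist_edge,
                    "near_cleft": near_cleft,
                }
            )
        )
        shapes.append(shape)
        lm_records.append((f, "leading_edge", edge[0], edge[1], edge[2]))
        duct_x = max(edge[0] - (p.tip_extent + 75.0), p.tube_radius)
        lm_records.append((f, "duct_center", duct_x, 0.0, 0.0))
        if bif is not None and widening:
            lm_records.append((f, "daughter_tip_A", tipA[0], tipA[1], tipA[2]))
            lm_records.append((f, "daughter_tip_B", tipB[0], tipB[1], tipB[2]))
            neck = base + np.array([0.0, 0.0, 0.0])
            lm_records.append((f, "neck_midpoint", neck[0], neck[1], neck[2]))
        if post_t0:
            lm_records.append((f, "cleft", cleft_pos[0], cleft_pos[1], cleft_pos[2]))
            lm_records.append(
                (f, "branch_point", cleft_pos[0], cleft_pos[1], cleft_pos[2])
            )

        if f == p.n_frames - 1:
            break

        # --- advance agents ------------------------------------------------
        if bif is not None and widening and daughter_len > 0:
            # local axis: daughter direction for cells past the branch base
            axes = np.tile(np.array([1.0, 0.0]), (p.n_cells, 1))
            past = pos[:, 0] > branch_base_x
            upper = pos[:, 1] >= 0
            axes[past & upper] = uA[:2]
            axes[past & ~upper] = uB[:2]
        else:
            axes = np.tile(np.array([1.0, 0.0]), (p.n_cells, 1))
        dirs_xy = _step_directions(axes, p.directional_kappa, rng)
        step = speed * dt_h
        dz = rng.normal(0.0, p.z_jitter_sd, size=p.n_cells)
        new = pos + np.column_stack([dirs_xy * step[:, None], dz])

        # --- advance tissue front ------------------------------------------
        front_cohort = dist_edge <= p.tip_extent
        v_front = float(np.mean(speed[front_cohort])) if front_cohort.any() else 0.0
        if bif is not None and widening:
            daughter_len += v_front * dt_h
            if post_t0:
                cleft_pos = cleft_pos - np.array([bif.cleft_speed * dt_h, 0.0, 0.0])
            next_shape = _bifurcation_shape(branch_base_x, daughter_len, p)
        else:
            L += v_front * dt_h
            next_shape = _elongation_shape(L, p)

        pos = _reflect_inside(new, next_shape, rng)

    cells = pd.concat(rows, ignore_index=True)
    lms = LandmarkSet.from_records(lm_records, t0_frame=bif.t0_frame if bif else None)
    return GroundTruth(cells=cells, landmarks=lms, params=p, _shapes=shapes)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def render_stack(gt: GroundTruth, imaging: ImagingParams | None = None) -> VoxelStack:
    """Render a ground truth into a noisy two-channel (green, red) stack.

    Each nucleus becomes an anisotropy-aware Gaussian blob in the channel
    of its cycle class; Poisson photon noise and additive Gaussian read
    noise are applied on top.
    """
    imaging = imaging or ImagingParams()
    imaging.validate()
    if gt.cells.empty:
        raise InputError("ground truth has no cells")
    if max(imaging.voxel_size) > imaging.nucleus_sigma * 4:
        warnings.warn(
            "voxel size exceeds 4x nucleus sigma; nuclei may be undetectable",
            stacklevel=2,
        )
    rng = np.random.default_rng(gt.params.seed + 987654321)
    vz, vy, vx = imaging.voxel_size
    pad = 4.0 * imaging.nucleus_sigma
    hi = gt.cells[["x", "y", "z"]].to_numpy().max(axis=0) + pad
    lo = gt.cells[["x", "y", "z"]].to_numpy().min(axis=0) - pad
    lo_x, lo_y, lo_z = lo
    nx = int(np.ceil((hi[0] - lo_x) / vx)) + 1
    ny = int(np.ceil((hi[1] - lo_y) / vy)) + 1
    nz = int(np.ceil((hi[2] - lo_z) / vz)) + 1
    n_frames = gt.n_frames

    frames = np.zeros((n_frames, 2, nz, ny, nx), dtype=float)
    sig_vox = np.array([imaging.nucleus_sigma / vz, imaging.nucleus_sigma / vy, imaging.nucleus_sigma / vx])
    half = np.ceil(3.0 * sig_vox).astype(int)

    for f in range(n_frames):
        sub = gt.cells_at(f)
        for _, row in sub.iterrows():
            ch = 0 if row["cls"] == GREEN else 1
            cz = (row["z"] - lo_z) / vz
            cy = (row["y"] - lo_y) / vy
            cx = (row["x"] - lo_x) / vx
            z0, z1 = max(int(cz) - half[0], 0), min(int(cz) + half[0] + 2, nz)
            y0, y1 = max(int(cy) - half[1], 0), min(int(cy) + half[1] + 2, ny)
            x0, x1 = max(int(cx) - half[2], 0), min(int(cx) + half[2] + 2, nx)
            zz = (np.arange(z0, z1) - cz) / sig_vox[0]
            yy = (np.arange(y0, y1) - cy) / sig_vox[1]
            xx = (np.arange(x0, x1) - cx) / sig_vox[2]
            blob = np.exp(
                -0.5
                * (
                    zz[:, None, None] ** 2
                    + yy[None, :, None] ** 2
                    + xx[None, None, :] ** 2
                )
            )
            frames[f, ch, z0:z1, y0:y1, x0:x1] += blob

    signal = frames * imaging.photon_scale
    if imaging.poisson and imaging.photon_scale > 0:
        noisy = rng.poisson(signal).astype(float)
    else:
        noisy = signal
    if imaging.gaussian_noise_sd > 0:
        noisy += rng.normal(0.0, imaging.gaussian_noise_sd, size=noisy.shape)
    maxval = 2**imaging.bit_depth - 1
    noisy = np.clip(noisy, 0, maxval)
    dtype = np.uint8 if imaging.bit_depth == 8 else np.uint16
    stack = VoxelStack(
        noisy.astype(dtype),
        voxel_size=imaging.voxel_size,
        frame_interval_min=gt.params.frame_interval,
        channel_names=(GREEN, RED),
    )
    # origin offsets so detected voxel coords map back onto truth µm coords
    stack.origin_um = (float(lo_z), float(lo_y), float(lo_x))  # (z, y, x)
    return stack
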