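"""Masks, distance fields and spatial classification, with independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from branchmorph.datatypes import EpithelialMask, InputError, LandmarkSet, ParameterError
from branchmorph.geometry import (
    assign_domains,
    classify_compartment,
    estimate_tip_boundary,
    geodesic_distance_field,
    mask_from_points,
    resample_isotropic,
    surface_distance_field,
)


# ------------------------------------------------------------- oracles


def brute_force_surface_distance(mask: np.ndarray, voxel: float) -> np.ndarray:
    """Exhaustive min Euclidean distance from each fg voxel to bg centers."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.full(mask.shape, np.inf)
    for v in fg:
        d = np.linalg.norm((bg - v) * voxel, axis=1)
        out[tuple(v)] = d.min()
    return out


def dijkstra_geodesic(mask: np.ndarray, voxel: float, seed_idx) -> np.ndarray:
    """Dijkstra on the 26-connected voxel graph, Euclidean edge weights."""
    fg = np.argwhere(mask)
    index = -np.ones(mask.shape, dtype=int)
    index[tuple(fg.T)] = np.arange(len(fg))
    rows, cols, w = [], [], []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for off in offsets:
        nb = fg + off
        ok = np.all((nb >= 0) & (nb < mask.shape), axis=1)
        src = index[tuple(fg[ok].T)]
        dst = index[tuple(nb[ok].T)]
        valid = dst >= 0
        rows.extend(src[valid])
        cols.extend(dst[valid])
        w.extend([np.linalg.norm(np.array(off)) * voxel] * int(valid.sum()))
    g = coo_matrix((w, (rows, cols)), shape=(len(fg), len(fg)))
    d = dijkstra(g.tocsr(), indices=index[tuple(seed_idx)])
    out = np.full(mask.shape, np.inf)
    out[tuple(fg.T)] = d
    return out


def _ball_mask(radius_vox: int, voxel: float = 1.0) -> EpithelialMask:
    n = 2 * radius_vox + 5
    c = n // 2
    zz, yy, xx = np.mgrid[:n, :n, :n]
    grid = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2
    return EpithelialMask(grid, (voxel,) * 3)


# ------------------------------------------------------------- resampling


def test_resample_identity():
    m = _ball_mask(5)
    assert resample_isotropic(m, 1.0) is m


def test_resample_preserves_volume():
    # anisotropic 2 µm z / 1 µm xy ball
    zz, yy, xx = np.mgrid[:20, :40, :40]
    grid = ((zz - 10) * 2.0) ** 2 + (yy - 20.0) ** 2 + (xx - 20.0) ** 2 <= 15.0**2
    m = EpithelialMask(grid, (2.0, 1.0, 1.0))
    vol0 = grid.sum() * 2.0
    r = resample_isotropic(m, 1.0)
    vol1 = r.data.sum() * 1.0
    assert vol1 == pytest.approx(vol0, rel=0.05)


def test_resample_roundtrip_jaccard():
    zz, yy, xx = np.mgrid[:24, :24, :24]
    grid = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 9**2
    m = EpithelialMask(grid, (1.0, 1.0, 1.0))
    up = resample_isotropic(m, 0.5)
    down = resample_isotropic(up, 1.0)
    inter = (m.data & down.data).sum()
    union = (m.data | down.data).sum()
    assert inter / union >= 0.9


def test_resample_rejects_bad_target():
    with pytest.raises(ParameterError):
        resample_isotropic(_ball_mask(4), -1.0)


# ------------------------------------------------------------- mask building


def test_mask_single_ball_volume():
    m = mask_from_points([[20.0, 20.0, 20.0]], radius=5.0, voxel_size=1.0, closing_radius=0)
    vol = m.data.sum() * 1.0
    assert vol == pytest.approx(4 / 3 * np.pi * 5**3, rel=0.10)


def test_mask_contains_all_points():
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 60, size=(40, 3))
    m = mask_from_points(pts, radius=4.0, voxel_size=2.0)
    assert m.contains_points(pts).all()


def test_mask_two_components():
    pts = [[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]]
    m = mask_from_points(pts, radius=5.0, voxel_size=1.0, closing_radius=2.0)
    assert m.n_components() == 2


def test_mask_empty_points_raise():
    with pytest.raises(InputError):
        mask_from_points(np.empty((0, 3)), 5.0, 1.0)


# ------------------------------------------------------------- surface field


def test_single_voxel_distance_one():
    grid = np.zeros((5, 5, 5), dtype=bool)
    grid[2, 2, 2] = True
    f = surface_distance_field(EpithelialMask(grid, (1.0, 1.0, 1.0)))
    assert f.data[2, 2, 2] == pytest.approx(1.0)
    assert np.isinf(f.data[0, 0, 0])


def test_all_foreground_raises():
    grid = np.ones((4, 4, 4), dtype=bool)
    with pytest.raises(InputError):
        surface_distance_field(EpithelialMask(grid, (1.0, 1.0, 1.0)))


@pytest.mark.parametrize("method,tol", [("exact", 1e-9), ("chamfer", 0.08)])
def test_cube_center_matches_bruteforce(method, tol):
    grid = np.zeros((25, 25, 25), dtype=bool)
    grid[2:23, 2:23, 2:23] = True  # 21^3 solid cube
    m = EpithelialMask(grid, (1.0, 1.0, 1.0))
    f = surface_distance_field(m, method=method)
    # exhaustive scan oracle at a handful of probe voxels
    bg = np.argwhere(~grid)
    for probe in [(12, 12, 12), (3, 12, 12), (12, 5, 20)]:
        exact = np.linalg.norm(bg - np.array(probe), axis=1).min()
        got = f.data[probe]
        assert abs(got - exact) <= max(tol * exact, 1e-6)


def test_chamfer_error_bound_random_blob():
    rng = np.random.default_rng(5)
    grid = np.zeros((20, 20, 20), dtype=bool)
    pts = rng.integers(4, 16, size=(6, 3))
    zz, yy, xx = np.mgrid[:20, :20, :20]
    for p in pts:
        grid |= (zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2 <= 16
    m = EpithelialMask(grid, (1.0, 1.0, 1.0))
    exact = surface_distance_field(m, method="exact").data
    cham = surface_distance_field(m, method="chamfer").data
    fg = m.data
    rel = np.abs(cham[fg] - exact[fg]) / np.maximum(exact[fg], 1e-9)
    assert rel.max() <= 0.08 + 1e-9


def test_nuclear_shell_histogram_peak(elongation_gt):
    # place nuclei on a shell 4.5 µm deep inside a ball and check the
    # surface-distance histogram peaks in the [4,5) bin
    rng = np.random.default_rng(6)
    R, depth = 20.0, 4.5
    n = 200
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = 30.0 + u * (R - depth)
    zz, yy, xx = np.mgrid[:61, :61, :61]
    grid = (zz - 30.0) ** 2 + (yy - 30.0) ** 2 + (xx - 30.0) ** 2 <= R**2
    m = EpithelialMask(grid, (1.0, 1.0, 1.0))
    f = surface_distance_field(m)
    vals = f.sample(pts)
    hist, edges = np.histogram(vals[np.isfinite(vals)], bins=np.arange(0, 11))
    assert edges[np.argmax(hist)] == 4.0


# ------------------------------------------------------------- geodesic field


def _tube_mask(length_vox=100, radius_vox=4, voxel=2.0):
    grid = np.zeros((2 * radius_vox + 3, 2 * radius_vox + 3, length_vox + 3), dtype=bool)
    c = radius_vox + 1
    zz, yy = np.mgrid[: grid.shape[0], : grid.shape[1]]
    disk = (zz - c) ** 2 + (yy - c) ** 2 <= radius_vox**2
    grid[:, :, 1 : length_vox + 2] = disk[:, :, None]
    return EpithelialMask(grid, (voxel,) * 3)


def test_geodesic_zero_at_seed():
    m = _ball_mask(6)
    c = np.array(m.data.shape) // 2
    seed = tuple((c * 1.0)[::-1])  # (x,y,z)
    f = geodesic_distance_field(m, seed)
    assert f.data[tuple(c)] == 0.0


def test_geodesic_tube_matches_dijkstra():
    m = _tube_mask(length_vox=100, radius_vox=3, voxel=2.0)
    c = (m.data.shape[0] // 2, m.data.shape[1] // 2)
    seed_idx = (c[0], c[1], 1)
    seed_um = (1 * 2.0, c[1] * 2.0, c[0] * 2.0)  # (x,y,z)
    f = geodesic_distance_field(m, seed_um)
    oracle = dijkstra_geodesic(m.data, 2.0, seed_idx)
    far = (c[0], c[1], 101)
    # ~200 µm tube: within 2% of the Dijkstra value, and of the length
    assert f.data[far] == pytest.approx(oracle[far], rel=0.02)
    assert f.data[far] == pytest.approx(200.0, rel=0.02)


def test_geodesic_u_shape_exceeds_euclidean():
    # U: two vertical arms joined at the bottom
    grid = np.zeros((5, 40, 30), dtype=bool)
    grid[:, 2:38, 2:6] = True  # left arm
    grid[:, 2:38, 24:28] = True  # right arm
    grid[:, 34:38, 2:28] = True  # bottom bar
    m = EpithelialMask(grid, (1.0, 1.0, 1.0))
    tip_a = (4.0, 3.0, 2.0)  # (x,y,z) top of left arm
    tip_b = (26.0, 3.0, 2.0)
    f = geodesic_distance_field(m, tip_a)
    val = f.sample([tip_b])[0]
    eucl = np.linalg.norm(np.array(tip_a) - np.array(tip_b))
    assert val >= 2 * eucl


def test_geodesic_seed_snap_and_error():
    m = _ball_mask(5)
    c = np.array(m.data.shape) // 2
    outside = tuple((c * 1.0)[::-1] + np.array([20.0, 0, 0]))
    with pytest.raises(InputError):
        geodesic_distance_field(m, outside, snap_radius=5.0)
    near = tuple((c * 1.0)[::-1] + np.array([6.5, 0, 0]))
    f = geodesic_distance_field(m, near, snap_radius=5.0)
    assert np.isfinite(f.data[tuple(c)])


def test_surface_leq_geodesic_from_surface_seed():
    m = _ball_mask(8)
    surf = surface_distance_field(m)
    # seed on the surface shell
    fg = np.argwhere(m.data & (surf.data <= 1.0))
    seed_idx = fg[0]
    seed_um = tuple(seed_idx[::-1].astype(float))
    geo = geodesic_distance_field(m, seed_um)
    sel = m.data & np.isfinite(geo.data)
    # surface distance can never exceed the geodesic to one surface point
    # (allow chamfer/discretization slack of one voxel diagonal)
    assert (surf.data[sel] <= geo.data[sel] + np.sqrt(3) + 1e-9).all()


def test_geodesic_geq_euclidean():
    m = _tube_mask(length_vox=40, radius_vox=3, voxel=1.0)
    c = (m.data.shape[0] // 2, m.data.shape[1] // 2)
    seed_um = (1.0, float(c[1]), float(c[0]))
    f = geodesic_distance_field(m, seed_um)
    fg = np.argwhere(np.isfinite(f.data))
    seed_vec = np.array([c[0], c[1], 1])
    eucl = np.linalg.norm(fg - seed_vec, axis=1)
    got = f.data[tuple(fg.T)]
    assert (got >= eucl - 1e-6).all()


# ------------------------------------------------------------- classification


def _cells_at(points):
    pts = np.atleast_2d(points)
    return pd.DataFrame(
        {
            "frame": 0,
            "id": np.arange(len(pts)),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "cls": "red",
        }
    )


def test_compartment_threshold_boundary():
    # a synthetic field: constant slab so sampled distances are exact
    grid = np.ones((3, 3, 30), dtype=bool)
    grid[:, :, 0] = False
    from branchmorph.datatypes import ScalarField

    data = np.tile(np.arange(30, dtype=float), (3, 3, 1))
    data[~grid] = np.inf
    f = ScalarField(data, (1.0, 1.0, 1.0), kind="surface_distance")
    cells = _cells_at([[6.0, 1.0, 1.0], [6.01, 1.0, 1.0]])
    out = classify_compartment(cells, f, threshold=6.0)
    assert list(out["compartment"]) == ["basal", "inner"]


def test_compartment_partition(elongation_gt):
    mask = elongation_gt.mask_at(0)
    f = surface_distance_field(mask)
    cells = elongation_gt.cells_at(0)
    out = classify_compartment(cells, f)
    assigned = out[out["compartment"] != "unassigned"]
    assert set(out["compartment"].unique()) <= {"basal", "inner", "unassigned"}
    assert len(assigned) == ((out["compartment"] == "basal") | (out["compartment"] == "inner")).sum()
    # relabeling is idempotent
    again = classify_compartment(out, f)
    assert (again["compartment"] == out["compartment"]).all()


def test_domain_rules(elongation_gt):
    mask = elongation_gt.mask_at(0)
    lms = elongation_gt.landmarks
    fields = {
        "leading_edge": geodesic_distance_field(mask, tuple(lms.get("leading_edge", 0))),
        "duct_center": geodesic_distance_field(mask, tuple(lms.get("duct_center", 0))),
    }
    cells = elongation_gt.cells_at(0)
    out = assign_domains(cells, lms, fields, tip_extent=100.0, center_radius=50.0)
    d_tip = fields["leading_edge"].sample(cells[["x", "y", "z"]].to_numpy())
    d_duct = fields["duct_center"].sample(cells[["x", "y", "z"]].to_numpy())
    # tip has precedence
    sel = np.isfinite(d_tip) & (d_tip <= 100.0)
    assert (out["domain"][sel] == "tip").all()
    sel2 = np.isfinite(d_duct) & (d_duct <= 50.0) & ~sel
    assert (out["domain"][sel2] == "duct").all()
    # idempotent
    again = assign_domains(out, lms, fields, tip_extent=100.0, center_radius=50.0)
    assert (again["domain"] == out["domain"]).all()


def test_domain_center_radius_range():
    with pytest.raises(ParameterError):
        assign_domains(_cells_at([[0, 0, 0]]), LandmarkSet.from_records([]), {}, center_radius=30.0)


def test_daughter_tip_tiebreak(bifurcation_gt):
    f = bifurcation_gt.n_frames - 1
    mask = bifurcation_gt.mask_at(f)
    lms = bifurcation_gt.landmarks
    names = ("leading_edge", "duct_center", "cleft", "daughter_tip_A", "daughter_tip_B")
    fields = {
        n: geodesic_distance_field(mask, tuple(lms.get(n, f)))
        for n in names
        if lms.get(n, f) is not None
    }
    cells = bifurcation_gt.cells_at(f)
    out = assign_domains(
        cells, lms, fields, split_bifurcating_tip=True, center_radius=75.0
    )
    assert {"daughter_tip", "cleft_region"} <= set(out["domain"].unique())
    # every tip-cohort cell got exactly one of the two split labels
    labels = set(out["domain"].unique())
    assert "tip" not in labels


def test_missing_landmark_warns(elongation_gt):
    cells = elongation_gt.cells_at(0)
    with pytest.warns(UserWarning, match="missing"):
        out = assign_domains(cells, elongation_gt.landmarks, {}, center_radius=75.0)
    assert (out["domain"] == "unassigned").all()


# ------------------------------------------------------------- tip boundary


def _profile_cells(rng, n, fracs):
    """Cells on a line with distance-dependent green probability."""
    d = rng.uniform(0, 160, size=n)
    p = np.where(d < 80, fracs[0], fracs[1])
    cls = np.where(rng.uniform(size=n) < p, "green", "red")
    cells = _cells_at(np.column_stack([d, np.zeros(n), np.zeros(n)]))
    cells["cls"] = cls
    return cells, d


def test_boundary_step_profile():
    from branchmorph.datatypes import ScalarField

    rng = np.random.default_rng(7)
    cells, d = _profile_cells(rng, 3000, (0.6, 0.2))
    data = np.tile(np.arange(170, dtype=float), (3, 3, 1))
    f = ScalarField(data, (1.0, 1.0, 1.0), kind="geodesic_distance")
    cells[["y", "z"]] = 1.0
    est = estimate_tip_boundary(cells, f, window=20.0, step=10.0)
    assert est == pytest.approx(80.0, abs=20.0)


def test_boundary_flat_profile_fallback():
    from branchmorph.datatypes import ScalarField

    rng = np.random.default_rng(8)
    cells, d = _profile_cells(rng, 2000, (0.3, 0.3))
    data = np.tile(np.arange(170, dtype=float), (3, 3, 1))
    f = ScalarField(data, (1.0, 1.0, 1.0), kind="geodesic_distance")
    cells[["y", "z"]] = 1.0
    est = estimate_tip_boundary(cells, f, window=20.0, step=10.0)
    assert est == 100.0


def test_boundary_too_few_cells():
    from branchmorph.datatypes import ScalarField

    data = np.tile(np.arange(170, dtype=float), (3, 3, 1))
    f = ScalarField(data, (1.0, 1.0, 1.0), kind="geodesic_distance")
    cells = _cells_at(np.array([[1.0, 1.0, 1.0]] * 5))
    with pytest.raises(InputError):
        estimate_tip_boundary(cells, f)


def test_boundary_recovers_scenario_extent():
    from branchmorph.synthetic import ScenarioParams, generate_elongation_scenario

    hits = 0
    n_seeds = 10
    for s in range(n_seeds):
        p = ScenarioParams(
            n_cells=600, n_frames=2, seed=300 + s, tip_cycle_fraction=0.5, duct_cycle_fraction=0.15
        )
        gt = generate_elongation_scenario(p)
        mask = gt.mask_at(0)
        f = geodesic_distance_field(mask, tuple(gt.landmarks.get("leading_edge", 0)))
        est = estimate_tip_boundary(gt.cells_at(0), f, window=20.0, step=10.0)
        if abs(est - 100.0) <= 20.0:
            hits += 1
    assert hits >= 0.8 * n_seeds
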