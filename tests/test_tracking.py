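"""Linking, drift correction and track statistics, with a matching oracle."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from branchmorph.datatypes import InputError
from branchmorph.tracking import (
    MAX_STEP_UM,
    displacement_vector,
    drift_correct,
    flow_analysis,
    link_tracks,
    step_speeds,
    track_metrics,
    track_metrics_table,
)


def _spots(rows):
    """rows: (frame, id, x, y, z, cls)"""
    return pd.DataFrame(rows, columns=["frame", "id", "x", "y", "z", "cls"])


def brute_force_matching(prev, curr, cap):
    """Max-cardinality, then min-total-distance matching under the cap."""
    n, m = len(prev), len(curr)
    d = np.linalg.norm(prev[:, None, :] - curr[None, :, :], axis=2)
    best = (-1, np.inf, [])
    k = min(n, m)
    from itertools import combinations

    for size in range(k, -1, -1):
        found = False
        for rows in combinations(range(n), size):
            for cols in permutations(range(m), size):
                if all(d[i, j] <= cap for i, j in zip(rows, cols)):
                    total = sum(d[i, j] for i, j in zip(rows, cols))
                    found = True
                    if (size, -total) > (best[0], -best[1]):
                        best = (size, total, list(zip(rows, cols)))
        if found:
            break
    return best


# ------------------------------------------------------------- drift


def test_drift_stationary_identity():
    spots = _spots([(f, f * 10 + i, float(i), 0.0, 0.0, "red") for f in range(3) for i in range(2)])
    ref = {f: np.array([5.0, 5.0, 5.0]) for f in range(3)}
    out = drift_correct(spots, ref)
    pd.testing.assert_frame_equal(out, spots)


def test_drift_constant_cancellation():
    base = _spots([(f, f * 10 + i, float(i), 1.0, 2.0, "red") for f in range(4) for i in range(3)])
    drifted = base.copy()
    drifted["x"] += drifted["frame"] * 2.0
    ref = {f: np.array([10.0 + 2.0 * f, 0.0, 0.0]) for f in range(4)}
    out = drift_correct(drifted, ref)
    np.testing.assert_allclose(out[["x", "y", "z"]], base[["x", "y", "z"]], atol=1e-12)


def test_drift_sinusoidal_residual():
    frames = np.arange(10)
    drift = np.column_stack(
        [5 * np.sin(frames / 3), 2 * np.cos(frames / 2), np.zeros(10)]
    )
    ref = {int(f): np.array([50.0, 50.0, 0.0]) + drift[f] for f in frames}
    spots = _spots(
        [(int(f), int(f), 50.0 + drift[f][0], 50.0 + drift[f][1], 0.0, "red") for f in frames]
    )
    out = drift_correct(spots, ref)
    # the reference (and anything riding on it) becomes stationary
    assert out[["x", "y", "z"]].std().max() < 1e-6


def test_drift_mostly_missing_reference():
    spots = _spots([(f, f, 0.0, 0.0, 0.0, "red") for f in range(10)])
    ref = {0: np.zeros(3), 1: np.zeros(3)}
    with pytest.raises(InputError):
        drift_correct(spots, ref)


# ------------------------------------------------------------- linking


def test_single_track_retained():
    rows = [(f, f, 5.0 * f, 0.0, 0.0, "green") for f in range(8)]
    out = link_tracks(_spots(rows), frame_interval_min=20.0)
    assert out["track_id"].nunique() == 1
    assert (out["track_id"] >= 0).all()
    m = track_metrics(out, frame_interval_min=20.0)
    assert m.duration_h == pytest.approx(7 * 20 / 60.0)


def test_over_cap_step_fragments_and_excluded():
    # 10 µm steps exceed the green 9.3 µm cap; each fragment < 2 h
    rows = [(f, f, 10.0 * f, 0.0, 0.0, "green") for f in range(4)]
    out = link_tracks(_spots(rows), frame_interval_min=20.0)
    assert (out["track_id"] == -1).all()
    assert out.attrs["n_discarded_short"] == 4


def test_no_step_exceeds_cap(elongation_gt):
    tr = elongation_gt.tracks().copy()
    tr["id"] = np.arange(len(tr))
    out = link_tracks(tr, frame_interval_min=elongation_gt.params.frame_interval)
    for tid, sub in out[out["track_id"] >= 0].groupby("track_id"):
        sub = sub.sort_values("frame")
        cap = MAX_STEP_UM[sub["cls"].iloc[0]]
        steps = np.linalg.norm(
            np.diff(sub[["x", "y", "z"]].to_numpy(), axis=0), axis=1
        )
        assert (steps <= cap + 1e-9).all()
        assert (np.diff(sub["frame"]) == 1).all()  # no gaps


def test_min_duration_exclusion():
    rows = [(f, f, 1.0 * f, 0.0, 0.0, "red") for f in range(5)]  # 4 steps = 1.33 h
    out = link_tracks(_spots(rows), frame_interval_min=20.0, min_duration_h=2.0)
    assert (out["track_id"] == -1).all()
    out2 = link_tracks(_spots(rows), frame_interval_min=40.0, min_duration_h=2.0)
    assert (out2["track_id"] >= 0).all()


def test_duplicate_ids_rejected():
    rows = [(0, 1, 0.0, 0.0, 0.0, "red"), (1, 1, 1.0, 0.0, 0.0, "red")]
    with pytest.raises(InputError):
        link_tracks(_spots(rows))


def test_classes_never_mixed():
    rows = [
        (0, 0, 0.0, 0.0, 0.0, "red"),
        (1, 1, 1.0, 0.0, 0.0, "green"),  # nearest neighbour but wrong class
        (1, 2, 30.0, 0.0, 0.0, "red"),
    ]
    out = link_tracks(_spots(rows), min_duration_h=0.0, frame_interval_min=20.0)
    t_red0 = out[out["id"] == 0]["track_id"].iloc[0]
    t_green = out[out["id"] == 1]["track_id"].iloc[0]
    assert t_red0 != t_green


@pytest.mark.parametrize("seed", range(6))
def test_matching_equals_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n, m = rng.integers(2, 6, size=2)
    prev = rng.uniform(0, 20, size=(n, 3))
    curr = rng.uniform(0, 20, size=(m, 3))
    cap = 12.0
    from branchmorph.tracking import _match_frame_pair

    got = _match_frame_pair(prev, curr, cap, "optimal")
    size, total, _ = brute_force_matching(prev, curr, cap)
    d = np.linalg.norm(prev[:, None, :] - curr[None, :, :], axis=2)
    got_total = sum(d[i, j] for i, j in got)
    assert len(got) == size
    assert got_total == pytest.approx(total, abs=1e-9)


def test_crossing_configuration_optimal():
    # two spots swap-adjacent: optimal matching picks the non-crossing pairing
    prev = np.array([[0.0, 0, 0], [4.0, 0, 0]])
    curr = np.array([[0.5, 0, 0], [4.5, 0, 0]])
    from branchmorph.tracking import _match_frame_pair

    got = sorted(_match_frame_pair(prev, curr, 8.0, "optimal"))
    assert got == [(0, 0), (1, 1)]


def test_link_identity_accuracy_on_sparse_truth():
    # nuclei spaced far beyond 2x the cap: identity must be >= 99%
    rng = np.random.default_rng(9)
    n = 40
    base = rng.uniform(0, 400, size=(n, 3))
    # enforce spacing > 2 * 9.3 via grid placement
    base = np.array(
        [[i * 25.0, (i % 5) * 25.0, (i % 3) * 25.0] for i in range(n)]
    ) + rng.uniform(0, 3, size=(n, 3))
    rows = []
    for f in range(8):
        for i in range(n):
            step = rng.uniform(-2, 2, size=3)
            base[i] += step
            rows.append((f, f * n + i, *base[i], "green"))
    out = link_tracks(_spots(rows), frame_interval_min=20.0)
    correct = 0
    for tid, sub in out[out["track_id"] >= 0].groupby("track_id"):
        ids = sub.sort_values("frame")["id"].to_numpy() % n
        correct += int((ids == ids[0]).all())
    assert correct / n >= 0.99


# ------------------------------------------------------------- metrics


def test_collinear_metrics():
    t = _spots(
        [(0, 0, 0.0, 0.0, 0.0, "red"), (1, 1, 3.0, 4.0, 0.0, "red"), (2, 2, 6.0, 8.0, 0.0, "red")]
    )
    t["track_id"] = 0
    m = track_metrics(t, frame_interval_min=20.0)
    assert m.velocity == pytest.approx(15.0)
    assert m.net_velocity == pytest.approx(15.0)
    assert m.straightness == pytest.approx(1.0)


def test_loop_metrics():
    pts = [(0.0, 0.0), (5.0, 0.0), (5.0, 5.0), (0.0, 5.0), (0.0, 0.0)]
    t = _spots([(f, f, x, y, 0.0, "red") for f, (x, y) in enumerate(pts)])
    t["track_id"] = 0
    m = track_metrics(t, frame_interval_min=20.0)
    assert m.straightness == 0.0
    assert m.net_velocity == 0.0
    assert m.velocity > 0


def test_single_point_error():
    t = _spots([(0, 0, 0.0, 0.0, 0.0, "red")])
    with pytest.raises(InputError):
        track_metrics(t, 20.0)


def test_net_velocity_leq_velocity_random_walks():
    rng = np.random.default_rng(10)
    rows = []
    for i in range(200):
        p = rng.uniform(0, 100, size=3)
        for f in range(10):
            p = p + rng.normal(0, 2, size=3)
            rows.append((f, i * 10 + f, *p, "red"))
    df = _spots(rows)
    df["track_id"] = df["id"] // 10
    mt = track_metrics_table(df, frame_interval_min=20.0)
    assert (mt["net_velocity"] <= mt["velocity"] + 1e-12).all()
    assert ((mt["straightness"] >= 0) & (mt["straightness"] <= 1)).all()


def test_straightness_decreases_with_length():
    rng = np.random.default_rng(11)
    means = []
    for n_steps in (5, 20, 80):
        vals = []
        for i in range(300):
            steps = rng.normal(0, 1, size=(n_steps, 3))
            xyz = np.cumsum(steps, axis=0)
            path = np.linalg.norm(steps, axis=1).sum()
            disp = np.linalg.norm(xyz[-1])
            vals.append(disp / path)
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]


# ------------------------------------------------------------- flow


def test_displacement_vector_basic():
    t = _spots([(0, 0, 0.0, 0.0, 0.0, "red"), (1, 1, 10.0, 0.0, 0.0, "red")])
    vec, zero = displacement_vector(t)
    np.testing.assert_allclose(vec, [10.0, 0.0, 0.0])
    assert not zero


def test_displacement_vector_loop_flagged():
    t = _spots([(0, 0, 1.0, 2.0, 3.0, "red"), (1, 1, 1.0, 2.0, 3.0, "red")])
    vec, zero = displacement_vector(t)
    assert zero


def test_flow_transition_counts():
    df = _spots(
        [
            (0, 0, 0.0, 0.0, 0.0, "red"),
            (1, 1, 1.0, 0.0, 0.0, "red"),
            (0, 2, 50.0, 0.0, 0.0, "green"),
            (1, 3, 51.0, 0.0, 0.0, "green"),
        ]
    )
    df["track_id"] = [0, 0, 1, 1]
    df["domain"] = ["tip", "duct", "duct", "duct"]
    out = flow_analysis(df)
    td = out["tip_duct"]
    assert td["tip_to_duct"] == pytest.approx(0.5)
    assert td["duct_to_tip"] == 0.0
    assert td["tip_to_duct"] + td["duct_to_tip"] + td["stationary_or_other"] == pytest.approx(1.0)


def test_flow_elongation_retrograde(elongation_gt):
    """Speed gradient => more tip->duct than duct->tip; Delta negative
    correlation with starting distance."""
    from branchmorph.geometry import geodesic_distance_field

    gt = elongation_gt
    tr = gt.tracks().copy()
    tr["id"] = np.arange(len(tr))
    out = link_tracks(tr, frame_interval_min=gt.params.frame_interval)
    f_last = gt.n_frames - 1
    fields = {}
    for f in (0, f_last):
        mask = gt.mask_at(f)
        fields[f] = geodesic_distance_field(
            mask, tuple(gt.landmarks.get("leading_edge", f))
        )
    # label start/end frames by tip/duct membership
    d0 = fields[0].sample(out[["x", "y", "z"]].to_numpy())
    d1 = fields[f_last].sample(out[["x", "y", "z"]].to_numpy())
    dist = np.where(out["frame"] == 0, d0, np.where(out["frame"] == f_last, d1, np.nan))
    out["domain"] = np.where(
        np.isnan(dist), None, np.where(dist <= 100.0, "tip", "duct")
    )
    flow = flow_analysis(out, edge_field_per_frame=fields)
    td = flow["tip_duct"]
    assert td["tip_to_duct"] > td["duct_to_tip"]
    delta = flow["edge_distance_change"]
    from scipy.stats import pearsonr

    r, _ = pearsonr(delta["start_dist"], delta["delta_dist_to_edge"])
    assert r < 0


def test_step_speeds_table():
    rows = [(f, f, 5.0 * f, 0.0, 0.0, "green") for f in range(8)]
    out = link_tracks(_spots(rows), frame_interval_min=20.0)
    sp = step_speeds(out, frame_interval_min=20.0)
    assert len(sp) == 7
    np.testing.assert_allclose(sp["speed"], 15.0)
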