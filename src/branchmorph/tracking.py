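"""Nucleus linking and track-level statistics.

Links per-frame detections into gap-free tracks by optimal bipartite
matching between consecutive frames, under hard per-class step caps
(8 µm for red/G1-G0 nuclei, 9.3 µm for green/S-G2-M); tracks shorter than
2 h are discarded.  Velocity, net velocity and straightness follow the
path-length / displacement definitions:

    velocity      = path length / duration
    net velocity  = displacement length / duration
    straightness  = displacement length / path length
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datatypes import GREEN, RED, InputError, ParameterError, ScalarField, validate_cell_table

__all__ = [
    "MAX_STEP_UM",
    "MIN_DURATION_H",
    "drift_correct",
    "link_tracks",
    "track_metrics",
    "track_metrics_table",
    "flow_analysis",
    "displacement_vector",
    "step_speeds",
]

#: per-class maximum frame-to-frame displacement (µm)
MAX_STEP_UM = {RED: 8.0, GREEN: 9.3}

#: minimum track duration kept (hours)
MIN_DURATION_H = 2.0


# --------------------------------------------------------------------------
# drift correction
# --------------------------------------------------------------------------


def drift_correct(
    cells: pd.DataFrame, reference: pd.DataFrame | dict[int, np.ndarray]
) -> pd.DataFrame:
    """Rigidly translate positions so the reference point is stationary.

    ``reference`` maps frame -> (x, y, z) µm (dict, or a table with
    ``frame, x, y, z``); frames missing a reference are linearly
    interpolated, but more than half missing is an error.  The reference
    is pinned at its frame-0 (first available) location.
    """
    validate_cell_table(cells)
    frames = np.array(sorted(cells["frame"].unique()))
    if isinstance(reference, pd.DataFrame):
        ref = {
            int(r["frame"]): np.array([r["x"], r["y"], r["z"]], dtype=float)
            for _, r in reference.iterrows()
        }
    else:
        ref = {int(k): np.asarray(v, dtype=float) for k, v in reference.items()}
    have = np.array(sorted(k for k in ref if k in set(frames)))
    if len(have) < max(1, len(frames) // 2 + (len(frames) % 2)):
        raise InputError("reference missing at more than half of the frames")
    ref_xyz = np.array([ref[f] for f in have])
    interp = np.column_stack(
        [np.interp(frames, have, ref_xyz[:, i]) for i in range(3)]
    )
    anchor = interp[0]
    shift = {int(f): anchor - interp[i] for i, f in enumerate(frames)}
    out = cells.copy()
    offsets = np.array([shift[int(f)] for f in out["frame"]])
    out[["x", "y", "z"]] = out[["x", "y", "z"]].to_numpy() + offsets
    return out


# --------------------------------------------------------------------------
# linking
# --------------------------------------------------------------------------


def _match_frame_pair(
    prev: np.ndarray, curr: np.ndarray, cap: float, method: str
) -> list[tuple[int, int]]:
    """Match rows of prev to rows of curr, minimizing total distance.

    Pairs farther apart than ``cap`` are never linked.  ``method`` is
    ``"optimal"`` (Hungarian with unlink penalty just above the cap, so an
    over-cap link is never preferred) or ``"greedy"`` (ascending-distance
    first-come).
    """
    if len(prev) == 0 or len(curr) == 0:
        return []
    d = np.linalg.norm(prev[:, None, :] - curr[None, :, :], axis=2)
    if method == "greedy":
        pairs = []
        used_p: set[int] = set()
        used_c: set[int] = set()
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        for i, j in order:
            if d[i, j] > cap:
                break
            if i in used_p or j in used_c:
                continue
            pairs.append((int(i), int(j)))
            used_p.add(int(i))
            used_c.add(int(j))
        return pairs
    # optimal: square cost matrix with dummy rows/cols at cost just above cap
    n, m = d.shape
    size = n + m
    penalty = cap * 1.000001
    cost = np.full((size, size), penalty)
    cost[:n, :m] = np.where(d <= cap, d, 2 * penalty + d)
    cost[n:, m:] = 0.0
    ri, cj = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(ri, cj)
        if i < n and j < m and d[i, j] <= cap
    ]


def link_tracks(
    spots: pd.DataFrame,
    max_step: dict[str, float] | float | None = None,
    min_duration_h: float = MIN_DURATION_H,
    frame_interval_min: float = 20.0,
    method: str = "optimal",
) -> pd.DataFrame:
    """Link per-frame spots of the same class into gap-free tracks.

    Returns the spot table with a ``track_id`` column (−1 for spots on
    discarded short tracks).  ``attrs["n_discarded_short"]`` counts tracks
    dropped by the duration filter.
    """
    validate_cell_table(spots, require_cls=True)
    if spots["id"].duplicated().any():
        raise InputError("duplicate spot ids")
    if max_step is None:
        max_step = dict(MAX_STEP_UM)
    if isinstance(max_step, (int, float)):
        max_step = {c: float(max_step) for c in spots["cls"].unique()}

    out = spots.sort_values(["frame", "id"]).reset_index(drop=True)
    out["track_id"] = -1
    next_track = 0
    frames = sorted(out["frame"].unique())
    # row index per (frame, class) for fast lookup
    for cls in sorted(out["cls"].unique()):
        cap = max_step[cls]
        open_tracks: dict[int, int] = {}  # row index of track head in prev frame -> track id
        prev_rows = out.index[(out["frame"] == frames[0]) & (out["cls"] == cls)]
        for r in prev_rows:
            out.at[r, "track_id"] = next_track
            next_track += 1
        for fa, fb in zip(frames[:-1], frames[1:]):
            prev_rows = out.index[(out["frame"] == fa) & (out["cls"] == cls)].to_numpy()
            curr_rows = out.index[(out["frame"] == fb) & (out["cls"] == cls)].to_numpy()
            if fb - fa != 1:
                # a missing frame breaks every open track (no gaps tolerated)
                for r in curr_rows:
                    out.at[r, "track_id"] = next_track
                    next_track += 1
                continue
            prev_xyz = out.loc[prev_rows, ["x", "y", "z"]].to_numpy()
            curr_xyz = out.loc[curr_rows, ["x", "y", "z"]].to_numpy()
            pairs = _match_frame_pair(prev_xyz, curr_xyz, cap, method)
            matched_curr = set()
            for i, j in pairs:
                out.at[curr_rows[j], "track_id"] = out.at[prev_rows[i], "track_id"]
                matched_curr.add(j)
            for j, r in enumerate(curr_rows):
                if j not in matched_curr:
                    out.at[r, "track_id"] = next_track
                    next_track += 1

    # duration filter
    n_short = 0
    for tid, sub in out.groupby("track_id"):
        dur_h = (sub["frame"].max() - sub["frame"].min()) * frame_interval_min / 60.0
        if dur_h < min_duration_h:
            out.loc[sub.index, "track_id"] = -1
            n_short += 1
    out.attrs["n_discarded_short"] = n_short
    return out


# --------------------------------------------------------------------------
# per-track metrics
# --------------------------------------------------------------------------


@dataclass
class TrackMetrics:
    track_id: int
    cls: str
    n_points: int
    duration_h: float
    path_length: float
    displacement: float
    velocity: float
    net_velocity: float
    straightness: float


def track_metrics(track: pd.DataFrame, frame_interval_min: float) -> TrackMetrics:
    """Metrics of one track (ordered rows of one track_id)."""
    if len(track) < 2:
        raise InputError("track needs at least two points")
    track = track.sort_values("frame")
    xyz = track[["x", "y", "z"]].to_numpy(dtype=float)
    steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    path = float(steps.sum())
    disp = float(np.linalg.norm(xyz[-1] - xyz[0]))
    dur = (track["frame"].iloc[-1] - track["frame"].iloc[0]) * frame_interval_min / 60.0
    return TrackMetrics(
        track_id=int(track["track_id"].iloc[0]) if "track_id" in track else -1,
        cls=str(track["cls"].iloc[0]) if "cls" in track else "generic",
        n_points=len(track),
        duration_h=dur,
        path_length=path,
        displacement=disp,
        velocity=path / dur if dur > 0 else float("nan"),
        net_velocity=disp / dur if dur > 0 else float("nan"),
        straightness=disp / path if path > 0 else 0.0,
    )


def track_metrics_table(tracks: pd.DataFrame, frame_interval_min: float) -> pd.DataFrame:
    """Metrics for every retained track (track_id >= 0)."""
    rows = []
    for tid, sub in tracks[tracks["track_id"] >= 0].groupby("track_id"):
        if len(sub) < 2:
            continue
        rows.append(vars(track_metrics(sub, frame_interval_min)))
    return pd.DataFrame(rows)


def displacement_vector(track: pd.DataFrame) -> tuple[np.ndarray, bool]:
    """(end − start) displacement vector and a zero-displacement flag."""
    if len(track) < 2:
        raise InputError("track needs at least two points")
    track = track.sort_values("frame")
    xyz = track[["x", "y", "z"]].to_numpy(dtype=float)
    vec = xyz[-1] - xyz[0]
    return vec, bool(np.allclose(vec, 0.0))


def step_speeds(tracks: pd.DataFrame, frame_interval_min: float) -> pd.DataFrame:
    """Instantaneous per-step speeds (µm/h) for every retained track."""
    dt_h = frame_interval_min / 60.0
    rows = []
    for tid, sub in tracks[tracks["track_id"] >= 0].groupby("track_id"):
        sub = sub.sort_values("frame")
        xyz = sub[["x", "y", "z"]].to_numpy(dtype=float)
        sp = np.linalg.norm(np.diff(xyz, axis=0), axis=1) / dt_h
        for f, s in zip(sub["frame"].to_numpy()[:-1], sp):
            rows.append({"track_id": tid, "frame": int(f), "speed": float(s)})
    return pd.DataFrame(rows, columns=["track_id", "frame", "speed"])


# --------------------------------------------------------------------------
# flow analysis
# --------------------------------------------------------------------------


def flow_analysis(
    tracks: pd.DataFrame,
    edge_field_per_frame: dict[int, ScalarField] | None = None,
) -> dict:
    """Start-vs-end transition fractions plus per-track edge-distance change.

    ``tracks`` must carry ``track_id`` and, where the respective statistic
    is wanted, ``domain`` and/or ``compartment`` columns.  The
    distance-to-edge change is ``d(start) − d(end)`` — positive means the
    cell ended closer to the leading edge (kept pace or advanced).
    """
    if "track_id" not in tracks.columns:
        raise InputError("tracks need a 'track_id' column")
    kept = tracks[tracks["track_id"] >= 0]
    summary: dict = {"n_tracks": int(kept["track_id"].nunique())}
    ends = []
    for tid, sub in kept.groupby("track_id"):
        sub = sub.sort_values("frame")
        ends.append((tid, sub.iloc[0], sub.iloc[-1]))

    def _transition(col: str, a: str, b: str) -> dict:
        n_ab = n_ba = n_other = n_missing = 0
        for _, s, e in ends:
            la, lb = s.get(col), e.get(col)
            if la is None or lb is None or pd.isna(la) or pd.isna(lb):
                n_missing += 1
            elif la == a and lb == b:
                n_ab += 1
            elif la == b and lb == a:
                n_ba += 1
            else:
                n_other += 1
        n = n_ab + n_ba + n_other
        return {
            f"{a}_to_{b}": n_ab / n if n else float("nan"),
            f"{b}_to_{a}": n_ba / n if n else float("nan"),
            "stationary_or_other": n_other / n if n else float("nan"),
            "n_scored": n,
            "n_missing": n_missing,
        }

    if "domain" in kept.columns:
        summary["tip_duct"] = _transition("domain", "tip", "duct")
        # movement out of / into the branch point, per cycle class
        if (kept["domain"] == "branch_point").any() or (
            kept["domain"] == "cleft_region"
        ).any():
            bp_label = (
                "branch_point"
                if (kept["domain"] == "branch_point").any()
                else "cleft_region"
            )
            per_cls = {}
            for cls in sorted(kept["cls"].unique()) if "cls" in kept.columns else []:
                sub_ends = [
                    (s, e) for _, s, e in ends if s.get("cls") == cls
                ]
                started = [
                    (s, e) for s, e in sub_ends if s.get("domain") == bp_label
                ]
                moved_out = [1 for s, e in started if e.get("domain") != bp_label]
                per_cls[cls] = {
                    "n_started_in_branch_point": len(started),
                    "fraction_moved_out": (
                        len(moved_out) / len(started) if started else float("nan")
                    ),
                }
            summary["branch_point_exit"] = per_cls
    if "compartment" in kept.columns:
        summary["basal_inner"] = _transition("compartment", "basal", "inner")

    if edge_field_per_frame is not None:
        deltas = []
        for tid, s, e in ends:
            fs, fe = int(s["frame"]), int(e["frame"])
            if fs not in edge_field_per_frame or fe not in edge_field_per_frame:
                continue
            d0 = edge_field_per_frame[fs].sample([[s["x"], s["y"], s["z"]]])[0]
            d1 = edge_field_per_frame[fe].sample([[e["x"], e["y"], e["z"]]])[0]
            if np.isfinite(d0) and np.isfinite(d1):
                deltas.append({"track_id": tid, "delta_dist_to_edge": float(d0 - d1),
                               "start_dist": float(d0)})
        summary["edge_distance_change"] = pd.DataFrame(
            deltas, columns=["track_id", "delta_dist_to_edge", "start_dist"]
        )
    return summary
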