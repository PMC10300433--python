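"""Spatial cell-cycle statistics.

Green (S/G2/M) fractions per group, distance-binned profiles, the
branch-point-to-tip ratio time series around cleft appearance (T0), and
per-cell keratin dominance classification with the gray-value floor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GREEN, RED, InputError, ParameterError, ScalarField, validate_cell_table

__all__ = [
    "cycle_fraction",
    "distance_profile",
    "branchpoint_tip_ratio",
    "classify_marker_dominance",
    "KERATIN_FLOOR",
]

#: minimum gray value below which a cell counts as marker-negative
KERATIN_FLOOR = 25.0

#: minimum cells per region-frame for a ratio to be trusted
MIN_CELLS_PER_REGION = 10


def cycle_fraction(cells: pd.DataFrame, group_by: list[str] | str) -> pd.DataFrame:
    """Green fraction per group.

    Returns one row per group with ``n_green``, ``n_red``, ``n`` and
    ``fraction`` (NaN, flagged ``undefined=True``, when the group is
    empty of classified cells).
    """
    validate_cell_table(cells, require_cls=True)
    if isinstance(group_by, str):
        group_by = [group_by]
    for key in group_by:
        if key not in cells.columns:
            raise InputError(f"group key {key!r} not in cell table")
    rows = []
    # observed=False so empty categorical groups surface as flagged rows
    for keys, sub in cells.groupby(group_by, dropna=False, observed=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        n_green = int((sub["cls"] == GREEN).sum())
        n_red = int((sub["cls"] == RED).sum())
        n = n_green + n_red
        rows.append(
            dict(zip(group_by, keys))
            | {
                "n_green": n_green,
                "n_red": n_red,
                "n": n,
                "fraction": (n_green / n) if n else float("nan"),
                "undefined": n == 0,
            }
        )
    return pd.DataFrame(rows)


def distance_profile(
    cells: pd.DataFrame,
    field: ScalarField | None = None,
    bin_width: float = 1.0,
    distances: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cell count and green fraction per right-open distance bin.

    Distances are sampled from ``field`` at the cell positions unless
    given directly.  Bins are ``[k*w, (k+1)*w)``; cells whose distance is
    NaN/inf are reported in the ``n_unassigned`` attribute column of the
    result's ``attrs``.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    validate_cell_table(cells, require_cls=True)
    if distances is None:
        if field is None:
            raise InputError("need a field or explicit distances")
        distances = field.sample(cells[["x", "y", "z"]].to_numpy())
    distances = np.asarray(distances, dtype=float)
    ok = np.isfinite(distances)
    d = distances[ok]
    green = (cells["cls"].to_numpy() == GREEN)[ok]
    if d.size == 0:
        out = pd.DataFrame(columns=["bin_left", "bin_right", "n", "n_green", "fraction"])
        out.attrs["n_unassigned"] = int((~ok).sum())
        return out
    idx = np.floor(d / bin_width).astype(int)
    rows = []
    for k in range(idx.max() + 1):
        sel = idx == k
        n = int(sel.sum())
        ng = int(green[sel].sum())
        rows.append(
            {
                "bin_left": k * bin_width,
                "bin_right": (k + 1) * bin_width,
                "n": n,
                "n_green": ng,
                "fraction": (ng / n) if n else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_unassigned"] = int((~ok).sum())
    return out


def branchpoint_tip_ratio(
    cells: pd.DataFrame,
    t0_frame: int,
    frame_interval_min: float,
    branch_label: str = "cleft_region",
    tip_label: str = "daughter_tip",
    min_cells: int = MIN_CELLS_PER_REGION,
) -> pd.DataFrame:
    """Per-frame branch-point vs daughter-tip green-fraction ratio.

    The time axis is hours relative to T0 (cleft appearance).  Frames in
    which either region holds fewer than ``min_cells`` classified cells
    are flagged ``low_n=True`` (ratio still reported when defined).
    """
    validate_cell_table(cells, require_cls=True)
    if "domain" not in cells.columns:
        raise InputError("cells need a 'domain' column (run assign_domains)")
    frames = sorted(cells["frame"].unique())
    if t0_frame not in frames:
        raise InputError(f"t0 frame {t0_frame} not present in the cell table")
    rows = []
    for f in frames:
        sub = cells[cells["frame"] == f]
        bp = sub[sub["domain"] == branch_label]
        tp = sub[sub["domain"] == tip_label]
        fb = (bp["cls"] == GREEN).mean() if len(bp) else float("nan")
        ft = (tp["cls"] == GREEN).mean() if len(tp) else float("nan")
        ratio = fb / ft if len(bp) and len(tp) and ft > 0 else float("nan")
        rows.append(
            {
                "frame": f,
                "time_h": (f - t0_frame) * frame_interval_min / 60.0,
                "branch_fraction": fb,
                "tip_fraction": ft,
                "n_branch": len(bp),
                "n_tip": len(tp),
                "ratio": ratio,
                "low_n": (len(bp) < min_cells) or (len(tp) < min_cells),
            }
        )
    return pd.DataFrame(rows)


def classify_marker_dominance(
    cells: pd.DataFrame,
    k14_col: str = "K14",
    k8_col: str = "K8",
    floor: float = KERATIN_FLOOR,
) -> pd.DataFrame:
    """Classify each cell by its dominant keratin.

    Cells negative for both markers (both gray values below ``floor``) are
    excluded; otherwise the higher channel wins and exact ties go to K8.
    The K14/K8 ratio is returned for distance-trend analyses.
    """
    for col in (k14_col, k8_col):
        if col not in cells.columns:
            raise InputError(f"column {col!r} missing")
    k14 = cells[k14_col].to_numpy(dtype=float)
    k8 = cells[k8_col].to_numpy(dtype=float)
    if (k14 < 0).any() or (k8 < 0).any():
        raise InputError("negative marker intensities")
    out = cells.copy()
    excluded = (k14 < floor) & (k8 < floor)
    dominance = np.where(k14 > k8, "K14", "K8")  # ties -> K8
    out["dominance"] = np.where(excluded, "excluded", dominance)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["k14_k8_ratio"] = np.where(k8 > 0, k14 / k8, np.inf)
    out["floor_used"] = floor
    return out
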