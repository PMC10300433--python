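"""Shared domain types.

Coordinate conventions
----------------------
* Physical coordinates are always ``(x, y, z)`` in micrometres (µm).
* Voxel arrays are indexed ``(z, y, x)`` (NumPy order); voxel sizes are
  stored ``(z, y, x)`` in µm to match.
* Time is indexed by integer frame; the frame interval is carried in
  minutes and durations are reported in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical cycle-class labels (green = S/G2/M reporter, red = G1/G0)
GREEN = "green"
RED = "red"
CYCLE_CLASSES = (GREEN, RED)

#: columns every cell table must provide
CELL_COLUMNS = ("frame", "id", "x", "y", "z", "cls")


class ParameterError(ValueError):
    """A parameter violates its documented contract."""


class InputError(ValueError):
    """An input (stack, table, landmark set, ...) violates a precondition."""


@dataclass
class VoxelStack:
    """Multi-channel 3D(+T) intensity grid with physical metadata.

    Parameters
    ----------
    data:
        Array of shape ``(T, C, Z, Y, X)``.  Single-frame data may be
        passed as ``(C, Z, Y, X)`` and is promoted to ``T=1``.
    voxel_size:
        ``(z, y, x)`` voxel edge lengths in µm.
    frame_interval_min:
        Time between frames in minutes (ignored for ``T == 1``).
    channel_names:
        Optional channel identifiers, e.g. ``("green", "red")``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_interval_min: float = 0.0
    channel_names: tuple[str, ...] = ()
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (z, y, x)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 4:
            arr = arr[np.newaxis]
        if arr.ndim != 5:
            raise InputError(
                f"stack must be (T,C,Z,Y,X) or (C,Z,Y,X); got ndim={arr.ndim}"
            )
        self.data = arr
        vz, vy, vx = self.voxel_size
        if min(vz, vy, vx) <= 0:
            raise ParameterError("voxel sizes must be positive")
        self.voxel_size = (float(vz), float(vy), float(vx))
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(arr.shape[1]))
        if len(self.channel_names) != arr.shape[1]:
            raise InputError("channel_names length mismatch")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise InputError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError as exc:
            raise InputError(
                f"channel {channel!r} not in {self.channel_names}"
            ) from exc

    def get(self, frame: int, channel: int | str) -> np.ndarray:
        """Return one ``(Z, Y, X)`` volume."""
        return self.data[frame, self.channel_index(channel)]


@dataclass
class EpithelialMask:
    """Binary voxel mask of the epithelium on an (ideally isotropic) grid.

    ``origin`` is the physical ``(z, y, x)`` position (µm) of the centre of
    voxel ``[0, 0, 0]``; grids covering negative coordinates carry a
    negative origin.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    frame: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise InputError("mask must be a 3D (Z,Y,X) array")
        if not self.data.any():
            raise InputError("mask has no foreground voxels")
        vz, vy, vx = self.voxel_size
        if min(vz, vy, vx) <= 0:
            raise ParameterError("voxel sizes must be positive")
        self.voxel_size = (float(vz), float(vy), float(vx))

    @property
    def is_isotropic(self) -> bool:
        vz, vy, vx = self.voxel_size
        return abs(vz - vy) < 1e-9 and abs(vy - vx) < 1e-9

    def n_components(self, connectivity: int = 3) -> int:
        from scipy import ndimage

        structure = ndimage.generate_binary_structure(3, connectivity)
        _, n = ndimage.label(self.data, structure=structure)
        return int(n)

    def voxel_indices(self, xyz_um: np.ndarray) -> np.ndarray:
        """Nearest voxel (z, y, x) index per physical (x, y, z) point."""
        xyz_um = np.atleast_2d(np.asarray(xyz_um, dtype=float))
        vz, vy, vx = self.voxel_size
        oz, oy, ox = self.origin
        return np.round(
            np.column_stack(
                [
                    (xyz_um[:, 2] - oz) / vz,
                    (xyz_um[:, 1] - oy) / vy,
                    (xyz_um[:, 0] - ox) / vx,
                ]
            )
        ).astype(int)

    def contains_points(self, xyz_um: np.ndarray) -> np.ndarray:
        """Boolean per point: does the point fall on a foreground voxel."""
        xyz_um = np.atleast_2d(np.asarray(xyz_um, dtype=float))
        idx = self.voxel_indices(xyz_um)
        inside = np.all(idx >= 0, axis=1) & np.all(
            idx < np.array(self.data.shape), axis=1
        )
        out = np.zeros(len(xyz_um), dtype=bool)
        out[inside] = self.data[tuple(idx[inside].T)]
        return out


@dataclass
class ScalarField:
    """Per-voxel distance field in µm over a mask's grid.

    ``kind`` is ``"surface_distance"`` or ``"geodesic_distance"``.
    Voxels outside the domain of definition (background, or unreachable
    foreground for geodesics) hold ``+inf``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    kind: str
    mask: EpithelialMask | None = None
    source: str = ""
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InputError("field must be a 3D (Z,Y,X) array")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and finite.min() < -1e-9:
            raise InputError("distance fields must be non-negative")

    def sample(self, xyz_um: np.ndarray) -> np.ndarray:
        """Trilinear sample at physical positions; NaN outside the domain.

        Interpolation is validity-weighted so domain-boundary voxels do not
        poison their neighbours: a sample is finite when at least half of
        its trilinear weight falls on in-domain voxels.
        """
        from scipy import ndimage

        xyz_um = np.atleast_2d(np.asarray(xyz_um, dtype=float))
        vz, vy, vx = self.voxel_size
        oz, oy, ox = self.origin
        coords = np.vstack(
            [
                (xyz_um[:, 2] - oz) / vz,
                (xyz_um[:, 1] - oy) / vy,
                (xyz_um[:, 0] - ox) / vx,
            ]
        )
        valid = np.isfinite(self.data)
        filled = np.where(valid, self.data, 0.0)
        num = ndimage.map_coordinates(filled, coords, order=1, mode="constant", cval=0.0)
        den = ndimage.map_coordinates(
            valid.astype(float), coords, order=1, mode="constant", cval=0.0
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den >= 0.5, num / np.maximum(den, 1e-12), np.nan)
        return out


@dataclass
class LandmarkSet:
    """Named reference points per frame plus the T0 annotation.

    Backed by a tidy table with columns ``frame, name, x, y, z`` (µm).
    """

    table: pd.DataFrame
    t0_frame: int | None = None

    REQUIRED = ("frame", "name", "x", "y", "z")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise InputError(f"landmark table missing columns {missing}")
        self.table = self.table.reset_index(drop=True)

    def get(self, name: str, frame: int) -> np.ndarray | None:
        sel = self.table[
            (self.table["name"] == name) & (self.table["frame"] == frame)
        ]
        if sel.empty:
            return None
        return sel[["x", "y", "z"]].to_numpy(dtype=float)[0]

    def get_all(self, name: str, frame: int) -> np.ndarray:
        sel = self.table[
            (self.table["name"] == name) & (self.table["frame"] == frame)
        ]
        return sel[["x", "y", "z"]].to_numpy(dtype=float)

    def names(self, frame: int | None = None) -> list[str]:
        t = self.table if frame is None else self.table[self.table["frame"] == frame]
        return sorted(t["name"].unique())

    @classmethod
    def from_records(
        cls,
        records: Sequence[tuple[int, str, float, float, float]],
        t0_frame: int | None = None,
    ) -> "LandmarkSet":
        df = pd.DataFrame(records, columns=list(cls.REQUIRED))
        return cls(df, t0_frame=t0_frame)


def validate_cell_table(cells: pd.DataFrame, require_cls: bool = False) -> pd.DataFrame:
    """Check a cell table for the canonical columns; returns it unchanged."""
    needed = ["frame", "id", "x", "y", "z"] + (["cls"] if require_cls else [])
    missing = [c for c in needed if c not in cells.columns]
    if missing:
        raise InputError(f"cell table missing columns {missing}")
    if require_cls:
        bad = set(cells["cls"].unique()) - set(CYCLE_CLASSES)
        if bad:
            raise InputError(f"unknown cycle classes {sorted(bad)}")
    return cells
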