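"""Nuclear spot detection and intensity quantification.

Spot detection is scale-matched Laplacian-of-Gaussian filtering with
anisotropy-aware per-axis sigmas, followed by local-maximum suppression at
a minimum physical separation.  Default diameters follow the fixed-image
convention: 6 µm for the red (G1/G0) channel and 7 µm for the green
(S/G2/M) channel.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .datatypes import EpithelialMask, InputError, ParameterError, VoxelStack

__all__ = [
    "DEFAULT_DIAMETERS",
    "detect_nuclei",
    "normalize_contrast",
    "regional_mean_intensity",
    "nuclear_intensity_by_size_filter",
]

#: per-channel default spot diameters (µm)
DEFAULT_DIAMETERS = {"red": 6.0, "green": 7.0}

#: suppression radius as a fraction of the spot diameter; spots are kept
#: slightly smaller than nuclei so touching neighbours stay separable
SEPARATION_FACTOR = 0.75


def detect_nuclei(
    stack: VoxelStack,
    channel: int | str,
    diameter: float | None = None,
    intensity_threshold: float | str = "auto",
    frame: int | None = None,
    separation_factor: float = SEPARATION_FACTOR,
) -> pd.DataFrame:
    """Detect blob-like nuclei in one channel of a stack.

    Parameters
    ----------
    stack:
        Input :class:`VoxelStack`.
    channel:
        Channel name or index.
    diameter:
        Expected nucleus diameter in µm.  ``None`` picks the per-channel
        default (6 µm red, 7 µm green) when the channel name is known.
    intensity_threshold:
        Minimum blob response (a.u.), or ``"auto"`` for Otsu on the
        positive response distribution.
    frame:
        Restrict to one frame; default all frames.

    Returns
    -------
    DataFrame with columns ``frame, id, channel, x, y, z, peak, response``
    — positions in physical µm (stack origin applied).
    """
    ci = stack.channel_index(channel)
    cname = stack.channel_names[ci]
    if diameter is None:
        if cname not in DEFAULT_DIAMETERS:
            raise ParameterError(
                f"no default diameter for channel {cname!r}; pass diameter="
            )
        diameter = DEFAULT_DIAMETERS[cname]
    vz, vy, vx = stack.voxel_size
    if diameter < 2.0 * min(vz, vy, vx):
        raise ParameterError("diameter must be >= 2x the smallest voxel dimension")

    # LoG scale: blob radius r matches sigma*sqrt(ndim) for a 3D Gaussian blob
    sigma_um = (diameter / 2.0) / np.sqrt(3.0)
    sigma_vox = (sigma_um / vz, sigma_um / vy, sigma_um / vx)
    sep_um = diameter * separation_factor
    foot = tuple(
        max(1, int(round(sep_um / v)) * 2 + 1) for v in (vz, vy, vx)
    )

    frames = range(stack.n_frames) if frame is None else [frame]
    oz, oy, ox = stack.origin_um
    rows = []
    next_id = 0
    for f in frames:
        vol = stack.get(f, ci).astype(float)
        # negated LoG: bright blobs become positive peaks
        resp = -ndimage.gaussian_laplace(vol, sigma=sigma_vox)
        pos = resp[resp > 0]
        if pos.size == 0:
            continue
        if intensity_threshold == "auto":
            thr = float(threshold_otsu(pos))
        else:
            thr = float(intensity_threshold)
        maxima = (resp == ndimage.maximum_filter(resp, size=foot)) & (resp > thr)
        zz, yy, xx = np.nonzero(maxima)
        order = np.argsort(-resp[zz, yy, xx])
        zz, yy, xx = zz[order], yy[order], xx[order]
        # greedy physical-distance suppression for plateaus/close seeds
        kept: list[int] = []
        pts = np.column_stack([xx * vx + ox, yy * vy + oy, zz * vz + oz])
        for i in range(len(pts)):
            if all(np.linalg.norm(pts[i] - pts[j]) >= sep_um for j in kept):
                kept.append(i)
        for i in kept:
            rows.append(
                {
                    "frame": f,
                    "id": next_id,
                    "channel": cname,
                    "x": pts[i, 0],
                    "y": pts[i, 1],
                    "z": pts[i, 2],
                    "peak": float(vol[zz[i], yy[i], xx[i]]),
                    "response": float(resp[zz[i], yy[i], xx[i]]),
                }
            )
            next_id += 1
    cols = ["frame", "id", "channel", "x", "y", "z", "peak", "response"]
    return pd.DataFrame(rows, columns=cols)


def detect_nuclei_two_channel(
    stack: VoxelStack,
    diameters: dict[str, float] | None = None,
    intensity_threshold: float | str = "auto",
    frame: int | None = None,
) -> pd.DataFrame:
    """Detect both Fucci channels and resolve doubly detected loci.

    When a green and a red spot fall within half the larger diameter of
    each other, the one with the higher normalized blob response wins;
    exact ties go to green.  Returns a cell table with a ``cls`` column.
    """
    diameters = diameters or DEFAULT_DIAMETERS
    parts = []
    for ch in ("green", "red"):
        det = detect_nuclei(
            stack, ch, diameters[ch], intensity_threshold, frame=frame
        )
        det = det.rename(columns={"channel": "cls"})
        if not det.empty:
            med = det["response"].median()
            det["norm_response"] = det["response"] / (med if med > 0 else 1.0)
        parts.append(det)
    both = pd.concat(parts, ignore_index=True)
    if both.empty:
        return both
    cut = max(diameters.values()) / 2.0
    keep = np.ones(len(both), dtype=bool)
    for f, sub in both.groupby("frame"):
        g = sub[sub["cls"] == "green"]
        r = sub[sub["cls"] == "red"]
        if g.empty or r.empty:
            continue
        gp = g[["x", "y", "z"]].to_numpy()
        rp = r[["x", "y", "z"]].to_numpy()
        d = np.linalg.norm(gp[:, None, :] - rp[None, :, :], axis=2)
        for gi, ri in zip(*np.where(d < cut)):
            g_row, r_row = g.iloc[gi], r.iloc[ri]
            if r_row["norm_response"] > g_row["norm_response"]:
                keep[both.index.get_loc(g.index[gi])] = False
            else:  # ties -> green
                keep[both.index.get_loc(r.index[ri])] = False
    out = both[keep].reset_index(drop=True)
    out["id"] = np.arange(len(out))
    return out


def normalize_contrast(
    image: np.ndarray, saturated_fraction: float = 0.0002
) -> np.ndarray:
    """Linear contrast stretch saturating a fixed pixel fraction.

    ``saturated_fraction / 2`` of the pixels are clipped at each tail and
    the remaining range is mapped onto the full dtype range.  Constant
    images are returned unchanged.
    """
    if not 0.0 <= saturated_fraction < 1.0:
        raise ParameterError("saturated_fraction must be in [0, 1)")
    image = np.asarray(image)
    if image.size == 0:
        raise InputError("empty image")
    lo = np.quantile(image, saturated_fraction / 2.0)
    hi = np.quantile(image, 1.0 - saturated_fraction / 2.0)
    if hi <= lo:
        return image.copy()
    if np.issubdtype(image.dtype, np.integer):
        out_max = float(np.iinfo(image.dtype).max)
        dtype = image.dtype
    else:
        out_max = 1.0
        dtype = image.dtype
    scaled = (image.astype(float) - lo) / (hi - lo) * out_max
    scaled = np.clip(scaled, 0.0, out_max)
    return scaled.astype(dtype) if np.issubdtype(dtype, np.integer) else scaled


def regional_mean_intensity(
    stack: VoxelStack,
    center: tuple[float, float, float],
    radius: float,
    partition_mask: EpithelialMask | None = None,
    channel: int | str = 0,
    frame: int = 0,
) -> dict[str, dict[str, float]]:
    """Intensity statistics inside a physical ball, optionally split by a mask.

    Returns ``{region: {"sum": .., "mean": .., "voxel_count": ..}}`` with
    regions ``"all"`` (always) plus ``"epithelium"`` / ``"mesenchyme"``
    when a partition mask is given.  The split sums add up to the unsplit
    sum exactly.
    """
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    vol = stack.get(frame, channel).astype(float)
    vz, vy, vx = stack.voxel_size
    oz, oy, ox = stack.origin_um
    cx, cy, cz = center
    nz, ny, nx = vol.shape
    zc = oz + vz * np.arange(nz)
    yc = oy + vy * np.arange(ny)
    xc = ox + vx * np.arange(nx)
    inside = (
        ((zc[:, None, None] - cz) ** 2)
        + ((yc[None, :, None] - cy) ** 2)
        + ((xc[None, None, :] - cx) ** 2)
    ) <= radius**2
    if not inside.any():
        raise InputError("ball does not intersect the stack")

    def _stats(sel: np.ndarray) -> dict[str, float]:
        n = int(sel.sum())
        s = float(vol[sel].sum()) if n else 0.0
        return {"sum": s, "mean": (s / n) if n else float("nan"), "voxel_count": n}

    out = {"all": _stats(inside)}
    if partition_mask is not None:
        pts_z, pts_y, pts_x = np.nonzero(inside)
        xyz = np.column_stack(
            [xc[pts_x], yc[pts_y], zc[pts_z]]
        )
        in_epi = partition_mask.contains_points(xyz)
        epi = np.zeros_like(inside)
        epi[pts_z[in_epi], pts_y[in_epi], pts_x[in_epi]] = True
        out["epithelium"] = _stats(inside & epi)
        out["mesenchyme"] = _stats(inside & ~epi)
    return out


def nuclear_intensity_by_size_filter(
    labels: np.ndarray,
    intensity: np.ndarray,
    min_size: float = 20.0,
    max_size: float = 120.0,
    pixel_size_um: float = 1.0,
    size_metric: str = "area_um2",
) -> pd.DataFrame:
    """Per-nucleus mean intensity after a size filter on a 2D label image.

    Regions whose size (area in µm², or equivalent diameter in µm,
    depending on ``size_metric``) falls outside ``[min_size, max_size]``
    are dropped — this keeps single nuclei and discards debris and merged
    clumps.
    """
    labels = np.asarray(labels)
    intensity = np.asarray(intensity, dtype=float)
    if labels.shape != intensity.shape:
        raise InputError("labels and intensity must be congruent")
    if size_metric not in ("area_um2", "equivalent_diameter_um"):
        raise ParameterError(f"unknown size_metric {size_metric!r}")
    rows = []
    for rp in regionprops(labels, intensity_image=intensity):
        if size_metric == "area_um2":
            size = rp.area * pixel_size_um**2
        else:
            size = rp.equivalent_diameter * pixel_size_um
        if min_size <= size <= max_size:
            rows.append(
                {"label": rp.label, "mean_intensity": rp.intensity_mean, "size": size}
            )
    if not rows:
        warnings.warn("no regions survived the size filter", stacklevel=2)
    return pd.DataFrame(rows, columns=["label", "mean_intensity", "size"])
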