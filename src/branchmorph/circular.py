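"""Directional statistics for displacement-vector analyses.

Angles between displacement vectors and a reference direction are
computed in the xy projection, signed counterclockwise in [0, 360) or
folded to [0, 180] (parallel = 0°, antiparallel = 180°).  Uniformity is
tested with the Rayleigh test and two samples are compared with Watson's
two-sample U² (permutation p by default; the classic asymptotic series is
available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import InputError, ParameterError

__all__ = [
    "angle_to_reference",
    "fold_angle",
    "rayleigh_test",
    "watson_u2_two_sample",
    "rose_histogram",
    "CircularTestResult",
]


@dataclass
class CircularTestResult:
    statistic: float
    p_value: float
    n: int
    m: int | None = None
    method: str = ""
    mean_resultant_length: float | None = None


def angle_to_reference(
    vec,
    ref,
    folded: bool = False,
    projection: str = "xy",
) -> float:
    """Angle (degrees) of ``vec`` relative to ``ref``.

    With ``projection="xy"`` both vectors are projected to the xy-plane
    and the angle is signed counterclockwise in [0, 360) (the sign comes
    from the cross-product z component); ``projection="none"`` gives the
    unsigned 3D angle in [0, 180].  ``folded=True`` maps signed angles to
    [0, 180] via min(θ, 360−θ).
    """
    v = np.asarray(vec, dtype=float)
    r = np.asarray(ref, dtype=float)
    if projection == "xy":
        v2, r2 = v[:2], r[:2]
        if np.linalg.norm(v2) == 0 or np.linalg.norm(r2) == 0:
            raise InputError("zero-length projected vector")
        theta = np.degrees(
            np.arctan2(
                r2[0] * v2[1] - r2[1] * v2[0],  # cross z
                float(r2 @ v2),
            )
        )
        theta = theta % 360.0
        return fold_angle(theta) if folded else float(theta)
    if projection == "none":
        if np.linalg.norm(v) == 0 or np.linalg.norm(r) == 0:
            raise InputError("zero-length vector")
        c = float(v @ r / (np.linalg.norm(v) * np.linalg.norm(r)))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    raise ParameterError(f"unknown projection {projection!r}")


def fold_angle(theta_deg: float | np.ndarray) -> float | np.ndarray:
    """Fold signed angles [0, 360) onto [0, 180]."""
    t = np.asarray(theta_deg, dtype=float) % 360.0
    out = np.minimum(t, 360.0 - t)
    return float(out) if np.isscalar(theta_deg) else out


def rayleigh_test(
    angles_deg, folded: bool = False, double_folded: bool = True
) -> CircularTestResult:
    """Rayleigh test of circular uniformity.

    ``R̄`` is the mean resultant length, ``Z = n R̄²`` and the p-value uses
    the standard small-sample-corrected exponential approximation.  Folded
    ([0, 180]) samples are, by default, tested on the doubled-angle circle
    (the axial-data correction); set ``double_folded=False`` for the naive
    treatment.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    if n < 4:
        raise InputError("Rayleigh test needs n >= 4")
    if n < 10:
        import warnings

        warnings.warn("Rayleigh test is unreliable below n = 10", stacklevel=2)
    note = "rayleigh"
    if folded and double_folded:
        a = 2.0 * a
        note = "rayleigh (doubled angles, axial data)"
    rad = np.deg2rad(a)
    C, S = np.cos(rad).sum(), np.sin(rad).sum()
    rbar = float(np.sqrt(C**2 + S**2) / n)
    Z = n * rbar**2
    # Wilkie / Zar small-sample correction
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z**2) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n**2)
    )
    p = float(np.clip(p, 0.0, 1.0))
    return CircularTestResult(
        statistic=float(Z), p_value=p, n=n, method=note, mean_resultant_length=rbar
    )


def _watson_u2_stat(a_rad: np.ndarray, b_rad: np.ndarray) -> float:
    """Watson two-sample U² via the pooled-rank formulation (midrank ties)."""
    n, m = a_rad.size, b_rad.size
    N = n + m
    pooled = np.concatenate([a_rad, b_rad]) % (2 * np.pi)
    labels = np.concatenate([np.zeros(n, dtype=bool), np.ones(m, dtype=bool)])
    order = np.argsort(pooled, kind="mergesort")
    pooled, labels = pooled[order], labels[order]
    # cumulative empirical CDF steps; ties handled by averaging d_k over
    # tied blocks (midrank treatment)
    cdf_a = np.cumsum(~labels) / n
    cdf_b = np.cumsum(labels) / m
    d = cdf_a - cdf_b
    # average d within blocks of tied pooled values
    uniq, inv, counts = np.unique(pooled, return_inverse=True, return_counts=True)
    if len(uniq) != N:
        d_block = np.zeros(len(uniq))
        np.add.at(d_block, inv, d)
        d = (d_block / counts)[inv]
    dbar = d.mean()
    return float(n * m / N**2 * np.sum((d - dbar) ** 2))


def _watson_asymptotic_p(u2: float, terms: int = 50) -> float:
    k = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * np.pi**2 * u2))
    return float(np.clip(p, 0.0, 1.0))


def watson_u2_two_sample(
    a_deg,
    b_deg,
    p_mode: str = "permutation",
    n_perm: int = 999,
    seed: int | None = None,
) -> CircularTestResult:
    """Watson's two-sample U² test of homogeneity on the circle.

    ``p_mode="permutation"`` (default) relabels the pooled sample
    ``n_perm`` times; ``"asymptotic"`` uses the classic series and needs
    n, m >= 8 with n + m >= 17.
    """
    a = np.deg2rad(np.asarray(a_deg, dtype=float))
    b = np.deg2rad(np.asarray(b_deg, dtype=float))
    n, m = a.size, b.size
    if n < 4 or m < 4:
        raise InputError("need at least 4 observations per sample")
    if p_mode == "asymptotic" and (n < 8 or m < 8 or n + m < 17):
        raise InputError("asymptotic mode needs n, m >= 8 and n + m >= 17")
    u2 = _watson_u2_stat(a, b)
    if p_mode == "asymptotic":
        p = _watson_asymptotic_p(u2)
    elif p_mode == "permutation":
        # every permutation of the pooled sample sorts to the same vector,
        # so permuting group labels over the sorted positions is exact and
        # lets all n_perm statistics be computed in one vectorized pass
        rng = np.random.default_rng(seed)
        pooled = np.sort(np.concatenate([a, b]) % (2 * np.pi))
        N = n + m
        base = np.concatenate([np.ones(n), np.zeros(m)])  # 1 = sample a
        labels = np.tile(base, (n_perm, 1))
        idx = rng.permuted(np.tile(np.arange(N), (n_perm, 1)), axis=1)
        labels = np.take_along_axis(labels, idx, axis=1)
        d = np.cumsum(labels / n - (1 - labels) / m, axis=1)
        uniq, inv, counts = np.unique(pooled, return_inverse=True, return_counts=True)
        if len(uniq) != N:  # midrank treatment of tied pooled values
            d_block = np.zeros((n_perm, len(uniq)))
            np.add.at(d_block.T, inv, d.T)
            d = (d_block / counts)[:, inv]
        dbar = d.mean(axis=1, keepdims=True)
        stats = n * m / N**2 * np.sum((d - dbar) ** 2, axis=1)
        count = 1 + int(np.sum(stats >= u2 - 1e-15))
        p = count / (n_perm + 1)
    else:
        raise ParameterError(f"unknown p_mode {p_mode!r}")
    return CircularTestResult(
        statistic=u2, p_value=float(p), n=n, m=m, method=f"watson_u2/{p_mode}"
    )


def rose_histogram(
    angles_deg, n_bins: int = 12, folded: bool = False
) -> "np.ndarray":
    """Equal-width angular histogram counts over [0, 360) or [0, 180]."""
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    a = np.asarray(angles_deg, dtype=float)
    hi = 180.0 if folded else 360.0
    if np.any(a < 0) or np.any(a > hi):
        raise InputError(f"angles must lie in [0, {hi}]")
    edges = np.linspace(0.0, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return counts
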