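"""Growth-direction statistics of regrown neurites.

Each neurite contributes one vector from the point where it exits the
explant body (its assigned start point) to its ending. The direction is
expressed as a bearing against the vertical image axis: 0° points to the
top of the image and angles increase clockwise, so 90° is to the right.
Bearings are pooled across explants, binned into 36 bins of 10°, and
tested for departure from circular uniformity (one-sample Rayleigh test)
or for a difference between stimulated and unstimulated populations
(two-sample Watson U² with a seeded permutation null).

Coordinates are 0-based ``(row, col)`` with the origin at the top-left,
so "up" is the direction of decreasing row index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NeuriteVector",
    "AngleHistogram",
    "CircularTestResult",
    "bearing_from_points",
    "compute_angles",
    "bin_angles",
    "rayleigh_test",
    "compare_stimulated_vs_control",
]


@dataclass(frozen=True)
class NeuriteVector:
    start: tuple[float, float]
    tip: tuple[float, float]
    angle_deg: float


@dataclass(frozen=True)
class AngleHistogram:
    bin_edges: np.ndarray  # 37 edges, 0..360 by 10
    counts: np.ndarray  # 36 ints
    n: int


@dataclass(frozen=True)
class CircularTestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int


def bearing_from_points(start: np.ndarray, tip: np.ndarray) -> np.ndarray:
    """Clockwise bearing (deg, [0, 360)) of tip-start vectors, 0° = up.

    ``start`` and ``tip`` are ``(n, 2)`` arrays of (row, col) coordinates.
    """
    d = np.asarray(tip, dtype=float) - np.asarray(start, dtype=float)
    # up is -row; clockwise takes +col at 90°
    ang = np.degrees(np.arctan2(d[:, 1], -d[:, 0]))
    return np.mod(ang, 360.0)


def compute_angles(endings: pd.DataFrame) -> list[NeuriteVector]:
    """One direction vector per ending from the morphometry endings table.

    Expects the per-ending table produced by the image pipeline with
    columns ``r, c`` (ending) and ``start_r, start_c`` (assigned start
    point). Endings coincident with their start point are dropped with a
    warning (no direction defined).
    """
    start = endings[["start_r", "start_c"]].to_numpy(dtype=float)
    tip = endings[["r", "c"]].to_numpy(dtype=float)
    keep = np.any(tip != start, axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-length direction vector(s)")
    angles = bearing_from_points(start[keep], tip[keep])
    return [
        NeuriteVector(tuple(s), tuple(t), float(a))
        for s, t, a in zip(start[keep], tip[keep], angles)
    ]


def bin_angles(angles_deg: np.ndarray | list) -> AngleHistogram:
    """10° polar histogram with half-open bins [k·10°, (k+1)·10°)."""
    if isinstance(angles_deg, list) and angles_deg and isinstance(angles_deg[0], NeuriteVector):
        angles_deg = [v.angle_deg for v in angles_deg]
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    edges = np.arange(0.0, 361.0, 10.0)
    # np.histogram closes the last bin; half-open semantics come from the mod
    counts, _ = np.histogram(a, bins=edges)
    return AngleHistogram(bin_edges=edges, counts=counts.astype(int), n=int(a.size))


def _resultant_length(angles_rad: np.ndarray) -> float:
    return float(np.abs(np.exp(1j * angles_rad).mean()))


def rayleigh_test(angles_deg: np.ndarray) -> CircularTestResult:
    """One-sample Rayleigh test of circular uniformity.

    Z = n·R̄² with the second-order small-sample correction of the
    classical closed form; requires n >= 10.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    if n < 10:
        raise ValueError(f"Rayleigh test needs n >= 10, got {n}")
    rbar = _resultant_length(np.radians(a))
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    p = float(min(max(p, 0.0), 1.0))
    return CircularTestResult("rayleigh", float(z), p, n)


def _watson_u2_from_membership(member_a: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """Watson U² from sample-A membership indicators in pooled sorted order.

    ``member_a`` may be 1-D (one split) or 2-D ``(B, N)`` for B permuted
    splits; returns the statistic per row.
    """
    m = np.atleast_2d(member_a).astype(float)
    n_tot = n_a + n_b
    f_a = np.cumsum(m, axis=1) / n_a
    f_b = np.cumsum(1.0 - m, axis=1) / n_b
    d = f_a - f_b
    dbar = d.mean(axis=1, keepdims=True)
    u2 = n_a * n_b / n_tot**2 * np.sum((d - dbar) ** 2, axis=1)
    return u2


def compare_stimulated_vs_control(
    angles_a: np.ndarray,
    angles_b: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> CircularTestResult:
    """Two-sample Watson U² with a seeded permutation p-value.

    The U² statistic is invariant to a common rotation of both samples, so
    it is the appropriate two-sample test on the circle. The p-value is
    ``(1 + #{U²_perm >= U²_obs}) / (n_permutations + 1)``.
    """
    a = np.mod(np.asarray(angles_a, dtype=float), 360.0)
    b = np.mod(np.asarray(angles_b, dtype=float), 360.0)
    if a.size < 10 or b.size < 10:
        raise ValueError("both samples need n >= 10")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    member = np.zeros(n_a + n_b)
    member[:n_a] = 1.0
    member_sorted = member[order]
    u2_obs = float(_watson_u2_from_membership(member_sorted, n_a, n_b)[0])

    rng = np.random.default_rng(seed)
    perms = np.tile(member_sorted, (n_permutations, 1))
    perms = rng.permuted(perms, axis=1)
    u2_perm = _watson_u2_from_membership(perms, n_a, n_b)
    p = (1.0 + np.sum(u2_perm >= u2_obs)) / (n_permutations + 1.0)
    return CircularTestResult("watson-u2-permutation", u2_obs, float(p), n_a + n_b)
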