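"""The 12 morphological VCG loop features.

Ventricular depolarization (QRS) and repolarization (T) trace closed
spatial loops in orthogonal-lead space. Infarcted myocardium propagates
activation more slowly and over less tissue, which shows up as smaller,
slower, more irregular loops. The features quantify this per beat:

================  ==========================================================
arcQRS            length of the QRS loop projected onto its optimal plane
areaQRS, areaT    polygon (shoelace) area of the optimal-plane projection
maxVecQRS/T       sqrt of summed squared per-lead maxima over the window
maxGravQRS        max distance from the QRS loop's centre of gravity
max/mean/stdVel   statistics of the tracing speed ||dK/dt|| per loop
================  ==========================================================

The *optimal plane* of a loop is the least-squares plane through its
points: the span of the first two right singular vectors of the centered
point matrix, anchored at the centroid. Projecting onto it reduces the
spatial loop to the 2D curve on which arc length and area are measured.

Per-beat vectors are aggregated to one record-level vector by the
per-feature median (robust to the outlier beats deliberately kept in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delineate import BeatLoops
from .io import FEATURE_NAMES

__all__ = [
    "OptimalPlane",
    "fit_optimal_plane",
    "project_to_plane",
    "arc_length",
    "max_vector",
    "max_centroid_distance",
    "velocity_stats",
    "loop_area",
    "beat_features",
    "record_features",
    "FEATURE_NAMES",
]


class DegenerateLoopError(ValueError):
    """All loop points coincide; no plane can be fitted."""


@dataclass
class OptimalPlane:
    """Least-squares plane of a 3D loop.

    ``axes`` holds the right singular vectors of the centered point matrix
    as columns (w1, w2 span the plane, w3 is its unit normal);
    ``singular_values`` are non-negative and sorted descending.
    """

    centroid: np.ndarray
    axes: np.ndarray             # (3, 3), columns w1, w2, w3
    singular_values: np.ndarray  # (3,), descending

    @property
    def normal(self) -> np.ndarray:
        return self.axes[:, 2]


def fit_optimal_plane(points: np.ndarray) -> OptimalPlane:
    """Fit the least-squares (optimal) plane through an ordered 3D loop.

    The centroid is the point mean; axes and singular values come from the
    SVD of the centered point matrix. Requires at least 3 points not all
    identical.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {points.shape}")
    if len(points) < 3:
        raise ValueError("at least 3 points are required to fit a plane")
    centroid = points.mean(axis=0)
    centered = points - centroid
    if not np.any(centered):
        raise DegenerateLoopError("all loop points are identical")
    # SVD of the centered matrix: right singular vectors = plane axes.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    return OptimalPlane(centroid=centroid, axes=vt.T, singular_values=s)


def project_to_plane(points: np.ndarray, plane: OptimalPlane) -> np.ndarray:
    """Project loop points onto the optimal plane.

    Returns the (n, 2) principal-component coordinates
    ``((p - centroid) . w1, (p - centroid) . w2)``.
    """
    points = np.asarray(points, dtype=float)
    return (points - plane.centroid) @ plane.axes[:, :2]


def arc_length(loop2d: np.ndarray) -> float:
    """Discrete curve length: sum of consecutive Euclidean step lengths.

    The loop is *not* closed — no segment from the last point back to the
    first is added; this is the discrete form of the curve integral over
    the traced samples.
    """
    loop2d = np.asarray(loop2d, dtype=float)
    if len(loop2d) < 2:
        raise ValueError("arc length needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(loop2d, axis=0), axis=1)))


def max_vector(points: np.ndarray, strict_max_norm: bool = False) -> float:
    """Maximum loop vector, literal per-lead-maxima form.

    ``sqrt(max(X)^2 + max(Y)^2 + max(Z)^2)`` with each maximum taken
    independently per lead over the window. Note the maxima need not occur
    at the same sample, so this generally exceeds the largest point norm;
    ``strict_max_norm=True`` computes ``max ||point||`` instead.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("max_vector of an empty point set")
    if strict_max_norm:
        return float(np.max(np.linalg.norm(points, axis=1)))
    return float(np.sqrt(np.sum(points.max(axis=0) ** 2)))


def max_centroid_distance(points: np.ndarray) -> float:
    """Maximum Euclidean distance from the loop's centre of gravity."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        raise ValueError("max_centroid_distance needs at least 2 points")
    return float(np.max(np.linalg.norm(points - points.mean(axis=0), axis=1)))


def velocity_stats(points: np.ndarray, fs: float) -> tuple[float, float, float]:
    """(max, mean, population std) of the loop tracing speed in mV/s.

    Speed at sample i is the forward-difference step length times the
    sampling rate: ``||p[i+1] - p[i]|| * fs``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        raise ValueError("velocity_stats needs at least 2 points")
    speed = np.linalg.norm(np.diff(points, axis=0), axis=1) * fs
    return float(speed.max()), float(speed.mean()), float(speed.std())


def loop_area(loop2d: np.ndarray) -> float:
    """Unsigned shoelace area of the projected loop, closed last-to-first.

    ``0.5 * |sum (x_i + x_{i+1}) (y_i - y_{i+1})|`` over consecutive
    vertices with wrap-around. For a self-intersecting (figure-eight) loop
    this is the absolute *signed* area, not the geometric enclosed area.
    """
    loop2d = np.asarray(loop2d, dtype=float)
    if len(loop2d) < 3:
        raise ValueError("loop area needs at least 3 points")
    x, y = loop2d[:, 0], loop2d[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(0.5 * abs(np.sum((x + xn) * (y - yn))))


def beat_features(beat: BeatLoops, fs: float,
                  strict_max_norm: bool = False) -> dict[str, float]:
    """All 12 features for one beat, keyed by canonical name.

    Arc length and areas are measured on each loop's own optimal-plane
    projection (QRS and T planes fitted separately); maximum-vector,
    centre-of-gravity and velocity features use the raw 3D windows.
    """
    qrs_plane = fit_optimal_plane(beat.qrs_points)
    qrs2d = project_to_plane(beat.qrs_points, qrs_plane)
    t_plane = fit_optimal_plane(beat.t_points)
    t2d = project_to_plane(beat.t_points, t_plane)

    max_vel_qrs, mean_vel_qrs, std_vel_qrs = velocity_stats(beat.qrs_points, fs)
    max_vel_t, mean_vel_t, std_vel_t = velocity_stats(beat.t_points, fs)

    return {
        "stdVelT": std_vel_t,
        "areaQRS": loop_area(qrs2d),
        "stdVelQRS": std_vel_qrs,
        "maxVecT": max_vector(beat.t_points, strict_max_norm),
        "arcQRS": arc_length(qrs2d),
        "maxVelQRS": max_vel_qrs,
        "meanVelT": mean_vel_t,
        "meanVelQRS": mean_vel_qrs,
        "maxVelT": max_vel_t,
        "maxGravQRS": max_centroid_distance(beat.qrs_points),
        "maxVecQRS": max_vector(beat.qrs_points, strict_max_norm),
        "areaT": loop_area(t2d),
    }


def record_features(beat_vectors: list[dict[str, float]],
                    aggregate: str = "median") -> dict[str, float]:
    """Aggregate per-beat vectors to one record-level vector.

    ``aggregate`` is ``"median"`` (default; robust to outlier beats) or
    ``"mean"``.
    """
    if not beat_vectors:
        raise ValueError("record_features needs at least one beat vector")
    if aggregate not in ("median", "mean"):
        raise ValueError(f"aggregate must be 'median' or 'mean', got {aggregate!r}")
    agg = np.median if aggregate == "median" else np.mean
    return {name: float(agg([bv[name] for bv in beat_vectors]))
            for name in FEATURE_NAMES}
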