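"""Tortuosity metrics on vessel centerline polylines.

A centerline is an ordered sequence of (x, y) points in pixel coordinates
(x rightward, y downward, 0-based). Three indexes quantify how twisted the
curve is:

* **SOAM** (sum of angles metric): total absolute turning angle along the
  curve divided by its arc length, in radians per pixel. A straight line
  scores 0; a circular arc of radius ``r`` scores ``1/r``.
* **PAD** (product of angle distance): each turning angle weighted by the
  mean length of its two adjacent chords, summed and divided by arc
  length. Dimensionless (radians). Under exactly uniform point spacing
  ``s`` it reduces to ``s * SOAM``.
* **I2e** (triangular index): sliding-window mean of the arc-to-chord
  ratio of triangles built from points ``e`` samples apart,
  ``(|p[k-e]-p[k]| + |p[k]-p[k+e]|) / |p[k-e]-p[k+e]|``. Always >= 1 by
  the triangle inequality, with equality exactly on straight lines.

Turning-angle metrics depend on point spacing, so every metric is computed
on a polyline resampled to uniform arc-length spacing (default 5 px) —
segments of different lengths and digitization densities then remain
comparable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "MetricConfig",
    "TortuosityResult",
    "as_polyline",
    "arc_length",
    "resample_polyline",
    "turning_angles",
    "soam",
    "pad",
    "i2e",
    "compute_all",
]


class DegeneratePolylineError(ValueError):
    """Raised when a polyline is too short or geometrically degenerate."""


@dataclass(frozen=True)
class MetricConfig:
    """Configuration for the metric pipeline.

    Parameters
    ----------
    resample_spacing_px:
        Target uniform arc-length spacing before computing metrics.
    i2e_step:
        Sample offset ``e`` of the triangular index.
    min_points:
        Minimum number of points required after resampling.
    angle_clip:
        Denominator guard for degenerate I2e triangles.
    """

    resample_spacing_px: float = 5.0
    i2e_step: int = 2
    min_points: int = 10
    angle_clip: float = 1e-9

    def __post_init__(self) -> None:
        if self.resample_spacing_px <= 0:
            raise ValueError("resample_spacing_px must be positive")
        if self.i2e_step < 1 or int(self.i2e_step) != self.i2e_step:
            raise ValueError("i2e_step must be an integer >= 1")
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")


@dataclass(frozen=True)
class TortuosityResult:
    """The three tortuosity indexes for one segment, with provenance."""

    soam: float  # rad / px
    pad: float  # dimensionless (rad)
    i2e: float  # dimensionless, >= 1
    n_points: int
    arc_length_px: float
    resample_spacing_px: float
    subject_id: Optional[str] = None
    group: Optional[str] = None
    sex: Optional[str] = None
    age: Optional[float] = None
    eye: Optional[str] = None
    site: Optional[str] = None
    segment_id: Optional[str] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


def as_polyline(points) -> np.ndarray:
    """Coerce to an (N, 2) float array and validate basic shape."""
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError(f"polyline must be (N, 2), got shape {p.shape}")
    if p.shape[0] < 2:
        raise DegeneratePolylineError("polyline needs at least 2 points")
    if not np.all(np.isfinite(p)):
        raise ValueError("polyline contains non-finite coordinates")
    return p


def _chords(p: np.ndarray) -> np.ndarray:
    return np.diff(p, axis=0)


def arc_length(points) -> float:
    """Total polygonal arc length L = sum |p[k+1] - p[k]|."""
    p = as_polyline(points)
    return float(np.linalg.norm(_chords(p), axis=1).sum())


def resample_polyline(points, spacing: float) -> np.ndarray:
    """Resample to uniform arc-length spacing along the linear interpolant.

    The first and last points are preserved exactly; all interior spacings
    equal ``spacing`` except possibly the final interval, which absorbs
    the remainder.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    p = as_polyline(points)
    seg = np.linalg.norm(_chords(p), axis=1)
    keep = np.concatenate(([True], seg > 0))
    p = p[keep]
    if p.shape[0] < 2:
        raise DegeneratePolylineError("all points coincide")
    seg = np.linalg.norm(_chords(p), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    total = s[-1]
    targets = np.arange(0.0, total, spacing)
    if total - targets[-1] > 1e-12:
        targets = np.concatenate((targets, [total]))
    else:
        targets[-1] = total
    x = np.interp(targets, s, p[:, 0])
    y = np.interp(targets, s, p[:, 1])
    out = np.column_stack((x, y))
    out[0] = p[0]
    out[-1] = p[-1]
    return out


def turning_angles(points) -> np.ndarray:
    """Absolute turning angle at each interior vertex, in [0, pi].

    theta_k = arccos(v_{k-1} . v_k / (|v_{k-1}| |v_k|)) with the cosine
    clamped to [-1, 1] to absorb floating-point drift.
    """
    p = as_polyline(points)
    if p.shape[0] < 3:
        raise DegeneratePolylineError("need >= 3 points for turning angles")
    v = _chords(p)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise DegeneratePolylineError("zero-length chord")
    dots = np.einsum("ij,ij->i", v[:-1], v[1:])
    cosang = np.clip(dots / (norms[:-1] * norms[1:]), -1.0, 1.0)
    return np.arccos(cosang)


def soam(points) -> float:
    """Sum of angles metric: (sum_k theta_k) / L, rad per px."""
    p = as_polyline(points)
    return float(turning_angles(p).sum() / arc_length(p))


def pad(points) -> float:
    """Product of angle distance: (sum_k theta_k * d_k) / L.

    d_k is the mean of the two chord lengths adjacent to vertex k.
    """
    p = as_polyline(points)
    theta = turning_angles(p)
    seg = np.linalg.norm(_chords(p), axis=1)
    d = 0.5 * (seg[:-1] + seg[1:])
    return float((theta * d).sum() / arc_length(p))


def i2e(points, e: int = 2, angle_clip: float = 1e-9) -> float:
    """Triangular index with sample step ``e``.

    Mean over interior points of (|p[k-e]-p[k]| + |p[k]-p[k+e]|) divided
    by |p[k-e]-p[k+e]|. Requires at least 2e+1 points. Raises if any base
    chord degenerates (curve folds back onto itself).
    """
    if e < 1 or int(e) != e:
        raise ValueError("e must be an integer >= 1")
    p = as_polyline(points)
    n = p.shape[0]
    if n < 2 * e + 1:
        raise DegeneratePolylineError(f"need >= {2 * e + 1} points for I2e with e={e}")
    a = np.linalg.norm(p[e:-e] - p[: n - 2 * e], axis=1)
    b = np.linalg.norm(p[2 * e :] - p[e:-e], axis=1)
    base = np.linalg.norm(p[2 * e :] - p[: n - 2 * e], axis=1)
    if np.any(base < angle_clip):
        raise DegeneratePolylineError("degenerate I2e triangle: curve folds back on itself")
    return float(np.mean((a + b) / base))


def compute_all(
    points,
    cfg: MetricConfig = MetricConfig(),
    **provenance,
) -> TortuosityResult:
    """Resample a raw polyline and compute SOAM, PAD and I2e.

    ``provenance`` keywords (subject_id, group, sex, age, eye, site,
    segment_id) are carried through to the result unchanged.

    The polyline is first oriented canonically (lexicographically smaller
    endpoint first), making the result exactly independent of tracing
    direction despite the arc-length remainder landing in the final
    resampling interval.
    """
    p = as_polyline(points)
    if tuple(p[-1]) < tuple(p[0]):
        p = p[::-1]
    rs = resample_polyline(p, cfg.resample_spacing_px)
    n = rs.shape[0]
    if n < cfg.min_points:
        raise DegeneratePolylineError(
            f"only {n} points after resampling at "
            f"{cfg.resample_spacing_px} px (min {cfg.min_points})"
        )
    # shared chord geometry: computing it once roughly halves the cost of
    # the Monte Carlo harnesses that call this per segment
    v = np.diff(rs, axis=0)
    norms = np.sqrt(np.einsum("ij,ij->i", v, v))
    if np.any(norms == 0):
        raise DegeneratePolylineError("zero-length chord after resampling")
    L = float(norms.sum())
    cosang = np.clip(
        np.einsum("ij,ij->i", v[:-1], v[1:]) / (norms[:-1] * norms[1:]), -1.0, 1.0
    )
    theta = np.arccos(cosang)
    d = 0.5 * (norms[:-1] + norms[1:])
    e = cfg.i2e_step
    if n < 2 * e + 1:
        raise DegeneratePolylineError(f"need >= {2 * e + 1} points for I2e with e={e}")
    a = np.linalg.norm(rs[e:-e] - rs[: n - 2 * e], axis=1)
    b = np.linalg.norm(rs[2 * e :] - rs[e:-e], axis=1)
    base = np.linalg.norm(rs[2 * e :] - rs[: n - 2 * e], axis=1)
    if np.any(base < cfg.angle_clip):
        raise DegeneratePolylineError("degenerate I2e triangle: curve folds back on itself")
    return TortuosityResult(
        soam=float(theta.sum() / L),
        pad=float((theta * d).sum() / L),
        i2e=float(np.mean((a + b) / base)),
        n_points=int(n),
        arc_length_px=L,
        resample_spacing_px=cfg.resample_spacing_px,
        **provenance,
    )
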