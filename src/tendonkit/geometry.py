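"""Tendon cross-sectional geometry, knee rotation axis, and moment arm.

Transverse MRI slices of the patellar tendon are segmented as planar polygons
with an explicit 3D placement (origin, normal, orthonormal in-plane basis).
Because the tendon axis is never perfectly aligned with the scanner axis, the
in-plane areas overestimate the true cross-section; each slice area is
projected onto the plane orthogonal to the tendon line of action (the
total-least-squares line through the slice centroids), i.e. multiplied by the
cosine of the tilt between slice normal and line direction. Regional means
are taken over the proximal or distal 40 % of tendon length measured along
that line.

The knee rotation axis is the 3D line through the centers of least-squares
circles fitted to the posterior contours of the medial and lateral femoral
condyles; the tendon moment arm is the common-perpendicular distance between
the line of action and that axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Slice",
    "SegmentationStack",
    "LineOfAction",
    "CircleFit",
    "PlanePlacement",
    "MomentArm",
    "polygon_area_centroid",
    "fit_line_of_action",
    "reorient_csa",
    "regional_csa",
    "fit_circle",
    "knee_axis",
    "moment_arm",
]

_CONDITION_LIMIT = 1e8  # normal-equation conditioning threshold for circle fits
_MIN_ARC_DEG = 30.0


def polygon_area_centroid(polygon: np.ndarray) -> tuple[float, np.ndarray]:
    """Shoelace area (absolute) and centroid of a simple polygon.

    Output is independent of vertex orientation. Degenerate (zero-area)
    polygons raise ``ValueError``.
    """
    p = np.asarray(polygon, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise ValueError("polygon needs >= 3 2D vertices")
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a_signed = 0.5 * cross.sum()
    if a_signed == 0.0:
        raise ValueError("degenerate polygon (zero area)")
    cx = ((x + xn) * cross).sum() / (6.0 * a_signed)
    cy = ((y + yn) * cross).sum() / (6.0 * a_signed)
    return abs(float(a_signed)), np.array([cx, cy])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return np.asarray(v, dtype=float) / n


@dataclass(frozen=True)
class Slice:
    """One segmented tendon cross-section with its 3D placement.

    ``polygon`` holds in-plane mm coordinates; a point ``(u, v)`` maps to
    ``origin_mm + u * basis[0] + v * basis[1]`` in the common frame.
    """

    polygon: np.ndarray
    origin_mm: np.ndarray
    normal: np.ndarray
    in_plane_basis: np.ndarray  # shape (2, 3), orthonormal

    def __post_init__(self) -> None:
        object.__setattr__(self, "polygon", np.asarray(self.polygon, dtype=float))
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, dtype=float))
        object.__setattr__(self, "normal", _unit(self.normal))
        b = np.asarray(self.in_plane_basis, dtype=float)
        if b.shape != (2, 3):
            raise ValueError("in_plane_basis must be two 3D vectors")
        g = b @ b.T
        if not np.allclose(g, np.eye(2), atol=1e-9):
            raise ValueError("in-plane basis must be orthonormal (tol 1e-9)")
        object.__setattr__(self, "in_plane_basis", b)

    def centroid_3d(self) -> np.ndarray:
        _, c = polygon_area_centroid(self.polygon)
        return self.origin_mm + c @ self.in_plane_basis

    def area_mm2(self) -> float:
        a, _ = polygon_area_centroid(self.polygon)
        return a


@dataclass(frozen=True)
class SegmentationStack:
    """Ordered proximal (patellar apex) -> distal (tibial tuberosity) slices."""

    slices: list

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("stack needs at least one slice")

    def centroids_3d(self) -> np.ndarray:
        return np.array([s.centroid_3d() for s in self.slices])


@dataclass(frozen=True)
class LineOfAction:
    """3D line (point + unit direction)."""

    point_mm: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point_mm", np.asarray(self.point_mm, dtype=float))
        object.__setattr__(self, "direction", _unit(self.direction))


def fit_line_of_action(stack: SegmentationStack) -> LineOfAction:
    """Total-least-squares 3D line through the slice centroids.

    The direction is the first principal axis of the centroid cloud about its
    mean, with the sign fixed to point proximal -> distal (first slice to
    last slice).
    """
    c = stack.centroids_3d()
    if len(c) < 2:
        raise ValueError("need >= 2 slices to fit a line of action")
    mean = c.mean(axis=0)
    dev = c - mean
    if np.allclose(dev, 0, atol=1e-12):
        raise ValueError("coincident centroids: line of action undefined")
    _, _, vt = np.linalg.svd(dev, full_matrices=False)
    d = vt[0]
    span = c[-1] - c[0]
    if span @ d < 0:
        d = -d
    return LineOfAction(point_mm=mean, direction=d)


def reorient_csa(slc: Slice, line: LineOfAction) -> float:
    """In-plane polygon area projected orthogonal to the line of action.

    For a thin slice of a near-prismatic body the planar section area times
    ``cos(theta)`` (tilt between slice normal and line direction) is the
    perpendicular cross-sectional area.
    """
    cos_t = abs(float(slc.normal @ line.direction))
    if cos_t <= 1e-12:
        raise ValueError("slice plane parallel to line of action (tilt >= 90 deg)")
    return slc.area_mm2() * cos_t


def regional_csa(stack: SegmentationStack, line: LineOfAction, region: str = "full") -> float:
    """Mean reoriented CSA over a region of tendon length.

    Tendon length is measured along the line of action between the
    projections of the first and last slice centroids. ``proximal40`` keeps
    slices whose centroid projects into the first 40 % of that length from
    the patellar apex; ``distal40`` into the last 40 %; ``full`` keeps all.
    """
    if region not in ("proximal40", "distal40", "full"):
        raise ValueError(f"unknown region {region!r}")
    c = stack.centroids_3d()
    t = (c - line.point_mm) @ line.direction
    t0, t1 = t[0], t[-1]
    length = t1 - t0
    if length <= 0:
        raise ValueError("degenerate tendon length along line of action")
    frac = (t - t0) / length
    if region == "proximal40":
        keep = frac <= 0.4 + 1e-12
    elif region == "distal40":
        keep = frac >= 0.6 - 1e-12
    else:
        keep = np.ones(len(t), dtype=bool)
    if not keep.any():
        raise ValueError(f"region {region!r} contains no slice")
    areas = [reorient_csa(s, line) for s, k in zip(stack.slices, keep) if k]
    return float(np.mean(areas))


def tendon_length_mm(stack: SegmentationStack, line: LineOfAction) -> float:
    """Length along the line of action between first and last centroids."""
    c = stack.centroids_3d()
    t = (c - line.point_mm) @ line.direction
    return float(t[-1] - t[0])


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle: center, radius, RMS geometric residual.

    ``condition_flag`` is raised for poorly constrained fits: arc span below
    30 degrees or normal-equation condition number above 1e8.
    """

    center_mm: np.ndarray
    radius_mm: float
    rms_residual_mm: float
    condition_flag: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "center_mm", np.asarray(self.center_mm, dtype=float))
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")


def fit_circle(points: np.ndarray) -> CircleFit:
    """Kasa algebraic circle fit refined by Gauss-Newton on geometric distance.

    The algebraic stage solves the linear system ``[2x 2y 1] p = x^2 + y^2``;
    the refinement minimizes ``|r_i - R|`` with ``scipy.optimize.least_squares``.
    Collinear points raise ``ValueError``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 2D points")
    x, y = pts[:, 0], pts[:, 1]
    # collinearity: rank of centered cloud
    dev = pts - pts.mean(axis=0)
    sv = np.linalg.svd(dev, compute_uv=False)
    if sv[1] <= 1e-12 * max(1.0, sv[0]):
        raise ValueError("collinear points: no circle fit")
    a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    normal = a_mat.T @ a_mat
    cond = float(np.linalg.cond(normal))
    sol = np.linalg.solve(normal, a_mat.T @ b)
    cx, cy = sol[0], sol[1]
    r = float(np.sqrt(sol[2] + cx ** 2 + cy ** 2))

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    out = least_squares(resid, x0=[cx, cy, r], method="lm")
    cx, cy, r = out.x
    res = resid(out.x)
    rms = float(np.sqrt(np.mean(res ** 2)))
    ang = np.unwrap(np.sort(np.arctan2(y - cy, x - cx)))
    # angular span of the data around the fitted center
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    span_deg = np.degrees(2 * np.pi - gaps.max())
    flag = bool(span_deg < _MIN_ARC_DEG or cond > _CONDITION_LIMIT)
    return CircleFit(center_mm=np.array([cx, cy]), radius_mm=float(r),
                     rms_residual_mm=rms, condition_flag=flag)


@dataclass(frozen=True)
class PlanePlacement:
    """Placement of a sagittal segmentation plane in the common 3D frame."""

    origin_mm: np.ndarray
    basis: np.ndarray  # (2, 3) orthonormal

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, dtype=float))
        b = np.asarray(self.basis, dtype=float)
        if b.shape != (2, 3) or not np.allclose(b @ b.T, np.eye(2), atol=1e-9):
            raise ValueError("basis must be two orthonormal 3D vectors")
        object.__setattr__(self, "basis", b)

    def to_3d(self, point_2d: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(point_2d, dtype=float) @ self.basis


def knee_axis(
    medial: CircleFit,
    medial_placement: PlanePlacement,
    lateral: CircleFit,
    lateral_placement: PlanePlacement,
) -> LineOfAction:
    """Rotation axis: the 3D line through the two condyle circle centers."""
    p_med = medial_placement.to_3d(medial.center_mm)
    p_lat = lateral_placement.to_3d(lateral.center_mm)
    d = p_lat - p_med
    if np.linalg.norm(d) <= 1e-12:
        raise ValueError("coincident condyle centers: axis undefined")
    return LineOfAction(point_mm=p_med, direction=d)


@dataclass(frozen=True)
class MomentArm:
    """Perpendicular distance from tendon line of action to the knee axis."""

    value_mm: float
    axis: LineOfAction
    reference_angle_deg: float = 10.0


def moment_arm(
    line_of_action: LineOfAction,
    axis: LineOfAction,
    reference_angle_deg: float = 10.0,
) -> MomentArm:
    """Common-perpendicular distance between two 3D lines.

    Skew lines use ``|(p2 - p1) . (d1 x d2)| / |d1 x d2|``; parallel lines
    the point-to-line distance. Intersecting lines return 0 with a warning.
    """
    d1, d2 = line_of_action.direction, axis.direction
    dp = axis.point_mm - line_of_action.point_mm
    cross = np.cross(d1, d2)
    nc = np.linalg.norm(cross)
    if nc < 1e-12:  # parallel
        dist = float(np.linalg.norm(dp - (dp @ d1) * d1))
    else:
        dist = float(abs(dp @ cross) / nc)
    if dist < 1e-12:
        warnings.warn("line of action intersects the rotation axis; moment arm 0")
        dist = 0.0
    return MomentArm(value_mm=dist, axis=axis, reference_angle_deg=reference_angle_deg)
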