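"""Landmark-based volume alignment and virtual reslicing.

The correlative workflow: a section imaged by another modality (histology,
mosaic microscopy, ...) corresponds to some oblique plane inside the
tomographic volume.  Three landmark points identified in both data sets
define that plane; the volume is then rotated so the plane's normal lies
along the stack axis, after which the matching view is an ordinary
axis-perpendicular slice - or, for sections that were not flat, a "curved
reslice" sampled along a polyline.

Conventions: landmark coordinates are continuous, 0-based, voxel-centre
(x, y, z) positions.  Volumes are arrays ``[z, y, x]``; the stack axis is z.
Rotations are right-handed about the x and y axes; the rotation pair
``(alpha_x, alpha_y)`` satisfies ``R_x(alpha_x) R_y(alpha_y) n = e_z`` for
the (canonically oriented) unit plane normal ``n = (n1, n2, n3)``, which for
this decomposition gives the closed forms ``sin(alpha_x) = n2`` and
``sin(alpha_y) = -n1 / cos(alpha_x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DataError, ValidationError, Volume3D

__all__ = [
    "Landmarks",
    "PlaneSpec",
    "AlignmentAngles",
    "PolylinePath",
    "plane_from_landmarks",
    "alignment_angles",
    "rotation_matrix",
    "rotate_volume",
    "extract_reslice",
    "curved_reslice",
]

_COLLINEAR_EPS = 1e-9
_GIMBAL_EPS = 1e-12


@dataclass(frozen=True)
class Landmarks:
    """Three (x, y, z) positions defining a plane."""

    p1: tuple[float, float, float]
    p2: tuple[float, float, float]
    p3: tuple[float, float, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3], dtype=float)

    def __post_init__(self) -> None:
        a = self.as_array()
        if not np.all(np.isfinite(a)):
            raise ValidationError("landmark coordinates must be finite")
        cross = np.cross(a[1] - a[0], a[2] - a[0])
        if np.linalg.norm(cross) <= _COLLINEAR_EPS:
            raise ValidationError(
                f"landmarks are collinear (p1={self.p1}, p2={self.p2}, p3={self.p3}); "
                "they do not define a plane"
            )


@dataclass(frozen=True)
class PlaneSpec:
    """A plane in point-normal form; the normal is unit length."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise ValidationError("plane normal must be unit length")


@dataclass(frozen=True)
class AlignmentAngles:
    """Rotation pair (radians) aligning a plane normal with the stack axis."""

    alpha_x: float
    alpha_y: float


@dataclass(frozen=True)
class PolylinePath:
    """Cutting line of a curved reslice, drawn within an aligned slice."""

    vertices: tuple[tuple[float, float], ...]   # (x, y) positions
    slab_axis: int = 0                          # through-plane axis (z)

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValidationError("a polyline path needs at least two vertices")
        v = np.asarray(self.vertices, float)
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise ValidationError("consecutive polyline vertices must be distinct")
        if self.slab_axis != 0:
            raise ValidationError("only the stack (z) axis is supported as slab axis")


def _canonical_normal(n: np.ndarray) -> np.ndarray:
    """Fix the sign ambiguity: n3 >= 0, ties broken by n2 >= 0, then n1 >= 0."""
    for comp in (2, 1, 0):
        if abs(n[comp]) > 0:
            if n[comp] < 0:
                n = -n
            break
    return n


def plane_from_landmarks(l: Landmarks) -> PlaneSpec:
    """Plane through three landmarks via the vector product.

    ``normal = normalize((p2 - p1) x (p3 - p1))``, oriented canonically
    (non-negative z-component; ties resolved toward +y, then +x); the plane
    point is p1.
    """
    a = l.as_array()
    cross = np.cross(a[1] - a[0], a[2] - a[0])
    norm = np.linalg.norm(cross)
    if norm <= _COLLINEAR_EPS:   # unreachable for a valid Landmarks, kept for safety
        raise ValidationError("degenerate landmark configuration")
    n = _canonical_normal(cross / norm)
    return PlaneSpec(point=tuple(a[0]), normal=tuple(n))


def alignment_angles(plane: PlaneSpec) -> AlignmentAngles:
    """The rotation pair mapping the plane normal onto the stack axis.

    Solves ``R_x(ax) R_y(ay) n = e_z`` for right-handed rotations about x
    and y.  Writing ``n = R_y(-ay) R_x(-ax) e_z`` component-wise gives
    ``n = (-sin(ay) cos(ax), sin(ax), cos(ay) cos(ax))``, hence
    ``ax = asin(n2)`` and ``ay = asin(-n1 / cos(ax))`` on the principal
    branch.  A normal pointing along +-y makes ``cos(ax) = 0``; the
    in-plane direction about z is then unconstrained (gimbal degeneracy)
    and an error is raised.
    """
    n = _canonical_normal(np.asarray(plane.normal, dtype=float))
    alpha_x = float(np.arcsin(np.clip(n[1], -1.0, 1.0)))
    cos_ax = np.cos(alpha_x)
    if abs(cos_ax) < _GIMBAL_EPS:
        raise ValidationError(
            "gimbal degeneracy: plane normal lies along the y-axis; the x/y "
            "rotation pair cannot align it with the stack axis"
        )
    alpha_y = float(np.arcsin(np.clip(-n[0] / cos_ax, -1.0, 1.0)))
    return AlignmentAngles(alpha_x=alpha_x, alpha_y=alpha_y)


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def rotation_matrix(a: AlignmentAngles) -> np.ndarray:
    """The composite rotation ``R_x(alpha_x) @ R_y(alpha_y)`` in xyz space."""
    return _rx(a.alpha_x) @ _ry(a.alpha_y)


def rotate_volume(
    v: Volume3D, a: AlignmentAngles, order: int = 1, inverse: bool = False
) -> Volume3D:
    """Resample a volume under the alignment rotation about its centre.

    Trilinear interpolation by default (``order=1``); pass ``order=0`` for
    label volumes, whose classes must never be averaged.  The output
    bounding box is grown to contain the whole rotated volume;
    out-of-bounds voxels are zero-filled.  ``inverse=True`` applies the
    transpose (undoing) rotation ``(R_x R_y)^T``.
    """
    if v.data.size == 0:
        raise ValidationError("cannot rotate an empty volume")
    if a.alpha_x == 0.0 and a.alpha_y == 0.0:
        return v.with_data(np.array(v.data, copy=True))

    r_xyz = rotation_matrix(a)
    if inverse:
        r_xyz = r_xyz.T
    # array axes are (z, y, x) = reversed xyz
    r_zyx = r_xyz[::-1, ::-1]

    shape_in = np.asarray(v.shape, dtype=float)
    corners = np.array(
        [[z, y, x] for z in (0, shape_in[0] - 1)
         for y in (0, shape_in[1] - 1)
         for x in (0, shape_in[2] - 1)]
    )
    c_in = (shape_in - 1) / 2.0
    rotated = (r_zyx @ (corners - c_in).T).T
    half_extent = np.abs(rotated).max(axis=0)
    required = np.ceil(2 * half_extent + 1).astype(int)
    # grow symmetrically by whole voxels per side so the centre stays on the
    # voxel lattice (keeps repeated rotations exactly invertible on-grid)
    margin = np.maximum(0, np.ceil((required - np.asarray(v.shape)) / 2).astype(int))
    shape_out = np.asarray(v.shape) + 2 * margin
    c_out = (shape_out - 1) / 2.0

    # inverse mapping: output index -> input index
    m = r_zyx.T
    offset = c_in - m @ c_out
    out = ndimage.affine_transform(
        np.asarray(v.data, dtype=np.float32 if order > 0 else v.data.dtype),
        m, offset=offset, output_shape=tuple(shape_out),
        order=order, mode="constant", cval=0.0, prefilter=False,
    )
    return v.with_data(out)


def extract_reslice(v: Volume3D, z_index: float) -> np.ndarray:
    """The plane perpendicular to the stack axis at (possibly fractional) z.

    Integer indices return the exact array slice; fractional indices
    interpolate linearly between the two neighbouring slabs.
    """
    nz = v.shape[0]
    if z_index < 0 or z_index > nz - 1:
        raise ValidationError(f"z_index {z_index} out of range [0, {nz - 1}]")
    k = int(np.floor(z_index))
    f = z_index - k
    if f == 0:
        return np.array(v.data[k], copy=True)
    return (1.0 - f) * np.asarray(v.data[k], float) + f * np.asarray(v.data[k + 1], float)


def _arc_length_samples(vertices: np.ndarray) -> np.ndarray:
    """(x, y) sample points at unit-voxel arc-length steps along the polyline."""
    seg = np.diff(vertices, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    width = int(np.ceil(total))
    s = np.arange(width, dtype=float)
    # clamp into the last segment to avoid rounding past the end
    s = np.minimum(s, total)
    idx = np.searchsorted(cum, s, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    local = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    return vertices[idx] + local[:, None] * seg[idx]


def curved_reslice(v: Volume3D, path: PolylinePath) -> np.ndarray:
    """Sample a volume along a polyline x the stack axis.

    The polyline is parameterized by arc length at unit-voxel steps; the
    output has width ``ceil(total arc length)`` and height equal to the
    stack extent.  Values are interpolated trilinearly.
    """
    nz, ny, nx = v.shape
    verts = np.asarray(path.vertices, dtype=float)
    for i, (x, y) in enumerate(verts):
        if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
            raise DataError(
                f"polyline vertex {i} at (x={x}, y={y}) lies outside the "
                f"volume bounds (x in [0,{nx - 1}], y in [0,{ny - 1}])"
            )
    pts = _arc_length_samples(verts)             # [s, (x, y)]
    width = pts.shape[0]
    z_idx = np.broadcast_to(np.arange(nz, dtype=float)[:, None], (nz, width))
    y_idx = np.broadcast_to(pts[:, 1][None, :], (nz, width))
    x_idx = np.broadcast_to(pts[:, 0][None, :], (nz, width))
    return ndimage.map_coordinates(
        np.asarray(v.data, float), [z_idx, y_idx, x_idx], order=1, mode="nearest"
    )
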