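"""Mosaic stitching: translation-basis estimation, linear blending, assembly.

A tiled acquisition is described by two step vectors: ``u``, the translation
between column-adjacent tiles, and ``v``, between row-adjacent tiles, both in
(x, y) pixel units.  Because the translation stage and the optical scan axes
are slightly tilted against each other, u and v are neither integer nor
axis-aligned; they are estimated iteratively from the overlap regions the
current estimate predicts.  Tiles are merged with a separable linear
pre-weighting mask so adjacent tiles blend seamlessly, then splatted
bilinearly onto the canvas at their (subpixel) positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import DataError, ValidationError, Volume3D

__all__ = [
    "TranslationBasis",
    "TileRecord",
    "TileSet",
    "MosaicCanvas",
    "blend_mask",
    "assemble_mosaic",
    "estimate_basis",
    "stack_mosaics",
]


@dataclass(frozen=True)
class TranslationBasis:
    """Inter-tile step vectors in (x, y) pixel units."""

    u: tuple[float, float]   # step between column-adjacent tiles
    v: tuple[float, float]   # step between row-adjacent tiles

    def __post_init__(self) -> None:
        u = np.asarray(self.u, float)
        v = np.asarray(self.v, float)
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise ValidationError("translation basis must be finite")
        cross = u[0] * v[1] - u[1] * v[0]
        if abs(cross) < 1e-9:
            raise ValidationError("u and v must not be parallel")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.u, float), np.asarray(self.v, float)


@dataclass
class TileRecord:
    image: np.ndarray
    row: int
    col: int


@dataclass
class TileSet:
    """Tiles of one mosaic slice plus grid bookkeeping."""

    tiles: list[TileRecord]
    tile_px: tuple[int, int]            # (height, width)
    nominal_overlap: float = 0.05
    z_index: Optional[int] = None
    true_basis: Optional[TranslationBasis] = None   # ground truth, fixtures only
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        seen = set()
        for t in self.tiles:
            if t.image.shape[-2:] != tuple(self.tile_px):
                raise ValidationError(
                    f"tile ({t.row},{t.col}) shape {t.image.shape} != tile_px {self.tile_px}"
                )
            if (t.row, t.col) in seen:
                raise DataError(f"duplicate grid index ({t.row},{t.col})")
            seen.add((t.row, t.col))

    @property
    def n_rows(self) -> int:
        return max(t.row for t in self.tiles) + 1

    @property
    def n_cols(self) -> int:
        return max(t.col for t in self.tiles) + 1

    def get(self, row: int, col: int) -> Optional[TileRecord]:
        for t in self.tiles:
            if t.row == row and t.col == col:
                return t
        return None


@dataclass
class MosaicCanvas:
    image: np.ndarray    # weighted accumulation
    weight: np.ndarray   # summed blend weights

    def normalized(self) -> np.ndarray:
        out = np.zeros_like(self.image)
        np.divide(self.image, self.weight, out=out, where=self.weight > 1e-12)
        return out


def _ramp(n: int, margin: int) -> np.ndarray:
    """1D blend profile: linear 0->1 over ``margin`` samples at both ends.

    Built so two profiles offset by (n - margin) sum to exactly 1 across the
    overlap: ramp(i) = (i + 0.5)/margin on the way up.
    """
    w = np.ones(n)
    if margin > 0:
        i = np.arange(n, dtype=float)
        w = np.minimum(w, (i + 0.5) / margin)
        w = np.minimum(w, (n - 1 - i + 0.5) / margin)
    return w


def blend_mask(tile_shape: tuple[int, int], margin_px: tuple[int, int]) -> np.ndarray:
    """Separable linear pre-weighting mask for one tile.

    Weight is 1 in the interior and ramps linearly to ~0 across ``margin_px``
    pixels at each edge (per axis); the mask is the outer product of the two
    per-axis ramps.  Two tiles abutting at offset ``extent - margin`` have
    complementary ramps: their weights sum to exactly 1 in the overlap.
    """
    h, w = int(tile_shape[0]), int(tile_shape[1])
    mh, mw = int(margin_px[0]), int(margin_px[1])
    if mh < 0 or mw < 0:
        raise ValidationError("margins must be non-negative")
    if 2 * mh >= h or 2 * mw >= w:
        raise ValidationError(f"margins {margin_px} must be < half the tile extent ({h}x{w})")
    return np.outer(_ramp(h, mh), _ramp(w, mw))


def _splat(canvas: MosaicCanvas, tile: np.ndarray, mask: np.ndarray, x: float, y: float) -> None:
    """Accumulate tile*mask at continuous position (x, y) by bilinear splatting."""
    h, w = tile.shape
    ix, iy = int(np.floor(x)), int(np.floor(y))
    fx, fy = x - ix, y - iy
    weights = [
        (iy, ix, (1 - fy) * (1 - fx)),
        (iy, ix + 1, (1 - fy) * fx),
        (iy + 1, ix, fy * (1 - fx)),
        (iy + 1, ix + 1, fy * fx),
    ]
    wm = tile * mask
    for oy, ox, a in weights:
        if a == 0.0:
            continue
        canvas.image[oy : oy + h, ox : ox + w] += a * wm
        canvas.weight[oy : oy + h, ox : ox + w] += a * mask


def assemble_mosaic(
    ts: TileSet,
    basis: TranslationBasis,
    margin_px: Optional[tuple[int, int]] = None,
    return_canvas: bool = False,
):
    """Paste all tiles onto a canvas at positions ``r*v + c*u`` and normalize.

    Tiles are pre-weighted with :func:`blend_mask`, accumulated with bilinear
    splatting at their continuous positions, and the canvas is divided by the
    summed weights where coverage exists (zero elsewhere).  The canvas is
    auto-sized to the placed extent.
    """
    u, v = basis.as_arrays()
    h, w = ts.tile_px
    if margin_px is None:
        # default: margin = predicted overlap between adjacent tiles
        mx = max(0, int(round(w - abs(u[0])))) if ts.n_cols > 1 else 0
        my = max(0, int(round(h - abs(v[1])))) if ts.n_rows > 1 else 0
        margin_px = (my, mx)
    mask = blend_mask((h, w), margin_px)

    pos = np.array([c * u + r * v for t in ts.tiles for r, c in [(t.row, t.col)]])
    pmin = pos.min(axis=0)
    pos -= pmin
    max_x = int(np.ceil(pos[:, 0].max())) + w + 1
    max_y = int(np.ceil(pos[:, 1].max())) + h + 1
    canvas = MosaicCanvas(
        image=np.zeros((max_y, max_x)), weight=np.zeros((max_y, max_x))
    )
    for t, (px, py) in zip(ts.tiles, pos):
        _splat(canvas, np.asarray(t.image, float), mask, float(px), float(py))
    if return_canvas:
        return canvas
    return canvas.normalized()


def _ncc_shift(a: np.ndarray, b: np.ndarray, max_shift: int) -> tuple[np.ndarray, float]:
    """Residual shift (dx, dy) maximizing normalized cross-correlation of b vs a.

    Exhaustive search over integer shifts within +-max_shift, then 3-point
    quadratic interpolation of the NCC surface for a subpixel peak.
    Returns (shift, peak_ncc).
    """
    best = (-2.0, 0, 0)
    scores = {}
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ay0, ay1 = max(0, dy), min(a.shape[0], b.shape[0] + dy)
            ax0, ax1 = max(0, dx), min(a.shape[1], b.shape[1] + dx)
            if ay1 - ay0 < 4 or ax1 - ax0 < 4:
                continue
            sa = a[ay0:ay1, ax0:ax1]
            sb = b[ay0 - dy : ay1 - dy, ax0 - dx : ax1 - dx]
            sa = sa - sa.mean()
            sb = sb - sb.mean()
            denom = np.sqrt((sa * sa).sum() * (sb * sb).sum())
            score = float((sa * sb).sum() / denom) if denom > 1e-12 else -1.0
            scores[(dy, dx)] = score
            if score > best[0]:
                best = (score, dy, dx)
    peak, dy, dx = best
    if peak <= -1.5:
        return np.array([0.0, 0.0]), -1.0

    def _sub(c_m, c_0, c_p):
        denom = c_m - 2 * c_0 + c_p
        if abs(denom) < 1e-12:
            return 0.0
        off = 0.5 * (c_m - c_p) / denom
        return float(np.clip(off, -0.5, 0.5))

    oy = ox = 0.0
    if (dy - 1, dx) in scores and (dy + 1, dx) in scores:
        oy = _sub(scores[(dy - 1, dx)], scores[(dy, dx)], scores[(dy + 1, dx)])
    if (dy, dx - 1) in scores and (dy, dx + 1) in scores:
        ox = _sub(scores[(dy, dx - 1)], scores[(dy, dx)], scores[(dy, dx + 1)])
    return np.array([dx + ox, dy + oy]), peak


def _pair_offset(tile_a, tile_b, predicted, max_shift, min_peak):
    """Measured (x, y) offset of tile_b relative to tile_a near ``predicted``.

    Crops the overlap strips the predicted offset implies, then refines with
    NCC.  Returns None when the correlation peak is too weak.
    """
    h, w = tile_a.shape
    px, py = predicted
    ix, iy = int(round(px)), int(round(py))
    ax0, ax1 = max(0, ix), min(w, w + ix)
    ay0, ay1 = max(0, iy), min(h, h + iy)
    if ax1 - ax0 < 4 or ay1 - ay0 < 4:
        return None
    strip_a = tile_a[ay0:ay1, ax0:ax1]
    strip_b = tile_b[ay0 - iy : ay1 - iy, ax0 - ix : ax1 - ix]
    shift, peak = _ncc_shift(strip_a, strip_b, max_shift)
    if peak < min_peak:
        return None
    return np.array([ix, iy], float) + shift


def estimate_basis(
    ts: TileSet,
    init: TranslationBasis,
    max_iter: int = 10,
    tol_px: float = 0.05,
    max_shift: int = 5,
    min_peak: float = 0.2,
) -> tuple[TranslationBasis, dict]:
    """Iteratively refine the two inter-tile translation vectors.

    Each iteration predicts the overlap strip of every column-adjacent pair
    from the current ``u`` (row-adjacent for ``v``), measures the actual
    offset by normalized cross-correlation with subpixel quadratic peak
    interpolation, and takes the median measured offset across pairs as the
    new estimate.  Stops when the largest update falls below ``tol_px``.

    Returns the refined basis and convergence metadata
    (iterations, final update size, pairs used).
    """
    if ts.n_cols < 2 or ts.n_rows < 2:
        raise ValidationError("basis estimation needs at least a 2 x 2 tile grid")
    u, v = init.as_arrays()
    u, v = u.copy(), v.copy()
    info = {"iterations": 0, "max_update_px": np.inf, "n_pairs_u": 0, "n_pairs_v": 0}
    for it in range(max_iter):
        meas_u, meas_v = [], []
        for t in ts.tiles:
            right = ts.get(t.row, t.col + 1)
            if right is not None:
                m = _pair_offset(np.asarray(t.image, float), np.asarray(right.image, float),
                                 u, max_shift, min_peak)
                if m is not None:
                    meas_u.append(m)
            below = ts.get(t.row + 1, t.col)
            if below is not None:
                m = _pair_offset(np.asarray(t.image, float), np.asarray(below.image, float),
                                 v, max_shift, min_peak)
                if m is not None:
                    meas_v.append(m)
        if not meas_u and not meas_v:
            raise DataError("correlation peak below threshold on all tile pairs")
        new_u = np.median(np.asarray(meas_u), axis=0) if meas_u else u
        new_v = np.median(np.asarray(meas_v), axis=0) if meas_v else v
        update = max(np.abs(new_u - u).max(), np.abs(new_v - v).max())
        u, v = new_u, new_v
        info.update(
            iterations=it + 1,
            max_update_px=float(update),
            n_pairs_u=len(meas_u),
            n_pairs_v=len(meas_v),
        )
        if update < tol_px:
            break
    return TranslationBasis(u=tuple(u), v=tuple(v)), info


def stack_mosaics(
    slices: Sequence[np.ndarray],
    nominal_z_step_um: float,
    z_scale_factor: float = 1.0,
    xy_pixel_um: float = 1.0,
) -> Volume3D:
    """Stack 2D mosaics into a volume with index-mismatch-scaled z-spacing.

    The recorded z-spacing is ``nominal_z_step_um * z_scale_factor`` (the
    measured focal displacement per nominal stage step).  The z-extent
    follows the slice-thickness convention: n_slices * scaled step.
    """
    if not slices:
        raise ValidationError("no slices to stack")
    shape0 = slices[0].shape
    for i, s in enumerate(slices):
        if s.shape != shape0:
            raise DataError(f"slice {i} shape {s.shape} != slice 0 shape {shape0}")
    if nominal_z_step_um <= 0 or z_scale_factor <= 0:
        raise ValidationError("z step and scale factor must be positive")
    data = np.stack([np.asarray(s) for s in slices], axis=0)
    z_um = nominal_z_step_um * z_scale_factor
    return Volume3D(data, spacing=(z_um, xy_pixel_um, xy_pixel_um), channel="reconstructed")
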