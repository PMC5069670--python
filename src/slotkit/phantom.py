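"""Synthetic specimens for end-to-end pipeline testing.

The lobe phantom emulates a cleared, resin-embedded lung lobe at mesoscopic
sampling: an ellipsoidal lobe wrapped in a thin bright pleural shell, filled
with vesicular voids standing in for alveoli (diameter about three beam
widths), a few levels of tapering tubular airways, and optional dense
"fibrotic" patches with elevated absorption and fluorescence.  It is a
texture phantom, not an anatomical model: its purpose is to give every
downstream stage (projection, reconstruction, reslicing, segmentation)
a ground truth to be checked against.

All randomness flows from one `numpy.random.Generator` seeded from
``PhantomParams.seed``; identical parameters give bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DataError, ValidationError, Volume3D
from .stitch import TileRecord, TileSet, TranslationBasis

__all__ = [
    "PhantomParams",
    "PhantomPair",
    "LABEL_BACKGROUND",
    "LABEL_PARENCHYMA",
    "LABEL_AIRWAY",
    "LABEL_PLEURA",
    "LABEL_FIBROSIS",
    "make_lobe_phantom",
    "make_tile_fixture",
]

LABEL_BACKGROUND = 0
LABEL_PARENCHYMA = 1
LABEL_AIRWAY = 2
LABEL_PLEURA = 3
LABEL_FIBROSIS = 4


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and texture parameters of the synthetic lobe.

    Lengths are micrometres.  ``alveolus_diameter`` defaults to 60 um,
    i.e. three times a 20 um focal beam width, matching the alveolar scale
    the scan is designed to resolve.  ``fibrosis_fraction`` is the target
    fraction of lobe voxels covered by dense patches; the generator hits it
    within +-0.03 by thresholding a random blob field.
    ``contrast_ratio`` sets how much denser/brighter fibrotic tissue is than
    normal parenchyma (dimensionless multiplier on both channels).
    """

    shape: tuple[int, int, int] = (96, 96, 96)   # voxels, (z, y, x)
    voxel_size: float = 20.0                      # um, isotropic
    lobe_radii: tuple[float, float, float] = (760.0, 860.0, 700.0)  # um, (z, y, x)
    pleura_thickness: float = 45.0                # um
    alveolus_diameter: float = 60.0               # um
    airway_levels: int = 3                        # branching depth (0 = none)
    fibrosis_fraction: float = 0.0                # target fraction of lobe voxels
    contrast_ratio: float = 2.0                   # fibrotic vs parenchyma intensity
    noise_sd: float = 0.05                        # relative texture noise
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValidationError(f"shape must be three positive counts, got {self.shape}")
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be positive")
        if any(r <= 0 for r in self.lobe_radii):
            raise ValidationError("lobe radii must be positive")
        if not 0.0 <= self.fibrosis_fraction <= 1.0:
            raise ValidationError(
                f"fibrosis_fraction must lie in [0, 1], got {self.fibrosis_fraction}"
            )
        if self.alveolus_diameter <= self.voxel_size:
            raise ValidationError("alveolus_diameter must exceed the voxel size")
        if self.pleura_thickness < 0:
            raise ValidationError("pleura_thickness must be non-negative")
        if self.contrast_ratio <= 1.0:
            raise ValidationError("contrast_ratio must exceed 1")


@dataclass
class PhantomPair:
    """Absorption + fluorescence channels of one phantom, with truth labels."""

    absorption: Volume3D     # mu, 1/um
    fluorescence: Volume3D   # arbitrary density units
    truth_labels: Volume3D   # integer classes, see LABEL_* constants
    params: PhantomParams | None = None

    def __post_init__(self) -> None:
        shapes = {self.absorption.shape, self.fluorescence.shape, self.truth_labels.shape}
        if len(shapes) != 1:
            raise ValidationError(f"phantom channels disagree in shape: {shapes}")
        if self.absorption.spacing != self.fluorescence.spacing:
            raise ValidationError("phantom channels disagree in spacing")
        if np.any(self.absorption.data < 0) or np.any(self.fluorescence.data < 0):
            raise ValidationError("absorption and fluorescence must be non-negative")


# per-class base intensities; fibrosis is parenchyma * contrast_ratio
_MU_PARENCHYMA = 0.002      # 1/um
_MU_PLEURA = 0.0035
_MU_VOID = 0.0002           # residual resin absorption inside alveoli/airways
_F_PARENCHYMA = 1.0         # autofluorescence, arbitrary units
_F_PLEURA = 1.6
_F_VOID = 0.05


def _ellipsoid_mask(shape, spacing_um, radii_um):
    zz, yy, xx = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2.0) * spacing_um for n in shape], indexing="ij"
    )
    return (zz / radii_um[0]) ** 2 + (yy / radii_um[1]) ** 2 + (xx / radii_um[2]) ** 2 <= 1.0


def _poisson_disc_centres(rng, mask, min_dist_vox, n_target):
    """Greedy dart throwing with a coarse occupancy grid (Poisson-disc-like)."""
    cand = np.argwhere(mask)
    if len(cand) == 0:
        return np.empty((0, 3), dtype=int)
    order = rng.permutation(len(cand))
    cell = max(1.0, min_dist_vox / np.sqrt(3.0))
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}
    accepted = []
    r2 = min_dist_vox**2
    for idx in order:
        p = cand[idx]
        key = tuple((p // cell).astype(int))
        ok = True
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for q in grid.get((key[0] + dz, key[1] + dy, key[2] + dx), ()):
                        d = p - q
                        if d @ d < r2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append(p)
            grid.setdefault(key, []).append(p)
            if len(accepted) >= n_target:
                break
    return np.asarray(accepted, dtype=int)


def _carve_balls(mask_out, centres, radius_vox):
    """Set True inside balls of radius_vox around each centre (in-place)."""
    r = int(np.ceil(radius_vox))
    if r < 1 or len(centres) == 0:
        return
    zz, yy, xx = np.meshgrid(*[np.arange(-r, r + 1)] * 3, indexing="ij")
    ball = zz**2 + yy**2 + xx**2 <= radius_vox**2
    shape = mask_out.shape
    for c in centres:
        sl_out, sl_ball = [], []
        for ax in range(3):
            lo, hi = c[ax] - r, c[ax] + r + 1
            blo = max(0, -lo)
            bhi = ball.shape[ax] - max(0, hi - shape[ax])
            sl_out.append(slice(max(0, lo), min(shape[ax], hi)))
            sl_ball.append(slice(blo, bhi))
        mask_out[tuple(sl_out)] |= ball[tuple(sl_ball)]


def _carve_tube(mask_out, p0, p1, r0_vox, r1_vox):
    """Carve a tapering tube from p0 to p1 (voxel coords, radii in voxels)."""
    length = float(np.linalg.norm(np.asarray(p1) - np.asarray(p0)))
    n_steps = max(2, int(np.ceil(length * 2)))
    ts = np.linspace(0.0, 1.0, n_steps)
    centres = np.asarray(p0)[None, :] + ts[:, None] * (np.asarray(p1) - np.asarray(p0))[None, :]
    for t, c in zip(ts, centres):
        r = r0_vox + t * (r1_vox - r0_vox)
        _carve_balls(mask_out, [np.round(c).astype(int)], r)


def _airway_tree(rng, shape, lobe_mask, levels, stem_radius_vox):
    """2-3 levels of tapering cylinders from a single stem along the y-axis."""
    tube = np.zeros(shape, dtype=bool)
    if levels < 1:
        return tube
    nz, ny, nx = shape
    centre = np.array([nz / 2.0, ny / 2.0, nx / 2.0])
    # stem enters from the top of the lobe (high y), pointing down the y-axis
    ys = np.where(lobe_mask.any(axis=(0, 2)))[0]
    if len(ys) == 0:
        return tube
    top = np.array([nz / 2.0, ys[-1], nx / 2.0])
    segments = [(top, centre, stem_radius_vox, 0.72 * stem_radius_vox)]
    ends = [(centre, np.array([0.0, -1.0, 0.0]), 0.72 * stem_radius_vox)]
    for _ in range(levels - 1):
        new_ends = []
        for start, direction, r in ends:
            for _child in range(2):
                # tilt the child direction by a random azimuth in the xz-plane
                phi = rng.uniform(0, 2 * np.pi)
                tilt = rng.uniform(0.5, 0.9)
                d = np.array(
                    [tilt * np.cos(phi), direction[1] * (1 - tilt**2) ** 0.5, tilt * np.sin(phi)]
                )
                d /= np.linalg.norm(d)
                seg_len = rng.uniform(0.12, 0.2) * min(shape)
                end = start + d * seg_len
                end = np.clip(end, 1, np.asarray(shape) - 2)
                segments.append((start, end, r, 0.7 * r))
                new_ends.append((end, d, 0.7 * r))
        ends = new_ends
    for p0, p1, r0, r1 in segments:
        _carve_tube(tube, p0, p1, r0, r1)
    tube &= lobe_mask
    return tube


def _fibrosis_field(rng, shape, allowed, fraction, n_lobe, max_iter=20, tol=0.01):
    """Blob field thresholded to cover ``fraction`` of the lobe.

    Sum of anisotropic Gaussian blobs, thresholded starting at half maximum;
    the threshold is bisected (<= max_iter steps) until the fraction of the
    ``n_lobe`` lobe voxels covered is within ``tol`` of the target.
    """
    zz, yy, xx = np.meshgrid(*[np.arange(n, dtype=np.float32) for n in shape], indexing="ij")
    field = np.zeros(shape, dtype=np.float32)
    n_blobs = max(3, int(np.ceil(fraction * 40)))
    centres = np.argwhere(allowed)
    if len(centres) == 0:
        return np.zeros(shape, dtype=bool)
    picks = centres[rng.integers(0, len(centres), size=n_blobs)]
    for c in picks:
        sig = rng.uniform(0.04, 0.12, size=3) * np.asarray(shape)
        field += np.exp(
            -(
                ((zz - c[0]) / sig[0]) ** 2
                + ((yy - c[1]) / sig[1]) ** 2
                + ((xx - c[2]) / sig[2]) ** 2
            )
        )
    field *= allowed
    lo, hi = 0.0, float(field.max())
    thr = 0.5 * hi
    best = None
    for _ in range(max_iter):
        mask = field >= thr
        frac = mask.sum() / n_lobe
        if best is None or abs(frac - fraction) < abs(best[1] - fraction):
            best = (thr, frac)
        if abs(frac - fraction) <= tol:
            return mask
        if frac > fraction:   # covering too much -> raise threshold
            lo = thr
        else:
            hi = thr
        thr = 0.5 * (lo + hi)
    return field >= best[0]


def make_lobe_phantom(params: PhantomParams) -> PhantomPair:
    """Generate a synthetic cleared-lobe specimen.

    Returns a :class:`PhantomPair` with absorption (1/um), fluorescence
    (arbitrary units) and integer truth labels.  Fibrotic voxels (label 4)
    have ``contrast_ratio`` times the parenchymal absorption and
    fluorescence; alveolar and airway lumina are near-transparent voids.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(int(n) for n in params.shape)
    sp = params.voxel_size

    lobe = _ellipsoid_mask(shape, sp, params.lobe_radii)
    if not lobe.any():
        raise ValidationError("lobe radii leave no voxel inside the volume")

    # pleura: boundary shell of the lobe, pleura_thickness deep
    n_erode = max(1, int(round(params.pleura_thickness / sp)))
    interior = ndimage.binary_erosion(lobe, iterations=n_erode)
    pleura = lobe & ~interior

    # airways: tapering tubes from a single stem
    stem_r_vox = max(2.0, 0.035 * min(shape))
    airway = _airway_tree(rng, shape, interior, params.airway_levels, stem_r_vox)

    # alveoli: Poisson-disc spherical voids in the parenchyma
    alv_r_vox = 0.5 * params.alveolus_diameter / sp
    parenchyma_region = interior & ~airway
    min_dist = 2.6 * alv_r_vox
    # dart density chosen to give a vesicular (foam-like) texture
    n_target = int(parenchyma_region.sum() / (min_dist**3) * 2.5)
    centres = _poisson_disc_centres(rng, parenchyma_region, min_dist, n_target)
    voids = np.zeros(shape, dtype=bool)
    _carve_balls(voids, centres, alv_r_vox)
    voids &= parenchyma_region

    labels = np.zeros(shape, dtype=np.uint16)
    labels[interior] = LABEL_PARENCHYMA
    labels[voids] = LABEL_BACKGROUND          # alveolar lumina are voids
    labels[airway] = LABEL_AIRWAY
    labels[pleura] = LABEL_PLEURA

    if params.fibrosis_fraction > 0:
        allowed = interior & ~airway          # consolidation fills parenchyma and voids
        fib = _fibrosis_field(
            rng, shape, allowed, params.fibrosis_fraction, n_lobe=int(lobe.sum())
        )
        labels[fib] = LABEL_FIBROSIS

    mu = np.zeros(shape, dtype=np.float32)
    flu = np.zeros(shape, dtype=np.float32)
    in_lobe_void = lobe & (labels == LABEL_BACKGROUND)
    mu[in_lobe_void] = _MU_VOID
    flu[in_lobe_void] = _F_VOID
    mu[labels == LABEL_PARENCHYMA] = _MU_PARENCHYMA
    flu[labels == LABEL_PARENCHYMA] = _F_PARENCHYMA
    mu[labels == LABEL_AIRWAY] = _MU_VOID
    flu[labels == LABEL_AIRWAY] = _F_VOID
    mu[labels == LABEL_PLEURA] = _MU_PLEURA
    flu[labels == LABEL_PLEURA] = _F_PLEURA
    mu[labels == LABEL_FIBROSIS] = params.contrast_ratio * _MU_PARENCHYMA
    flu[labels == LABEL_FIBROSIS] = params.contrast_ratio * _F_PARENCHYMA

    if params.noise_sd > 0:
        tex = rng.normal(1.0, params.noise_sd, size=shape).astype(np.float32)
        mu *= np.clip(tex, 0.0, None)
        flu *= np.clip(rng.normal(1.0, params.noise_sd, size=shape).astype(np.float32), 0.0, None)

    spacing = (sp, sp, sp)
    return PhantomPair(
        absorption=Volume3D(mu, spacing, "absorption"),
        fluorescence=Volume3D(flu, spacing, "fluorescence"),
        truth_labels=Volume3D(labels, spacing, "label"),
        params=params,
    )


def make_tile_fixture(
    image: np.ndarray,
    rows: int,
    cols: int,
    basis: TranslationBasis,
    overlap_px: int,
    noise_sd: float = 0.0,
    falloff: float = 0.0,
    seed: int = 0,
) -> TileSet:
    """Cut a mosaic tile set out of a reference image.

    Tile (r, c) is the crop of ``image`` at position ``r*v + c*u`` (x, y
    pixel units, possibly subpixel -> bilinear sampling), optionally with
    additive Gaussian noise (``noise_sd``) and a radially symmetric
    intensity falloff (vignetting; ``falloff`` in [0, 1] is the relative
    attenuation at the tile corner).  The true basis and tile origin are
    recorded as ground-truth metadata.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValidationError("make_tile_fixture expects a 2D image")
    if rows < 1 or cols < 1:
        raise ValidationError("rows and cols must be >= 1")
    if overlap_px < 0:
        raise ValidationError("overlap_px must be >= 0")
    u = np.asarray(basis.u, dtype=float)
    v = np.asarray(basis.v, dtype=float)

    tile_w = int(round(abs(u[0]))) + overlap_px
    tile_h = int(round(abs(v[1]))) + overlap_px
    if tile_w < 1 or tile_h < 1:
        raise ValidationError("degenerate tile size; check basis and overlap")
    if tile_w > image.shape[1] or tile_h > image.shape[0]:
        raise DataError(
            f"image {image.shape} smaller than one tile ({tile_h} x {tile_w})"
        )

    # positions in (x, y); shift so the smallest position is 0
    pos = np.array([[c * u + r * v for c in range(cols)] for r in range(rows)])
    origin = pos.reshape(-1, 2).min(axis=0)
    pos = pos - origin

    max_x = pos[..., 0].max() + tile_w
    max_y = pos[..., 1].max() + tile_h
    if max_x > image.shape[1] or max_y > image.shape[0]:
        raise DataError(
            f"image {image.shape} smaller than the tiled extent "
            f"({int(np.ceil(max_y))} x {int(np.ceil(max_x))})"
        )

    if falloff:
        yy, xx = np.meshgrid(np.arange(tile_h), np.arange(tile_w), indexing="ij")
        cy, cx = (tile_h - 1) / 2.0, (tile_w - 1) / 2.0
        rho2 = ((yy - cy) / max(cy, 0.5)) ** 2 + ((xx - cx) / max(cx, 0.5)) ** 2
        vignette = 1.0 - falloff * rho2 / 2.0
    else:
        vignette = None

    rng = np.random.default_rng(seed)
    tiles = []
    for r in range(rows):
        for c in range(cols):
            px, py = pos[r, c]
            if float(px).is_integer() and float(py).is_integer():
                ix, iy = int(px), int(py)
                tile = image[iy : iy + tile_h, ix : ix + tile_w].copy()
            else:
                yy, xx = np.meshgrid(
                    py + np.arange(tile_h), px + np.arange(tile_w), indexing="ij"
                )
                tile = ndimage.map_coordinates(image, [yy, xx], order=1, mode="nearest")
            if vignette is not None:
                tile = tile * vignette
            if noise_sd > 0:
                tile = tile + rng.normal(0.0, noise_sd, size=tile.shape)
            tiles.append(TileRecord(image=tile, row=r, col=c))

    return TileSet(
        tiles=tiles,
        tile_px=(tile_h, tile_w),
        nominal_overlap=overlap_px / max(tile_w, 1),
        true_basis=TranslationBasis(u=tuple(u), v=tuple(v)),
        origin=tuple(origin),
    )
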