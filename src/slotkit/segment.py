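"""Density-based ROI screening of reconstructed volumes.

Fibrotic (remodelled) tissue is denser than normal parenchyma, so it shows
up in the absorption channel as compact high-intensity patches.  The
screening chain is the classic edge-preserving one: gradient anisotropic
diffusion to flatten texture while keeping lesion boundaries, gradient
magnitude to turn boundaries into ridges, watershed to partition the volume
into basins bounded by those ridges, and a per-region mean-intensity rule to
call each basin fibrotic or normal parenchyma.  Everything is batch and
deterministic: markers come from a flood level (or are supplied explicitly),
never from interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed as _skimage_watershed

from .core import DataError, ValidationError, Volume3D

__all__ = [
    "DiffusionParams",
    "LabelVolume",
    "ScreenParams",
    "anisotropic_diffusion",
    "gradient_magnitude",
    "watershed_regions",
    "classify_regions",
    "screen_rois",
]

CLASS_BACKGROUND = "background"
CLASS_PARENCHYMA = "parenchyma"
CLASS_FIBROTIC = "fibrotic"


@dataclass(frozen=True)
class DiffusionParams:
    """Perona-Malik gradient anisotropic diffusion settings.

    conductance
        Edge threshold kappa in intensity units (per-voxel neighbour
        difference scale): differences well below kappa diffuse freely,
        differences above are preserved.
    time_step
        Explicit-scheme step; the von Neumann stability bound for the 3D
        6-neighbour Laplacian is 1/6, so the step is capped at 0.25 and
        defaults to 0.15.
    """

    conductance: float
    iterations: int = 10
    time_step: float = 0.15

    def __post_init__(self) -> None:
        if self.conductance <= 0:
            raise ValidationError("conductance must be positive")
        if self.iterations < 0:
            raise ValidationError("iterations must be >= 0")
        if not 0 < self.time_step <= 0.25:
            raise ValidationError("time_step must lie in (0, 0.25]")


@dataclass
class LabelVolume:
    """Integer region labels plus a class per region."""

    labels: np.ndarray
    class_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be integers")
        if self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")

    def mask_of(self, cls: str) -> np.ndarray:
        ids = [i for i, c in self.class_map.items() if c == cls]
        return np.isin(self.labels, ids)


def anisotropic_diffusion(v: Volume3D, p: DiffusionParams) -> Volume3D:
    """Edge-preserving smoothing (Perona-Malik, conservative explicit scheme).

    Flux between 6-neighbours is ``g(d) * d`` with the exponential
    conductance ``g(d) = exp(-(d / kappa)^2)``; Neumann (zero-flux)
    boundaries make the scheme conserve the global mean exactly.
    """
    out = np.asarray(v.data, dtype=np.float64).copy()
    inv_k2 = 1.0 / p.conductance**2
    for _ in range(p.iterations):
        div = np.zeros_like(out)
        for ax in range(3):
            d = np.diff(out, axis=ax)                    # interface differences
            flux = d * np.exp(-(d * d) * inv_k2)         # flux across interface (i, i+1)
            pad = [(0, 0)] * 3
            pad[ax] = (0, 1)
            right = np.pad(flux, pad)                    # interface right of voxel i
            pad[ax] = (1, 0)
            left = np.pad(flux, pad)                     # interface left of voxel i
            div += right - left                          # zero flux across the border
        out += p.time_step * div
    return v.with_data(out)


def gradient_magnitude(v: Volume3D) -> Volume3D:
    """Euclidean norm of the central-difference gradient, scaled by spacing."""
    grads = np.gradient(np.asarray(v.data, dtype=np.float64), *v.spacing)
    mag = np.sqrt(sum(g * g for g in grads))
    return v.with_data(mag)


def watershed_regions(
    gradient: Volume3D,
    markers: np.ndarray | None = None,
    flood_level: float | None = None,
) -> LabelVolume:
    """Marker-based watershed of a gradient-magnitude image.

    Markers may be given explicitly (integer seed labels) or derived from a
    flood level: connected components (6-connectivity) of voxels whose
    gradient lies below the level.  Flooding order is deterministic; on
    ridges the basin of the lowest marker id wins.
    """
    g = np.asarray(gradient.data, dtype=np.float64)
    if np.any(g < 0):
        raise ValidationError("gradient image must be non-negative")
    if markers is None:
        if flood_level is None:
            raise ValidationError("watershed needs markers or a flood level")
        seeds, _ = ndimage.label(g < flood_level)        # 6-connectivity default
        markers = seeds
    else:
        markers = np.asarray(markers)
        if markers.shape != g.shape:
            raise DataError("marker grid shape does not match the gradient")
        if not markers.any():
            raise ValidationError("marker grid contains no seeds")
    labels = _skimage_watershed(g, markers=markers, connectivity=1)
    return LabelVolume(labels=labels.astype(np.int32))


def classify_regions(
    labels: LabelVolume,
    intensity: Volume3D,
    density_threshold: float,
) -> tuple[LabelVolume, pd.DataFrame]:
    """Call each watershed region fibrotic or parenchymal by mean intensity.

    A region whose mean intensity is at or above ``density_threshold`` is
    classed fibrotic, otherwise parenchyma; label 0 stays background.
    Returns the labelled volume (class map filled in) and a per-region
    report (id, voxel count, mean intensity, class).
    """
    lab = labels.labels
    img = np.asarray(intensity.data, dtype=np.float64)
    if lab.shape != img.shape:
        raise DataError(
            f"label grid {lab.shape} does not match intensity volume {img.shape}"
        )
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if len(ids):
        means = ndimage.mean(img, labels=lab, index=ids)
        counts = ndimage.sum_labels(np.ones_like(img), labels=lab, index=ids)
    else:
        means, counts = np.array([]), np.array([])
    class_map = {
        int(i): (CLASS_FIBROTIC if m >= density_threshold else CLASS_PARENCHYMA)
        for i, m in zip(ids, means)
    }
    report = pd.DataFrame(
        {
            "region_id": ids.astype(int),
            "voxel_count": counts.astype(int),
            "mean_intensity": means,
            "class": [class_map[int(i)] for i in ids],
        }
    )
    out = LabelVolume(labels=lab, class_map=class_map)
    return out, report


@dataclass(frozen=True)
class ScreenParams:
    """Shipped default parameter set for phantom-scale absorption volumes.

    Tuned for the lobe phantom's absorption channel (parenchyma ~0.002/um,
    fibrosis at twice that): conductance at a quarter of the class step so
    texture diffuses but lesion boundaries survive; markers flood from the
    flattest decile of the gradient image; the density threshold sits
    between the pleural and fibrotic means.
    """

    diffusion: DiffusionParams = field(
        default_factory=lambda: DiffusionParams(conductance=5e-4, iterations=12)
    )
    flood_level_frac: float = 0.10          # fraction of the max gradient
    density_threshold: float = 0.00375      # intensity units of the input volume
    min_region_voxels: int = 8              # drop speckle regions from the report


def screen_rois(
    volume: Volume3D, params: ScreenParams = ScreenParams()
) -> tuple[LabelVolume, pd.DataFrame, np.ndarray]:
    """Full screening chain: diffuse -> gradient -> watershed -> classify.

    Returns the classified label volume, the region report, and the boolean
    fibrotic mask.
    """
    smoothed = anisotropic_diffusion(volume, params.diffusion)
    grad = gradient_magnitude(smoothed)
    level = params.flood_level_frac * float(grad.data.max())
    regions = watershed_regions(grad, flood_level=level)
    classified, report = classify_regions(regions, smoothed, params.density_threshold)
    if params.min_region_voxels > 1 and len(report):
        small = report[report.voxel_count < params.min_region_voxels].region_id
        for i in small:
            classified.class_map[int(i)] = CLASS_PARENCHYMA
        report = report[report.voxel_count >= params.min_region_voxels].reset_index(drop=True)
    return classified, report, classified.mask_of(CLASS_FIBROTIC)
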