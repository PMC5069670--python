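"""Closed-form acquisition planning for a scanned weakly-focused laser setup.

These are the arithmetic rules a tomography operator uses before a scan:
how thin the beam is, how far it stays thin, how many projections a full
revolution needs, and how a tiled mosaic maps onto pixels.  All formulas are
elementary; the value of this module is that every number is computed the
same way everywhere else in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import ValidationError

__all__ = [
    "OpticsParams",
    "MosaicPlan",
    "PlannerReport",
    "depth_of_field_mm",
    "lateral_resolution_um",
    "required_projections",
    "angular_increment_deg",
    "axial_step_scale",
    "plan_mosaic",
    "total_tiles",
    "make_report",
]


@dataclass(frozen=True)
class OpticsParams:
    """Illumination optics of the scanner.

    n_imm
        Refractive index of the immersion medium (matched to the sample).
    wavelength_nm
        Laser wavelength in nanometres.
    na
        Numerical aperture of the weakly focused scanning beam.
    """

    n_imm: float
    wavelength_nm: float
    na: float

    def __post_init__(self) -> None:
        if self.n_imm <= 0 or self.wavelength_nm <= 0:
            raise ValidationError("refractive index and wavelength must be positive")
        if self.na <= 0:
            raise ValidationError("numerical aperture must be positive")
        if self.na >= self.n_imm:
            raise ValidationError(
                f"NA ({self.na}) must be smaller than the immersion index ({self.n_imm})"
            )


def depth_of_field_mm(p: OpticsParams) -> float:
    """Depth of field DoF = 2 n lambda / NA**2, in millimetres.

    The sample must be covered by the DoF of the illumination beam for
    projection tomography to be valid.  The quadratic NA dependence is the
    standard Gaussian-beam confocal-parameter scaling: halving NA quadruples
    the usable depth (and only the quadratic form reproduces a ~10 mm depth
    at NA = 0.013, n = 1.556, 532 nm).
    """
    wavelength_mm = p.wavelength_nm * 1e-6
    return 2.0 * p.n_imm * wavelength_mm / p.na**2


def lateral_resolution_um(p: OpticsParams) -> float:
    """Focal beam width (lateral resolution) dx = lambda / (2 NA), in um."""
    return (p.wavelength_nm * 1e-3) / (2.0 * p.na)


def required_projections(n_lateral_samples: int) -> int:
    """Number of projections demanded by the angular sampling theorem.

    For a full revolution the number of projections must equal the number of
    lateral (x-axis) sampling points of each projection.
    """
    n = int(n_lateral_samples)
    if n < 1:
        raise ValidationError("need at least one lateral sample")
    return n


def angular_increment_deg(n_projections: int) -> float:
    """Angular step of a full 360 degree revolution split into n projections."""
    n = int(n_projections)
    if n < 1:
        raise ValidationError("need at least one projection")
    return 360.0 / n


def axial_step_scale(nominal_step_um: float, scale_factor: float) -> float:
    """True axial displacement per nominal stage step.

    Index mismatch between the objective's design immersion and the sample
    shifts the focus by more than the stage moves; the measured offset is
    ``nominal_step * scale_factor`` (e.g. 2 um steps -> 2.72 um at the
    water/polymer mismatch, factor 1.36).
    """
    if nominal_step_um <= 0 or scale_factor <= 0:
        raise ValidationError("step and scale factor must be positive")
    return nominal_step_um * scale_factor


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class MosaicPlan:
    tile_px: int
    mosaic_px: tuple[int, ...]
    grid: tuple[int, ...]          # tiles per axis (minimal covering counts)
    step_um: float                 # tile pitch at the requested overlap


def plan_mosaic(
    extent_um: tuple[float, ...],
    tile_um: float,
    overlap_fraction: float,
    px_um: float,
) -> MosaicPlan:
    """Tile/pixel bookkeeping for a mosaic scan.

    tile_px is floored (a tile cannot exceed its physical field of view);
    mosaic extents are rounded half-up to pixels; grid counts are the minimal
    number of tiles at pitch ``tile_um * (1 - overlap_fraction)`` that cover
    each extent.
    """
    if px_um <= 0:
        raise ValidationError("pixel size must be positive")
    if not 0 <= overlap_fraction < 1:
        raise ValidationError("overlap fraction must be in [0, 1)")
    if tile_um <= 0:
        raise ValidationError("tile size must be positive")
    for e in extent_um:
        if tile_um > e:
            raise ValidationError(f"tile ({tile_um} um) larger than extent ({e} um)")

    tile_px = int(math.floor(tile_um / px_um))
    mosaic_px = tuple(_round_half_up(e / px_um) for e in extent_um)
    step = tile_um * (1.0 - overlap_fraction)
    grid = []
    for e in extent_um:
        if e <= tile_um:
            grid.append(1)
        else:
            # minimal n with (n-1) * step + tile_um >= e
            grid.append(1 + math.ceil((e - tile_um) / step - 1e-9))
    return MosaicPlan(tile_px=tile_px, mosaic_px=mosaic_px, grid=tuple(grid), step_um=step)


def total_tiles(grid: tuple[int, ...], n_slices: int = 1) -> int:
    """Total tile count of a (rows x cols) mosaic repeated over n_slices."""
    if n_slices < 1 or any(g < 1 for g in grid):
        raise ValidationError("grid counts and slice count must be >= 1")
    out = int(n_slices)
    for g in grid:
        out *= int(g)
    return out


@dataclass(frozen=True)
class PlannerReport:
    """Everything the planner derives for one acquisition."""

    dof_mm: float
    lateral_resolution_um: float
    n_projections_required: int
    angular_increment_deg: float
    tile_px: int
    mosaic_px: tuple[int, ...]
    grid: tuple[int, ...]
    measured_z_step_um: float
    total_depth_um: float

    def as_dict(self) -> dict:
        d = {
            "dof_mm": self.dof_mm,
            "lateral_resolution_um": self.lateral_resolution_um,
            "n_projections_required": self.n_projections_required,
            "angular_increment_deg": self.angular_increment_deg,
            "tile_px": self.tile_px,
            "mosaic_px": list(self.mosaic_px),
            "grid": list(self.grid),
            "measured_z_step_um": self.measured_z_step_um,
            "total_depth_um": self.total_depth_um,
        }
        return d


def make_report(
    optics: OpticsParams,
    n_lateral_samples: int,
    extent_um: tuple[float, ...],
    tile_um: float,
    overlap_fraction: float,
    px_um: float,
    nominal_z_step_um: float = 2.0,
    z_scale_factor: float = 1.36,
    n_z_slices: int = 1,
) -> PlannerReport:
    """Assemble the full planning report for one run configuration."""
    n_proj = required_projections(n_lateral_samples)
    mosaic = plan_mosaic(extent_um, tile_um, overlap_fraction, px_um)
    z_step = axial_step_scale(nominal_z_step_um, z_scale_factor)
    return PlannerReport(
        dof_mm=depth_of_field_mm(optics),
        lateral_resolution_um=lateral_resolution_um(optics),
        n_projections_required=n_proj,
        angular_increment_deg=angular_increment_deg(n_proj),
        tile_px=mosaic.tile_px,
        mosaic_px=mosaic.mosaic_px,
        grid=mosaic.grid,
        measured_z_step_um=z_step,
        total_depth_um=n_z_slices * z_step,
    )
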