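"""Core containers shared across the pipeline.

Coordinate convention (used everywhere in this package):

* ``y`` is the rotation axis of the tomographic scan (vertical),
* ``z`` is the beam propagation axis,
* ``x`` is the lateral scan axis.

Volumes are stored as ``data[z, y, x]`` with per-axis voxel spacing in
micrometres ordered ``(z, y, x)``.  Projection stacks (sinograms) are stored
as ``data[angle, y, x]``.  All voxel/pixel coordinates are 0-based and refer
to voxel centres; continuous coordinates interpolate between centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SlotkitError",
    "ValidationError",
    "DataError",
    "Volume3D",
    "FanGeometry",
    "AcquisitionGeometry",
    "Sinogram",
    "CHANNELS",
]


class SlotkitError(Exception):
    """Base class for all package errors."""


class ValidationError(SlotkitError, ValueError):
    """Invalid parameters or geometry (CLI exit code 2)."""


class DataError(SlotkitError, ValueError):
    """Malformed or inconsistent data (CLI exit code 3)."""


#: Channel roles a volume or sinogram may carry.
CHANNELS = (
    "absorption",       # absorption coefficient mu, 1/um
    "fluorescence",     # fluorophore density, arbitrary units
    "transmission",     # detected transmitted intensity, (0, i0]
    "line_integral",    # -log(I/i0), i.e. integral of mu along the beam
    "reconstructed",    # FBP output intensity
    "label",            # integer class labels
)


@dataclass
class Volume3D:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data:
        Array indexed ``[z, y, x]``.
    spacing:
        Voxel spacing in micrometres, ordered ``(z, y, x)``.
    channel:
        One of :data:`CHANNELS`; describes what the values mean.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel: str = "reconstructed"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"Volume3D requires a 3D array, got ndim={self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent per axis (slice-thickness convention: n * spacing)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, channel: Optional[str] = None) -> "Volume3D":
        """New volume sharing this volume's spacing."""
        return Volume3D(data=data, spacing=self.spacing, channel=channel or self.channel)


@dataclass(frozen=True)
class FanGeometry:
    """First-order model of the f-theta scan lens fan.

    The beam launched at detector column ``x`` propagates at an in-plane
    angle ``beta(x) = shear_rate * (x - center_x)`` (degrees) relative to the
    optical axis; ``shear_rate = 0`` degenerates to parallel geometry.
    """

    shear_rate: float  # degrees per detector pixel
    center_x: float    # detector column where beta crosses zero

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shear_rate) and np.isfinite(self.center_x)):
            raise ValidationError("fan parameters must be finite")

    def beta_deg(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.shear_rate * (np.asarray(x, dtype=float) - self.center_x)


@dataclass
class AcquisitionGeometry:
    """Scan geometry of one projection set."""

    n_projections: int
    detector_x: int
    detector_y: int
    pixel_um: float = 1.0
    i0: float = 1.0
    angles_deg: Optional[np.ndarray] = None
    fan: Optional[FanGeometry] = None

    def __post_init__(self) -> None:
        if self.n_projections < 1:
            raise ValidationError("n_projections must be >= 1")
        if self.detector_x < 1 or self.detector_y < 1:
            raise ValidationError("detector dimensions must be positive")
        if self.pixel_um <= 0:
            raise ValidationError("pixel_um must be positive")
        if self.i0 <= 0:
            raise ValidationError("i0 must be positive")
        if self.angles_deg is None:
            # bin centres starting at 0 deg, half-open [0, 360)
            self.angles_deg = np.arange(self.n_projections) * (360.0 / self.n_projections)
        else:
            self.angles_deg = np.asarray(self.angles_deg, dtype=float)
            if len(self.angles_deg) != self.n_projections:
                raise ValidationError(
                    f"{len(self.angles_deg)} angles given for {self.n_projections} projections"
                )
            if np.any(np.diff(self.angles_deg) <= 0):
                raise ValidationError("angles must be strictly increasing")
            if self.angles_deg[0] < 0 or self.angles_deg[-1] >= 360.0:
                raise ValidationError("angles must lie in [0, 360)")

    @property
    def uniform_spacing(self) -> bool:
        if self.n_projections < 2:
            return True
        d = np.diff(self.angles_deg)
        return bool(np.allclose(d, d[0], rtol=0, atol=1e-9))


@dataclass
class Sinogram:
    """A stack of projections indexed ``[angle, y, x]``."""

    data: np.ndarray
    geometry: AcquisitionGeometry
    channel: str = "line_integral"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError("Sinogram data must be [angle, y, x]")
        n, ny, nx = self.data.shape
        g = self.geometry
        if (n, ny, nx) != (g.n_projections, g.detector_y, g.detector_x):
            raise ValidationError(
                f"sinogram shape {self.data.shape} does not match geometry "
                f"({g.n_projections}, {g.detector_y}, {g.detector_x})"
            )
        if self.channel not in ("transmission", "fluorescence", "line_integral"):
            raise ValidationError(f"invalid sinogram channel {self.channel!r}")

    @property
    def angles_deg(self) -> np.ndarray:
        return self.geometry.angles_deg

    def with_data(self, data: np.ndarray, channel: Optional[str] = None) -> "Sinogram":
        return Sinogram(data=data, geometry=self.geometry, channel=channel or self.channel)
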