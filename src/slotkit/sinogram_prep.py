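"""Pre-reconstruction sinogram processing.

Three steps sit between raw acquisition and filtered back projection:

1. converting detected transmission intensities to attenuation line
   integrals (Beer-Lambert inversion),
2. undoing the f-theta fan by de-shearing the sinogram along the angle
   axis, so that point traces are sinusoids again and a parallel-beam
   reconstruction applies,
3. checking the angular sampling rule (number of projections >= number of
   lateral sampling points for a full revolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataError, Sinogram, ValidationError

__all__ = [
    "ShearModel",
    "SamplingReport",
    "transmission_to_line_integral",
    "deshear",
    "check_angular_sampling",
]


@dataclass(frozen=True)
class ShearModel:
    """Linear shear of sinusoid traces along the angle axis.

    A beam launched at detector column x is tilted by
    ``beta(x) = shear_rate * (x - center_x)`` degrees, so its trace in the
    (x, phi) sinogram is displaced along phi by the same amount.  The model
    is linear in x - the first-order description of an f-theta scan lens.
    """

    shear_rate: float   # degrees per detector pixel
    center_x: float     # column where the tilt crosses zero

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shear_rate) and np.isfinite(self.center_x)):
            raise ValidationError("shear model parameters must be finite")


def transmission_to_line_integral(s: Sinogram, i0: float | None = None) -> Sinogram:
    """Beer-Lambert inversion: ``value <- -log(value / i0)``.

    Raises a data error (with the offending pixel count) if any intensity is
    non-positive, since the logarithm is undefined there.
    """
    if s.channel != "transmission":
        raise ValidationError(f"expected a transmission sinogram, got {s.channel!r}")
    i0 = float(s.geometry.i0 if i0 is None else i0)
    data = np.asarray(s.data, dtype=np.float64)
    n_bad = int(np.count_nonzero(data <= 0))
    if n_bad:
        raise DataError(
            f"{n_bad} non-positive intensity pixel(s); cannot take the logarithm"
        )
    out = -np.log(data / i0)
    return s.with_data(out.astype(np.float32), channel="line_integral")


def deshear(s: Sinogram, model: ShearModel) -> Sinogram:
    """Remove the fan-induced shearing along the phi-axis of a sinogram.

    Each column x of every y-row sinogram is resampled along the angle axis
    at ``phi - beta(x)`` with ``beta(x) = shear_rate * (x - center_x)``,
    circularly (the scan covers a full 360 degree revolution), with linear
    interpolation between angle samples.  Applied to fan-beam data this
    restores the sinusoid traces of parallel-beam geometry.

    ``deshear(s, model)`` is inverted (to interpolation accuracy) by
    ``deshear(s, ShearModel(-shear_rate, center_x))``.
    """
    g = s.geometry
    if g.n_projections < 2:
        raise ValidationError("de-shearing needs at least two angles")
    if not g.uniform_spacing:
        raise ValidationError("de-shearing requires uniformly spaced angles")
    if model.shear_rate == 0.0:
        return s.with_data(np.array(s.data, copy=True))

    n, ny, nx = s.data.shape
    dphi = 360.0 / n   # full-revolution scan, circular in phi
    beta_deg = model.shear_rate * (np.arange(nx) - model.center_x)
    shift = beta_deg / dphi                      # angle samples, per column

    k = np.arange(n, dtype=np.float64)[:, None] - shift[None, :]   # [angle, x]
    k = np.mod(k, n)
    k0 = np.floor(k).astype(int)
    frac = (k - k0).astype(s.data.dtype if np.issubdtype(s.data.dtype, np.floating) else np.float64)
    k1 = (k0 + 1) % n

    y_idx = np.arange(ny)[None, :, None]
    x_idx = np.arange(nx)[None, None, :]
    lo = s.data[k0[:, None, :], y_idx, x_idx]
    hi = s.data[k1[:, None, :], y_idx, x_idx]
    out = (1.0 - frac[:, None, :]) * lo + frac[:, None, :] * hi
    return s.with_data(out)


@dataclass(frozen=True)
class SamplingReport:
    adequate: bool
    required: int
    actual: int


def check_angular_sampling(s: Sinogram) -> SamplingReport:
    """Angular sampling rule for a full revolution.

    The number of projections must be at least the number of lateral (x)
    sampling points; fewer projections undersample the high spatial
    frequencies at the field edge.
    """
    required = s.geometry.detector_x
    actual = s.geometry.n_projections
    return SamplingReport(adequate=actual >= required, required=required, actual=actual)
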