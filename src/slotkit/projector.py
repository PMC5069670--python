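"""Forward projection: simulated two-channel tomographic acquisition.

Emulates a scanning-laser optical tomography scan of a phantom: at every
rotation angle the transmitted intensity (Beer-Lambert attenuation of the
absorption channel) and the fluorescence line integral are recorded on a
detector grid [y, x].  ``y`` is the rotation axis, the beam propagates
along ``z``, ``x`` is the lateral scan position.

Two geometries are provided:

* :func:`forward_project` - ideal parallel beams (the yz-plane case, where
  the scan lens keeps all beams orthogonal to the rotation axis);
* :func:`fan_project` - beams whose in-plane direction tilts linearly with
  the lateral scan position (the xz-plane fan of an f-theta lens), the
  artifact that sinogram de-shearing must undo.

A point at radius r from the rotation axis traces the sinusoid
``x(phi) = x_c + r cos(phi - phi_0)`` in the parallel sinogram.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import AcquisitionGeometry, DataError, Sinogram, ValidationError, Volume3D

__all__ = ["default_geometry", "forward_project", "fan_project", "project_volume"]


def default_geometry(
    vol: Volume3D,
    n_projections: int,
    i0: float = 1.0,
    fan=None,
) -> AcquisitionGeometry:
    """Geometry whose detector matches the volume grid one-to-one."""
    nz, ny, nx = vol.shape
    return AcquisitionGeometry(
        n_projections=n_projections,
        detector_x=nx,
        detector_y=ny,
        pixel_um=vol.spacing[2],
        i0=i0,
        fan=fan,
    )


def _check_compat(vol: Volume3D, geom: AcquisitionGeometry) -> None:
    nz, ny, nx = vol.shape
    if geom.detector_y != ny:
        raise DataError(
            f"detector_y ({geom.detector_y}) must match the volume y-extent ({ny})"
        )
    if geom.detector_x < nx:
        raise DataError(
            f"detector_x ({geom.detector_x}) does not cover the lateral extent ({nx})"
        )
    if abs(vol.spacing[0] - vol.spacing[2]) > 1e-9:
        raise ValidationError("projection requires isotropic in-plane (z, x) spacing")


def _rotated(vol_data: np.ndarray, phi_deg: float, nzp: int, nxp: int) -> np.ndarray:
    """Resample the volume into the beam frame at rotation angle phi.

    Output ``out[z', y, x']`` samples the volume at
    ``x = x' cos(phi) - z' sin(phi)``, ``z = x' sin(phi) + z' cos(phi)``
    (coordinates about the respective grid centres, linear interpolation,
    zeros outside).  Summing ``out`` over z' gives the parallel projection;
    a point at polar position (r, phi0) lands at x' = r cos(phi - phi0).
    """
    nz, ny, nx = vol_data.shape
    phi = np.deg2rad(phi_deg)
    c, s = np.cos(phi), np.sin(phi)
    # matrix mapping output index (z', y, x') -> input index (z, y, x)
    m = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    c_in = (np.array([nz, ny, nx]) - 1) / 2.0
    c_out = (np.array([nzp, ny, nxp]) - 1) / 2.0
    offset = c_in - m @ c_out
    return ndimage.affine_transform(
        vol_data, m, offset=offset, output_shape=(nzp, ny, nxp),
        order=1, mode="constant", cval=0.0, prefilter=False,
    )


def project_volume(vol: Volume3D, geom: AcquisitionGeometry) -> np.ndarray:
    """Parallel line integrals of one volume: array [angle, y, x] in value*um."""
    _check_compat(vol, geom)
    nz, ny, nx = vol.shape
    nxp = geom.detector_x
    nzp = int(np.ceil(np.hypot(nz, nx)))   # cover the rotated footprint
    dl = vol.spacing[0]
    data = np.asarray(vol.data, dtype=np.float32)
    out = np.empty((geom.n_projections, ny, nxp), dtype=np.float32)
    for k, phi in enumerate(geom.angles_deg):
        rot = _rotated(data, float(phi), nzp, nxp)
        out[k] = rot.sum(axis=0) * dl
    return out


def _fan_line_integrals(vol: Volume3D, geom: AcquisitionGeometry) -> np.ndarray:
    """Line integrals along beams tilted by beta(x) in the xz-plane."""
    fan = geom.fan
    nz, ny, nx = vol.shape
    nxp = geom.detector_x
    nzp = int(np.ceil(np.hypot(nz, nx)))
    beta = np.deg2rad(np.asarray(fan.beta_deg(np.arange(nxp))))
    if np.any(np.abs(beta) > np.deg2rad(45.0)):
        raise ValidationError(
            "fan model invalid: beam tilt exceeds 45 degrees at the field edge"
        )
    dl = vol.spacing[0]
    data = np.asarray(vol.data, dtype=np.float32)

    # beam through detector column x crosses the focal (centre) plane at x
    # and is displaced by tan(beta(x)) * (z' - z'_c) elsewhere
    zc = (nzp - 1) / 2.0
    zp = np.arange(nzp, dtype=np.float64)
    xs = np.arange(nxp, dtype=np.float64)
    x_coords = xs[None, :] - np.tan(beta)[None, :] * (zp[:, None] - zc)   # [z', x]
    z_coords = np.broadcast_to(zp[:, None], x_coords.shape)
    path_scale = (dl / np.cos(beta)).astype(np.float32)                   # per column

    out = np.empty((geom.n_projections, ny, nxp), dtype=np.float32)
    coords = np.stack([z_coords, x_coords])                               # for (z', x') sampling
    for k, phi in enumerate(geom.angles_deg):
        rot = _rotated(data, float(phi), nzp, nxp)                        # [z', y, x']
        for j in range(ny):
            samp = ndimage.map_coordinates(
                rot[:, j, :], coords, order=1, mode="constant", cval=0.0
            )
            out[k, j] = samp.sum(axis=0) * path_scale
    return out


def _to_sinograms(
    line_mu: np.ndarray, line_f: np.ndarray, geom: AcquisitionGeometry
) -> tuple[Sinogram, Sinogram]:
    transmission = geom.i0 * np.exp(-line_mu)
    return (
        Sinogram(transmission, geometry=geom, channel="transmission"),
        Sinogram(line_f, geometry=geom, channel="fluorescence"),
    )


def forward_project(phantom, geom: AcquisitionGeometry) -> tuple[Sinogram, Sinogram]:
    """Parallel-beam acquisition of a phantom pair.

    Returns ``(transmission, fluorescence)`` sinograms: per angle and row,
    ``I(x) = i0 exp(-sum mu dl)`` along the beam, and the fluorescence line
    integral ``sum f dl`` along the same path (no self-absorption; the
    cleared-sample assumption).
    """
    if geom.fan is not None and geom.fan.shear_rate != 0.0:
        raise ValidationError("forward_project is parallel-beam; use fan_project")
    line_mu = project_volume(phantom.absorption, geom)
    line_f = project_volume(phantom.fluorescence, geom)
    return _to_sinograms(line_mu, line_f, geom)


def fan_project(phantom, geom: AcquisitionGeometry) -> tuple[Sinogram, Sinogram]:
    """Acquisition with an f-theta-style fan in the xz-plane.

    The beam at detector column x propagates at in-plane angle
    ``beta(x) = shear_rate * (x - center_x)``; equivalently each sinogram
    column is the parallel projection at effective angle ``phi + beta(x)``.
    With ``shear_rate = 0`` this reduces exactly to :func:`forward_project`.
    """
    if geom.fan is None:
        raise ValidationError("fan_project requires fan geometry parameters")
    if geom.fan.shear_rate == 0.0:
        return forward_project(phantom, _strip_fan(geom))
    _check_compat(phantom.absorption, geom)
    line_mu = _fan_line_integrals(phantom.absorption, geom)
    line_f = _fan_line_integrals(phantom.fluorescence, geom)
    return _to_sinograms(line_mu, line_f, geom)


def _strip_fan(geom: AcquisitionGeometry) -> AcquisitionGeometry:
    return AcquisitionGeometry(
        n_projections=geom.n_projections,
        detector_x=geom.detector_x,
        detector_y=geom.detector_y,
        pixel_um=geom.pixel_um,
        i0=geom.i0,
        angles_deg=geom.angles_deg.copy(),
        fan=None,
    )
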