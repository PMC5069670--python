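"""Readers and writers for the formats the pipeline touches.

Volumes and sinograms travel as multipage grayscale TIFF stacks with a YAML
sidecar (``<name>.yaml``) carrying the physical metadata - voxel spacing,
channel role, angle lists, fan parameters.  The sidecar is authoritative:
TIFF resolution tags cannot hold micrometre-precision spacing or per-angle
lists cleanly, so they are not relied upon.  Volumes can additionally be
written as MRC/CCP4 mode-2 float maps (via gemmi), the interchange format of
tomographic reconstruction tooling; the MRC cell dimensions encode
``shape * spacing`` with the header axis order matching the array axes
(z first).

Landmarks, polylines and tile indices are CSV with a header row; all
coordinates are 0-based voxel units.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    AcquisitionGeometry,
    DataError,
    FanGeometry,
    Sinogram,
    ValidationError,
    Volume3D,
)
from .reslice import Landmarks, PolylinePath
from .stitch import TileRecord, TileSet

__all__ = [
    "write_volume",
    "read_volume",
    "write_volume_mrc",
    "read_volume_mrc",
    "write_sinogram",
    "read_sinogram",
    "read_landmarks",
    "read_polyline",
    "read_tile_index",
    "write_tile_index",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml") if path.suffix != ".yaml" else path


def write_volume(path: str | os.PathLike, v: Volume3D) -> None:
    """Write a volume as multipage TIFF (one page per z) + YAML sidecar."""
    path = Path(path)
    data = np.asarray(v.data)
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric='minisblack')
    meta = {
        "kind": "volume",
        "spacing_um": [float(s) for s in v.spacing],
        "channel": v.channel,
        "shape": [int(n) for n in data.shape],
        "dtype": str(data.dtype),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def _read_tiff_gray(path: Path) -> np.ndarray:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise DataError(
                f"{path}: RGB/multisample TIFF not supported "
                f"(samplesperpixel={page.samplesperpixel}); need grayscale"
            )
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise DataError(f"{path}: expected a 2D/3D grayscale stack, got shape {data.shape}")
    return data


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a multipage TIFF volume; spacing/channel come from the sidecar."""
    path = Path(path)
    data = _read_tiff_gray(path)
    side = _sidecar(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text())
        spacing = tuple(meta.get("spacing_um", (1.0, 1.0, 1.0)))
        channel = meta.get("channel", "reconstructed")
    else:
        spacing, channel = (1.0, 1.0, 1.0), "reconstructed"
    return Volume3D(data, spacing=spacing, channel=channel)


def write_volume_mrc(path: str | os.PathLike, v: Volume3D) -> None:
    """Write a volume as an MRC/CCP4 mode-2 float map.

    Cell dimensions are ``shape * spacing`` (Angstrom-free, plain um
    numbers), with header axis order equal to the array axis order (z, y, x).
    """
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(v.data, dtype=np.float32))
    nz, ny, nx = v.shape
    m.grid.unit_cell = gemmi.UnitCell(
        nz * v.spacing[0], ny * v.spacing[1], nx * v.spacing[2], 90.0, 90.0, 90.0
    )
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_volume_mrc(path: str | os.PathLike, channel: str = "reconstructed") -> Volume3D:
    """Read an MRC map written by :func:`write_volume_mrc`."""
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    spacing = tuple(
        c / n if n else 1.0 for c, n in zip((cell.a, cell.b, cell.c), data.shape)
    )
    return Volume3D(data, spacing=spacing, channel=channel)


def write_sinogram(path: str | os.PathLike, s: Sinogram) -> None:
    """Write a sinogram as multipage TIFF (one page per angle) + sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(s.data, dtype=np.float32), photometric='minisblack')
    g = s.geometry
    meta = {
        "kind": "sinogram",
        "channel": s.channel,
        "n_projections": int(g.n_projections),
        "detector_x": int(g.detector_x),
        "detector_y": int(g.detector_y),
        "pixel_um": float(g.pixel_um),
        "i0": float(g.i0),
        "angles_deg": [float(a) for a in g.angles_deg],
    }
    if g.fan is not None:
        meta["fan"] = {
            "shear_rate": float(g.fan.shear_rate),
            "center_x": float(g.fan.center_x),
        }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def read_sinogram(path: str | os.PathLike) -> Sinogram:
    """Read a sinogram; the YAML sidecar (angles, channel, fan) is mandatory."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise DataError(f"sinogram sidecar {side} is missing; cannot interpret {path}")
    meta = yaml.safe_load(side.read_text())
    data = _read_tiff_gray(path)
    angles = meta.get("angles_deg")
    if angles is None or len(angles) != data.shape[0]:
        raise DataError(
            f"sidecar angle count ({None if angles is None else len(angles)}) "
            f"does not match {data.shape[0]} projection pages"
        )
    fan = None
    if meta.get("fan") is not None:
        fan = FanGeometry(
            shear_rate=float(meta["fan"]["shear_rate"]),
            center_x=float(meta["fan"]["center_x"]),
        )
    geom = AcquisitionGeometry(
        n_projections=data.shape[0],
        detector_x=data.shape[2],
        detector_y=data.shape[1],
        pixel_um=float(meta.get("pixel_um", 1.0)),
        i0=float(meta.get("i0", 1.0)),
        angles_deg=np.asarray(angles, dtype=float),
        fan=fan,
    )
    return Sinogram(data, geometry=geom, channel=meta.get("channel", "line_integral"))


def _read_csv(path, required_cols) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as e:  # noqa: BLE001 - report as a data error with the path
        raise DataError(f"cannot parse {path} as CSV: {e}") from e
    missing = set(required_cols) - set(df.columns)
    if missing:
        raise DataError(
            f"{path}: missing column(s) {sorted(missing)}; found {list(df.columns)}"
        )
    for c in required_cols:
        if not np.issubdtype(df[c].dtype, np.number):
            raise DataError(f"{path}: column {c!r} contains non-numeric cells")
    return df


def read_landmarks(path: str | os.PathLike) -> Landmarks:
    """Read three landmark points from CSV (columns x,y,z; 0-based voxels)."""
    df = _read_csv(path, ("x", "y", "z"))
    if len(df) != 3:
        raise DataError(f"{path}: landmarks need exactly 3 rows, found {len(df)}")
    pts = [tuple(map(float, row)) for row in df[["x", "y", "z"]].itertuples(index=False)]
    return Landmarks(p1=pts[0], p2=pts[1], p3=pts[2])


def read_polyline(path: str | os.PathLike) -> PolylinePath:
    """Read a curved-reslice cutting line from CSV (columns x,y)."""
    df = _read_csv(path, ("x", "y"))
    verts = tuple(
        (float(r.x), float(r.y)) for r in df.itertuples(index=False)
    )
    return PolylinePath(vertices=verts)


def read_tile_index(path: str | os.PathLike, base_dir: str | os.PathLike | None = None) -> TileSet:
    """Load a tile set from a CSV index (columns file,row,col[,z])."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # noqa: BLE001
        raise DataError(f"cannot parse {path} as CSV: {e}") from e
    for c in ("file", "row", "col"):
        if c not in df.columns:
            raise DataError(f"{path}: tile index must have columns file,row,col")
    base = Path(base_dir) if base_dir is not None else path.parent
    tiles = []
    for r in df.itertuples(index=False):
        img = _read_tiff_gray(base / str(r.file))
        if img.shape[0] == 1:
            img = img[0]
        tiles.append(TileRecord(image=np.asarray(img, float), row=int(r.row), col=int(r.col)))
    shape = tiles[0].image.shape
    z = int(df["z"].iloc[0]) if "z" in df.columns else None
    return TileSet(tiles=tiles, tile_px=shape, z_index=z)


def write_tile_index(
    out_dir: str | os.PathLike, ts: TileSet, prefix: str = "tile"
) -> Path:
    """Write a tile set as TIFFs plus a CSV index; returns the index path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in ts.tiles:
        name = f"{prefix}_r{t.row:03d}_c{t.col:03d}.tif"
        tifffile.imwrite(out / name, np.asarray(t.image, dtype=np.float32), photometric='minisblack')
        rows.append({"file": name, "row": t.row, "col": t.col})
    idx = out / f"{prefix}_index.csv"
    pd.DataFrame(rows).to_csv(idx, index=False)
    return idx
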