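"""Categorical raster container and plain-format I/O.

A :class:`CategoricalRaster` is a single-band integer grid holding land-use
category codes for one epoch.  Coordinates are abstract length units: the
origin is the lower-left corner of the grid and ``resolution`` is the edge
length of one (square) pixel.  Rows of ``values`` run top-to-bottom
(row 0 = northernmost), the usual raster convention.

Two on-disk formats are supported: ESRI ASCII grid (``.asc``, plain text)
and single-band TIFF (``.tif``/``.tiff``) via :mod:`tifffile`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_NODATA = 255


@dataclass
class CategoricalRaster:
    """Integer category grid for one epoch.

    Parameters
    ----------
    values
        2-D integer array of category codes (row 0 is the top row).
    resolution
        Pixel edge length in abstract length units.
    origin
        ``(x, y)`` of the lower-left corner of the grid.
    nodata
        Code marking masked / missing pixels.
    """

    values: np.ndarray
    resolution: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: int = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.values.size == 0:
            raise ValueError("raster dimensions must be positive")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("raster values must be integers")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata pixels."""
        return self.values != self.nodata

    def categories(self) -> np.ndarray:
        """Sorted category codes present, excluding nodata."""
        cats = np.unique(self.values)
        return cats[cats != self.nodata]

    def copy(self) -> "CategoricalRaster":
        return CategoricalRaster(
            self.values.copy(), self.resolution, tuple(self.origin), self.nodata
        )

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every pixel centre, same shape as values."""
        nrow, ncol = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.resolution
        ys = y0 + (nrow - np.arange(nrow) - 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def aligned_with(self, other: "CategoricalRaster", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.resolution - other.resolution) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: CategoricalRaster, path: str | Path) -> Path:
    """Write an ESRI ASCII grid (text) file."""
    path = Path(path)
    nrow, ncol = raster.shape
    header = (
        f"ncols {ncol}\n"
        f"nrows {nrow}\n"
        f"xllcorner {raster.origin[0]:.10g}\n"
        f"yllcorner {raster.origin[1]:.10g}\n"
        f"cellsize {raster.resolution:.10g}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    try:
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, raster.values, fmt="%d")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing raster to {path}: {exc}") from exc
    return path


def read_ascii_grid(path: str | Path) -> CategoricalRaster:
    """Read an ESRI ASCII grid (text) file."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, dtype=np.int64)
    values = np.atleast_2d(values)
    nodata = int(header.get("nodata_value", DEFAULT_NODATA))
    return CategoricalRaster(
        values=values,
        resolution=header.get("cellsize", 1.0),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=nodata,
    )


def write_tiff(raster: CategoricalRaster, path: str | Path) -> Path:
    """Write a single-band integer TIFF, geo-metadata in a JSON sidecar."""
    import tifffile

    path = Path(path)
    try:
        tifffile.imwrite(path, raster.values.astype(np.uint8))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "resolution": raster.resolution,
            "origin": list(raster.origin),
            "nodata": raster.nodata,
        }))
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed writing raster to {path}: {exc}") from exc
    return path


def read_tiff(path: str | Path) -> CategoricalRaster:
    import tifffile

    path = Path(path)
    values = np.asarray(tifffile.imread(path)).astype(np.int64)
    meta = {"resolution": 1.0, "origin": [0.0, 0.0], "nodata": DEFAULT_NODATA}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return CategoricalRaster(
        values=values,
        resolution=float(meta["resolution"]),
        origin=tuple(meta["origin"]),
        nodata=int(meta["nodata"]),
    )


def write_raster(raster: CategoricalRaster, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return write_tiff(raster, path)
    return write_ascii_grid(raster, path)


def read_raster(path: str | Path) -> CategoricalRaster:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return read_tiff(path)
    return read_ascii_grid(path)
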