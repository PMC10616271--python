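"""Land-use change metrics between two harmonized categorical rasters.

The analysis quantifies change at the level of coarse grid squares (10 km
squares in the British application): per-category cover fractions per epoch,
their per-square fractional change, the overall *land conversion* L (share
of fine pixels whose harmonized category differs between epochs), pixel-fate
transition matrices for a focal category, and per-square temperature trends
(OLS slope in degC/decade).

Squares are indexed ``(col, row)`` from the lower-left corner of the raster,
with half-open extents; square ids are the strings ``"{col}_{row}"``.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rasters import CategoricalRaster

__all__ = [
    "harmonize",
    "resample_nearest",
    "apply_common_mask",
    "category_fractions",
    "fractional_change",
    "land_conversion",
    "transition_matrix",
    "specialist_change",
    "temperature_trend",
    "temperature_trend_table",
    "pixel_agreement",
    "rmsd_per_square",
    "square_id",
]

#: Harmonized broad land-use categories used throughout the pipeline.
HARMONIZED_CATEGORIES: dict[int, str] = {
    1: "urban",
    2: "grassland",       # semi-natural grassland incl. heath, meadow, pasture
    3: "arable",
    4: "woodland",
    5: "water",
    6: "improved_grassland",
}


def square_id(col: int, row: int) -> str:
    return f"{col}_{row}"


# ---------------------------------------------------------------------------
# Raster operations
# ---------------------------------------------------------------------------

def harmonize(raster: CategoricalRaster,
              category_map: Mapping[int, int]) -> CategoricalRaster:
    """Map native class codes onto harmonized categories.

    Every non-nodata code present in the raster must appear in
    ``category_map``; unmapped codes raise with the offending codes listed.
    Codes may be mapped to the raster's nodata value to drop them (e.g.
    littoral classes).
    """
    present = set(raster.categories().tolist())
    unmapped = sorted(present - set(category_map))
    if unmapped:
        raise ValueError(f"unmapped native codes: {unmapped}")
    out = raster.values.copy()
    for native, target in category_map.items():
        out[raster.values == native] = target
    out[~raster.valid] = raster.nodata
    return CategoricalRaster(out, raster.resolution, tuple(raster.origin),
                             raster.nodata)


def resample_nearest(raster: CategoricalRaster,
                     target_resolution: float,
                     tol: float = 1e-6) -> CategoricalRaster:
    """Nearest-neighbour resampling to ``target_resolution`` over the same extent.

    The target resolution must divide (or be divided by) the source
    resolution within ``tol`` so that the extent is preserved exactly.
    """
    if target_resolution <= 0:
        raise ValueError("target resolution must be positive")
    ratio = raster.resolution / target_resolution
    if abs(ratio - round(ratio)) > tol and abs(1 / ratio - round(1 / ratio)) > tol:
        raise ValueError(
            f"target resolution {target_resolution} incompatible with source "
            f"resolution {raster.resolution}")
    nrow, ncol = raster.shape
    width = ncol * raster.resolution
    height = nrow * raster.resolution
    new_ncol = int(round(width / target_resolution))
    new_nrow = int(round(height / target_resolution))
    # nearest source pixel for each target pixel centre
    xs = (np.arange(new_ncol) + 0.5) * target_resolution
    ys_from_top = (np.arange(new_nrow) + 0.5) * target_resolution
    src_col = np.clip((xs / raster.resolution).astype(int), 0, ncol - 1)
    src_row = np.clip((ys_from_top / raster.resolution).astype(int), 0, nrow - 1)
    out = raster.values[np.ix_(src_row, src_col)]
    return CategoricalRaster(out, target_resolution, tuple(raster.origin),
                             raster.nodata)


def apply_common_mask(a: CategoricalRaster, b: CategoricalRaster,
                      mask_geometry=None,
                      buffer_width: float = 75.0,
                      ) -> tuple[CategoricalRaster, CategoricalRaster]:
    """Mask both rasters within ``buffer_width`` of a geometry and mutually.

    Pixels whose centre lies within ``buffer_width`` length units of
    ``mask_geometry`` (a shapely geometry, e.g. a road network) are set to
    nodata in *both* rasters.  The two rasters are then masked against one
    another so they share an identical nodata footprint.
    """
    if not a.aligned_with(b):
        raise ValueError("rasters are not co-registered (shape/origin/resolution)")
    if buffer_width < 0:
        raise ValueError("buffer_width must be non-negative")
    va, vb = a.values.copy(), b.values.copy()
    if mask_geometry is not None and not getattr(mask_geometry, "is_empty", False):
        import shapely

        xx, yy = a.pixel_centres()
        pts = shapely.points(xx.ravel(), yy.ravel())
        hit = shapely.dwithin(pts, mask_geometry, buffer_width)
        hit = hit.reshape(a.shape)
        va[hit] = a.nodata
        vb[hit] = b.nodata
    # mutual extent alignment
    invalid = (va == a.nodata) | (vb == b.nodata)
    va[invalid] = a.nodata
    vb[invalid] = b.nodata
    return (CategoricalRaster(va, a.resolution, tuple(a.origin), a.nodata),
            CategoricalRaster(vb, b.resolution, tuple(b.origin), b.nodata))


# ---------------------------------------------------------------------------
# Square-level summaries
# ---------------------------------------------------------------------------

def _square_blocks(raster: CategoricalRaster, square_size: float):
    """Yield (square_id, values-block) for each coarse square."""
    px = square_size / raster.resolution
    if abs(px - round(px)) > 1e-9 or round(px) < 1:
        raise ValueError("square_size must be a positive multiple of pixel size")
    px = int(round(px))
    nrow, ncol = raster.shape
    ny, nx = nrow // px, ncol // px
    if ny * px != nrow or nx * px != ncol:
        raise ValueError("raster dimensions are not a whole number of squares")
    for row in range(ny):           # row 0 at the bottom (lower-left origin)
        top = nrow - (row + 1) * px
        for col in range(nx):
            block = raster.values[top:top + px, col * px:(col + 1) * px]
            yield square_id(col, row), block


def category_fractions(raster: CategoricalRaster, square_size: float,
                       categories: Sequence[int] | None = None,
                       min_valid_fraction: float = 0.5) -> pd.DataFrame:
    """Per-square cover fraction of each category over non-nodata pixels.

    Squares whose valid-pixel share falls below ``min_valid_fraction`` are
    omitted (partially masked edge squares).  Rows sum to 1 over the valid
    pixels of each retained square.
    """
    if categories is None:
        categories = raster.categories().tolist()
    rows, ids = [], []
    for sid, block in _square_blocks(raster, square_size):
        valid = block[block != raster.nodata]
        if valid.size < min_valid_fraction * block.size or valid.size == 0:
            continue
        counts = np.array([(valid == c).sum() for c in categories], dtype=float)
        rows.append(counts / valid.size)
        ids.append(sid)
    return pd.DataFrame(rows, index=pd.Index(ids, name="square_id"),
                        columns=list(categories))


def fractional_change(frac_hist: pd.DataFrame,
                      frac_mod: pd.DataFrame) -> pd.DataFrame:
    """Modern minus historical cover fraction, per square and category.

    Squares present in only one epoch are excluded.  Per-square changes sum
    to zero because each epoch's fractions sum to one.
    """
    common = frac_hist.index.intersection(frac_mod.index)
    cats = frac_hist.columns.union(frac_mod.columns)
    h = frac_hist.reindex(index=common, columns=cats, fill_value=0.0)
    m = frac_mod.reindex(index=common, columns=cats, fill_value=0.0)
    return m - h


def land_conversion(hist: CategoricalRaster, mod: CategoricalRaster,
                    square_size: float,
                    min_valid_fraction: float = 0.5) -> pd.Series:
    """Fraction of valid fine pixels per square whose category changed.

    ``L in [0, 1]``; squares with no valid pixels (or below the valid-share
    threshold) are absent from the result.
    """
    if not hist.aligned_with(mod):
        raise ValueError("rasters are not co-registered")
    vals = {}
    mod_blocks = dict(_square_blocks(mod, square_size))
    for sid, hblock in _square_blocks(hist, square_size):
        mblock = mod_blocks[sid]
        valid = (hblock != hist.nodata) & (mblock != mod.nodata)
        n = int(valid.sum())
        if n < min_valid_fraction * hblock.size or n == 0:
            continue
        vals[sid] = float((hblock[valid] != mblock[valid]).sum()) / n
    return pd.Series(vals, name="land_conversion").rename_axis("square_id")


def transition_matrix(hist: CategoricalRaster, mod: CategoricalRaster,
                      from_category: int) -> pd.Series:
    """Fate of pixels historically in ``from_category``.

    Returns the proportion of those pixels found in each modern category
    (self-retention included), summing to 1.  Empty if the category is
    absent historically.
    """
    if not hist.aligned_with(mod):
        raise ValueError("rasters are not co-registered")
    valid = hist.valid & mod.valid
    sel = valid & (hist.values == from_category)
    dest = mod.values[sel]
    if dest.size == 0:
        return pd.Series(dtype=float, name=f"fate_of_{from_category}")
    cats, counts = np.unique(dest, return_counts=True)
    return pd.Series(counts / dest.size, index=cats,
                     name=f"fate_of_{from_category}")


def specialist_change(square_table: pd.DataFrame, habitat_category: int) -> pd.Series:
    """Per-square fractional change of one habitat category.

    Drop-in replacement for the generic land-conversion covariate when
    modelling habitat specialists: positive values mean the specialist's
    habitat was retained or gained.
    """
    col = f"change_{habitat_category}"
    if col not in square_table.columns:
        raise KeyError(f"unknown habitat category {habitat_category!r}: "
                       f"no column {col}")
    return square_table[col].rename("habitat_change")


# ---------------------------------------------------------------------------
# Climate trend
# ---------------------------------------------------------------------------

def temperature_trend(years: Iterable[float], temps: Iterable[float],
                      window: tuple[int, int] | None = None) -> float | None:
    """OLS slope of temperature on year, scaled to degC per decade.

    ``window=(start, end)`` restricts to ``start <= year <= end``.  Returns
    ``None`` when fewer than three annual values fall inside the window.
    Multiple values per year (e.g. monthly series) are averaged to annual
    means before fitting.
    """
    df = pd.DataFrame({"year": list(years), "temp": list(temps)}).dropna()
    if window is not None:
        df = df[(df.year >= window[0]) & (df.year <= window[1])]
    annual = df.groupby("year")["temp"].mean()
    if len(annual) < 3:
        return None
    x = annual.index.to_numpy(dtype=float)
    y = annual.to_numpy(dtype=float)
    slope = np.polyfit(x, y, 1)[0]
    return float(slope * 10.0)


def temperature_trend_table(climate: pd.DataFrame,
                            window: tuple[int, int] | None = None) -> pd.Series:
    """Per-square decadal trend from a long table (square_id, year, temp)."""
    out = {}
    for sid, grp in climate.groupby("square_id"):
        tr = temperature_trend(grp["year"], grp["temp"], window)
        if tr is not None:
            out[sid] = tr
    return pd.Series(out, name="temperature_trend").rename_axis("square_id")


# ---------------------------------------------------------------------------
# Digitisation agreement utilities
# ---------------------------------------------------------------------------

def pixel_agreement(a: CategoricalRaster, b: CategoricalRaster) -> float:
    """Share of mutually valid pixels assigned the same category."""
    if not a.aligned_with(b):
        raise ValueError("rasters are not co-registered")
    valid = a.valid & b.valid
    if not valid.any():
        raise ValueError("no overlapping valid pixels")
    return float((a.values[valid] == b.values[valid]).mean())


def rmsd_per_square(frac_a: pd.DataFrame, frac_b: pd.DataFrame) -> pd.Series:
    """Root-mean-square deviation of category fractions per square."""
    common = frac_a.index.intersection(frac_b.index)
    cats = frac_a.columns.union(frac_b.columns)
    a = frac_a.reindex(index=common, columns=cats, fill_value=0.0)
    b = frac_b.reindex(index=common, columns=cats, fill_value=0.0)
    return np.sqrt(((a - b) ** 2).mean(axis=1)).rename("rmsd")
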