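"""Synthetic landscapes with known persistence structure.

Generates a complete synthetic study system so every downstream stage can be
exercised by parameter recovery: a two-epoch categorical land-use raster
pair (coarse squares subdivided into fine pixels), a spatially smooth
warming surface with a tunable correlation to land conversion, recorder
effort, a microclimate covariate, and two-period occurrence records of
species whose square-level persistence follows a known logit-linear model

    logit P(persist) = b0 + bT zT + bL zL + bI zL zT + bE zE + bM zM

in the *standardized* (z-scored across squares) covariates, so coefficient
magnitudes are comparable across covariates.  Detection is imperfect:
``P(detect | occupied) = 1 - (1 - q_j)^{E_it}`` with species detectability
``q_j`` and square-period effort ``E_it``.

Spatial structure comes from smoothed Gaussian latent fields; the
conversion/warming correlation is induced by a shared latent field whose
mixing weight is solved numerically against the realized fields, giving
direct control of the collinearity regime.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit

from .landuse import square_id
from .rasters import CategoricalRaster, write_raster

__all__ = ["SpeciesGroupSpec", "SyntheticConfig", "SyntheticWorld",
           "generate_world", "generate_records", "write_fixture",
           "read_fixture"]

#: Historical cover fractions mirroring mid-century Britain:
#: urban 4%, semi-natural grassland 65%, arable 22%, woodland 6%,
#: water 1%, improved grassland 2% (trace).
DEFAULT_HISTORICAL = (0.04, 0.65, 0.22, 0.06, 0.01, 0.02)

#: Fate of converted pixels by source category (rows; zero self-retention —
#: retention is governed by the per-square conversion intensity).  Converted
#: semi-natural grassland goes mostly to improved grassland and arable.
DEFAULT_KERNEL = np.array([
    #  urb   grass  arable wood   water  improved
    [0.00, 0.05, 0.25, 0.10, 0.05, 0.55],   # from urban
    [0.08, 0.00, 0.25, 0.10, 0.02, 0.55],   # from grassland
    [0.15, 0.05, 0.00, 0.10, 0.05, 0.65],   # from arable
    [0.10, 0.20, 0.30, 0.00, 0.05, 0.35],   # from woodland
    [0.10, 0.20, 0.30, 0.30, 0.00, 0.10],   # from water
    [0.10, 0.10, 0.60, 0.15, 0.05, 0.00],   # from improved grassland
])


@dataclass(frozen=True)
class SpeciesGroupSpec:
    """A group of species sharing coefficient distributions.

    Each coefficient is drawn Normal(mean, sd) per species, acting on the
    standardized covariate.  ``b_int`` nonzero makes the group's true model
    interactive.
    """

    count: int
    b0: tuple[float, float] = (1.5, 0.5)
    b_t: tuple[float, float] = (0.0, 0.0)
    b_l: tuple[float, float] = (0.0, 0.0)
    b_int: tuple[float, float] = (0.0, 0.0)
    b_e: tuple[float, float] = (0.3, 0.1)
    b_m: tuple[float, float] = (0.2, 0.1)
    col_prob: float | None = None      # overrides config.colonisation_prob
    psi_range: tuple[float, float] | None = None   # overrides occupancy_range


def _default_species_spec() -> dict[str, list[SpeciesGroupSpec]]:
    """Four taxa mixing null, single-driver, additive and interactive species."""
    def groups(n):
        return [
            SpeciesGroupSpec(n, b_t=(0.0, 0.0)),                      # controls only
            SpeciesGroupSpec(n, b_t=(1.2, 0.6)),                      # warming driven
            SpeciesGroupSpec(n, b_l=(-1.2, 0.6)),                     # conversion driven
            SpeciesGroupSpec(n, b_t=(1.0, 0.5), b_l=(-1.0, 0.5)),     # additive
            SpeciesGroupSpec(n, b_t=(1.0, 0.5), b_l=(-1.0, 0.5),
                             b_int=(1.0, 0.4)),                       # interactive
        ]
    return {"plants": groups(8), "birds": groups(4),
            "butterflies": groups(3), "macromoths": groups(5)}


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_squares_x: int = 16
    n_squares_y: int = 16
    fine_per_square: int = 10
    n_categories: int = 6
    historical_proportions: tuple[float, ...] = DEFAULT_HISTORICAL
    conversion_beta_params: tuple[float, float] = (2.0, 3.0)
    climate_mean_trend: float = 0.20      # degC/decade
    climate_sd: float = 0.08
    rho_LT: float = 0.50                  # target corr(conversion, warming)
    smoothing_bandwidth: float = 2.0      # coarse-field Gaussian sigma, squares
    fine_bandwidth: float = 4.0           # fine latent-field sigma, pixels
    species_spec: dict[str, list[SpeciesGroupSpec]] = field(
        default_factory=_default_species_spec)
    effort_spec: tuple[float, float] = (4.0, 0.25)   # gamma shape, scale
    detectability: tuple[float, float] = (0.4, 0.9)  # uniform q_j range
    occupancy_range: tuple[float, float] = (0.35, 0.85)
    colonisation_prob: float = 0.05
    period_years: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {1: (1930, 1960), 2: (2000, 2015)})
    square_size: float = 10.0             # abstract 10 km units

    def __post_init__(self) -> None:
        props = np.asarray(self.historical_proportions, float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("historical_proportions must sum to 1")
        if len(props) != self.n_categories:
            raise ValueError("historical_proportions length != n_categories")
        if min(self.n_squares_x, self.n_squares_y, self.fine_per_square) < 1:
            raise ValueError("all grid counts must be positive")
        if not abs(self.rho_LT) < 1:
            raise ValueError("|rho_LT| must be < 1")
        a, b = self.conversion_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("conversion_beta_params must be positive")


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    raster_hist: CategoricalRaster
    raster_mod: CategoricalRaster
    square_table: pd.DataFrame       # covariates per square, raw and z-scored
    species: pd.DataFrame            # truth: taxon, coefficients, psi, q
    occupancy: dict[int, pd.DataFrame]   # period -> squares x species (truth)
    persist_prob: pd.DataFrame       # squares x species true P(persist)
    records: pd.DataFrame            # species_id, taxon, square_id, period, year
    effort: pd.DataFrame             # squares x periods true effort


# ---------------------------------------------------------------------------
# Field helpers
# ---------------------------------------------------------------------------

def _smooth_standard_field(rng: np.random.Generator, shape: tuple[int, int],
                           sigma: float) -> np.ndarray:
    z = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (z - z.mean()) / z.std()


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _solve_mixing_weight(c: np.ndarray, z1: np.ndarray, z2: np.ndarray,
                         rho: float) -> float:
    """Mixing weight w with corr(c, w z1 + sqrt(1-w^2) z2) = rho, on the
    realized fields; explicit failure when the target is unattainable."""
    def r(w: float) -> float:
        mix = w * z1 + np.sqrt(max(0.0, 1 - w * w)) * z2
        return float(np.corrcoef(c, mix)[0, 1])

    lo, hi = r(-1.0), r(1.0)
    if not lo <= rho <= hi:
        raise ValueError(
            f"rho_LT={rho} unattainable: achievable range [{lo:.3f}, {hi:.3f}] "
            "under the configured smoothness settings")
    return brentq(lambda w: r(w) - rho, -1.0, 1.0, xtol=1e-12)


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def generate_world(config: SyntheticConfig | None = None) -> SyntheticWorld:
    """Build a complete deterministic synthetic world from a config."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    nx, ny, f = cfg.n_squares_x, cfg.n_squares_y, cfg.fine_per_square
    nrow, ncol = ny * f, nx * f
    resolution = cfg.square_size / f

    # Historical raster: smooth latent field -> rank-uniform -> category bins
    latent = _smooth_standard_field(rng, (nrow, ncol), cfg.fine_bandwidth)
    ranks = stats.rankdata(latent.ravel(), method="ordinal")
    u = (ranks - 0.5) / ranks.size
    edges = np.cumsum(cfg.historical_proportions)
    hist_vals = (np.searchsorted(edges, u, side="left") + 1
                 ).reshape(nrow, ncol).astype(np.int64)
    raster_hist = CategoricalRaster(hist_vals, resolution=resolution)

    # Coarse latent fields: conversion intensity and warming surface
    z1 = _smooth_standard_field(rng, (ny, nx), cfg.smoothing_bandwidth)
    z2 = _smooth_standard_field(rng, (ny, nx), cfg.smoothing_bandwidth)
    a, b = cfg.conversion_beta_params
    conv = stats.beta.ppf(stats.norm.cdf(z1.ravel()), a, b)
    w = _solve_mixing_weight(conv, z1.ravel(), z2.ravel(), cfg.rho_LT)
    mix = w * z1.ravel() + np.sqrt(max(0.0, 1 - w * w)) * z2.ravel()
    dT = cfg.climate_mean_trend + cfg.climate_sd * mix
    micro = _smooth_standard_field(rng, (ny, nx), cfg.smoothing_bandwidth).ravel()

    # Modern raster: convert a Beta-drawn fraction of pixels per square
    kernel = DEFAULT_KERNEL[:cfg.n_categories, :cfg.n_categories].copy()
    kernel /= kernel.sum(axis=1, keepdims=True)
    mod_vals = hist_vals.copy()
    sq_ids, sq_x, sq_y = [], [], []
    idx = 0
    conv_grid = conv.reshape(ny, nx)
    for row in range(ny):            # row 0 at the bottom
        top = nrow - (row + 1) * f
        for col in range(nx):
            block = mod_vals[top:top + f, col * f:(col + 1) * f]
            n_conv = int(round(conv_grid[row, col] * f * f))
            flat = rng.choice(f * f, size=n_conv, replace=False)
            for pix in flat:
                r_, c_ = divmod(pix, f)
                src = block[r_, c_] - 1
                block[r_, c_] = rng.choice(cfg.n_categories,
                                           p=kernel[src]) + 1
            sq_ids.append(square_id(col, row))
            sq_x.append((col + 0.5) * cfg.square_size)
            sq_y.append((row + 0.5) * cfg.square_size)
            idx += 1
    raster_mod = CategoricalRaster(mod_vals, resolution=resolution)

    # flatten coarse fields in (row-major over rows-from-bottom) square order
    def flat(field2d: np.ndarray) -> np.ndarray:
        return field2d.reshape(ny, nx).ravel()

    shape_g, scale_g = cfg.effort_spec
    effort = pd.DataFrame(
        {t: rng.gamma(shape_g, scale_g, size=ny * nx) for t in (1, 2)},
        index=pd.Index(sq_ids, name="square_id"))

    table = pd.DataFrame({
        "x": sq_x, "y": sq_y,
        "conversion_true": flat(conv_grid),
        "temperature_trend": flat(dT.reshape(ny, nx)),
        "microclimate": flat(micro.reshape(ny, nx)),
        "effort_1": effort[1].to_numpy(),
        "effort_2": effort[2].to_numpy(),
    }, index=pd.Index(sq_ids, name="square_id"))
    for raw, z in [("conversion_true", "z_L"), ("temperature_trend", "z_T"),
                   ("microclimate", "z_M"), ("effort_1", "z_E")]:
        table[z] = _zscore(table[raw].to_numpy())

    # Species truth and occupancy
    sp_rows = []
    for taxon, groups in cfg.species_spec.items():
        for gi, grp in enumerate(groups):
            for k in range(grp.count):
                coefs = {name: rng.normal(*getattr(grp, name))
                         for name in ("b0", "b_t", "b_l", "b_int", "b_e", "b_m")}
                sp_rows.append({
                    "species_id": f"{taxon[:2]}_{gi}_{k}", "taxon": taxon,
                    "group": gi, **coefs,
                    "psi": rng.uniform(*(grp.psi_range or cfg.occupancy_range)),
                    "q": rng.uniform(*cfg.detectability),
                    "col_prob": (cfg.colonisation_prob if grp.col_prob is None
                                 else grp.col_prob)})
    species = pd.DataFrame(sp_rows).set_index("species_id")

    zT, zL = table["z_T"].to_numpy(), table["z_L"].to_numpy()
    zE, zM = table["z_E"].to_numpy(), table["z_M"].to_numpy()
    occ1 = {}
    occ2 = {}
    pprob = {}
    for sp, row in species.iterrows():
        o1 = rng.random(len(table)) < row["psi"]
        eta = (row["b0"] + row["b_t"] * zT + row["b_l"] * zL
               + row["b_int"] * zL * zT + row["b_e"] * zE + row["b_m"] * zM)
        p = expit(eta)
        survive = rng.random(len(table)) < p
        colonise = rng.random(len(table)) < row["col_prob"]
        occ1[sp] = o1
        occ2[sp] = (o1 & survive) | (~o1 & colonise)
        pprob[sp] = p
    occupancy = {
        1: pd.DataFrame(occ1, index=table.index).astype(np.int8),
        2: pd.DataFrame(occ2, index=table.index).astype(np.int8)}
    persist_prob = pd.DataFrame(pprob, index=table.index)

    world = SyntheticWorld(cfg, raster_hist, raster_mod, table, species,
                           occupancy, persist_prob,
                           records=pd.DataFrame(), effort=effort)
    world.records = generate_records(world, effort, rng)
    return world


def generate_records(world: SyntheticWorld, effort: pd.DataFrame,
                     rng: np.random.Generator | int | None = None,
                     ) -> pd.DataFrame:
    """Effort-biased detection of the true occupancy pattern.

    ``P(detect | occupied) = 1 - (1 - q_j)^{E_it}``; zero effort in a
    square-period yields no records there; negative effort is rejected.
    """
    if (effort.to_numpy() < 0).any():
        raise ValueError("effort must be non-negative")
    rng = np.random.default_rng(
        rng if rng is not None else world.config.seed + 1)
    rows = []
    for t in sorted(world.occupancy):
        e = effort[t].reindex(world.square_table.index).to_numpy(float)
        year = int(np.mean(world.config.period_years[t]))
        occ = world.occupancy[t]
        for sp in occ.columns:
            q = world.species.loc[sp, "q"]
            p_det = (1.0 - (1.0 - q) ** e) * occ[sp].to_numpy()
            detected = rng.random(len(e)) < p_det
            taxon = world.species.loc[sp, "taxon"]
            for sq in occ.index[detected]:
                rows.append((sp, taxon, sq, t, year))
    return pd.DataFrame(rows, columns=["species_id", "taxon", "square_id",
                                       "period", "year"])


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(world: SyntheticWorld, directory: str | Path,
                  raster_format: str = "asc") -> Path:
    """Persist a world as plain files (rasters, CSVs, truth JSON).

    Emits ``hist.<fmt>``, ``mod.<fmt>``, ``records.csv``, ``squares.csv``,
    ``climate.csv`` (annual series consistent with each square's trend) and
    ``truth.json``; everything round-trips through the package readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_raster(world.raster_hist, directory / f"hist.{raster_format}")
    write_raster(world.raster_mod, directory / f"mod.{raster_format}")
    world.records.to_csv(directory / "records.csv", index=False)
    world.square_table.to_csv(directory / "squares.csv")
    world.effort.rename(columns=lambda t: f"effort_{t}").to_csv(
        directory / "effort.csv")

    # climate series: annual means consistent with each square's decadal trend
    y0 = world.config.period_years[1][0]
    y1 = world.config.period_years[2][1]
    years = np.arange(y0, y1 + 1)
    rng = np.random.default_rng(world.config.seed + 2)
    recs = []
    for sq, trend in world.square_table["temperature_trend"].items():
        base = 8.0 + rng.normal(0, 0.5)
        temps = base + trend / 10.0 * (years - y0) + rng.normal(0, 0.03,
                                                                len(years))
        recs.extend(zip([sq] * len(years), years, np.round(temps, 4)))
    pd.DataFrame(recs, columns=["square_id", "year", "temp"]).to_csv(
        directory / "climate.csv", index=False)

    truth = {
        "config": {k: v for k, v in dataclasses.asdict(world.config).items()
                   if k != "species_spec"},
        "species": {
            sp: {k: (float(v) if isinstance(v, (int, float, np.floating))
                     else v)
                 for k, v in row.items()}
            for sp, row in world.species.reset_index()
            .set_index("species_id").iterrows()},
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=1,
                                                     default=str))
    return directory


def read_fixture(directory: str | Path) -> dict:
    """Read a written fixture back into in-memory tables."""
    from .rasters import read_raster

    directory = Path(directory)
    raster_path = next(p for p in (directory / "hist.asc",
                                   directory / "hist.tif") if p.exists())
    mod_path = directory / ("mod" + raster_path.suffix)
    return {
        "raster_hist": read_raster(raster_path),
        "raster_mod": read_raster(mod_path),
        "records": pd.read_csv(directory / "records.csv"),
        "square_table": pd.read_csv(directory / "squares.csv",
                                    index_col="square_id"),
        "effort": pd.read_csv(directory / "effort.csv", index_col="square_id"
                              ).rename(columns=lambda c: int(c.split("_")[1])),
        "climate": pd.read_csv(directory / "climate.csv"),
        "truth": json.loads((directory / "truth.json").read_text()),
    }
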