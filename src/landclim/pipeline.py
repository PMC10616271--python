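"""End-to-end orchestration: synthetic world (or input files) to report.

Each stage reads only files persisted by earlier stages inside a run
directory, so any stage can be replayed in isolation and a rerun with the
same configuration is byte-identical for the deterministic stages.

Run directory layout::

    hist.asc / mod.asc       input rasters
    records.csv              occurrence records
    squares.csv              per-square covariates (x, y, microclimate, ...)
    climate.csv              long (square_id, year, temp) series
    landuse.csv              fractions, per-category change, land conversion
    climate_trend.csv        per-square, per-taxon temperature trend
    outcomes.csv             persistence/extirpation outcomes
    effort.csv               Frescalo effort covariate per taxon
    trends.csv               Frescalo time factors and decadal trends
    fits.csv                 per-species AICs, best model, coefficients, AMEs
    interaction.csv          paired-t results for interactive-best species
    report.json              final summary
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import frescalo as fr
from . import interaction as ia
from . import landuse as lu
from . import models as md
from . import records as rc
from . import reporting as rp
from .rasters import read_raster
from .synth import SyntheticConfig, generate_world, write_fixture

logger = logging.getLogger("landclim")

__all__ = ["RunConfig", "run_all"]

DEFAULT_PHI = dict(fr.DEFAULT_PHI)


@dataclass
class RunConfig:
    """One configuration drives the whole pipeline.

    ``synth`` generates inputs; alternatively ``input_dir`` must contain the
    raster/CSV inputs listed in the module docstring.  Defaults mirror the
    study constants: K = 100 Frescalo neighbours, taxon-specific Φ, 100
    bootstraps, an exclusive 100-square range filter and a 75-unit road
    buffer (the buffer only matters when a mask geometry is supplied).
    """

    seed: int = 0
    synth: dict | SyntheticConfig | None = None
    input_dir: str | None = None
    square_size: float = 10.0
    min_squares: int = 100
    alpha: float = 0.05
    n_boot: int = 100
    do_bootstrap: bool = False
    phi: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PHI))
    taxon_windows: dict[str, tuple[int, int]] = field(default_factory=dict)
    frescalo_neighbours: int = 100
    frescalo_candidates: int = 200
    buffer_width: float = 75.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def synth_config(self) -> SyntheticConfig | None:
        if self.synth is None:
            return None
        if isinstance(self.synth, SyntheticConfig):
            return self.synth
        kwargs = dict(self.synth)
        kwargs.setdefault("seed", self.seed)
        return SyntheticConfig(**kwargs)

    def validate_phi(self, taxa) -> None:
        missing = [t for t in taxa if t not in self.phi]
        if missing:
            raise ValueError(f"no Frescalo phi configured for taxa: {missing}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _centroids(square_ids: pd.Index, square_size: float) -> pd.DataFrame:
    cols = square_ids.str.split("_").str[0].astype(int)
    rows = square_ids.str.split("_").str[1].astype(int)
    return pd.DataFrame({"x": (cols + 0.5) * square_size,
                         "y": (rows + 0.5) * square_size}, index=square_ids)


def stage_prepare(config: RunConfig, run_dir: Path) -> None:
    """Materialise inputs: generate a synthetic fixture or link input files."""
    run_dir.mkdir(parents=True, exist_ok=True)
    scfg = config.synth_config()
    if scfg is not None:
        logger.info("generating synthetic world (seed=%d)", scfg.seed)
        write_fixture(generate_world(scfg), run_dir)
        return
    if config.input_dir is None:
        raise ValueError("config needs either a synth section or input_dir")
    src = Path(config.input_dir)
    needed = ["records.csv", "squares.csv", "climate.csv"]
    rasters = [p.name for p in src.glob("hist.*")] + \
              [p.name for p in src.glob("mod.*")]
    for name in needed + rasters:
        if not (src / name).exists():
            raise FileNotFoundError(src / name)
        data = (src / name).read_bytes()
        (run_dir / name).write_bytes(data)


def stage_landuse(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    """Cover fractions, per-category change, land conversion, grass fate."""
    hist = read_raster(next(run_dir.glob("hist.*")))
    mod = read_raster(next(p for p in run_dir.glob("mod.*")
                           if not p.name.endswith(".json")))
    hist, mod = lu.apply_common_mask(hist, mod, None, config.buffer_width)
    cats = sorted(set(hist.categories()) | set(mod.categories()))
    fh = lu.category_fractions(hist, config.square_size, cats)
    fm = lu.category_fractions(mod, config.square_size, cats)
    change = lu.fractional_change(fh, fm)
    conv = lu.land_conversion(hist, mod, config.square_size)
    out = pd.concat([fh.add_prefix("hist_"), fm.add_prefix("mod_"),
                     change.add_prefix("change_"), conv], axis=1).dropna()
    out.to_csv(run_dir / "landuse.csv")
    fate = lu.transition_matrix(hist, mod, from_category=2)
    fate.rename_axis("category").to_csv(run_dir / "grassland_fate.csv")
    logger.info("landuse: %d squares, mean L=%.3f", len(out),
                out["land_conversion"].mean())
    return out


def stage_climate(config: RunConfig, run_dir: Path,
                  taxa: list[str]) -> pd.DataFrame:
    """Per-square decadal temperature trend, per taxon window."""
    climate = pd.read_csv(run_dir / "climate.csv")
    out = {}
    for taxon in taxa:
        window = config.taxon_windows.get(taxon)
        out[f"trend_{taxon}"] = lu.temperature_trend_table(climate, window)
    df = pd.DataFrame(out)
    df.to_csv(run_dir / "climate_trend.csv")
    return df


def stage_outcomes(config: RunConfig, run_dir: Path):
    """Presence matrices -> outcome table with coverage and range filters."""
    recs = pd.read_csv(run_dir / "records.csv")
    species_taxon = recs.drop_duplicates("species_id").set_index(
        "species_id")["taxon"]
    p1, cov1 = rc.presence_matrix(recs, 1)
    p2, cov2 = rc.presence_matrix(recs, 2)
    outcomes, colonisations = rc.build_outcomes(p1, p2, cov2, species_taxon,
                                                coverage1=cov1)
    outcomes = rc.filter_range_size_presence(outcomes, p1, config.min_squares)
    outcomes.to_csv(run_dir / "outcomes.csv", index=False)
    colonisations.to_csv(run_dir / "colonisations.csv", index=False)
    logger.info("outcomes: %d rows, %d species", len(outcomes),
                outcomes["species_id"].nunique())
    return outcomes


def stage_frescalo(config: RunConfig, run_dir: Path) -> None:
    """Per-taxon effort covariate and distribution trends (plus Telfer)."""
    recs = pd.read_csv(run_dir / "records.csv")
    taxa = sorted(recs["taxon"].unique())
    config.validate_phi(taxa)
    squares = pd.read_csv(run_dir / "squares.csv", index_col="square_id")
    centroids = (squares[["x", "y"]] if {"x", "y"} <= set(squares.columns)
                 else _centroids(squares.index, config.square_size))
    fcfg = fr.FrescaloConfig(n_candidates=config.frescalo_candidates,
                             n_neighbours=config.frescalo_neighbours)
    period_years = {1: (1930, 1960), 2: (2000, 2015)}
    efforts, trends, telfer = [], [], []
    for taxon in taxa:
        sub = recs[recs["taxon"] == taxon]
        pres = {}
        for t in (1, 2):
            p, _ = rc.presence_matrix(sub, t) if (sub["period"] == t).any() \
                else (pd.DataFrame(index=centroids.index), None)
            pres[t] = p.reindex(index=centroids.index, fill_value=0)
        fit = fr.run_frescalo(pres, centroids, config.phi[taxon],
                              period_years, config=fcfg)
        efforts.append(fit.effort.rename(taxon))
        tdf = fit.time_factors.copy()
        tdf.columns = [f"tf_{t}" for t in tdf.columns]
        tdf["trend"] = fit.trend
        tdf["taxon"] = taxon
        trends.append(tdf.rename_axis("species_id"))
        n1, n2 = pres[1].sum(axis=0), pres[2].sum(axis=0)
        try:
            telfer.append(fr.telfer_index(n1, n2, len(centroids),
                                          len(centroids)).rename("telfer")
                          .rename_axis("species_id").reset_index()
                          .assign(taxon=taxon))
        except ValueError:
            pass
    pd.concat(efforts, axis=1).rename_axis("square_id").to_csv(
        run_dir / "effort.csv")
    pd.concat(trends).to_csv(run_dir / "trends.csv")
    if telfer:
        pd.concat(telfer).to_csv(run_dir / "telfer.csv", index=False)


def build_model_frame(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    """Per species x square modelling frame joining all covariates."""
    outcomes = pd.read_csv(run_dir / "outcomes.csv")
    landuse = pd.read_csv(run_dir / "landuse.csv", index_col="square_id")
    trend = pd.read_csv(run_dir / "climate_trend.csv", index_col="square_id")
    effort = pd.read_csv(run_dir / "effort.csv", index_col="square_id")
    squares = pd.read_csv(run_dir / "squares.csv", index_col="square_id")
    centroids = (squares[["x", "y"]] if {"x", "y"} <= set(squares.columns)
                 else _centroids(landuse.index, config.square_size))
    pcnm = md.pcnm_axes(centroids)

    df = outcomes.copy()
    df["land_conversion"] = df["square_id"].map(landuse["land_conversion"])
    df["temperature_trend"] = [
        trend.at[sq, f"trend_{tx}"] if f"trend_{tx}" in trend.columns
        else np.nan
        for sq, tx in zip(df["square_id"], df["taxon"])]
    df["effort"] = [effort.at[sq, tx] if tx in effort.columns else np.nan
                    for sq, tx in zip(df["square_id"], df["taxon"])]
    df["microclimate"] = df["square_id"].map(squares["microclimate"])
    df["pcnm1"] = df["square_id"].map(pcnm["pcnm1"])
    df["pcnm2"] = df["square_id"].map(pcnm["pcnm2"])
    return df.dropna(subset=["land_conversion", "temperature_trend", "effort",
                             "microclimate", "pcnm1", "pcnm2"])


AME_UNITS = {md.ENV_T: 0.1, md.ENV_L: 0.1}   # 0.1 degC/decade; 10 pp conversion


def stage_models(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    """Five formulations per species, AIC selection, AMEs, separation screen."""
    frame = build_model_frame(config, run_dir)
    rows, ame_rows = [], []
    predictors = [md.ENV_L, md.ENV_T, *md.CONTROLS]
    for sp, sub in frame.groupby("species_id"):
        y = sub["outcome"].to_numpy(float)
        flag, reason = rc.detect_separation(y, sub[predictors])
        if flag:
            rows.append({"species_id": sp, "taxon": sub["taxon"].iloc[0],
                         "n": len(sub), "excluded": reason})
            continue
        fits = md.fit_formulations(sub, y)
        if not fits:
            rows.append({"species_id": sp, "taxon": sub["taxon"].iloc[0],
                         "n": len(sub), "excluded": "no converged fit"})
            continue
        best = md.select_best(fits)
        row = {"species_id": sp, "taxon": sub["taxon"].iloc[0], "n": len(sub),
               "excluded": "", "best": best.spec.formulation_id}
        for fid, f in fits.items():
            row[f"aic_{fid}"] = f.aic
        for name, val in best.params.items():
            row[f"beta_{name}"] = val
        rows.append(row)
        for var, unit in AME_UNITS.items():
            if var in best.params.index:
                res = md.average_marginal_effect(best, var, unit)
                ame_rows.append({"species_id": sp, "variable": var,
                                 "unit": unit, "ame": res.ame,
                                 "formulation": best.spec.formulation_id})
    fits_df = pd.DataFrame(rows)
    fits_df.to_csv(run_dir / "fits.csv", index=False)
    pd.DataFrame(ame_rows, columns=["species_id", "variable", "unit", "ame",
                                    "formulation"]
                 ).to_csv(run_dir / "ames.csv", index=False)
    logger.info("models: %d species fitted, %d excluded",
                (fits_df["excluded"] == "").sum(),
                (fits_df["excluded"] != "").sum())
    return fits_df


def stage_interaction(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    """Decile-grid comparison for species whose best model is interactive."""
    fits_df = pd.read_csv(run_dir / "fits.csv")
    inter_sp = fits_df.loc[(fits_df["excluded"].fillna("") == "")
                           & (fits_df["best"] == 5), "species_id"]
    frame = build_model_frame(config, run_dir)
    grids = []
    for sp in inter_sp:
        sub = frame[frame["species_id"] == sp]
        y = sub["outcome"].to_numpy(float)
        try:
            full = md.fit_logistic(sub, y, md.ModelSpec(5))
            add = md.fit_logistic(sub, y, md.ModelSpec(4))
            grids.append(ia.build_grid(full, add, sub, species_id=sp))
        except (ValueError, np.linalg.LinAlgError):
            logger.warning("interaction grid failed for %s", sp)
    if grids:
        tests = ia.paired_comparison(grids, config.alpha)
        table = ia.difference_table(grids)
        table.to_csv(run_dir / "difference_table.csv")
    else:
        tests = pd.DataFrame(columns=["species_id", "t", "p", "df",
                                      "significant", "flag"])
    tests.to_csv(run_dir / "interaction.csv", index=False)
    meta = {"threshold": tests.attrs.get("threshold"),
            "n_tested": int(len(tests))}
    (run_dir / "interaction_meta.json").write_text(json.dumps(meta))
    return tests


def stage_report(config: RunConfig, run_dir: Path) -> dict:
    """Cohorts, trend association and the machine-readable summary."""
    fits_df = pd.read_csv(run_dir / "fits.csv")
    fitted = fits_df[fits_df["excluded"].fillna("") == ""]
    ames = pd.read_csv(run_dir / "ames.csv")
    tests = pd.read_csv(run_dir / "interaction.csv")
    meta = json.loads((run_dir / "interaction_meta.json").read_text()) \
        if (run_dir / "interaction_meta.json").exists() else {}
    trends = pd.read_csv(run_dir / "trends.csv", index_col="species_id")

    rows = []
    for _, r in fitted.iterrows():
        fid = int(r["best"])
        if fid == 1:
            rows.append((r["species_id"], fid, None, "controls-only best model"))
        elif fid == 5:
            rows.append((r["species_id"], fid, None, "interactive best model"))
        else:
            bt, bl = r.get("beta_temperature_trend"), r.get("beta_land_conversion")
            if fid == 3:
                cohort = "T+" if bt > 0 else "T-"
            elif fid == 2:
                cohort = "L+" if bl > 0 else "L-"
            else:
                cohort = ("+" if bt > 0 else "-") + ("+" if bl > 0 else "-")
            rows.append((r["species_id"], fid, cohort, None))
    assignments = pd.DataFrame(rows, columns=["species_id", "formulation",
                                              "cohort", "excluded_reason"])
    report = {
        "n_species_input": int(len(fits_df)),
        "n_species_analysed": int(len(fitted)),
        "n_separated_excluded": int((fits_df["excluded"].fillna("") != "").sum()),
        "n_best_with_env": int((fitted["best"] > 1).sum()),
        "n_best_interactive": int((fitted["best"] == 5).sum()),
        "best_model_tally": {str(k): int(v) for k, v in
                             fitted["best"].value_counts().items()},
    }
    if len(ames):
        report["median_ame_pct"] = {
            var: float(np.median(grp["ame"]) * 100)
            for var, grp in ames[ames["formulation"] != 5].groupby("variable")}
    if len(tests):
        report["n_interactions_tested"] = int(len(tests))
        report["n_interactions_meaningful"] = int(tests["significant"].sum())
        report["bonferroni_threshold"] = meta.get("threshold")
    try:
        chi2, dof, p, table = rp.cohort_trend_test(assignments,
                                                   trends["trend"])
        report["cohort_trend_chi2"] = chi2
        report["cohort_trend_df"] = dof
        report["cohort_trend_p"] = p
        table.to_csv(run_dir / "fig3_table.csv")
    except (ValueError, KeyError) as exc:
        logger.warning("cohort trend test skipped: %s", exc)
    counts = assignments["cohort"].value_counts(dropna=True)
    report["cohort_counts"] = {c: int(counts.get(c, 0)) for c in rp.COHORTS}
    assignments.to_csv(run_dir / "cohorts.csv", index=False)
    (run_dir / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
    return report


STAGES = ["prepare", "landuse", "climate", "outcomes", "frescalo", "models",
          "interaction", "report"]


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order; a failure halts with the stage name."""
    run_dir = Path(out_dir)
    stage = "prepare"
    try:
        stage_prepare(config, run_dir)
        recs = pd.read_csv(run_dir / "records.csv")
        taxa = sorted(recs["taxon"].unique())
        config.validate_phi(taxa)
        stage = "landuse"
        stage_landuse(config, run_dir)
        stage = "climate"
        stage_climate(config, run_dir, taxa)
        stage = "outcomes"
        stage_outcomes(config, run_dir)
        stage = "frescalo"
        stage_frescalo(config, run_dir)
        stage = "models"
        stage_models(config, run_dir)
        stage = "interaction"
        stage_interaction(config, run_dir)
        stage = "report"
        return stage_report(config, run_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
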