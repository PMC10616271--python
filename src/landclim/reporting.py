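"""Response cohorts, trend association test, and run summaries.

Species whose best model contains land conversion and/or warming without an
interaction are sorted into eight response cohorts by coefficient sign
(T+, T-, L+, L-, and the four additive sign pairs).  A chi-square test on
the cohorts x trend-sign table asks whether square-level persistence
responses translate into national distribution gains or losses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .models import ENV_L, ENV_T, ModelFit

__all__ = ["classify_cohort", "cohort_trend_test", "summarize",
           "COHORTS"]

COHORTS = ("T+", "T-", "L+", "L-", "++", "+-", "-+", "--")


def classify_cohort(best_fits: dict[str, ModelFit]) -> pd.DataFrame:
    """Assign each species a response cohort from its best model.

    Only formulations 2 (L), 3 (T) and 4 (additive) are classifiable;
    controls-only and interactive species are excluded with a reason, as is
    any species with an exactly zero coefficient.
    Returns columns: species_id, formulation, cohort, excluded_reason.
    """
    rows = []
    for sp, fit in best_fits.items():
        fid = fit.spec.formulation_id
        if fid == 1:
            rows.append((sp, fid, None, "controls-only best model"))
            continue
        if fid == 5:
            rows.append((sp, fid, None, "interactive best model"))
            continue
        bt = fit.params.get(ENV_T, np.nan)
        bl = fit.params.get(ENV_L, np.nan)
        if (fid in (3, 4) and bt == 0) or (fid in (2, 4) and bl == 0):
            rows.append((sp, fid, None, "exactly zero coefficient"))
            continue
        if fid == 3:
            cohort = "T+" if bt > 0 else "T-"
        elif fid == 2:
            cohort = "L+" if bl > 0 else "L-"
        else:  # additive: (sign of T, sign of L)
            cohort = ("+" if bt > 0 else "-") + ("+" if bl > 0 else "-")
        rows.append((sp, fid, cohort, None))
    return pd.DataFrame(rows, columns=["species_id", "formulation",
                                       "cohort", "excluded_reason"])


def cohort_trend_test(assignments: pd.DataFrame, trends: pd.Series,
                      ) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square of response cohort vs distribution-trend sign.

    Zero-trend species are dropped (and reported via the table margin);
    empty cohort rows are removed before testing, which lowers the degrees
    of freedom from the nominal 7.  Returns (chi2, df, p, table).
    """
    df = assignments.dropna(subset=["cohort"]).copy()
    df["trend"] = df["species_id"].map(trends)
    df = df.dropna(subset=["trend"])
    df = df[df["trend"] != 0]
    df["trend_sign"] = np.where(df["trend"] > 0, "positive", "negative")
    table = (df.groupby(["cohort", "trend_sign"]).size().unstack(fill_value=0)
             .reindex(index=[c for c in COHORTS
                             if c in df["cohort"].unique()], fill_value=0)
             .reindex(columns=["positive", "negative"], fill_value=0))
    table = table.loc[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        raise ValueError("need at least two non-empty cohorts")
    chi2, p, dof, _ = chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p), table


def summarize(best_fits: dict[str, ModelFit],
              species_taxon: pd.Series,
              ames: pd.DataFrame | None = None,
              interaction_tests: pd.DataFrame | None = None,
              assignments: pd.DataFrame | None = None,
              separated: list[str] | None = None,
              out_dir: str | Path | None = None) -> dict:
    """Machine-readable summary of a completed run.

    Tallies best-model formulations per taxon, median AMEs per stated unit
    (0.1 degC/decade; 10 percentage points of conversion, both expressed as
    percentage-point changes in persistence probability), interaction
    significance counts and cohort bookkeeping.  Optionally persists
    ``report.json`` and ``cohorts.csv`` under ``out_dir``.
    """
    report: dict = {"n_species_analysed": len(best_fits),
                    "n_separated_excluded": len(separated or [])}
    tally: dict[str, dict[str, int]] = {}
    for sp, fit in best_fits.items():
        tx = str(species_taxon.get(sp, "unknown"))
        tally.setdefault(tx, {})[str(fit.spec.formulation_id)] = \
            tally.setdefault(tx, {}).get(str(fit.spec.formulation_id), 0) + 1
    report["best_model_tally"] = tally
    fids = pd.Series({sp: f.spec.formulation_id for sp, f in best_fits.items()})
    report["n_best_with_env"] = int((fids > 1).sum())
    report["n_best_interactive"] = int((fids == 5).sum())
    report["n_best_non_interactive_env"] = int(fids.isin([2, 3, 4]).sum())

    if ames is not None and len(ames):
        med = {}
        for var, grp in ames.groupby("variable"):
            med[var] = float(np.median(grp["ame"]) * 100)   # percentage points
        report["median_ame_pct"] = med
    if interaction_tests is not None and len(interaction_tests):
        report["n_interactions_tested"] = int(len(interaction_tests))
        report["n_interactions_meaningful"] = int(
            interaction_tests["significant"].sum())
        report["bonferroni_threshold"] = float(
            interaction_tests.attrs.get("threshold", np.nan))
    if assignments is not None and len(assignments):
        counts = assignments["cohort"].value_counts(dropna=True)
        report["cohort_counts"] = {c: int(counts.get(c, 0)) for c in COHORTS}
        report["n_cohort_excluded"] = int(assignments["cohort"].isna().sum())

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2,
                                                        sort_keys=True))
        if assignments is not None:
            assignments.to_csv(out_dir / "cohorts.csv", index=False)
    return report
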