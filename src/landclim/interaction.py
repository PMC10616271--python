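"""Is an interaction "meaningful"?  Decile prediction-grid comparison.

For each species whose best model includes the land-conversion x warming
interaction, persistence is predicted over an 11 x 11 grid of predictor
values (observed minimum, the nine deciles, and maximum of each predictor;
controls at their medians) from both the interactive fit and the matched
additive fit.  A paired t test on the 121 prediction differences, at a
Bonferroni-corrected threshold across the species family, decides
significance; a decile-by-size-bin table summarises where in predictor
space the two models disagree and by how much.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ENV_L, ENV_T, ModelFit, build_design

__all__ = ["PredictionGrid", "build_grid", "paired_comparison",
           "difference_table", "bonferroni_threshold"]

DECILE_LABELS = ["min"] + [f"p{d}" for d in range(10, 100, 10)] + ["max"]


@dataclass
class PredictionGrid:
    """121 paired persistence predictions for one species."""

    species_id: str
    t_values: np.ndarray          # 11 grid values of temperature trend
    l_values: np.ndarray          # 11 grid values of land conversion
    pred_interactive: np.ndarray  # (11, 11): rows follow t_values
    pred_additive: np.ndarray

    @property
    def differences(self) -> np.ndarray:
        return self.pred_interactive - self.pred_additive


def _grid_values(x: np.ndarray) -> np.ndarray:
    """min, 10th..90th percentile (linear interpolation), max: 11 values."""
    qs = np.percentile(x, np.arange(10, 100, 10), method="linear")
    return np.r_[x.min(), qs, x.max()]


def build_grid(fit_full: ModelFit, fit_additive: ModelFit,
               data: pd.DataFrame, species_id: str = "") -> PredictionGrid:
    """Predict persistence over the 11 x 11 decile grid from both fits.

    ``data`` holds the species' observed squares (the same rows both models
    were fitted to); control variables are held at their medians.
    """
    t_obs = data[ENV_T].to_numpy(float)
    l_obs = data[ENV_L].to_numpy(float)
    for name, x in ((ENV_T, t_obs), (ENV_L, l_obs)):
        if np.ptp(x) == 0:
            raise ValueError(f"degenerate predictor {name!r} (constant)")
    tv, lv = _grid_values(t_obs), _grid_values(l_obs)
    tt, ll = np.meshgrid(tv, lv, indexing="ij")
    grid = pd.DataFrame({ENV_T: tt.ravel(), ENV_L: ll.ravel()})
    for ctrl in fit_full.spec.controls:
        grid[ctrl] = float(data[ctrl].median())
    pred_i = fit_full.predict(build_design(grid, fit_full.spec))
    pred_a = fit_additive.predict(build_design(grid, fit_additive.spec))
    return PredictionGrid(species_id, tv, lv,
                          pred_i.reshape(11, 11), pred_a.reshape(11, 11))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold for a family of ``m`` paired comparisons."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


def paired_comparison(grids: list[PredictionGrid],
                      alpha: float = 0.05) -> pd.DataFrame:
    """Paired t test per species on the 121 prediction differences.

    Bonferroni-corrects across the ``len(grids)`` species family; a species
    with exactly zero difference variance and nonzero mean difference is a
    degenerate (infinite-t) case, flagged and counted significant; all-zero
    differences give p = 1 by convention.
    """
    if not grids:
        raise ValueError("at least one grid required")
    thresh = bonferroni_threshold(alpha, len(grids))
    rows = []
    for g in grids:
        d = g.differences.ravel()
        dof = len(d) - 1
        if np.allclose(d.std(ddof=1), 0):
            if np.allclose(d, 0):
                t, p, flag = 0.0, 1.0, "zero differences"
            else:
                t, p, flag = np.inf, 0.0, "constant nonzero differences"
        else:
            t, p = stats.ttest_rel(g.pred_interactive.ravel(),
                                   g.pred_additive.ravel())
            flag = ""
        rows.append((g.species_id, float(t), float(p), dof,
                     bool(p < thresh), flag))
    out = pd.DataFrame(rows, columns=["species_id", "t", "p", "df",
                                      "significant", "flag"])
    out.attrs["threshold"] = thresh
    return out


def difference_table(grids: list[PredictionGrid],
                     bin_edges: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4),
                     axis: str = ENV_T,
                     statistic: str = "max") -> pd.DataFrame:
    """Decile-row x size-bin counts of between-model prediction differences.

    For each of the 11 grid levels of ``axis``, each species contributes one
    summary of |interactive - additive| across the 11 values of the other
    predictor (``max`` by default, ``mean`` optional), binned by size; every
    row sums to the number of species.
    """
    if not grids:
        raise ValueError("at least one grid required")
    if statistic not in {"max", "mean"}:
        raise ValueError("statistic must be 'max' or 'mean'")
    edges = np.r_[0.0, np.asarray(bin_edges, float), np.inf]
    labels = [f"<{bin_edges[0]:g}"] + [
        f"{a:g}-{b:g}" for a, b in zip(bin_edges[:-1], bin_edges[1:])
    ] + [f">={bin_edges[-1]:g}"]
    counts = np.zeros((11, len(labels)), dtype=int)
    reducer = np.max if statistic == "max" else np.mean
    for g in grids:
        absdiff = np.abs(g.differences)
        per_level = (reducer(absdiff, axis=1) if axis == ENV_T
                     else reducer(absdiff, axis=0))
        idx = np.searchsorted(edges, per_level, side="right") - 1
        for row, b in enumerate(np.clip(idx, 0, len(labels) - 1)):
            counts[row, b] += 1
    return pd.DataFrame(counts, index=pd.Index(DECILE_LABELS, name=axis),
                        columns=labels)
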