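"""Frescalo recorder-effort correction and distribution trends.

Frescalo ("frequency scaling, local") estimates relative recorder effort for
each grid square from opportunistic occurrence data.  For a focal square it
pools presences over a weighted neighbourhood of biologically similar nearby
squares, giving local species frequencies ``f_ij``.  A per-square sampling
multiplier ``s_i`` then rescales frequencies, ``f*_ij = 1 - (1 - f_ij)^s_i``,
so that the mean rescaled frequency of locally common ("benchmark") species
equals a taxon-specific target Φ.  Well-recorded squares need little
rescaling (``s_i`` near 1); under-recorded squares need ``s_i`` > 1.  The
multiplier doubles as the recorder-effort covariate in downstream models.

Per-period time factors ``TF_jt`` measure the relative reportability of a
species after effort correction; their difference across periods, per
decade, is the species' distribution trend.  A weighted ("Telfer") logistic
regression of second-period on first-period range size provides an
independent relative range-change index used to sanity-check trend signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

__all__ = [
    "FrescaloConfig",
    "FrescaloFit",
    "NeighbourhoodWeights",
    "neighbourhood_weights",
    "local_frequencies",
    "effort_multiplier",
    "rescaled_frequencies",
    "time_factor",
    "telfer_index",
    "run_frescalo",
]

#: Standard neighbourhood frequency targets per taxon (British defaults).
DEFAULT_PHI = {"birds": 0.92, "butterflies": 0.86, "macromoths": 0.67,
               "plants": 0.75}


@dataclass
class FrescaloConfig:
    """Tuning constants for the neighbourhood and effort equations."""

    n_candidates: int = 200        #: G, geographic candidate pool per square
    n_neighbours: int = 100        #: K, similarity-ranked neighbours kept
    benchmark_fraction: float = 0.27   #: top share of species used as benchmarks
    tf_max: float = 20.0           #: cap when the time-factor equation has no root

    def __post_init__(self) -> None:
        if self.n_neighbours > self.n_candidates:
            raise ValueError("n_neighbours (K) must be <= n_candidates (G)")
        if not 0 < self.benchmark_fraction <= 1:
            raise ValueError("benchmark_fraction must lie in (0, 1]")


@dataclass
class NeighbourhoodWeights:
    """Per-square neighbour lists with combined proximity/similarity weights."""

    square_ids: pd.Index
    neighbours: list[np.ndarray]     # integer positions into square_ids
    weights: list[np.ndarray]


@dataclass
class FrescaloFit:
    """Outputs of a Frescalo run on a two-period presence dataset.

    ``multiplier`` is the sampling-effort multiplier alpha_i solved from the
    benchmark equation (large in under-recorded squares); ``effort`` is the
    recorder-effort covariate 1/alpha_i used in downstream models (large
    where recording was thorough).
    """

    effort: pd.Series                      # 1/alpha_i per square
    multiplier: pd.Series                  # alpha_i per square
    frequencies: pd.DataFrame              # f_ij, squares x species
    rescaled: pd.DataFrame                 # f*_ij
    time_factors: pd.DataFrame             # species x period
    trend: pd.Series                       # per-species decadal trend
    flags: dict = field(default_factory=dict)


def _sorensen(presence: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row sums and intersection counts needed for Sorensen similarity."""
    inter = presence @ presence.T
    sizes = presence.sum(axis=1)
    return sizes, inter


def neighbourhood_weights(centroids: pd.DataFrame, presence: pd.DataFrame,
                          config: FrescaloConfig | None = None,
                          ) -> NeighbourhoodWeights:
    """Rank-based neighbour weights per square.

    For each square: the ``G`` geographically nearest squares (self included,
    rank 1) are candidates; candidates are re-ranked by Sorensen similarity
    of species composition and the ``K`` most similar retained, with weight

        ``w = (1 - (r_sim - 1)/K)^4 * (1 - (r_dist - 1)/G)^4``.

    The focal square holds rank 1 on both scales, hence weight 1.
    """
    config = config or FrescaloConfig()
    if not centroids.index.equals(presence.index):
        presence = presence.reindex(index=centroids.index, fill_value=0)
    n = len(centroids)
    if n < config.n_neighbours:
        raise ValueError(
            f"need at least K={config.n_neighbours} squares, got {n}")
    G = min(config.n_candidates, n)
    K = min(config.n_neighbours, G)
    xy = centroids[["x", "y"]].to_numpy(dtype=float)
    P = presence.to_numpy(dtype=np.float64)
    sizes, inter = _sorensen(P)
    dist = cdist(xy, xy)
    np.fill_diagonal(dist, -1.0)     # self strictly first in distance order

    neighbours, weights = [], []
    for i in range(n):
        cand = np.argsort(dist[i], kind="stable")[:G]         # self at rank 1
        denom = sizes[cand] + sizes[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            sim = np.where(denom > 0, 2.0 * inter[i, cand] / denom, 0.0)
        sim[cand == i] = np.inf      # self strictly first in similarity order
        order = np.argsort(-sim, kind="stable")[:K]
        kept = cand[order]
        r_dist = order + 1.0         # candidate list is distance-ordered
        r_sim = np.arange(1.0, K + 1)
        w = (1 - (r_sim - 1) / K) ** 4 * (1 - (r_dist - 1) / G) ** 4
        neighbours.append(kept)
        weights.append(w)
    return NeighbourhoodWeights(presence.index, neighbours, weights)


def local_frequencies(presence: pd.DataFrame,
                      weights: NeighbourhoodWeights) -> pd.DataFrame:
    """Weighted neighbourhood frequency ``f_ij`` of each species per square."""
    P = presence.reindex(index=weights.square_ids, fill_value=0).to_numpy(float)
    out = np.empty((len(weights.square_ids), P.shape[1]))
    for i, (nb, w) in enumerate(zip(weights.neighbours, weights.weights)):
        out[i] = w @ P[nb] / w.sum()
    return pd.DataFrame(out, index=weights.square_ids, columns=presence.columns)


def effort_multiplier(f_i: np.ndarray, phi: float,
                      benchmark_fraction: float = 0.27) -> float:
    """Solve for the sampling multiplier ``s_i`` of one square.

    Benchmark species are the top ``benchmark_fraction`` of species with
    nonzero local frequency, ranked by frequency (the rescaling is monotone,
    so ranking by ``f`` equals ranking by ``f*``).  ``s_i`` solves

        ``mean_benchmark(1 - (1 - f_ij)^s) = phi``

    by bisection; NaN when the equation has no root (all benchmark
    frequencies are 0 or 1).
    """
    if not 0 < phi < 1:
        raise ValueError("phi must lie in (0, 1)")
    f = np.asarray(f_i, dtype=float)
    f = f[f > 0]
    if f.size == 0:
        return float("nan")
    f = np.sort(f)[::-1]
    n_bench = max(1, int(round(benchmark_fraction * f.size)))
    bench = f[:n_bench]
    if np.all(bench >= 1.0):
        return float("nan")

    def g(s: float) -> float:
        return float(np.mean(1.0 - (1.0 - bench) ** s)) - phi

    lo, hi = 1e-10, 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            return float("nan")
    return float(brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200))


def rescaled_frequencies(freq: pd.DataFrame, effort: pd.Series) -> pd.DataFrame:
    """``f*_ij = 1 - (1 - f_ij)^{s_i}``."""
    s = effort.reindex(freq.index).to_numpy(float)[:, None]
    return pd.DataFrame(1.0 - (1.0 - freq.to_numpy(float)) ** s,
                        index=freq.index, columns=freq.columns)


def time_factor(observed: int, fstar_j: np.ndarray, visited: np.ndarray,
                tf_max: float = 20.0) -> tuple[float, bool]:
    """Solve one species/period time-factor equation.

    ``TF`` solves ``sum_{i visited} (1 - (1 - f*_ij)^TF) = observed`` where
    ``observed`` is the number of visited squares recording the species in
    the period.  Monotone in TF; no finite root (observed >= attainable
    supremum) returns ``(tf_max, True)``; no records returns ``(0, False)``.
    """
    if observed == 0:
        return 0.0, False
    fv = np.asarray(fstar_j, float)[np.asarray(visited, bool)]
    fv = np.clip(fv, 0.0, 1.0 - 1e-12)
    sup = float(np.sum(fv > 0))

    def g(tf: float) -> float:
        return float(np.sum(1.0 - (1.0 - fv) ** tf)) - observed

    if observed >= sup or g(tf_max) < 0:
        return tf_max, True
    return float(brentq(g, 1e-10, tf_max, xtol=1e-10, maxiter=200)), False


def telfer_index(n1: pd.Series, n2: pd.Series, total1: int, total2: int,
                 ) -> pd.Series:
    """Relative range-change index per species.

    Regresses logit(second-period proportion of occupied squares) on
    logit(first-period proportion) across species, weighting each species
    inversely to the binomial variance of its second-period logit; the index
    is the standardized weighted residual.  Species occupying no or all
    squares in either period are excluded.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"n1": n1, "n2": n2}).dropna()
    p1, p2 = df.n1 / total1, df.n2 / total2
    ok = (p1 > 0) & (p1 < 1) & (p2 > 0) & (p2 < 1)
    df, p1, p2 = df[ok], p1[ok], p2[ok]
    if len(df) < 3:
        raise ValueError("need >=3 species with counts strictly inside (0, N)")
    y = np.log(p2 / (1 - p2))
    x = np.log(p1 / (1 - p1))
    # Var(logit p2_hat) ~ 1 / (N2 p2 q2); weight is its inverse
    w = (total2 * p2 * (1 - p2)).to_numpy()
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    resid = y - fit.fittedvalues
    scale = np.sqrt(np.sum(w * resid ** 2) / (len(df) - 2))
    index = np.sqrt(w) * resid / scale
    return pd.Series(index.to_numpy(), index=df.index, name="telfer")


def run_frescalo(presence_by_period: dict[int, pd.DataFrame],
                 centroids: pd.DataFrame, phi: float,
                 period_years: dict[int, tuple[int, int]],
                 visited_by_period: dict[int, pd.Series] | None = None,
                 config: FrescaloConfig | None = None,
                 effort_period: int | None = 1) -> FrescaloFit:
    """Full Frescalo run on two-period presence data for one taxon.

    Neighbourhood weights and local frequencies come from the pooled
    (either-period) presence.  The effort covariate is estimated from the
    ``effort_period`` presence alone (first period by default, matching its
    use as a control on historical recording); time factors use the pooled
    rescaled frequencies and per-period observed square counts over squares
    with any record of the taxon in that period.
    """
    config = config or FrescaloConfig()
    periods = sorted(presence_by_period)
    if len(periods) != 2:
        raise ValueError("exactly two periods required")
    squares = centroids.index
    pres = {t: presence_by_period[t].reindex(index=squares, fill_value=0)
            for t in periods}
    species = pres[periods[0]].columns.union(pres[periods[1]].columns)
    pres = {t: pres[t].reindex(columns=species, fill_value=0) for t in periods}
    pooled = (pres[periods[0]] | pres[periods[1]]).astype(np.int8)

    wts = neighbourhood_weights(centroids, pooled, config)
    freq = local_frequencies(pooled, wts)
    flags: dict = {"effort_nan": [], "tf_capped": []}

    basis = freq if effort_period is None else local_frequencies(
        pres[effort_period], wts)
    alpha = np.array([effort_multiplier(basis.iloc[i].to_numpy(), phi,
                                        config.benchmark_fraction)
                      for i in range(len(squares))])
    multiplier = pd.Series(alpha, index=squares, name="multiplier")
    effort = (1.0 / multiplier).rename("effort")
    flags["effort_nan"] = list(squares[np.isnan(alpha)])

    s_pooled = np.array([effort_multiplier(freq.iloc[i].to_numpy(), phi,
                                           config.benchmark_fraction)
                         for i in range(len(squares))])
    fstar = rescaled_frequencies(freq, pd.Series(s_pooled, index=squares))

    if visited_by_period is None:
        visited_by_period = {t: pres[t].sum(axis=1) > 0 for t in periods}
    tf = pd.DataFrame(index=species, columns=periods, dtype=float)
    for t in periods:
        visited = visited_by_period[t].reindex(squares, fill_value=False
                                               ).to_numpy(bool)
        for j, sp in enumerate(species):
            obs = int(pres[t].iloc[:, j].to_numpy()[visited].sum())
            val, capped = time_factor(obs, fstar.iloc[:, j].to_numpy(),
                                      visited, config.tf_max)
            tf.loc[sp, t] = val
            if capped:
                flags["tf_capped"].append((sp, t))

    mid = {t: (period_years[t][0] + period_years[t][1]) / 2 for t in periods}
    decades = (mid[periods[1]] - mid[periods[0]]) / 10.0
    trend = ((tf[periods[1]] - tf[periods[0]]) / decades).rename("trend")
    return FrescaloFit(effort, multiplier, freq, fstar, tf, trend, flags)
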