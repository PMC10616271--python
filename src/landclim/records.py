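"""From occurrence records to persistence/extirpation outcomes.

Records are a long table ``(species_id, taxon, square_id, period[, year])``
with ``period`` in {1, 2}.  A square contributes an outcome for a species
only when the species was present in period 1; an apparent loss counts as an
extirpation only when some *other* species of the same taxon was recorded in
that square in period 2 (otherwise the square may simply not have been
visited, and the square is excluded for that species).  Colonisations
(absent then present) are tabulated separately under the symmetric period-1
coverage rule; they feed the distribution-trend analysis, not the
persistence models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "presence_matrix",
    "build_outcomes",
    "filter_range_size",
    "detect_separation",
]

REQUIRED_COLUMNS = ("species_id", "taxon", "square_id", "period")


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table lacks columns {missing}")


def presence_matrix(records: pd.DataFrame, period: int,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary squares x species presence for one period, plus taxon coverage.

    Returns ``(presence, coverage)``: ``presence[sq, sp] = 1`` iff at least
    one record exists; ``coverage[sq, taxon] = 1`` iff any species of the
    taxon was recorded in the square in that period.
    """
    _check_records(records)
    known = set(pd.unique(records["period"]))
    if period not in known and len(records):
        raise ValueError(f"unknown period label {period!r}; "
                         f"records contain {sorted(known)}")
    sub = records[records["period"] == period]
    presence = (pd.crosstab(sub["square_id"], sub["species_id"]) > 0).astype(np.int8)
    coverage = (pd.crosstab(sub["square_id"], sub["taxon"]) > 0).astype(np.int8)
    presence.index.name = coverage.index.name = "square_id"
    return presence, coverage


def build_outcomes(p1: pd.DataFrame, p2: pd.DataFrame,
                   coverage2: pd.DataFrame,
                   species_taxon: pd.Series,
                   coverage1: pd.DataFrame | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Persistence (1) / extirpation (0) outcomes per species x square.

    Parameters
    ----------
    p1, p2
        Period presence matrices (squares x species); indices are aligned
        internally by union.
    coverage2
        Period-2 squares x taxon coverage, for the verified-absence rule.
    species_taxon
        Maps species_id -> taxon for every species in the matrices.
    coverage1
        Optional period-1 coverage; when given, colonisations are returned
        under the symmetric rule.

    Returns
    -------
    (outcomes, colonisations)
        ``outcomes``: columns species_id, taxon, square_id, outcome.
        ``colonisations``: columns species_id, taxon, square_id (empty when
        ``coverage1`` is None).
    """
    squares = p1.index.union(p2.index)
    species = p1.columns.union(p2.columns)
    a1 = p1.reindex(index=squares, columns=species, fill_value=0).to_numpy()
    a2 = p2.reindex(index=squares, columns=species, fill_value=0).to_numpy()

    out_rows, col_rows = [], []
    for j, sp in enumerate(species):
        taxon = species_taxon[sp]
        if taxon in coverage2.columns:
            cov2 = coverage2.reindex(index=squares, fill_value=0)[taxon].to_numpy()
        else:
            cov2 = np.zeros(len(squares), dtype=np.int8)
        occ1, occ2 = a1[:, j].astype(bool), a2[:, j].astype(bool)
        persist = occ1 & occ2
        extirp = occ1 & ~occ2 & (cov2 > 0)     # verified absence only
        for sq in squares[persist]:
            out_rows.append((sp, taxon, sq, 1))
        for sq in squares[extirp]:
            out_rows.append((sp, taxon, sq, 0))
        if coverage1 is not None:
            if taxon in coverage1.columns:
                cov1 = coverage1.reindex(index=squares, fill_value=0)[taxon].to_numpy()
            else:
                cov1 = np.zeros(len(squares), dtype=np.int8)
            colon = ~occ1 & occ2 & (cov1 > 0)
            for sq in squares[colon]:
                col_rows.append((sp, taxon, sq))

    outcomes = pd.DataFrame(out_rows,
                            columns=["species_id", "taxon", "square_id", "outcome"])
    colonisations = pd.DataFrame(col_rows,
                                 columns=["species_id", "taxon", "square_id"])
    return outcomes, colonisations


def filter_range_size(outcomes: pd.DataFrame, min_squares: int = 100,
                      ) -> pd.DataFrame:
    """Keep species recorded in strictly more than ``min_squares`` period-1 squares.

    The outcome table itself carries one row per period-1 square with a
    determinable fate, but range size is judged on *all* period-1 squares,
    so pass the unfiltered outcome rows (persisted + verified extirpations
    are a lower bound; callers with raw presence should count from it).
    """
    if min_squares < 0:
        raise ValueError("min_squares must be >= 0")
    if outcomes.empty:
        return outcomes.copy()
    n1 = outcomes.groupby("species_id")["square_id"].nunique()
    keep = n1[n1 > min_squares].index
    return outcomes[outcomes["species_id"].isin(keep)].reset_index(drop=True)


def count_period1_squares(p1: pd.DataFrame) -> pd.Series:
    """Unique period-1 squares per species, from the presence matrix."""
    return p1.sum(axis=0).rename("n_squares_p1")


def filter_range_size_presence(outcomes: pd.DataFrame, p1: pd.DataFrame,
                               min_squares: int = 100) -> pd.DataFrame:
    """Range-size filter judged on the full period-1 presence matrix."""
    n1 = count_period1_squares(p1)
    keep = n1[n1 > min_squares].index
    return outcomes[outcomes["species_id"].isin(keep)].reset_index(drop=True)


def detect_separation(y: np.ndarray, predictors: pd.DataFrame,
                      include_quasi: bool = True) -> tuple[bool, str]:
    """Screen one species for (quasi-)complete separation.

    Flags the species when, along any single predictor, the observed values
    under persistence and extirpation form non-overlapping ranges (complete
    separation) or ranges touching at exactly one value (quasi-separation,
    on by default).  Either condition leaves the logistic MLE unbounded, so
    flagged species are removed from species- and taxon-level model fits.

    Returns ``(flag, reason)``.
    """
    if predictors.shape[1] < 1:
        raise ValueError("at least one predictor column required")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        return True, "degenerate outcome"
    for name in predictors.columns:
        x = predictors[name].to_numpy(dtype=float)
        if x.min() == x.max():      # constant predictor separates nothing
            continue
        x0, x1 = x[y == 0], x[y == 1]
        if x0.max() < x1.min() or x1.max() < x0.min():
            return True, f"complete separation on {name}"
        if include_quasi and (x0.max() == x1.min() or x1.max() == x0.min()):
            return True, f"quasi-separation on {name}"
    return False, ""
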