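"""Market × item incidence matrices, shared/unique decompositions and
Euclidean market distances.

Items are compared at three levels: *species* (canonical binomials), *use*
(species–ailment pairs) and *category* (species–category pairs).  The
"plant-space" used for ordination concatenates the species-level and
use-level indicator columns.  Distances are computed on raw presence/absence
— the survey records occurrence only, so no abundance standardization
applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import ParameterError
from .model import MarketSurvey

LEVELS = ("species", "use", "category")


@dataclass
class IncidenceMatrix:
    """Binary markets × items presence/absence table."""

    frame: pd.DataFrame  # index: markets (registry order); columns: items
    level: str

    @property
    def markets(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


def _item(report, level: str) -> str:
    if level == "species":
        return report.species
    if level == "use":
        return f"{report.species}::{report.ailment.strip().casefold()}"
    if level == "category":
        return f"{report.species}::{report.category}"
    raise ParameterError(f"unknown incidence level {level!r}; "
                         f"expected one of {LEVELS}")


def incidence_matrix(survey: MarketSurvey, level: str = "species"
                     ) -> IncidenceMatrix:
    """Presence/absence of items per market, items sorted lexicographically.

    Rows follow the survey's market registry; only items present somewhere
    appear as columns (no all-zero columns).
    """
    _item_check(level)
    cells = {(r.market, _item(r, level)) for r in survey.reports}
    items = sorted({it for _, it in cells})
    col = {it: j for j, it in enumerate(items)}
    row = {m: i for i, m in enumerate(survey.markets)}
    mat = np.zeros((len(survey.markets), len(items)), dtype=np.int8)
    for market, it in cells:
        mat[row[market], col[it]] = 1
    frame = pd.DataFrame(mat, index=list(survey.markets), columns=items)
    return IncidenceMatrix(frame=frame, level=level)


def _item_check(level: str) -> None:
    if level not in LEVELS:
        raise ParameterError(f"unknown incidence level {level!r}; "
                             f"expected one of {LEVELS}")


def plant_space_matrix(survey: MarketSurvey) -> IncidenceMatrix:
    """Concatenated species-level and use-level indicator columns.

    This is the space in which markets are ordinated: a market's profile is
    both which plants it sells and which plant uses it reports.  Both blocks
    are unweighted.
    """
    sp = incidence_matrix(survey, "species")
    use = incidence_matrix(survey, "use")
    frame = pd.concat([sp.frame, use.frame], axis=1)
    return IncidenceMatrix(frame=frame, level="plantspace")


@dataclass
class SharedUnique:
    """Unique-item lists per market and pairwise shared counts."""

    unique_items: dict[str, list[str]]  # items found in that market only
    n_present: pd.Series  # items present per market
    proportion_unique: pd.Series  # unique / present per market
    shared_counts: pd.DataFrame  # symmetric pairwise co-presence counts


def shared_unique(matrix: IncidenceMatrix) -> SharedUnique:
    """Decompose an incidence matrix into unique and shared items."""
    frame = matrix.frame
    colsum = frame.sum(axis=0)
    singleton = colsum == 1
    unique_items = {
        m: sorted(frame.columns[(frame.loc[m] == 1) & singleton])
        for m in frame.index
    }
    present = frame.sum(axis=1)
    prop = pd.Series(
        {m: (len(unique_items[m]) / present[m]) if present[m] else 0.0
         for m in frame.index}, name="proportion_unique")
    x = frame.to_numpy()
    shared = pd.DataFrame(x @ x.T, index=frame.index, columns=frame.index)
    np.fill_diagonal(shared.values, present.to_numpy())
    return SharedUnique(unique_items=unique_items, n_present=present,
                        proportion_unique=prop, shared_counts=shared)


def unique_use_percent(survey: MarketSurvey) -> pd.DataFrame:
    """Percent of a plant's uses that are unique to each market.

    Defined for species occurring in at least two markets.  A use is unique
    to market *m* when the (species, use) pair occurs in *m* and nowhere
    else.  Returns one row per (species, market) with ``n_uses_here``,
    ``n_unique_here`` and ``pct_unique``.
    """
    occ = {(r.species, r.market, r.ailment.strip().casefold())
           for r in survey.reports}
    species_markets: dict[str, set] = {}
    use_markets: dict[tuple[str, str], set] = {}
    for species, market, use in occ:
        species_markets.setdefault(species, set()).add(market)
        use_markets.setdefault((species, use), set()).add(market)
    rows = []
    for species in sorted(species_markets):
        markets = species_markets[species]
        if len(markets) < 2:
            continue
        for market in sorted(markets):
            uses_here = [u for (s, u), mk in use_markets.items()
                         if s == species and market in mk]
            unique_here = [u for u in uses_here
                           if use_markets[(species, u)] == {market}]
            rows.append({
                "species": species, "market": market,
                "n_uses_here": len(uses_here),
                "n_unique_here": len(unique_here),
                "pct_unique": 100.0 * len(unique_here) / len(uses_here),
            })
    return pd.DataFrame(rows, columns=["species", "market", "n_uses_here",
                                       "n_unique_here", "pct_unique"])


def euclidean_distances(matrix: IncidenceMatrix | list[IncidenceMatrix]
                        ) -> DistanceMatrix:
    """Pairwise Euclidean distance between market incidence rows.

    Passing a list concatenates the matrices' item columns first (e.g.
    species + use = "plant-space").  For binary data the squared distance
    equals the number of items present in exactly one of the two markets.
    """
    if isinstance(matrix, (list, tuple)):
        frames = [m.frame for m in matrix]
        ids = frames[0].index
        for f in frames[1:]:
            if not f.index.equals(ids):
                raise ParameterError("incidence matrices have different "
                                     "market registries")
        frame = pd.concat(frames, axis=1)
    else:
        frame = matrix.frame
    if len(frame.index) < 2:
        raise ParameterError("need at least 2 markets for distances")
    condensed = pdist(frame.to_numpy(dtype=float), metric="euclidean")
    return DistanceMatrix(squareform(condensed), ids=list(frame.index))


def widespread_species(survey: MarketSurvey, k: int = 11) -> pd.DataFrame:
    """The k species occurring in the most markets (ties alphabetical)."""
    counts: dict[str, set] = {}
    for r in survey.reports:
        counts.setdefault(r.species, set()).add(r.market)
    rows = sorted(((s, len(m)) for s, m in counts.items()),
                  key=lambda kv: (-kv[1], kv[0]))[:k]
    return pd.DataFrame(rows, columns=["species", "n_markets"])
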