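"""Informant consensus and the logarithmic informant consensus (LIC) score.

Markets are the occurrence unit: one (species, market) pair counts once for
a use, however many vendors in that market reported it.  For a use *u*,

.. math::

    IC_u = \\frac{FC_u - NS_u}{FC_u - 1},

where :math:`FC_u` is the total number of (species, market) occurrences of
the use and :math:`NS_u` the number of distinct species reported for it.
:math:`IC_u` is 1 when every occurrence names the same species and 0 when
every occurrence names a different species.  A use with a single occurrence
(:math:`FC_u = 1`) carries no consensus information and is assigned
:math:`IC_u = 0` (the raw formula is 0/0 there).

Each species *s* is then scored

.. math::

    LIC_s = \\sum_u IC_u \\cdot \\ln(FC_{us}),

summing over the uses the species is reported for, with :math:`FC_{us}` the
number of markets in which species *s* is reported for use *u* (natural
logarithm).  A species whose every use occurs in a single market scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .model import MarketSurvey

_LEVELS = ("ailment", "category")


def _use_label(report, level: str) -> str:
    if level == "ailment":
        # ailments are compared case-insensitively after trimming
        return report.ailment.strip().casefold() or report.category
    return report.category


@dataclass(frozen=True)
class UseConsensusRecord:
    """Consensus bookkeeping for one use."""

    use: str
    FCu: int  # total (species, market) occurrences of the use
    NSu: int  # distinct species reported for the use
    ICu: float


@dataclass
class ConsensusTable:
    """Per-species LIC scores with their contributing uses."""

    scores: pd.DataFrame  # columns: species, lic, n_uses, n_markets
    detail: pd.DataFrame  # columns: species, use, FCus, ICu, term
    level: str
    percentile: float | None = None
    threshold: float | None = None


def use_consensus(survey: MarketSurvey,
                  level: str = "ailment") -> list[UseConsensusRecord]:
    """Informant consensus per use, with markets as occurrences.

    Expects a medicinal-filtered survey; reports are reduced to distinct
    (species, market, use) occurrences before counting.
    """
    if level not in _LEVELS:
        raise ParameterError(f"level must be one of {_LEVELS}, got {level!r}")
    occ = {(r.species, r.market, _use_label(r, level)) for r in survey.reports}
    by_use: dict[str, set] = {}
    for species, market, use in occ:
        by_use.setdefault(use, set()).add((species, market))
    records = []
    for use in sorted(by_use):
        pairs = by_use[use]
        fcu = len(pairs)
        nsu = len({s for s, _ in pairs})
        icu = (fcu - nsu) / (fcu - 1) if fcu > 1 else 0.0
        records.append(UseConsensusRecord(use=use, FCu=fcu, NSu=nsu, ICu=icu))
    return records


def species_lic(survey: MarketSurvey,
                level: str = "ailment") -> ConsensusTable:
    """Logarithmic informant consensus score for every species."""
    consensus = {rec.use: rec for rec in use_consensus(survey, level)}
    occ = {(r.species, r.market, _use_label(r, level)) for r in survey.reports}
    markets_per: dict[tuple[str, str], set] = {}
    species_markets: dict[str, set] = {}
    for species, market, use in occ:
        markets_per.setdefault((species, use), set()).add(market)
        species_markets.setdefault(species, set()).add(market)

    detail_rows = []
    for (species, use), mkts in markets_per.items():
        fcus = len(mkts)
        icu = consensus[use].ICu
        detail_rows.append({"species": species, "use": use, "FCus": fcus,
                            "ICu": icu, "term": icu * np.log(fcus)})
    detail = pd.DataFrame(detail_rows,
                          columns=["species", "use", "FCus", "ICu", "term"])
    if detail.empty:
        scores = pd.DataFrame(columns=["species", "lic", "n_uses", "n_markets"])
        return ConsensusTable(scores=scores, detail=detail, level=level)
    grouped = detail.groupby("species", sort=False)
    scores = pd.DataFrame({
        "lic": grouped["term"].sum(),
        "n_uses": grouped["use"].nunique(),
    })
    scores["n_markets"] = scores.index.map(lambda s: len(species_markets[s]))
    scores = (scores.reset_index()
              .sort_values(["lic", "species"], ascending=[False, True])
              .reset_index(drop=True))
    return ConsensusTable(scores=scores, detail=detail, level=level)


def lic_threshold(table: ConsensusTable, q: float = 0.95) -> ConsensusTable:
    """Species whose LIC strictly exceeds the empirical q-quantile.

    The quantile interpolates linearly between order statistics.  Returns a
    new table restricted to the exceedance set, carrying the threshold.
    """
    if not 0.0 < q < 1.0:
        raise ParameterError(f"percentile must be in (0, 1), got {q}")
    if table.scores.empty:
        raise ParameterError("consensus table is empty")
    threshold = float(np.quantile(table.scores["lic"].to_numpy(), q))
    subset = table.scores[table.scores["lic"] > threshold].reset_index(drop=True)
    keep = set(subset["species"])
    return ConsensusTable(
        scores=subset,
        detail=table.detail[table.detail["species"].isin(keep)].reset_index(drop=True),
        level=table.level, percentile=q, threshold=threshold,
    )
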