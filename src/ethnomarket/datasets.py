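"""Packaged transcription of the Bogotá medicinal-plant market inventory.

The inventory is shipped as a species-level table (one row per filing:
family, scientific name, vernacular names, a uses cell and a markets cell),
the shape in which such inventories are published.  ``load_bogota_survey``
expands it to long-format use reports.

.. note::
   The source inventory records which uses a species has and which markets
   it occurs in, but not which use was observed in which market.  The
   expansion therefore crosses every use of a species with every market it
   occurs in.  Species-level and use-category-level summaries are exact;
   per-market use-level quantities (and hence consensus indices computed on
   this dataset) are upper-bound reconstructions, not observations.
"""

from __future__ import annotations

import logging
from importlib import resources

import pandas as pd

from .io import NormalizationConfig
from .model import MarketSurvey, UseReport, canonicalize_binomial

logger = logging.getLogger("ethnomarket")

_TABLE1_PARTS = ("bogota_table1_part1.tsv", "bogota_table1_part2.tsv",
                 "bogota_table1_part3.tsv")


def parse_uses_cell(text: str) -> list[tuple[str, list[str], bool]]:
    """Parse a ``"Category (a, b); Category2 (c)*"`` uses cell.

    Parentheses inside ailments are balanced; a trailing ``*`` marks the use
    as non-medicinal in the source.  Returns ``(category, ailments, starred)``
    triples.
    """
    out: list[tuple[str, list[str], bool]] = []
    i, n = 0, len(text)
    while i < n:
        j = text.find("(", i)
        if j < 0:
            break
        category = text[i:j].strip(" ;")
        depth, k = 1, j + 1
        while k < n and depth:
            if text[k] == "(":
                depth += 1
            elif text[k] == ")":
                depth -= 1
            k += 1
        inner = text[j + 1:k - 1]
        starred = k < n and text[k] == "*"
        if starred:
            k += 1
        ailments, buf, d = [], "", 0
        for ch in inner:
            if ch == "(":
                d += 1
            elif ch == ")":
                d -= 1
            if ch == "," and d == 0:
                ailments.append(buf.strip())
                buf = ""
            else:
                buf += ch
        if buf.strip():
            ailments.append(buf.strip())
        out.append((category, ailments, starred))
        i = k
    return out


def load_bogota_config() -> NormalizationConfig:
    """The normalization rules shipped with the transcription."""
    with resources.as_file(
            resources.files("ethnomarket.data") / "bogota_config.yaml") as p:
        return NormalizationConfig.from_yaml(p)


def load_bogota_table1() -> pd.DataFrame:
    """The verbatim species-level transcription (one row per filing)."""
    frames = []
    for part in _TABLE1_PARTS:
        with resources.as_file(
                resources.files("ethnomarket.data") / part) as p:
            frames.append(pd.read_csv(p, sep="\t", dtype=str,
                                      keep_default_na=False))
    return pd.concat(frames, ignore_index=True)


def load_bogota_table2() -> pd.DataFrame:
    """The published per-species consensus ranking (reference values only).

    These scores cannot be recomputed from the species-level inventory
    because use-by-market occurrences are not published; they are shipped for
    comparison.  Note the ranking lists *Sambucus nigra* while the inventory
    files *Sambucus peruviana* — the mismatch is kept verbatim.
    """
    with resources.as_file(
            resources.files("ethnomarket.data") / "bogota_table2_lic.tsv") as p:
        return pd.read_csv(p, sep="\t")


def load_bogota_survey(config: NormalizationConfig | None = None) -> MarketSurvey:
    """Expand the transcription into a validated long-format survey."""
    config = config or load_bogota_config()
    table = load_bogota_table1()
    reports: list[UseReport] = []
    for row in table.itertuples(index=False):
        name = canonicalize_binomial(row.scientific_name)
        family = config.family_aliases.get(row.family.strip(),
                                           row.family.strip())
        vern = tuple(v.strip() for v in row.vernacular.split("/") if v.strip())
        markets = []
        for raw in row.markets.split(";"):
            raw = raw.strip()
            if not raw:
                continue
            market = config.market_aliases.get(raw, raw)
            if market is None:
                logger.info("dropping non-market token %r", raw)
                continue
            markets.append(market)
        for raw_cat, ailments, _starred in parse_uses_cell(row.uses):
            category = config.canon_category(raw_cat)
            medicinal = config.is_medicinal(category)
            for ailment in (ailments or [""]):
                for market in markets:
                    reports.append(UseReport(
                        family=family, species=name.binomial,
                        genus=name.genus, vernacular_names=vern,
                        category=category, ailment=ailment, market=market,
                        medicinal=medicinal, qualifier=name.qualifier,
                        hybrid=name.hybrid, genus_only=name.genus_only,
                    ))
    return MarketSurvey.from_reports(
        reports, provenance="Bogotá market inventory transcription")
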