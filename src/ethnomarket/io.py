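"""Reading and writing long-format survey tables and normalization configs.

The interchange format is UTF-8 delimited text (comma or tab, auto-detected
from the header line) with one row per ``(species, market, category,
ailment)`` observation and columns::

    family, species, vernacular, category, ailment, market[, nonmedicinal]

``vernacular`` holds ``/``-separated names.  The optional ``nonmedicinal``
column (0/1, true/false) overrides the category-registry convention.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import SchemaError, VocabularyError
from .model import (DEFAULT_NONMEDICINAL, MarketSurvey, UseReport,
                    canonicalize_binomial)

logger = logging.getLogger("ethnomarket")

REQUIRED_COLUMNS = ("family", "species", "vernacular", "category", "ailment",
                    "market")

_TRUTHY = {"1", "true", "yes", "y", "*"}


@dataclass
class NormalizationConfig:
    """Alias maps and vocabulary rules applied while ingesting a table.

    ``category_registry`` maps canonical category labels to a medicinal flag
    (``True`` = medicinal).  When it is empty the vocabulary is open: every
    canonical label is accepted and flagged medicinal unless it is in
    ``nonmedicinal_categories``.  ``market_aliases`` may map a raw market
    token to ``None`` to drop it (for source tokens that are not markets).
    """

    category_aliases: dict[str, str] = field(default_factory=dict)
    family_aliases: dict[str, str] = field(default_factory=dict)
    market_aliases: dict[str, str | None] = field(default_factory=dict)
    nonmedicinal_categories: set[str] = field(
        default_factory=lambda: set(DEFAULT_NONMEDICINAL))
    category_registry: dict[str, bool] = field(default_factory=dict)
    #: family merge map (e.g. legume subfamilies -> Fabaceae); NOT applied at
    #: ingest — pass it to :meth:`MarketSurvey.merge_families` explicitly.
    family_merge: dict[str, str] = field(default_factory=dict)

    def canon_category(self, raw: str) -> str:
        label = self.category_aliases.get(raw.strip(), raw.strip())
        if self.category_registry and label not in self.category_registry:
            raise VocabularyError(
                f"unknown use category {label!r} (not in registry, no alias)")
        return label

    def is_medicinal(self, category: str) -> bool:
        if self.category_registry:
            return self.category_registry[category]
        return category not in self.nonmedicinal_categories

    @classmethod
    def from_yaml(cls, source: str | Path) -> "NormalizationConfig":
        doc = yaml.safe_load(Path(source).read_text(encoding="utf-8")) or {}
        aliases = doc.get("aliases", {})
        registry = doc.get("category_registry", {})
        return cls(
            category_aliases=dict(aliases.get("categories", {})),
            family_aliases=dict(aliases.get("families", {})),
            market_aliases=dict(aliases.get("markets", {})),
            nonmedicinal_categories=set(
                doc.get("nonmedicinal_categories", DEFAULT_NONMEDICINAL)),
            category_registry={str(k): bool(v) for k, v in registry.items()},
            family_merge=dict(doc.get("family_merge", {})),
        )


def _sniff_sep(source) -> str:
    """Choose ',' or tab by inspecting the header line."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            header = fh.readline()
    else:
        header = source.readline()
        source.seek(0)
    return "\t" if "\t" in header else ","


def read_survey(source, config: NormalizationConfig | None = None,
                provenance: str = "") -> MarketSurvey:
    """Read a long-format use-report table into a validated survey.

    Raises :class:`SchemaError` when a required column is missing and
    :class:`VocabularyError` when a category is neither registered nor
    aliased (offenders listed).
    """
    config = config or NormalizationConfig()
    sep = _sniff_sep(source)
    frame = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if frame.empty:
        raise SchemaError("input table has no rows")

    offenders = []
    reports: list[UseReport] = []
    has_flag = "nonmedicinal" in frame.columns
    for row in frame.itertuples(index=False):
        raw_market = str(row.market).strip()
        market = config.market_aliases.get(raw_market, raw_market)
        if market is None:
            logger.info("dropping non-market token %r", raw_market)
            continue
        raw_cat = str(row.category).strip()
        raw_ail = str(row.ailment).strip()
        # an asterisk on the category (or its ailment) marks non-medicinal uses
        starred = raw_cat.endswith("*") or raw_ail.endswith("*")
        raw_cat = raw_cat.rstrip("*").strip()
        raw_ail = raw_ail.rstrip("*").strip()
        try:
            category = config.canon_category(raw_cat)
        except VocabularyError:
            offenders.append(raw_cat)
            continue
        name = canonicalize_binomial(str(row.species))
        family = str(row.family).strip()
        family = config.family_aliases.get(family, family)
        medicinal = config.is_medicinal(category)
        if starred and not config.category_registry:
            medicinal = False
        if has_flag and str(row.nonmedicinal).strip():
            medicinal = str(row.nonmedicinal).strip().lower() not in _TRUTHY
        vern = tuple(v.strip() for v in str(row.vernacular).split("/")
                     if v.strip())
        reports.append(UseReport(
            family=family, species=name.binomial, genus=name.genus,
            vernacular_names=vern, category=category,
            ailment=raw_ail, market=market,
            medicinal=medicinal, qualifier=name.qualifier,
            hybrid=name.hybrid, genus_only=name.genus_only,
        ))
    if offenders:
        raise VocabularyError(
            "unknown use categories (not in registry, no alias): "
            + ", ".join(sorted(set(offenders))))
    return MarketSurvey.from_reports(reports, provenance=provenance)


def write_survey(survey: MarketSurvey, target, sep: str = "\t") -> None:
    """Write a survey back to the long-format interchange table."""
    rows = []
    for r in survey.reports:
        name = r.species
        if r.qualifier or r.hybrid:
            genus, epithet = r.species.split(" ", 1)
            bits = [genus]
            if r.hybrid:
                bits.append("x")
            if r.qualifier:
                bits.append(r.qualifier + ".")
            bits.append(epithet)
            name = " ".join(bits)
        rows.append({
            "family": r.family, "species": name,
            "vernacular": " / ".join(r.vernacular_names),
            "category": r.category, "ailment": r.ailment, "market": r.market,
            "nonmedicinal": "" if r.medicinal else "1",
        })
    pd.DataFrame(rows).to_csv(target, sep=sep, index=False)


def read_group_map(source) -> dict[str, str]:
    """Read a two-column delimited file mapping market -> group label."""
    sep = _sniff_sep(source)
    frame = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise SchemaError("group map needs two columns: market, label")
    cols = frame.columns[:2]
    return dict(zip(frame[cols[0]].str.strip(), frame[cols[1]].str.strip()))
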