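"""Survey data model: use reports, market surveys, and name normalization.

The unit of observation is the *use report*: one species, sold in one market,
recorded for one use (an illness category plus a free-text ailment).  A
species may be filed under more than one family in the source inventory; the
pair ``(family, species)`` is called a *filing* and is the species-accounting
unit, while ``species_index`` keeps a one-to-one species-to-family map
(first filing wins) for operations that need a unique family per binomial.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import ParameterError, VocabularyError

logger = logging.getLogger("ethnomarket")

#: Category labels treated as non-medicinal when no explicit registry is given.
DEFAULT_NONMEDICINAL = frozenset(
    {"Human food", "Animal food", "Toxic", "Cultural", "Cosmetic"}
)

_RANK_QUALIFIERS = {"aff.", "cf."}
_HYBRID_MARKERS = {"x", "×"}
_INFRASPECIFIC = {"var.", "subsp.", "ssp.", "f.", "fo.", "forma"}


@dataclass(frozen=True)
class CanonicalName:
    """A canonical binomial plus the qualifiers stripped from the raw name."""

    binomial: str
    genus: str
    epithet: str
    qualifier: str | None = None  # "aff" or "cf"
    hybrid: bool = False
    genus_only: bool = False

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.binomial

    def raw_style(self) -> str:
        """Re-embed qualifier/hybrid markers, e.g. for round-trip output."""
        parts = [self.genus]
        if self.hybrid:
            parts.append("x")
        if self.qualifier:
            parts.append(self.qualifier + ".")
        parts.append(self.epithet)
        return " ".join(parts)


def canonicalize_binomial(raw_name: str) -> CanonicalName:
    """Normalize a scientific name to ``"Genus epithet"``.

    Authority strings, rank qualifiers (``aff.``, ``cf.``), hybrid markers
    (``x``) and infraspecific ranks are stripped; qualifiers are recorded as
    flags.  A single-token name (``"Caulerpa sp."``) is flagged as a
    genus-level determination with the placeholder epithet ``"sp."``.

    >>> canonicalize_binomial("Espeletia aff. corymbosa Bonpl.").binomial
    'Espeletia corymbosa'
    """
    if not raw_name or not raw_name.strip():
        raise ParameterError("empty scientific name")
    tokens = raw_name.split()
    genus = tokens[0].strip("*").capitalize()
    qualifier: str | None = None
    hybrid = False
    epithet: str | None = None
    for tok in tokens[1:]:
        t = tok.strip("*")
        if t.lower() in _HYBRID_MARKERS:
            hybrid = True
            continue
        if t.lower() in _RANK_QUALIFIERS:
            qualifier = t.lower().rstrip(".")
            continue
        if t.lower() in _INFRASPECIFIC:
            break  # drop infraspecific rank and everything after it
        if t == "sp." or t == "spp.":
            epithet = "sp."
            break
        # the epithet is the first all-lowercase word; anything capitalized,
        # parenthesized or abbreviated belongs to the authority
        if re.fullmatch(r"[a-zà-ÿ-]{2,}", t):
            epithet = t.lower()
            break
        break
    if epithet is None or epithet == "sp.":
        return CanonicalName(
            binomial=f"{genus} sp.", genus=genus, epithet="sp.",
            qualifier=qualifier, hybrid=hybrid, genus_only=True,
        )
    return CanonicalName(
        binomial=f"{genus} {epithet}", genus=genus, epithet=epithet,
        qualifier=qualifier, hybrid=hybrid, genus_only=False,
    )


@dataclass(frozen=True)
class UseReport:
    """One observation: a species sold in one market for one use."""

    family: str
    species: str  # canonical binomial
    genus: str
    vernacular_names: tuple[str, ...]
    category: str
    ailment: str
    market: str
    medicinal: bool
    qualifier: str | None = None
    hybrid: bool = False
    genus_only: bool = False

    def dedup_key(self) -> tuple[str, str, str, str]:
        """Identity used when collapsing duplicate rows.

        Ailments compare case-insensitively after whitespace trimming.
        """
        return (self.species, self.market, self.category,
                self.ailment.strip().casefold())


@dataclass
class MarketSurvey:
    """A validated collection of use reports with its registries."""

    reports: list[UseReport]
    markets: tuple[str, ...]
    filings: tuple[tuple[str, str], ...]  # ordered distinct (family, species)
    species_index: dict[str, str]  # species -> first-listed family
    category_registry: dict[str, bool]  # label -> medicinal flag
    provenance: str = ""
    n_duplicates_dropped: int = 0
    family_conflicts: tuple[tuple[str, str, str], ...] = ()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_reports(
        cls,
        reports: Iterable[UseReport],
        markets: Sequence[str] | None = None,
        provenance: str = "",
    ) -> "MarketSurvey":
        """Validate, deduplicate and index a stream of reports.

        Exact duplicate ``(species, market, category, ailment)`` rows are
        collapsed (count logged).  The first family a species is filed under
        wins in ``species_index``; later conflicting filings are logged and
        retained in ``filings``.
        """
        seen: dict[tuple, UseReport] = {}
        n_dups = 0
        for r in reports:
            key = r.dedup_key()
            if key in seen:
                n_dups += 1
            else:
                seen[key] = r
        deduped = list(seen.values())
        if n_dups:
            logger.info("collapsed %d duplicate use reports", n_dups)

        filings: list[tuple[str, str]] = []
        filing_set: set[tuple[str, str]] = set()
        species_index: dict[str, str] = {}
        conflicts: list[tuple[str, str, str]] = []
        registry: dict[str, bool] = {}
        for r in deduped:
            pair = (r.family, r.species)
            if pair not in filing_set:
                filing_set.add(pair)
                filings.append(pair)
            if r.species not in species_index:
                species_index[r.species] = r.family
            elif species_index[r.species] != r.family:
                conflicts.append((r.species, species_index[r.species], r.family))
            if r.category in registry:
                if registry[r.category] != r.medicinal:
                    raise VocabularyError(
                        f"category {r.category!r} used with inconsistent "
                        "medicinal flags"
                    )
            else:
                registry[r.category] = r.medicinal
        if conflicts:
            uniq = sorted(set(conflicts))
            logger.warning(
                "%d species filed under more than one family (first wins): %s",
                len(uniq), "; ".join(f"{s}: {a} vs {b}" for s, a, b in uniq),
            )
        if markets is None:
            markets = tuple(dict.fromkeys(r.market for r in deduped))
        else:
            markets = tuple(markets)
            missing = {r.market for r in deduped} - set(markets)
            if missing:
                raise VocabularyError(
                    f"reports reference markets absent from the registry: "
                    f"{sorted(missing)}"
                )
        return cls(
            reports=deduped, markets=markets, filings=tuple(filings),
            species_index=species_index, category_registry=registry,
            provenance=provenance, n_duplicates_dropped=n_dups,
            family_conflicts=tuple(sorted(set(conflicts))),
        )

    # -- views ------------------------------------------------------------

    @property
    def species(self) -> tuple[str, ...]:
        """Distinct canonical binomials, in first-seen order."""
        return tuple(dict.fromkeys(s for _, s in self.filings))

    def __len__(self) -> int:
        return len(self.reports)

    # -- transformations ---------------------------------------------------

    def filter_medicinal(self) -> "MarketSurvey":
        """Keep only medicinal reports; the market registry is unchanged."""
        kept = [r for r in self.reports if r.medicinal]
        if not kept:
            logger.warning("no medicinal reports remain after filtering")
        out = MarketSurvey.from_reports(kept, markets=self.markets,
                                        provenance=self.provenance)
        return out

    def merge_families(self, merge_map: Mapping[str, str]) -> "MarketSurvey":
        """Rewrite family labels through an idempotent merge map."""
        for src, dst in merge_map.items():
            if dst in merge_map and merge_map[dst] != dst:
                raise ParameterError(
                    f"family merge map is chained or cyclic at {src!r} -> "
                    f"{dst!r} -> {merge_map[dst]!r}"
                )
        if not merge_map:
            return self
        new = [replace(r, family=merge_map.get(r.family, r.family))
               for r in self.reports]
        return MarketSurvey.from_reports(new, markets=self.markets,
                                         provenance=self.provenance)


#: Default family merge: the three legume subfamily headings -> Fabaceae.
LEGUME_MERGE = {
    "Leguminosae-Caesalpinioideae": "Fabaceae",
    "Leguminosae-Mimosoideae": "Fabaceae",
    "Leguminosae-Papilionoideae": "Fabaceae",
}


def filter_medicinal(survey: MarketSurvey) -> MarketSurvey:
    """Functional alias for :meth:`MarketSurvey.filter_medicinal`."""
    return survey.filter_medicinal()


def merge_families(survey: MarketSurvey,
                   merge_map: Mapping[str, str]) -> MarketSurvey:
    """Functional alias for :meth:`MarketSurvey.merge_families`."""
    return survey.merge_families(merge_map)
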