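"""Descriptive summaries: taxon counts and ranked frequency tables.

Counting conventions
--------------------
The species-accounting unit is the *filing*: a distinct (as-filed family,
canonical binomial) pair.  A species legitimately filed under two families
counts once per family; ``n_distinct_binomials`` reports the stricter count.
Percentages are kept exact internally; ``round_half_up`` is applied only at
presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .model import MarketSurvey


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 10.45 -> 10.5), for table presentation."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TaxonSummary:
    n_species: int
    n_genera: int
    n_families: int
    n_markets: int
    n_medicinal_species: int
    #: species counted once even when filed under two families
    n_distinct_binomials: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def count_taxa(survey: MarketSurvey) -> TaxonSummary:
    """Count species filings, genera, families and markets.

    Genera are distinct first tokens of the canonical binomials; families are
    the distinct as-filed labels (after whatever merge has been applied to
    the survey).  Medicinal species are filings with at least one medicinal
    report.
    """
    filings = survey.filings
    binomials = {s for _, s in filings}
    med_filings = {(r.family, r.species) for r in survey.reports if r.medicinal}
    return TaxonSummary(
        n_species=len(filings),
        n_genera=len({s.split()[0] for s in binomials}),
        n_families=len({f for f, _ in filings}),
        n_markets=len(survey.markets),
        n_medicinal_species=len(med_filings),
        n_distinct_binomials=len(binomials),
    )


def _ranked(counts: dict[str, int], base: int, base_name: str) -> pd.DataFrame:
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    frame = pd.DataFrame(rows, columns=["label", "n_species"])
    frame["pct"] = 100.0 * frame["n_species"] / base if base else 0.0
    frame.attrs["base"] = base_name
    frame.attrs["base_n"] = base
    return frame


def family_table(survey: MarketSurvey) -> pd.DataFrame:
    """Species filings per family, ranked; percentage base = all species.

    Apply any configured family merge (e.g. legume subfamilies -> Fabaceae)
    to the survey before calling.
    """
    counts: dict[str, int] = {}
    for fam, _ in survey.filings:
        counts[fam] = counts.get(fam, 0) + 1
    return _ranked(counts, len(survey.filings), "all species")


def category_table(survey: MarketSurvey) -> pd.DataFrame:
    """Distinct medicinal species per use category, ranked.

    Percentage base = number of medicinal species; non-medicinal reports are
    ignored, so the result is the same whether or not the survey was already
    filtered to medicinal reports.
    """
    med = [r for r in survey.reports if r.medicinal]
    per_cat: dict[str, set] = {}
    for r in med:
        per_cat.setdefault(r.category, set()).add((r.family, r.species))
    n_med = len({(r.family, r.species) for r in med})
    return _ranked({c: len(s) for c, s in per_cat.items()}, n_med,
                   "medicinal species")


def ailment_table(survey: MarketSurvey) -> pd.DataFrame:
    """Distinct medicinal species per ailment label, ranked.

    Ailment labels are normalized case-insensitively after whitespace
    trimming (no stemming); the first-seen spelling is displayed.  Empty
    ailment strings (category-only records) are excluded.
    """
    med = [r for r in survey.reports if r.medicinal]
    display: dict[str, str] = {}
    per_ail: dict[str, set] = {}
    for r in med:
        key = r.ailment.strip().casefold()
        if not key:
            continue
        display.setdefault(key, r.ailment.strip())
        per_ail.setdefault(key, set()).add((r.family, r.species))
    n_med = len({(r.family, r.species) for r in med})
    return _ranked({display[k]: len(s) for k, s in per_ail.items()}, n_med,
                   "medicinal species")
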