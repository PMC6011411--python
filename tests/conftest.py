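import logging

import numpy as np
import pytest

from ethnomarket import MarketSurvey, UseReport, load_bogota_survey

logging.getLogger("ethnomarket").setLevel(logging.ERROR)


def make_report(species="Aloe vera", market="M1", category="Digestive system",
                ailment="Indigestion", family="Asphodelaceae",
                medicinal=True, vernacular=("sabila",)):
    return UseReport(
        family=family, species=species, genus=species.split()[0],
        vernacular_names=tuple(vernacular), category=category,
        ailment=ailment, market=market, medicinal=medicinal,
    )


def make_survey(rows, markets=None):
    """Build a survey from (species, market, use) or full-kwarg rows."""
    reports = []
    for row in rows:
        if isinstance(row, dict):
            reports.append(make_report(**row))
        else:
            species, market, ailment = row
            reports.append(make_report(species=species, market=market,
                                       ailment=ailment))
    return MarketSurvey.from_reports(reports, markets=markets)


def random_toy_survey(rng, max_species=6, max_markets=6, max_uses=6):
    """A random small survey for oracle-vs-implementation checks."""
    n_sp = int(rng.integers(1, max_species + 1))
    n_mk = int(rng.integers(1, max_markets + 1))
    n_use = int(rng.integers(1, max_uses + 1))
    species = [f"Genus{i} sp{chr(ord('a') + i)}" for i in range(n_sp)]
    markets = [f"M{j}" for j in range(n_mk)]
    uses = [f"ailment{k}" for k in range(n_use)]
    rows = []
    for s in species:
        for m in markets:
            for u in uses:
                if rng.random() < 0.35:
                    rows.append((s, m, u))
    if not rows:
        rows.append((species[0], markets[0], uses[0]))
    return make_survey(rows, markets=markets)


@pytest.fixture(scope="session")
def bogota():
    return load_bogota_survey()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140)
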