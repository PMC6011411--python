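"""Informant consensus: worked examples, degenerate conventions, and a
brute-force oracle over random small surveys."""

import math

import numpy as np
import pytest

from ethnomarket import lic_threshold, species_lic, use_consensus
from ethnomarket.errors import ParameterError

from conftest import make_survey, random_toy_survey


def brute_force_lic(survey):
    """Naive tally over (species, market, use) tuples, independent of the
    implementation: evaluates ICu and the per-species sum term by term."""
    tuples = {(r.species, r.market, r.ailment.strip().casefold())
              for r in survey.reports}
    uses = {u for _, _, u in tuples}
    icu = {}
    for u in uses:
        occs = [(s, m) for s, m, uu in tuples if uu == u]
        fcu = len(occs)
        nsu = len({s for s, _ in occs})
        icu[u] = (fcu - nsu) / (fcu - 1) if fcu > 1 else 0.0
    scores = {}
    for s in {s for s, _, _ in tuples}:
        total = 0.0
        for u in uses:
            fcus = len({m for ss, m, uu in tuples if ss == s and uu == u})
            if fcus:
                total += icu[u] * math.log(fcus)
        scores[s] = total
    return scores


class TestUseConsensus:
    def test_two_species_four_occurrences(self):
        # use reported by 2 species over 4 (species, market) pairs
        survey = make_survey([
            ("Aloe vera", "M1", "flu"), ("Aloe vera", "M2", "flu"),
            ("Ruta graveolens", "M1", "flu"), ("Ruta graveolens", "M3", "flu"),
        ])
        (rec,) = use_consensus(survey)
        assert (rec.FCu, rec.NSu) == (4, 2)
        assert rec.ICu == pytest.approx(2 / 3)

    def test_single_occurrence_has_zero_consensus(self):
        survey = make_survey([("Aloe vera", "M1", "flu")])
        (rec,) = use_consensus(survey)
        assert rec.FCu == 1 and rec.ICu == 0.0

    def test_all_distinct_species_zero_consensus(self):
        survey = make_survey([(f"Genus{i} spa", "M1", "flu")
                              for i in range(4)])
        (rec,) = use_consensus(survey)
        assert rec.FCu == rec.NSu == 4
        assert rec.ICu == 0.0

    def test_vendor_duplicates_count_once_per_market(self):
        # duplicate (species, market, use) rows collapse: markets are the
        # occurrence unit
        survey = make_survey([("Aloe vera", "M1", "flu"),
                              ("Aloe vera", "M1", "Flu ")])
        (rec,) = use_consensus(survey)
        assert rec.FCu == 1

    def test_new_species_never_raises_consensus(self, rng):
        for _ in range(50):
            survey = random_toy_survey(rng, max_species=4, max_markets=4,
                                       max_uses=3)
            recs = {r.use: r for r in use_consensus(survey)}
            target = next((u for u, r in recs.items() if r.FCu > 1), None)
            if target is None:
                continue
            extra = make_survey([("Zzz novum", "M0", target)])
            grown = make_survey(
                [(r.species, r.market, r.ailment) for r in survey.reports]
                + [("Zzz novum", "M0", target)])
            after = {r.use: r for r in use_consensus(grown)}
            assert after[target].ICu <= recs[target].ICu + 1e-12

    def test_invalid_level_rejected(self, rng):
        with pytest.raises(ParameterError):
            use_consensus(random_toy_survey(rng), level="species")


class TestSpeciesLic:
    def test_single_use_single_market_scores_zero(self):
        survey = make_survey([("Aloe vera", "M1", "flu")])
        table = species_lic(survey)
        assert table.scores["lic"].iloc[0] == 0.0

    def test_worked_toy(self):
        # use u1: FCu=4 (s in 3 markets + other species once), NSu=2 -> ICu=2/3
        # s also has a singleton use -> contributes 0
        survey = make_survey([
            ("Salvia carnea", "M1", "u1"), ("Salvia carnea", "M2", "u1"),
            ("Salvia carnea", "M3", "u1"), ("Other spa", "M1", "u1"),
            ("Salvia carnea", "M1", "u2"),
        ])
        table = species_lic(survey)
        s = table.scores.set_index("species")["lic"]
        assert s["Salvia carnea"] == pytest.approx((2 / 3) * math.log(3))
        assert s["Other spa"] == pytest.approx((2 / 3) * math.log(1))

    def test_matches_bruteforce_on_random_toys(self, rng):
        for _ in range(60):
            survey = random_toy_survey(rng)
            expected = brute_force_lic(survey)
            got = species_lic(survey).scores.set_index("species")["lic"]
            for species, value in expected.items():
                assert got[species] == pytest.approx(value, abs=1e-12)

    def test_doubling_markets_increases_scores(self, rng):
        base = [("Salvia carnea", "M1", "u1"), ("Salvia carnea", "M2", "u1"),
                ("Other spa", "M1", "u1"), ("Other spa", "M2", "u2")]
        doubled = base + [(s, m + "_copy", u) for s, m, u in base]
        s1 = species_lic(make_survey(base)).scores.set_index("species")["lic"]
        s2 = species_lic(make_survey(doubled)).scores.set_index("species")["lic"]
        # every FCus doubles; scores with any consensual use strictly increase
        assert s2["Salvia carnea"] > s1["Salvia carnea"]

    def test_adding_market_occurrence_never_decreases(self):
        # fixing ICu by construction: one shared use between two species
        base = [("Salvia carnea", "M1", "u1"), ("Salvia carnea", "M2", "u1"),
                ("Other spa", "M3", "u1"), ("Other spa", "M4", "u1")]
        grown = base + [("Salvia carnea", "M5", "u1"),
                        ("Other spa", "M5", "u1")]
        s1 = species_lic(make_survey(base)).scores.set_index("species")["lic"]
        s2 = species_lic(make_survey(grown)).scores.set_index("species")["lic"]
        assert (s2 >= s1 - 1e-12).all()

    def test_relabeling_invariance(self, rng):
        survey = random_toy_survey(rng)
        remap_m = {m: f"X{m}" for m in survey.markets}
        relabeled = make_survey(
            [(r.species, remap_m[r.market], r.ailment)
             for r in survey.reports],
            markets=[remap_m[m] for m in survey.markets])
        a = species_lic(survey).scores.set_index("species")["lic"]
        b = species_lic(relabeled).scores.set_index("species")["lic"]
        assert a.sort_index().round(12).equals(b.sort_index().round(12))


class TestLicThreshold:
    def test_all_equal_scores_empty_exceedance(self):
        survey = make_survey([(f"Genus{i} spa", "M1", f"u{i}")
                              for i in range(5)])
        table = species_lic(survey)
        top = lic_threshold(table, 0.95)
        assert top.scores.empty

    def test_order_statistic_interpolation(self):
        import pandas as pd
        from ethnomarket.consensus import ConsensusTable
        scores = pd.DataFrame({"species": [f"s{i}" for i in range(20)],
                               "lic": np.arange(20.0),
                               "n_uses": 1, "n_markets": 1})
        table = ConsensusTable(scores=scores, detail=pd.DataFrame(
            columns=["species", "use", "FCus", "ICu", "term"]),
            level="ailment")
        top = lic_threshold(table, 0.95)
        assert top.threshold == pytest.approx(18.05)
        assert list(top.scores["species"]) == ["s19"]

    def test_invalid_percentile(self, rng):
        table = species_lic(random_toy_survey(rng))
        with pytest.raises(ParameterError):
            lic_threshold(table, 1.5)
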