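"""Incidence matrices, shared/unique decomposition, unique-use percentages
and Euclidean market distances."""

import itertools

import numpy as np
import pytest

from ethnomarket import (euclidean_distances, incidence_matrix,
                         plant_space_matrix, shared_unique,
                         unique_use_percent)
from ethnomarket.comparison import widespread_species
from ethnomarket.errors import ParameterError

from conftest import make_survey, random_toy_survey


class TestIncidenceMatrix:
    def test_one_species_two_markets(self):
        survey = make_survey([("Aloe vera", "M1", "flu"),
                              ("Aloe vera", "M2", "flu")])
        for level in ("species", "use"):
            mat = incidence_matrix(survey, level)
            assert mat.frame.shape == (2, 1)
            assert (mat.frame.to_numpy() == 1).all()

    def test_disjoint_toy_layout(self):
        survey = make_survey([("Aaa spa", "M1", "u"), ("Bbb spb", "M2", "u")],
                             markets=["M1", "M2", "M3"])
        mat = incidence_matrix(survey, "species")
        assert mat.frame.shape == (3, 2)
        assert mat.frame.to_numpy().sum() == 2
        assert list(mat.frame.columns) == ["Aaa spa", "Bbb spb"]

    def test_unknown_level_rejected(self, rng):
        with pytest.raises(ParameterError):
            incidence_matrix(random_toy_survey(rng), "vendor")

    def test_use_level_marginalizes_to_species_level(self, rng):
        for _ in range(20):
            survey = random_toy_survey(rng)
            sp = incidence_matrix(survey, "species").frame
            use = incidence_matrix(survey, "use").frame
            marginal = (use.T.groupby(
                use.columns.str.split("::").str[0]).max().T)
            assert marginal.sort_index(axis=1).equals(
                sp.sort_index(axis=1).astype(marginal.dtypes.iloc[0]))

    def test_binary_entries_and_no_empty_columns(self, rng):
        survey = random_toy_survey(rng)
        for level in ("species", "use", "category"):
            mat = incidence_matrix(survey, level).frame
            assert set(np.unique(mat.to_numpy())) <= {0, 1}
            assert (mat.sum(axis=0) > 0).all()

    def test_plant_space_concatenates(self, rng):
        survey = random_toy_survey(rng)
        ps = plant_space_matrix(survey)
        n_sp = incidence_matrix(survey, "species").frame.shape[1]
        n_use = incidence_matrix(survey, "use").frame.shape[1]
        assert ps.frame.shape[1] == n_sp + n_use


class TestSharedUnique:
    def test_identical_markets(self):
        survey = make_survey([("Aloe vera", m, "flu") for m in ("M1", "M2")]
                             + [("Ruta graveolens", m, "x")
                                for m in ("M1", "M2")])
        dec = shared_unique(incidence_matrix(survey, "species"))
        assert all(len(v) == 0 for v in dec.unique_items.values())
        assert dec.shared_counts.loc["M1", "M2"] == 2

    def test_disjoint_markets(self):
        survey = make_survey([("Aaa spa", "M1", "u"), ("Bbb spb", "M2", "u")])
        dec = shared_unique(incidence_matrix(survey, "species"))
        assert dec.proportion_unique.tolist() == [1.0, 1.0]
        assert dec.shared_counts.loc["M1", "M2"] == 0

    def test_ubiquitous_plus_singleton(self):
        survey = make_survey(
            [("Aaa spa", m, "u") for m in ("M1", "M2", "M3")]
            + [("Bbb spb", "M1", "u")])
        dec = shared_unique(incidence_matrix(survey, "species"))
        assert dec.proportion_unique["M1"] == pytest.approx(0.5)
        assert dec.unique_items["M1"] == ["Bbb spb"]

    def test_pairwise_partition_property(self, rng):
        for _ in range(20):
            mat = incidence_matrix(random_toy_survey(rng), "species").frame
            for i, j in itertools.combinations(mat.index, 2):
                a, b = mat.loc[i].to_numpy(), mat.loc[j].to_numpy()
                shared = int((a & b).sum())
                only_i = int((a & ~b).sum())
                only_j = int((b & ~a).sum())
                union = int((a | b).sum())
                assert shared + only_i + only_j == union


class TestUniqueUsePercent:
    def test_half_unique_worked_case(self):
        survey = make_survey([("Aloe vera", "M1", "a"), ("Aloe vera", "M1", "b"),
                              ("Aloe vera", "M2", "b"), ("Aloe vera", "M2", "c")])
        prof = unique_use_percent(survey).set_index("market")
        assert prof.loc["M1", "pct_unique"] == pytest.approx(50.0)
        assert prof.loc["M2", "pct_unique"] == pytest.approx(50.0)

    def test_identical_use_sets_zero_percent(self):
        survey = make_survey([("Aloe vera", m, u) for m in ("M1", "M2")
                              for u in ("a", "b")])
        prof = unique_use_percent(survey)
        assert (prof["pct_unique"] == 0).all()

    def test_single_market_species_excluded(self):
        survey = make_survey([("Aloe vera", "M1", "a"),
                              ("Ruta graveolens", "M1", "b"),
                              ("Ruta graveolens", "M2", "b")])
        prof = unique_use_percent(survey)
        assert "Aloe vera" not in set(prof["species"])


class TestEuclideanDistances:
    def test_identical_rows_zero(self):
        survey = make_survey([("Aloe vera", m, "flu") for m in ("M1", "M2")])
        dm = euclidean_distances(incidence_matrix(survey, "species"))
        assert dm["M1", "M2"] == 0.0

    def test_three_market_hand_case(self):
        # rows (1,0), (0,1), (1,1)
        survey = make_survey([("Aaa spa", "M1", "u"), ("Bbb spb", "M2", "u"),
                              ("Aaa spa", "M3", "u"), ("Bbb spb", "M3", "u")])
        dm = euclidean_distances(incidence_matrix(survey, "species"))
        assert dm["M1", "M2"] == pytest.approx(np.sqrt(2))
        assert dm["M1", "M3"] == pytest.approx(1.0)
        assert dm["M2", "M3"] == pytest.approx(1.0)

    def test_squared_distance_equals_hamming_exhaustive(self):
        # all pairs of binary rows of length 4
        rows = list(itertools.product([0, 1], repeat=4))
        x = np.array(rows, dtype=float)
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(x))
        for i, j in itertools.combinations(range(len(rows)), 2):
            hamming = sum(a != b for a, b in zip(rows[i], rows[j]))
            assert d[i, j] ** 2 == pytest.approx(hamming)

    def test_squared_equals_hamming_on_surveys(self, rng):
        for _ in range(10):
            mat = incidence_matrix(random_toy_survey(rng), "species")
            if len(mat.markets) < 2:
                continue
            dm = euclidean_distances(mat)
            x = mat.frame.to_numpy()
            for i, j in itertools.combinations(range(len(mat.markets)), 2):
                assert dm.data[i, j] ** 2 == pytest.approx(
                    int((x[i] != x[j]).sum()))

    def test_single_market_rejected(self):
        survey = make_survey([("Aloe vera", "M1", "flu")])
        with pytest.raises(ParameterError):
            euclidean_distances(incidence_matrix(survey, "species"))

    def test_concatenation_mode(self, rng):
        survey = random_toy_survey(rng)
        if len(survey.markets) < 2:
            survey = make_survey([("Aaa spa", "M1", "u"),
                                  ("Bbb spb", "M2", "u")])
        parts = [incidence_matrix(survey, "species"),
                 incidence_matrix(survey, "use")]
        dm = euclidean_distances(parts)
        dm2 = euclidean_distances(plant_space_matrix(survey))
        assert np.allclose(dm.data, dm2.data)


class TestWidespread:
    def test_top_k_with_alphabetical_ties(self):
        survey = make_survey(
            [("Bbb spb", m, "u") for m in ("M1", "M2")]
            + [("Aaa spa", m, "u") for m in ("M1", "M2")]
            + [("Ccc spc", "M1", "u")])
        top = widespread_species(survey, k=2)
        assert list(top["species"]) == ["Aaa spa", "Bbb spb"]
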