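"""Synthetic market-survey generator.

Emulates the statistical structure of a metropolitan medicinal-plant market
inventory: a fixed species pool with skewed (Zipf-weighted) occurrence
frequencies, markets that mix draws from a shared pool with draws from a
market-private pool (the ``overlap`` dial), a category -> ailment use
hierarchy, and an optional geographic group structure for power studies.
All randomness flows through one :class:`numpy.random.Generator` seeded from
the config, so a survey is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .errors import ParameterError, SizingError
from .model import DEFAULT_NONMEDICINAL, MarketSurvey, UseReport

_NONMED_LABELS = tuple(sorted(DEFAULT_NONMEDICINAL))


def _letters(i: int, width: int = 4) -> str:
    """Deterministic alphabetic id (base-26), e.g. 0 -> 'aaaa'."""
    out = []
    for _ in range(width):
        i, r = divmod(i, 26)
        out.append(chr(ord("a") + r))
    return "".join(reversed(out))


@dataclass
class SyntheticConfig:
    """Parameters of the generator; defaults are inventory-scale-free."""

    n_markets: int = 24
    n_species_pool: int = 500
    n_families: int = 60
    n_categories_medicinal: int = 19
    n_ailments: int = 240
    mean_species_per_market: float = 30.0
    overlap: float = 0.7  # probability a draw comes from the shared pool
    zipf_exponent: float = 1.0
    p_nonmedicinal: float = 0.05
    uses_per_species_market: float = 3.0
    n_groups: int = 1
    divergence: float = 0.0  # between-group pool separation in [0, 1]
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_markets", "n_species_pool", "n_families",
                     "n_categories_medicinal", "n_ailments", "n_groups"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive count")
        for name in ("overlap", "p_nonmedicinal", "divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.zipf_exponent < 0:
            raise ParameterError("zipf_exponent must be >= 0")
        if self.mean_species_per_market <= 0:
            raise ParameterError("mean_species_per_market must be positive")
        if self.uses_per_species_market < 1:
            raise ParameterError("uses_per_species_market must be >= 1")
        if self.n_groups > self.n_markets:
            raise ParameterError("more groups than markets")

    # -- pool sizing -------------------------------------------------------
    #
    # Half the species pool is reserved for market-private blocks and half
    # for the shared pool, independent of ``overlap`` — so raising the
    # overlap dial changes only where draws come from, not the pool geometry.

    def private_pool_size(self) -> int:
        """Species reserved per market for private draws."""
        return int(self.n_species_pool // (2 * self.n_markets))

    def shared_pool_size(self) -> int:
        return self.n_species_pool - self.n_markets * self.private_pool_size()

    def check_feasible(self) -> None:
        self.validate()
        priv_demand = self.mean_species_per_market * (1.0 - self.overlap)
        if priv_demand > self.private_pool_size():
            raise SizingError(
                f"expected private draws per market ({priv_demand:.1f}) "
                f"exceed the private block ({self.private_pool_size()}); "
                "raise n_species_pool, raise overlap or lower "
                "mean_species_per_market")
        # shared draws saturate gracefully: a market asking for more shared
        # species than the (group) block holds simply draws the whole block


def bogota_preset() -> SyntheticConfig:
    """Scale anchors of the Bogotá inventory: 24 markets, a ~400-species
    pool, 19 medicinal categories, skewed occupancy and high per-market
    uniqueness."""
    return SyntheticConfig(
        n_markets=24, n_species_pool=400, n_families=120,
        n_categories_medicinal=19, n_ailments=300,
        mean_species_per_market=42.0, overlap=0.85, zipf_exponent=1.0,
        p_nonmedicinal=0.05, uses_per_species_market=3.0, seed=2014,
    )


# -- internals -------------------------------------------------------------

class _Vocabulary:
    """Species pool, taxonomy and use hierarchy, built deterministically."""

    def __init__(self, cfg: SyntheticConfig, rng: np.random.Generator):
        n = cfg.n_species_pool
        # genera: ~0.8 per species, each genus fixed to one family so the
        # taxonomy is conflict-free
        n_genera = max(1, int(round(0.8 * n)))
        fam_w = 1.0 / np.arange(1, cfg.n_families + 1)
        fam_w /= fam_w.sum()
        genus_family = rng.choice(cfg.n_families, size=n_genera, p=fam_w)
        species_genus = rng.integers(0, n_genera, size=n)
        self.genus_names = [f"{_letters(i).capitalize()}genus"
                            for i in range(n_genera)]
        self.family_names = [f"Family{_letters(i, 3)}"
                             for i in range(cfg.n_families)]
        self.species_binomial = [
            f"{self.genus_names[species_genus[i]]} sp{_letters(i)}"
            for i in range(n)]
        self.species_family = [
            self.family_names[genus_family[species_genus[i]]]
            for i in range(n)]

        # use hierarchy: category-prefixed ailment tokens
        self.med_categories = [f"Medicinal category {i + 1:02d}"
                               for i in range(cfg.n_categories_medicinal)]
        n_cats = cfg.n_categories_medicinal + len(_NONMED_LABELS)
        per_cat = max(1, math.ceil(cfg.n_ailments / n_cats))
        self.ailments = {
            cat: [f"c{k + 1:02d} ailment {j + 1:03d}" for j in range(per_cat)]
            for k, cat in enumerate(self.med_categories + list(_NONMED_LABELS))
        }
        cat_w = 1.0 / np.arange(1, cfg.n_categories_medicinal + 1) ** 0.7
        self.med_cat_weights = cat_w / cat_w.sum()

        # per-species use repertoire: the uses a species CAN be sold for;
        # twice the per-market mean so repertoires recur across markets
        rep_mean = 2.0 * cfg.uses_per_species_market
        self.repertoire: list[list[tuple[str, str]]] = []
        for _ in range(n):
            size = 1 + rng.poisson(rep_mean - 1.0)
            seen: dict[tuple[str, str], None] = {}
            for _ in range(size * 3):
                if len(seen) >= size:
                    break
                if rng.random() < cfg.p_nonmedicinal:
                    cat = _NONMED_LABELS[rng.integers(len(_NONMED_LABELS))]
                else:
                    cat = self.med_categories[
                        rng.choice(cfg.n_categories_medicinal,
                                   p=self.med_cat_weights)]
                ail = self.ailments[cat][rng.integers(len(self.ailments[cat]))]
                seen[(cat, ail)] = None
            self.repertoire.append(list(seen))


def _weighted_sample_without_replacement(
        rng: np.random.Generator, pool: np.ndarray, weights: np.ndarray,
        k: int) -> np.ndarray:
    """Gumbel top-k trick: Zipf-weighted sampling without replacement."""
    if k >= len(pool):
        return pool
    g = np.log(weights) + rng.gumbel(size=len(pool))
    return pool[np.argpartition(-g, k)[:k]]


def _build_reports(cfg: SyntheticConfig, rng: np.random.Generator,
                   vocab: _Vocabulary, market_species: dict[str, np.ndarray]
                   ) -> list[UseReport]:
    reports: list[UseReport] = []
    for market, species_ids in market_species.items():
        for sid in species_ids:
            rep = vocab.repertoire[int(sid)]
            n_uses = min(len(rep), 1 + rng.poisson(
                cfg.uses_per_species_market - 1.0))
            idx = rng.choice(len(rep), size=n_uses, replace=False)
            binomial = vocab.species_binomial[int(sid)]
            for j in idx:
                cat, ail = rep[int(j)]
                reports.append(UseReport(
                    family=vocab.species_family[int(sid)],
                    species=binomial, genus=binomial.split()[0],
                    vernacular_names=(), category=cat, ailment=ail,
                    market=market, medicinal=cat not in DEFAULT_NONMEDICINAL,
                ))
    return reports


def _market_names(cfg: SyntheticConfig) -> list[str]:
    return [f"Market {i + 1:02d}" for i in range(cfg.n_markets)]


def _draw_market_species(cfg: SyntheticConfig, rng: np.random.Generator,
                         group_of: list[int]) -> dict[str, np.ndarray]:
    """Assign species to markets: shared (Zipf) + private mixture."""
    n_priv = cfg.private_pool_size()
    shared_size = cfg.shared_pool_size()
    shared = np.arange(shared_size)
    zipf_w = 1.0 / np.arange(1, shared_size + 1) ** cfg.zipf_exponent \
        if shared_size else np.empty(0)

    # group structure: the first round(shared*(1-divergence)) species are
    # common to all groups; the rest is split into equal group blocks
    n_groups = max(group_of) + 1 if group_of else 1
    if n_groups > 1 and cfg.divergence > 0 and shared_size:
        n_common = int(round(shared_size * (1.0 - cfg.divergence)))
        block = (shared_size - n_common) // n_groups
        group_pool = {
            g: np.concatenate([shared[:n_common],
                               shared[n_common + g * block:
                                      n_common + (g + 1) * block]])
            for g in range(n_groups)}
    else:
        group_pool = {g: shared for g in range(n_groups)}

    out: dict[str, np.ndarray] = {}
    names = _market_names(cfg)
    for m, market in enumerate(names):
        k = max(1, int(rng.poisson(cfg.mean_species_per_market)))
        n_priv_draw = int(rng.binomial(k, 1.0 - cfg.overlap)) if cfg.overlap < 1 else 0
        n_priv_draw = min(n_priv_draw, n_priv)
        pool_g = group_pool[group_of[m]]
        # overflow beyond the private block spills into the shared pool,
        # except at overlap 0 where markets must stay disjoint
        n_shared_draw = (min(k - n_priv_draw, len(pool_g))
                         if cfg.overlap > 0 else 0)
        chosen = []
        if n_shared_draw:
            w = zipf_w[pool_g]
            chosen.append(_weighted_sample_without_replacement(
                rng, pool_g, w / w.sum(), n_shared_draw))
        if n_priv_draw:
            lo = shared_size + m * n_priv
            chosen.append(lo + rng.choice(n_priv, size=n_priv_draw,
                                          replace=False))
        if not chosen:
            raise SizingError(f"market {market}: no species could be drawn")
        out[market] = np.concatenate(chosen)
    return out


# -- public API ------------------------------------------------------------

def generate_survey(config: SyntheticConfig) -> MarketSurvey:
    """Generate a validated synthetic survey, deterministic given the seed."""
    config.check_feasible()
    rng = np.random.default_rng(config.seed)
    vocab = _Vocabulary(config, rng)
    market_species = _draw_market_species(
        config, rng, group_of=[0] * config.n_markets)
    reports = _build_reports(config, rng, vocab, market_species)
    return MarketSurvey.from_reports(
        reports, markets=_market_names(config),
        provenance=f"synthetic survey (seed={config.seed})")


def generate_grouped_survey(config: SyntheticConfig
                            ) -> tuple[MarketSurvey, dict[str, str]]:
    """Generate a survey with geographic group structure; returns the true
    group labels for recovery/power studies.

    Markets are partitioned into ``config.n_groups`` contiguous blocks.
    ``divergence`` scales how much of the shared pool is group-exclusive:
    0 means the labels carry no signal, 1 means groups share nothing beyond
    private noise.  With one group this reduces exactly to
    :func:`generate_survey`.
    """
    config.check_feasible()
    names = _market_names(config)
    group_of = [i * config.n_groups // config.n_markets
                for i in range(config.n_markets)]
    labels = {names[i]: f"G{group_of[i] + 1}" for i in range(config.n_markets)}
    if config.n_groups == 1:
        return generate_survey(config), labels
    rng = np.random.default_rng(config.seed)
    vocab = _Vocabulary(config, rng)
    market_species = _draw_market_species(config, rng, group_of)
    reports = _build_reports(config, rng, vocab, market_species)
    survey = MarketSurvey.from_reports(
        reports, markets=names,
        provenance=(f"synthetic grouped survey (seed={config.seed}, "
                    f"g={config.n_groups}, divergence={config.divergence})"))
    return survey, labels
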