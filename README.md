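# ethnomarket

Quantitative analysis of medicinal-plant market surveys: from long-format
use reports to taxonomic and use summaries, logarithmic informant consensus
(LIC) scores, incidence-based market comparison, principal coordinates
ordination and permutation tests — with a synthetic-survey generator so the
whole pipeline can be exercised and calibrated without any external data.

The package is written for quantitative ethnobotanists working with market
inventories: tables that record, for each plant species, the market stalls
where it is sold, the illness categories and ailments it is sold for, and
whether a use is medicinal. It ships a verbatim transcription of a large
metropolitan inventory — 24 food-supply markets in Bogotá, Colombia, with
409 species filings in 123 plant families sold for 19 categories of
illnesses — as a packaged dataset and reference point.

## The statistics

**Use reports and incidence.** The unit of observation is the use report
`(species, market, category, ailment)`. Markets are compared through binary
markets × items incidence matrices at three levels: *plant species*
(binomials), *plant uses* (species–ailment pairs) and *plant categories*
(species–category pairs). Between-market difference is the Euclidean
distance between incidence rows; for binary data its square is the number
of items found in exactly one of the two markets.

**Informant consensus.** With markets as "occurrences" (a species–market
pair counts once for a use regardless of how many vendors report it), each
use *u* gets

    ICu = (FCu − NSu) / (FCu − 1)

where `FCu` is the total number of occurrences of the use and `NSu` the
number of distinct species reported for it: 1 when all occurrences converge
on one species, 0 when every occurrence names a different species (and 0 by
convention when `FCu = 1`). Each species *s* is then ranked by

    LICs = Σu  ICu · ln(FCus)

summing over the species' uses, with `FCus` the number of markets reporting
species *s* for use *u*. Species above the 95th percentile of LIC are the
market pharmacopoeia's consensus core.

**Ordination and tests.** Markets are ordinated by principal coordinates
analysis (double-centering of squared distances, eigendecomposition) in
"plant-space" (species + use columns). Whether a grouping (e.g. geographic
zones) explains composition is tested with a PERMANOVA-style pseudo-F on
the distance matrix; association with market size with a Mantel-style
permutation correlation. Permutation p-values use the add-one convention
and are reproducible given a seed.

## Worked example

```python
import ethnomarket as em

survey = em.load_bogota_survey()          # packaged transcription
print(em.count_taxa(survey))
# TaxonSummary(n_species=409, n_genera=319, n_families=123, n_markets=24,
#              n_medicinal_species=402, n_distinct_binomials=405)

merged = survey.merge_families(em.LEGUME_MERGE)
print(em.family_table(merged).head(3))
#      label  n_species  pct
#   Fabaceae         43 10.5
# Asteraceae         34  8.3
#  Lamiaceae         24  5.9

mat = em.incidence_matrix(survey, "species")
print(em.shared_unique(mat).proportion_unique.mean())   # ≈ 0.19
```

409 species filings (four species are filed under two families; 405
distinct binomials) across 24 markets; 402 species have at least one
medicinal use, sold for 19 illness categories. On average 19% of a market's
species are found in no other market — the markets are strikingly
individual.

Consensus scores need use-by-market occurrences, which the published
inventory does not record (see `docs/methods.md`), so the LIC machinery is
demonstrated on a synthetic survey of the same scale:

```python
syn = em.generate_survey(em.bogota_preset()).filter_medicinal()
table = em.species_lic(syn)
best = em.lic_threshold(table, 0.95)
# 323 medicinal species, LIC 95th percentile = 6.10, 17 species above
```

The command-line interface mirrors the library:

```sh
ethnomarket simulate --preset bogota --out survey.tsv
ethnomarket summarize survey.tsv --out-dir summaries/
ethnomarket compare survey.tsv --level plantspace --out-dir cmp/
ethnomarket ordinate cmp/distance_plantspace.tsv --axes 2 --out coords.tsv
ethnomarket test cmp/distance_plantspace.tsv --groups zones.tsv \
    --perms 9999 --seed 1
```

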