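# Methods

## Data model and counting conventions

A **use report** is one `(species, market, category, ailment)` observation.
Scientific names are canonicalized to `Genus epithet`: authorities,
infraspecific ranks and the qualifiers `aff.`/`cf.`/hybrid `x` are stripped
(qualifiers are kept as flags), and single-token names become genus-level
determinations with the placeholder epithet `sp.`. Exact duplicate rows —
same species, market, category and (case-insensitively) ailment — collapse
to one report, which is what makes markets, not vendors, the occurrence
unit.

Market inventories sometimes file one binomial under two families. The
species-accounting unit is therefore the **filing**: a distinct (as-filed
family, binomial) pair. In the packaged Bogotá transcription four binomials
are double-filed, so there are 409 filings over 405 distinct binomials;
`TaxonSummary` reports both, and `species_index` additionally keeps a
one-to-one species → family map (first filing wins, conflicts logged) for
operations that need a unique family. Family tables count filings per
family, after an explicit, idempotent merge map (by default the three
legume subfamily headings → Fabaceae). Under these conventions the
transcription reproduces the inventory's published totals (409 species, 319
genera, 24 markets, 402 medicinal species, 19 medicinal categories,
Fabaceae 43 / Asteraceae 34 / Lamiaceae 24). The published family count of
122 falls between the two defensible conventions (123 as filed, 121 after
the legume merge) and is reported as a pair of diagnostics rather than
forced.

Percentages use different bases by table — all species for the family
table, medicinal species for the category and ailment tables — because
those are the only bases under which the published percentage pairs are
arithmetically consistent. Values are kept exact internally; half-up
rounding to one decimal is applied only at presentation. Ranked tables
break ties alphabetically so output is deterministic.

### Vocabulary normalization

Category labels are controlled vocabulary. The transcription keeps the
source's spellings verbatim (including "Respitarory system" and
"Muscular-skelettal system"); a shipped alias map resolves them to
canonical labels, and a registry fixes each canonical label's medicinal
flag. Four judgment calls in the shipped configuration:

* Three one-off labels that are ailments used in the category position
  ("Sinusitis", "Astringent", "Scabies") are filed by the semantics of the
  ailments they carry (urinary, skin, infections respectively).
* The label "Cultural" (three uses, asterisked in the source) is treated as
  the medicinal emic category "Cultural illnesses" rather than as a
  non-medicinal class: ritual/cultural illness uses are part of the
  medicinal pharmacopoeia here, and this reading is the only one consistent
  with the inventory's own count of 402 medicinal species. The
  non-medicinal set is thus Human food, Animal food, Toxic, Cosmetic.
* "Food" aliases to "Human food".
* Two Market-column tokens that are species names, not markets, are dropped
  (logged), leaving exactly the 24 real markets.

Ailments are free text, compared case-insensitively after trimming, with no
stemming: the inventory treats them as labels, and stemming would invent
equivalences the source does not assert.

## Consensus indices

For a use *u*, `ICu = (FCu − NSu)/(FCu − 1)` with `FCu` the number of
(species, market) occurrences and `NSu` the number of distinct species.
At `FCu = 1` the formula is 0/0; we define `ICu = 0`, matching the
degenerate-case handling of the informant-consensus-factor literature — a
single report carries no consensus — and making singleton species score
zero. Species scores are `LICs = Σu ICu · ln(FCus)` (natural log), with
`FCus` the per-species market count for the use: the subscript *s* reading
of the frequency term, which is the only reading under which a species'
score depends on its own occurrence pattern. The default "use" level is the
ailment; category-level scoring is available as an option. The 95th
percentile threshold interpolates linearly between order statistics, and
the exceedance set is strict (`LIC > threshold`).

The packaged inventory lists each species' uses and markets but not which
use was seen in which market, so `FCus` is not reconstructible from it and
published per-species scores cannot be recomputed at desk scale; the
shipped expansion crosses uses with markets and is documented as an
upper-bound reconstruction. The consensus machinery is therefore validated
property-based: on exhaustive small surveys the implementation must agree
term-by-term with a brute-force oracle that enumerates (species, market,
use) tuples, and the degenerate conventions must hold. The published
ranking table is shipped verbatim as a reference (including its listing of
*Sambucus nigra* where the inventory files *Sambucus peruviana* — kept, not
reconciled).

## Market comparison

Incidence matrices are binary; distances are Euclidean on raw
presence/absence (the survey records occurrence only). "Plant-space" for
ordination concatenates the species-level and use-level indicator blocks,
unweighted — the simplest reading of ordinating markets by "plant species
and their respective uses"; weighting is a configuration hook.
Per-plant unique-use percentages are defined only for species occurring in
at least two markets; a use is unique to a market when its (species, use)
pair occurs nowhere else.

## Ordination and permutation tests

PCoA: Gower double-centering of −½·d², symmetric eigendecomposition,
coordinates scaled by the square root of non-negative eigenvalues. Negative
eigenvalues (non-Euclidean inputs) are dropped and their absolute mass
reported; a Lingoes-type additive correction is available behind a flag.
Eigenvalues below a relative tolerance of 1e−9 count as zero.

The grouping test is a PERMANOVA-style pseudo-F computed from sums of
squared distances (`SS_total = Σ_{i<j} d²_ij / n`, within-group terms
analogously), with free permutation of group labels; the size test is a
Mantel-style Pearson correlation between off-diagonal distances and
absolute size differences, permuting market identities. Both use the
add-one p-value `p = (1 + #{perm ≥ obs})/(1 + n_perm)` (one-sided, large
statistic = group effect / positive association), so p is never zero and
is bounded below by `1/(n_perm + 1)`. Exact enumeration over all distinct
label arrangements is available for small surveys. Note the statistic
depends only on the *partition*, so with few markets many permutations
reproduce the observed value and the attainable minimum p is the fraction
of partition-preserving arrangements — p-floors near `1/(n_perm+1)` require
enough markets (the 24-market scale is ample). Defaults: 9999 permutations;
the CLI makes the seed mandatory.

The ordination method and test statistics are fixed design choices,
selected for determinism
(PCoA has no stress-minimization randomness) and for being the standard
distance-based tools for incidence data. Published p-values for zone,
locality and size groupings cannot be replicated exactly because the group
assignments are unpublished; the tests are validated by calibration
instead (see below).

## Synthetic surveys

The generator emulates the structure the analysis assumes:

* a species pool (default preset: 400) with half reserved as per-market
  private blocks and half as a shared pool whose draw weights are Zipf
  (`rank^−1`), giving few widespread species and many rare ones;
* each market draws `max(1, Poisson(mean))` species, each draw coming from
  the shared pool with probability `overlap` and from the market's private
  block otherwise (overflow spills to the shared pool; at `overlap = 0`
  markets stay disjoint, and a configuration whose private demand exceeds
  the private block raises a sizing error);
* a category → ailment hierarchy with category-prefixed ailment tokens;
  each species carries a use repertoire (mean twice the per-market use
  mean, so uses recur across markets and consensus is estimable), and each
  (species, market) pair expresses a shifted-Poisson number of repertoire
  uses (≥ 1, so no empty occurrence exists);
* optional group structure: `divergence` is the fraction of the shared
  pool that is group-exclusive (0 = no signal, 1 = groups share nothing);
  one group reduces exactly to the ungrouped generator;
* one seeded `numpy` generator drives all sampling, so surveys are
  byte-identical across runs given a seed.

The `bogota_preset` anchors scale to the packaged inventory — 24 markets,
~400-species pool, 19 medicinal categories, mean 42 species per market
(the inventory's mean), overlap 0.85 (the highest-uniqueness setting
feasible at that market size and pool) — it is scale-anchored, not fitted.
Preset surveys show ~15–20% per-market uniqueness and skewed occupancy,
like the real inventory; they do *not* reproduce its total richness (the
mixture observes ~230–320 of the pool's species rather than 400+), its
vernacular names, or any linkage structure beyond exchangeability. Passing
calibration tests on synthetic data therefore demonstrates correctness and
statistical calibration of the machinery, not goodness-of-fit to any real
market system.

## Calibration experiments (test suite)

* Type-I error: 500 preset surveys with random 3-group labels, 199
  permutations at α = 0.05; the rejection rate must fall in the 95%
  binomial interval [0.031, 0.069].
* Power: 24 markets in 3 groups at full divergence and overlap, 9999
  permutations, 40 replicates; rejection in > 95% of replicates.
* Exact agreement: Monte-Carlo p converges to the enumerated p on
  7-market toys.
* Overlap recovery: mean per-market proportion-unique over 100 replicates
  is strictly decreasing across overlap {0, 0.25, 0.5, 0.75, 1} (Spearman
  −1 on grid means), at 12 markets × 15 species so the whole grid is
  feasible.

Replicate counts and permutation numbers are chosen so the full suite runs
in about a minute on one core while keeping the binomial intervals tight
enough to detect miscalibration.

## Known limitations

* The use-by-market expansion of the packaged inventory is a cross
  product; any statistic that needs true use-level linkage (LIC, use-level
  uniqueness on the real data) is an upper-bound reconstruction there.
* Vernacular names are carried but unused by any statistic.
* No external taxonomic name resolution; canonicalization is syntactic.
* Only Euclidean distance is built in (a hook exists for alternatives);
  no abundance data, no rarefaction.
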