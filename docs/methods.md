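# Methods

## Problem setting

An ICH M7 impurity assessment combines one statistical and one expert
rule-based (Q)SAR prediction of bacterial-reverse-mutation (Ames) outcome into
a single consensus call. Because commercial models are revised roughly yearly
and a development programme spans many releases, the quantity of interest is
the distribution of call *transitions* between an initial and a contemporary
model version — per model, and for every statistical × rule-based pairing.
This package operates on harmonized categorical data; it does not implement or
approximate any vendor's predictive model, and all quantitative results it
produces describe the data it is given (or simulates), not the commercial
systems themselves.

## Curation

Standardization proceeds per structure in a fixed order; failures are encoded
as rejected records, never exceptions:

1. **Validation.** The SMILES must parse and sanitize (RDKit). Otherwise
   `INVALID`.
2. **Element filter.** Allowed elements are the organic subset
   (H, B, C, N, O, F, Si, P, S, Cl, Br, I, Se) plus group I/II metals;
   any other element gives `DISALLOWED_METAL`. The filter runs before the
   mixture test, so an organic mixture containing a mercury fragment is
   reported as a metal problem, not a mixture.
3. **Counterion stripping and mixture filter.** Fragments consisting solely of
   group I/II atoms are removed; if more than one fragment remains the record
   is a `MIXTURE`. A structure that is *nothing but* counterions (e.g.
   `[Na+]`) leaves no organic parent and is classed `INVALID` — a degenerate
   case outside the reject-reason order above, chosen because there is no
   parent structure to keep and no mixture to speak of.
4. **Normalization/contextualization.** Charges are neutralized where valence
   allows (RDKit Uncharger), stereochemistry and isotope labels are stripped,
   and the canonical SMILES is stored. The map is idempotent: standardizing a
   standardized structure returns it unchanged (asserted in tests).

Exclusion against training-set/assay databases compares canonical standardized
forms, so it is structural rather than id-based, and removes every id sharing
an excluded structure. Compounds dropped at this stage are marked
`EXCLUDED_KNOWN`; the funnel satisfies
`|input| = |kept| + Σ|rejected by reason|` and
`|final| = |selected| − |excluded|`.

### Fragment fingerprints

The cited fragment-fingerprinting approach is not parameterized in public
sources, so the implementation is a documented stand-in: all linear atom-bond
paths of 0..d bonds (d = 7 by default, configurable), atoms typed by element +
aromatic flag, bonds by order, each path labelled by the lexicographically
smaller of its two reading directions and hashed to a 64-bit identifier
(BLAKE2b). Including 0-bond paths makes single heavy atoms visible, so methane
and ethane already differ at depth 1. Branched fragments and richer atom
typing (charge, H-count) are deliberately out of scope; similarities computed
here will not numerically match any vendor tool, which is acceptable because
every downstream quantity depends only on the *relative* similarity structure.

Tanimoto similarity is `|A∩B| / |A∪B|` on the bit sets; two empty sets
compare as 1.0 (degenerate convention, documented at the function); comparing
fingerprints of different depths is a configuration error. Selection uses an
inclusive cutoff (≥ 0.5 by default): "selecting at a cutoff" reads as
inclusive, and the choice is configurable. A query compound matching several
reference compounds is selected once — multiplicity survives only as edges of
the similarity graph, which connects all pairs (within and between datasets)
at or above the threshold and reports connected-component and singleton
counts. Force-directed layout is presentation, not analysis; the graph is
exported (GraphML / edge-list CSV) for external viewers.

Alert profiling counts a compound once per SMARTS alert regardless of match
multiplicity, ranks alerts by descending count with ties broken
alphabetically, and sums everything below the top-k (default 6) into an
"other" bin.

## Harmonization

The vocabulary map is total over the input by construction: any unmapped term
raises a data error naming the term and model. Raw terms are matched
case-insensitively after whitespace collapsing (vendor exports vary in
casing). The default config encodes the six vendor/model-type identities; the
Lhasa rule-based system has no equivocal output, which the config enforces via
a `forbidden` list, and its alerting-structure reasoning levels (certain /
probable / plausible / equivocal — all ⇒ POSITIVE) are term-level entries
because raw exports name the level. "Negative with misclassified features" ⇒
NEGATIVE; "Negative with unclassified features" ⇒ OOD. The OOD binning of
unclassified-feature negatives follows common applicant practice rather than
the vendor's own interpretation; it is a mapping choice carried in config, not
code. Raw terms for software errors/timeouts have no defined mapping; if such
records occur they surface as unmapped-term errors and must be resolved in the
config, which is the safe default for a regulatory-adjacent pipeline.

A harmonized table is a *complete* matrix: every (compound, model-version)
cell present exactly once, with consistent release years per version label.
Violations are rejected at construction with row coordinates, which is what
makes the downstream conservation identities (marginals summing to the
compound count for every version) structural rather than empirical.

## Consensus

The rule list (positive dominates; equivocal next; negative requires both;
negative+OOD and OOD+OOD give OOD) is implemented literally, and separately as
`max` under POSITIVE > EQUIVOCAL > OOD > NEGATIVE; tests require exhaustive
agreement on all 16 ordered pairs, so either form can be read as the
specification of the other. Equivocal+equivocal, which the enumerated rules do
not cover, resolves to equivocal by the max-order extension (conservative and
consistent with the other rules' severity ordering). Consensus is defined only
for statistical × rule-based pairs; same-type pairings are rejected, since the
guideline's premise is complementary methodologies.

## Drift statistics

The default comparison is cumulative: each model's latest version released at
or before the window start versus its latest at or before the window end. The
default window starts at the earliest year by which *every* model in the table
has a release (for the study-shaped data, 2014) and ends at the latest release
year. Consecutive-version deltas are available by calling
`transition_matrix` on adjacent labels.

Change percentages default to the total-compounds denominator ("x% of the
compounds changed from negative to positive"), under which the 16 cells sum
to 100%. The per-from-category mode gives conditional rates, with empty rows
reported as NaN — an undefined rate is not a zero rate, and NaN propagates
through grid means rather than silently vanishing. Outputs round to one
decimal place; internal values are unrounded.

The combination grid is the full Cartesian product of statistical and
rule-based model identities, labelled intra-/inter-vendor; the unchanged
report gives each combination's trace percentage and their arithmetic mean.
`check_external_counts` lets published per-version category counts be entered
as fixtures and checked against an expected total; rows that do not sum are
flagged and never "corrected".

`VersionDriftModel`/`VersionDriftResults` package these computations
fit-style because drift estimation is the one genuinely model-like step: the
data are a complete categorical panel, the estimates are transition matrices
and derived rates, and `summary()` renders the standard report. Curation and
harmonization remain plain functions — they are data preparation, not
estimation.

## Synthetic generator

The generator emulates the *statistical* structure of a multi-vendor
prediction history: per compound and model, an initial category from a
4-vector of marginals, then one draw per version step from a row-stochastic
4×4 kernel, independently across compounds. An optional shared latent
Bernoulli ("true mutagenicity", prevalence 0.30 by default — about the
positive-call fraction in the study-shaped marginals) couples a vendor's two
models at the initial draw: `coupled_conditionals` splits the marginals into
latent-conditional distributions that mix back to the marginals exactly, with
a strength parameter (default 0.9) setting how much of the feasible
positive-call enrichment the mutagenic stratum receives. Transitions after
the initial draw are independent across models — real model updates are
correlated through shared new data, so simulated consensus churn is, if
anything, slightly pessimistic.

Default study conditions (chosen once, from the published per-version counts,
and not revisited): 3367 compounds; three vendors × (statistical, rule-based)
with one 2014 → 2018 step; initial marginals equal to the published 2014-era
category fractions per model (the 2013 column for the Leadscope statistical
model, whose releases bracket 2014); kernels with conditional off-diagonal
rates of 0.5–3% (negative→positive), echoing the published cumulative-change
magnitudes and narrative — the younger Leadscope rule-based and Lhasa
statistical systems move most, the mature Lhasa rule-based system is nearly
static apart from its negative→OOD reclassification step, and every
out-of-domain pool shrinks mostly into negative. Under these defaults the
simulated grid-mean consensus negative→positive rate lands near 2% and the
mean unchanged percentage in the mid-80s, the same regime as the published
analysis; the match is a consequence of the chosen marginals and kernels, not
a recomputation of the proprietary results.

Structure generation combines seven scaffolds with fourteen substituents
echoing the alert classes common among synthesis impurities (aryl amines,
nitroaromatics, acyl halides, alkyl esters, aldehydes, epoxides, sulfonate
esters, boronic acids, hydrazines) plus innocuous groups; a configurable
defect fraction injects mixtures, transition-metal records and exact
duplicates to exercise the curation filters. What the generator does *not*
emulate: realistic activity labels, size/property distributions of real
impurity sets, or structure-dependent prediction calls (calls and structures
are generated independently). Passing tests therefore demonstrate the
correctness of the bookkeeping and statistics on data with known ground
truth, not predictive performance on real chemistry.

## Numerical and test choices

* Simulation sizes: 10,000 compounds for kernel-recovery and
  consensus-damping properties (3-binomial-SE bands; at this n the bands are
  ~±0.4 percentage points on a 2% rate), 3367 for the study-shaped run,
  ≤200-compound tables for brute-force oracle recounts. Oracle comparisons
  are exact (same float operations recomputed independently), not
  tolerance-based.
* The consensus-damping property uses asymmetric single-model
  negative→positive rates (2% statistical, 0.5% rule-based) over a 0.62
  negative marginal. With symmetric rates the consensus total-denominator
  rate sits at the boundary of the single-model rate by construction
  (the smaller consensus-negative pool, ≈0.38 of compounds, roughly cancels
  the union of two flip probabilities), so the asymmetric configuration —
  which also matches the heterogeneous per-model rates reported in practice —
  is the informative one.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning, one substream per model, so adding a
  model does not perturb the others' draws.
* Percentages are computed as `100*count/n` in double precision; the one
  published-rate comparison that cannot be recomputed (grid-average consensus
  change rates, which require the non-redistributable per-combination
  percentage table) is left as an explicitly failing test rather than
  omitted.

## Known limitations

* The fragment grammar is linear-path only; highly branched toxicophores are
  represented by their constituent paths.
* Counterion stripping removes only *single-element* group I/II fragments;
  covalently bound group I/II organometallics (e.g. Grignard-like structures)
  pass the element filter and survive as drawn.
* Harmonization assumes vendor exports are term-exact after case/whitespace
  normalization; free-text reasoning fields are out of scope.
* The latent-coupling mechanism correlates initial calls only, not
  transitions; inter-vendor consensus damping from shared training data is
  therefore not modelled.
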