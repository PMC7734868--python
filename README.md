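# m7drift

Version-drift analysis of ICH M7 (Q)SAR mutagenicity predictions.

Pharmaceutical applicants assess actual and potential impurities for mutagenic
potential with two complementary (Q)SAR models — one statistical, one expert
rule-based — whose consensus call drives how tightly an impurity must be
controlled (down to the 1.5 µg/day threshold of toxicological concern for
mutagens). Commercial models are updated roughly yearly, while drug development
runs 6–7 years, so a practical question for toxicologists and regulatory
scientists is how much predictions drift across software versions: how often
does a compound once called negative become positive, and does the two-model
consensus damp or amplify that churn?

`m7drift` implements the full analysis workflow around that question:

* **Curation** (`m7drift.curation`) — standardize structures (validation,
  normalization, stripping of stereochemistry/isotopes, charge neutralization),
  reject mixtures and compounds with metals outside groups I/II (group I/II
  counterions are stripped first, so simple salts survive as their parent),
  fingerprint with hashed linear fragment paths (depth 7 by default, atoms
  typed by element + aromaticity), select the query compounds whose best
  Tanimoto similarity `T(A,B) = |A∩B| / |A∪B|` to a reference set is ≥ 0.5,
  drop structures present in model training sets or assay databases, build the
  thresholded similarity graph (components/singletons, GraphML export), and
  profile structural-alert (SMARTS) frequencies with top-k + "other" binning.
* **Harmonization** (`m7drift.harmonization`) — map vendor-specific output
  terms ("Indeterminate", "Inconclusive", "Negative with unclassified
  features", …) onto the common four-category vocabulary
  {POSITIVE, NEGATIVE, EQUIVOCAL, OOD}; the shipped default covers the
  Leadscope, MultiCASE and Lhasa statistical and rule-based systems.
* **Consensus** (`m7drift.consensus`) — the ICH M7 two-model rule: positive if
  either model is positive, else equivocal if either is equivocal, negative
  only when both are negative, otherwise OOD; equivalently the maximum under
  the severity order POSITIVE > EQUIVOCAL > OOD > NEGATIVE.
* **Drift analysis** (`m7drift.drift`) — 4×4 transition matrices between an
  initial and a contemporary version, change percentages on a total-compounds
  or per-from-category denominator, per-version marginal counts with
  conservation checks, the full statistical × rule-based combination grid
  (intra-/inter-vendor), and per-combination unchanged percentages with their
  mean — exposed both as functions and as the statsmodels-style
  `VersionDriftModel(...).fit() -> VersionDriftResults` with a `summary()`.
* **Synthetic data** (`m7drift.simulate`) — impurity-like structures from a
  scaffold/substituent grammar (aryl amines, nitroaromatics, acyl halides,
  esters, aldehydes, epoxides, boronic acids, …) with optional deliberate
  defects, and multi-vendor prediction histories: per-compound categorical
  calls drawn from per-model initial marginals and evolved by row-stochastic
  4×4 transition kernels, with an optional shared latent "true mutagenicity"
  Bernoulli coupling a vendor's two models.

## Worked example

```python
from m7drift import VersionDriftModel, default_history_spec, simulate_history

table = simulate_history(default_history_spec(n_compounds=1000, seed=42))
print(VersionDriftModel(table).fit().summary())
```

```
Version drift analysis
======================================================================
Compounds: 1000   window: 2014-2018   denominator: total

Single-model cumulative changes (% of compounds):
  Leadscope/rule_based                N->P   2.1  P->N   2.4  unchanged  84.7  (n=1000)
  Leadscope/statistical               N->P   1.6  P->N   1.2  unchanged  90.2  (n=1000)
  Lhasa/rule_based                    N->P   0.3  P->N   0.4  unchanged  96.8  (n=1000)
  Lhasa/statistical                   N->P   2.9  P->N   1.0  unchanged  86.0  (n=1000)
  MultiCASE/rule_based                N->P   1.0  P->N   3.7  unchanged  93.2  (n=1000)
  MultiCASE/statistical               N->P   0.6  P->N   1.1  unchanged  91.8  (n=1000)

Consensus combinations:
  Leadscope-stat + Leadscope-rule (intra)    N->P   2.7  P->N   1.2  unchanged  82.7
  ...
  MultiCASE-stat + MultiCASE-rule (intra)    N->P   1.1  P->N   1.2  unchanged  89.5

Mean consensus N->P: 2.1%   mean P->N: 1.1%   mean unchanged: 86.9%
```

`N->P` is the share of all compounds whose call moved from negative at the
2014-era version to positive at the 2018-era version — the safety-critical
direction, since un-rerun assessments would miss those new positives. Here
every single model stays below 3% and the grid-mean consensus rate is ~2%,
with ~87% of consensus calls unchanged over the four-year window: model
updates rarely flip a negative consensus to positive.

The same analysis is available from the shell:

```bash
m7drift simulate --n 1000 --seed 42 --out preds_raw.csv   # vendor-vocabulary CSV
m7drift changes --table preds_raw.csv --out results/      # matrices + summaries
m7drift report --n-structures 500 --n-compounds 1000 --seed 0 --out demo/
```

plus `curate`, `alerts`, `harmonize` and `consensus` subcommands for the
structure-curation and harmonization stages.

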