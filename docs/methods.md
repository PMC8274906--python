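# Methods

`trialcease` models whether a registered COVID-19 clinical trial will be
completed or ceased (terminated, suspended or withdrawn) from the public
registry record alone.  This note documents the modelling choices, the
defaults and their rationale, what the synthetic registry generator does and
does not emulate, and the numerical conventions.

## Cohort definition

Records are parsed from the legacy ClinicalTrials.gov `clinical_study` XML
dialect.  The binary label is derived from the overall recruitment status:
"Completed" is the completion (negative) class; "Terminated", "Suspended"
and "Withdrawn" together form the cessation (positive) class.  All other
statuses — recruiting-type and expanded-access statuses — are excluded from
the cohort.  Status matching is case-sensitive exact matching on the
registry vocabulary; unknown strings are excluded with a warning rather than
raised, because registry exports evolve.  The reference cohort this package
is calibrated to holds 772 trials, 144 of them cessation (18.65%, an
imbalance of 4.36:1), drawn from a registry snapshot of 4,441 COVID-19
trials.

A trial's *main country* is the modal country over its `<location>`
elements, one vote per site, with ties resolved to the first country in
document order.

## Feature families

**Statistics features (40 columns).**  Administrative (industry sponsorship
and collaboration, collaborator/official counts, responsible-party code),
study information (expanded access, DMC oversight, FDA regulation, phase,
interventional vs. observational, USA main country), study design
(randomization, masking level, placebo arm, group/country/site counts) and
eligibility (healthy-volunteer acceptance, age/gender restriction, and
line/word/digit counts over the inclusion, exclusion and whole criteria
text).  Categorical fields use documented ordinal code maps: phase is coded
0 (none) through 4 with half-steps for combined phases ("Phase 1/Phase 2" =
1.5) to preserve the staged ordering of clinical research; masking is coded
none=0 … quadruple=4; responsible party and unknown categories code to 0.
The placebo flag fires when any arm is typed "Placebo Comparator"
(case-insensitive) or an arm label contains "placebo".  Age restriction
means a minimum age above 18 years or any specified maximum.  "Number of
digits" counts digit *characters* ("120" contributes 3); the alternative
token reading is noted as ambiguous and was not adopted.  Where the
published list of 40 statistics columns is not fully enumerable from
available sources, the remaining columns (collaborator/phase presence flags,
parsed age bounds, split indicator and per-line digit averages) follow the
same four-group layout; the exact set is pinned in
`structured_features.STAT_FEATURE_NAMES` and tested.

**Drug features (top-drug one-hot + drug-class counts).**  Fitted on
training data only: the 20 intervention MeSH terms supported by the most
trials become one-hot columns (boundary ties break lexicographically), and
every drug class with at least 2 distinct supporting trials becomes a count
column (number of the trial's intervention terms mapping into the class).
The term-to-class mapping (ATC level 5, falling back to MeSH pharmacological
action) is a local TSV snapshot, not a live API call, for determinism and
offline testing.  The packaged map is a synthetic snapshot: memberships for
the major COVID-19 intervention classes (aminoquinolines, macrolides,
corticosteroids, antivirals, interferons, heparins, ARBs) are real; the long
tail is plausible filler.  Unmapped terms are reported in aggregate, never
silently dropped.

**Keyword features (top-500 TF-IDF).**  The keyword document is the
deduplicated union of the keyword, condition-MeSH and condition fields,
tokenized by splitting on punctuation/whitespace runs, lowercasing, and
dropping purely numeric tokens (so "SARS-CoV-2" yields `sars`, `cov`).
Term weight is raw count times smoothed idf, `idf = ln((1+n)/(1+df)) + 1`
with natural log, L2-normalized per document.  The vocabulary keeps the 500
terms with the highest mean normalized TF-IDF over the fitting corpus, fitted
per training fold (corpus-wide fitting is available through the `featurize`
command for descriptive tables, but the evaluated pipeline never uses it —
that would leak test-fold document frequencies).  No stemming, stop lists or
n-grams.

**Embedding features (100 dimensions).**  Distributed-memory paragraph
vectors over the Detailed Description field, implemented in numpy: each word
is predicted from the average of the document vector and the context word
vectors (window 5) with 5 negative samples drawn from the unigram^0.75
distribution; vocabulary threshold 2 occurrences; 20 training epochs with a
linearly decaying learning rate (0.025 → 1e-4); deterministic given the
seed.  New documents (including the training fold itself, at evaluation
time) are embedded by gradient steps on a fresh zero-initialized document
vector with word and output weights frozen; empty or fully
out-of-vocabulary documents map to the zero vector.  Mini-batches of 512
positions are used for speed; this makes the updates slightly more
batch-like than strict per-example SGD, which is immaterial for the
downstream use (the tests only rely on determinism, finiteness and topical
separation).

## ReliefF feature ranking

Weights follow the neighbor-based update with k nearest hits and, per
opposite class, k nearest misses weighted by `P(C)/(1 - P(class(x)))`.  The
diff function is the 0/1 indicator for nominal features (columns with at
most two distinct values) and the range-scaled absolute difference for
continuous ones; constant features score exactly 0.  Choices the update rule
leaves open:

- **k_neighbors = 10** (standard practice), capped by the pipeline at the
  smallest training-class size minus one.
- **Exhaustive visiting** (every instance once, in index order) instead of
  random sampling, for determinism; a seeded sampled policy is available.
- **Normalizer m = number of features** by default, with the classic
  m = number of iterations as an option; both are uniform positive scalings,
  so rankings are identical (tested).
- **Neighbor distance** is the sum of per-feature diffs (Manhattan on
  range-scaled features), consistent with the diff functions; distance ties
  break by instance index.

A caveat verified empirically: duplicating every instance does *not* leave
the full ranking invariant under this update (a duplicated instance's
nearest hit is its own copy at distance zero, which rescales hit sums
non-uniformly), so near-tied noise features can swap ranks; clearly
informative features remain above noise and constants, which is what the
property test asserts.

## Prediction

Cessation is the positive class throughout.  Imbalance is handled by random
undersampling of completion trials at majority:minority ratios 4.36 (none),
4, 3, 2, 1, 0.9; each ratio is resampled 10 times, each repeat training one
member with seed `base_seed + i`, and the ensemble averages member
cessation probabilities (classification threshold 0.5).  A ratio that
retains the whole majority class trains one model on the full data — the
single-model baseline.

Member hyperparameters are fixed values (from a nested grid search, taken
as given, not re-searched): neural net with one hidden layer of 50 logistic
units, Adam, batch size 50, 50 epochs, binary cross-entropy loss; random
forest with 1,500 trees, no bootstrap, entropy criterion, min 5 samples to
split and 2 per leaf, sqrt(m) features per split (the literal "m features
per split" reading contradicts random feature subsets; sqrt is the
conventional resolution and m-mode remains configurable); gradient-boosted
trees with 600 trees, minimum loss reduction 2, depth 5, min child weight 1,
feature subsampling 0.6, no row subsampling, learning rate 0.1 (unstated;
the library default); L2-penalized logistic regression with C = 1 (unstated)
solved to tolerance 1e-6.  Neural-net members use independent seeded
initializations across repeats.

## Evaluation and model comparison

Stratified 5-fold cross validation (per-fold class counts within one of
each other, total fold sizes within one; the dealing procedure is
hand-rolled so that classes smaller than k still split cleanly).  All
fitted objects — drug spec, keyword vocabulary, embedding model, ReliefF
ranking — are refitted inside each training fold; a canary test asserts
that test-fold-only tokens never enter any fitted vocabulary.  Metrics:
accuracy, balanced accuracy (mean of per-class accuracies), F1 on the
cessation class, and AUC with midrank tie handling.

Treating the feature-subset sizes as datasets, classifiers are compared
with the Friedman test (chi-square approximation, k-1 degrees of freedom;
per-dataset descending ranks, ties averaged) and the Nemenyi post-hoc
critical difference `CD = q_alpha * sqrt(k(k+1)/(6n))`, with a built-in
q-table for k = 2..10 at alpha 0.05 and 0.10 (q = 2.569 and 2.291 at k = 4).
Classifiers whose average ranks differ by less than CD share a bar in the
critical-difference diagram.

## The synthetic registry generator

The generator emits legacy-dialect XML so the entire pipeline — parsing
included — runs without any download.  It emulates the *class-conditional
structure* the analysis relies on:

- cessation label at rate 0.1865;
- interventional status, placebo arm, refusal of healthy volunteers and USA
  main country at the printed marginal and cessation-conditional rates, with
  the completion-conditional rate derived by the law of total probability
  (`derive_completion_conditional`), never guessed;
- per-drug intervention assignment at each top drug's observed prevalence
  (hydroxychloroquine is the only drug with a printed class-conditional
  rate, 31.94% of cessation trials; all other drugs are class-neutral);
- class-leaning keyword vocabularies and description templates sharing a
  common COVID stem, mixed 75/25 across classes so the vocabularies overlap;
- eligibility text with inclusion/exclusion bullets and embedded digits
  (5% of trials get an unsplit criteria block);
- fields with no printed class-conditional rates (industry sponsorship,
  collaborators, officials, DMC, FDA, ages, gender) are class-neutral, which
  makes them usable as negative controls in recovery tests.

One global seed drives a hierarchical per-record stream, so corpora are
byte-identical across runs and invariant to generation order.  The split of
cessation across Terminated/Withdrawn/Suspended (0.5/0.35/0.15) is a
generator default, not a published number.

What it does **not** emulate: real free-text grammar (template sentences
only), enrollment dynamics, "Why Study Stopped" text, correlations among
neutral fields, or the long tail of real MeSH vocabulary.  Passing recovery
tests therefore demonstrates that the pipeline recovers planted
class-conditional structure of realistic strength at the reference sample
size — not that the real-registry accuracy figures are reproduced, which
would require the actual registry snapshot (supported through the `ingest`
command).

## Problem sizes in tests and the acceptance script

Recovery checks run at the reference cohort size (n = 772): the ReliefF
planted-signal check over 20 generator seeds on the structured feature
block, and the random-forest checks over 3 seeds of the full
feature-fitting + 1:1 undersampling ensemble pipeline (10 members, 5 folds),
with the no-sampling single model as the baseline in the same runs.  Unit
tests use smaller corpora (120–772 records) and reduced embedding
dimensions where only contracts, not effect sizes, are under test.

## Known limitations

- The packaged drug-class map is a synthetic snapshot; real-registry use
  should supply a complete RxClass-derived TSV.
- The paragraph-vector trainer is a compact implementation tuned for
  determinism and small corpora, not a drop-in replacement for large-scale
  embedding libraries.
- Reported percentages round half-up to two decimals.
- Real-registry headline metrics depend on a specific registry snapshot and
  are outside what the synthetic generator can certify.
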