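# Methods

## The analysis model

The pipeline treats a search session as an off-then-on experiment: a user
formulates queries with the semantic expander disabled until satisfied,
then repeats with it enabled, and may toggle freely afterwards. Two
records per (user, scenario) group carry the analysis:

* **Q_A1** — the off-flagged record with minimal `seq`;
* **Q_Bn** — the on-flagged record with maximal `seq`, taken over the
  whole session even when an off-flagged query follows it (users often
  toggle the feature off at the very end; the last on-query is still the
  one the expander acted on).

Groups lacking either condition are excluded, never imputed: the pair is
the unit of analysis and there is nothing defensible to impute from. The
exclusion list is returned as data so reports can account for every
group (pairs + exclusions = groups, enforced by tests).

`seq` is authoritative for ordering; timestamps are carried as opaque
`HH:MM:SS` strings because time-of-day wraps across sessions.

### Similarity

Queries are tokenized by lower-casing and splitting on whitespace and
punctuation. Hyphenated tokens ("non-invasive") are kept as single terms
by default (`keep_hyphens=False` splits them); terms are merged into a
*set*, so repeated words and multiword phrases carry no extra weight.
The pair score is the Jaccard coefficient of the two sets. Per-scenario
aggregation reports mean, sample (n−1) SD, and median; the study-level
figure is the **unweighted mean of scenario means** (each scenario is one
experimental condition, weighted equally), with a pair-weighted pooled
mean available as an option.

Character counts in the activity table include spaces and punctuation of
the raw query string — the simplest reproducible convention. The
percentage of on-flagged queries is, by default, the mean over users of
each user's within-user percentage (users weighted equally); the pooled
alternative is a switch.

### Entropy / convergence

For scenario s and condition c ∈ {off, on}, each participant contributes
the first k = 10 entries of their result list (R_A1 or R_Bn). A
document's frequency counts **participants whose top-k contains it** —
deduplicated per participant, not pooled over rank positions — because
the quantity of interest is cross-user overlap, not rank mass. Pooled
counting is available as an option. Probability scores are frequencies
over the total mass; entropy is −Σ x·log₂ x.

The log base is a parameter (default 2). Every downstream quantity — the
percent difference 100·(H_on − H_off)/H_off and its Pearson correlation
with perceived performance — is exactly invariant to the base (the base
change is a common positive factor in numerator and denominator); a
property test pins this to 1e−9. Negative percent difference =
convergence. Participants with an empty list under one condition carry no
frequency mass and are dropped from that condition with a warning; a
scenario where every list is empty is an error, and a log with no result
lists at all (queries only) skips the entropy stage.

### Group statistics

Per-scenario Jaccard scores are tested with Kolmogorov-Smirnov against a
normal with the group's sample mean and SD. This is the plain
moment-matched KS, not Lilliefors: parameters estimated from the data
make the test conservative, which is acceptable here because Jaccard
scores piling up at 1.0 fail it by a wide margin anyway; the choice is
recorded in the report. Bartlett and Levene are both always computed.
Kruskal-Wallis runs whenever any group fails normality at α (default
0.05); `decide_median_test` records the full decision trail. Calibration
tests check type-I rates near α over 500 seeded replicates, balancing
statistical resolution against suite runtime.

## The synthetic study

The generator emulates the statistical structure the analysis assumes,
at desk scale:

* **Lexicon** — 12 unambiguous concepts × 4 lower-case synonym terms.
  Synonymy is modeled at the term level (no multiword phrases) so the
  engine and the similarity tokenizer share one vocabulary model.
* **Corpus** — default 400 documents of 40 terms; each document has a
  uniformly drawn focal concept, and each term position is a uniform
  synonym of that concept with probability 0.7, else a background term
  (200-word background vocabulary). Document/term counts are sized so
  that a 2-concept query has well over k candidate documents while a full
  run stays under a second.
* **Engine** — summed TF×IDF (IDF = log(N/df)), ties broken by ascending
  doc id, zero scores excluded. With the expander on, every recognized
  term is replaced by its concept's full synonym list before scoring.
* **Users** — 33 users × 5 scenarios (difficulty sequence
  medium–low–medium–high–medium), 2 target concepts per scenario, 1–5
  off-phase and 1–3 on-phase submissions, and a 0.2 chance of a trailing
  off-flagged resubmission so the "last on-query, not last query"
  selection rule is actually exercised.

Difficulty maps to three probabilities, with presets chosen once as
plausible magnitudes for easy/typical/hard search tasks:

| preset | divergence | noise | edit |
|--------|-----------|-------|------|
| low    | 0.15      | 0.10  | 0.10 |
| medium | 0.50      | 0.15  | 0.20 |
| high   | 0.85      | 0.35  | 0.40 |

*divergence* — chance a user picks a non-canonical synonym per target
concept; *noise* — chance of an off-target term in the query, and,
independently, chance the error-prone concept mapper spuriously expands
one unrelated concept for that user (engine-internal, like the expanded
query itself; `noise_expansion=False` disables the latter); *edit* —
chance each later submission re-draws one concept's synonym and toggles
the noise term.

Two causal mechanisms are recoverable from the simulator and pinned by
tests over 20 seeds each:

* **Convergence**: divergence ≥ 0.5, noise = edit = 0 → expansion
  collapses all synonym choices onto one query, so on-condition entropy
  is below off-condition entropy in ≥ 90% of scenario×seed cells.
* **Noise**: divergence = 0 with spurious expansion enabled → there is
  nothing to collapse, and per-user spurious concepts spread the on-
  condition result sets apart, so the mean entropy difference is ≥ 0.

What the simulator does **not** emulate: real concept-mapping errors on
clinical free text, phrase-level synonymy, document relevance, and any
calibration of per-scenario outcomes — in particular, the default presets
produce convergence in *all five* scenarios, not the published
per-scenario sign pattern, and the perceived-performance scores attached
to synthetic runs are the study constants, so the synthetic Pearson r is
not meaningful as a replication. Passing tests therefore demonstrate that
the pipeline measures the mechanisms correctly, not that the simulator
reproduces the original study's numbers.

## Numerical choices and degenerate inputs

* Jaccard of two empty term sets, entropy percent difference at
  H_off = 0, and correlations with zero variance raise typed errors
  rather than returning NaN.
* Distribution invariants (probabilities sum to 1 within 1e−9, total
  frequency ≤ k × participants) are validated at construction.
* Retrieval ties break by ascending doc id; all randomness flows from
  explicit integer seeds through `numpy.random.default_rng`, and
  identical (config, seed) reproduce byte-identical logs and reports.
* Problem sizes in tests and the acceptance script (200–400 documents,
  up to 33 users, 20 seeds per mechanism check) were chosen so the whole
  suite runs in well under a minute while keeping the mechanism effects
  far from their decision thresholds.

## Known limitations

* The published per-pair Jaccard scores are not redistributable, so the
  published p-values of the KS/variance/median tests are not
  reproduced here; the tests are instead calibrated on seeded synthetic
  data.
* The engine's ranking function is a stand-in: the production system's
  scoring is not public beyond its use of TF and IDF.
* The per-scenario perceived-performance scores are survey constants
  taken as inputs; no survey machinery is modeled.
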