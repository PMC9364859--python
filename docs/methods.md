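# Methods

This note records the model behind `trialpubs`, the parameters that matter,
the conventions adopted where registry practice is ambiguous, and what the
synthetic-corpus tests do and do not establish about real data.

## Problem and pipeline

A registered study and its result publications are connected, when they are
connected at all, through two structured mechanisms: the study record can
cite the article under a result-typed reference field (*registry channel*),
and the article's abstract can carry the trial's registry accession number,
which bibliographic indexing turns into a searchable secondary identifier
(*abstract channel*). The pipeline runs in stages, each a pure function
over the domain model:

1. **Selection.** Keyword match over brief title, official title, and
   condition terms (case-insensitive) selects the condition's studies;
   a status filter keeps recruiting, enrolling-by-invitation,
   active-not-recruiting, completed, and terminated studies by default.
   The keyword scope deliberately excludes intervention strings and
   summaries so the filter mirrors registry condition indexing and stays
   auditable; both the keyword list and the status set are configuration.
2. **Linking.** Registry-channel candidates come from result-typed
   references carrying a PMID (references without one are counted but
   unresolvable). A result reference whose article was published strictly
   before the trial's start date is misclassified — it cannot report the
   trial's results — and is removed with reason `predates_trial_start`;
   candidates whose PMID has no article metadata are removed as
   `missing_article`. Abstract-channel links come from each article's
   distinct canonical NCT secondary identifiers restricted to in-scope
   trials. The merge keeps one row per (trial, article) pair and tracks
   three counts: channel *combinations* (per-channel counts summed),
   distinct *pairs*, and distinct *articles*; they satisfy
   combinations = pairs + dual-channel pairs.
3. **Intervention scoring.** Free-text intervention strings are split on
   `|`, lowercased, punctuation-stripped, whitespace-collapsed, and passed
   through an optional synonym table. Each trial counts once per distinct
   canonical intervention, at its resolved (highest) phase. The
   significance score is the sum of phase values over occupied phases plus
   0.001 per trial, rounded to 3 decimals.
4. **Publication scoring and ranking** (below).
5. **Classification.** Registration timing, publication lag, publishing
   before completion, deposition categories, termination reasons, vaccine
   subset.
6. **Reporting.** CSV outputs and a deterministic Markdown report.

## Attention score

The score is additive with configurable weights:

```
A = w_rec · r + w_upd · min(u, c)/c + w_us · 1[US site] + m(type)
    + 1[interventional] · (w_ph · v(phase) + w_int · s_best)
```

where `r` is linear recency (1 at the query date, 0 at the window edge,
default window 730 days; future dates clamp to 1), `u` the update count
(version count minus the initial registration) capped at `c` (default 20,
so one hyper-updated record cannot dominate), `v(phase)` the resolved phase
value, `s_best` the significance score of the trial's highest-scoring
non-stop-list intervention (a publication inherits its trial's most
significant tested intervention; a mean-aggregate alternative is
configurable), and `m(type)` an article-type modifier: 0 for result
articles and negative constants for protocols (−1.0), editorials/comments
(−1.5), and other types (−0.5). Default weights are
w_rec = 1.0, w_ph = 0.5, w_int = 0.05, w_upd = 0.5, w_us = 0.5.

No canonical constants exist for this construct; the defaults were chosen
so that every component spans a comparable range (phase contributes 0–2,
recency 0–1, intervention significance roughly 0–0.6 at realistic scores,
updates and US site 0–0.5) and so that the documented ordering properties
hold: increasing any single component — recency, phase, intervention
significance, update count up to the cap, the US flag, or the type class
toward result article — never decreases the score. Rankings, not absolute
values, are the contract; the tests assert the monotonicity grid and exact
tie-breaking (equal scores order by newer publication date, then PMID),
never specific score values. For observational studies and registries the
phase and intervention terms are omitted — phase is not meaningful there —
and the score is algebraically the interventional formula with those
weights zeroed.

Article-type classification applies rules in a fixed order: *protocol* if
any publication type or the title contains the stem "protocol" (titles
catch protocol papers indexed only as journal articles), then
*editorial-or-comment* for editorial/comment/letter labels, then *result
article* for clinical-trial or journal-article labels, else *other*.

The shortlist keeps exactly the publications that are result articles from
phase-3-resolved trials with at least one US site and multiple record
updates. "Multiple updates" means version_count − 1 ≥ 2: updates exclude
the initial registration, and the threshold is configurable. "US site"
means a location country equal to "United States" after trimming; the
country is configurable for analyses centered elsewhere.

## Date and boundary conventions

Registry dates may carry only month precision. Month-precision dates impute
day 1, which never moves a date out of its calendar month and is
conservative for the misdated-reference comparison: borderline same-month
cases compare equal and are kept (the filter requires *strictly* earlier,
a boundary exposed in configuration). A trial with no start date cannot be
checked at all; its registry links are kept and flagged rather than
silently removed — absent data never discards evidence.

Registration timing uses ties-to-the-earlier-class boundaries: registration
on the start date is *prior*; on the primary completion date, *during*.
The primary completion date (final data collection for the primary
outcome), not the overall completion date, anchors the *during*/*after*
boundary and the published-before-completion check, because reporting
obligations attach to it. When completion is missing but registration
follows the start and the study has not ended, *during* is still assigned;
otherwise missing dates yield *indeterminate*. Publication lag is anchored
at the trial start date because registry completion dates are frequently
anticipated rather than actual; negative lags are legal and preserved.

Termination reasons are classified by an ordered, editable keyword-stem
table (recruitment/enrollment/accrual → recruitment; safety/adverse →
safety; futility; external-results stems; first match wins; empty text is
*unspecified*, unmatched text *other*). The rules are configuration, not
code, because registries describe categories rather than grammars.

Percentages round half-away-from-zero at 1 decimal (configurable), the
convention used when such shares are printed in registry meta-research.
NCT identifiers match `NCT` + 8 digits; secondary-identifier fields are
free text in practice, so matching canonicalizes to uppercased,
whitespace-stripped form first.

## Synthetic corpus: what it emulates, and what it does not

`trialpubs.synth` generates trials (phases, statuses, the three
registration-timing patterns, US/non-US sites, free-text interventions,
version counts, result and background references) and articles (titles,
types, dates, secondary identifiers), planting every fact in a ground-truth
ledger. Defaults: 200 trials; 75% interventional; publication lag normal
with mean 214 days and SD 90 (truncated at 7 days), matching the average
lag observed for pandemic-era trial publications; channel mix 57%
abstract-only / 40% registry-only / 3% dual, echoing the observed abstract-
channel majority and small overlap; 10% of trials get a deliberately
misdated result reference; registration timing mixed 45/42/13
prior/during/after; updates Poisson with mean 3. Each default is either the
observed value for the emulated corpus or a round value of realistic
magnitude; they are study conditions, not tuning knobs.

The generator writes the corpus in all three ingest dialects (registry-style
XML, pipe-delimited AACT-style tables, MEDLINE-style citation XML), so the
readers are exercised end to end and format equivalence is testable: both
trial renderings read back to identical records.

Ledger-exact tests establish that the pipeline computes precisely the
functions it claims on records it can parse: link extraction, the date
filter, merge counting, tallies, timing, subsets, shortlist membership.
They do not establish robustness to the messiness of real exports — absent
fields beyond those planted, inconsistent free-text interventions needing a
curated synonym table, registry dialect drift, or articles indexed with
malformed accession numbers. The statistical-recovery test (mean lag within
3 standard errors of 214 days at ≥ 500 planted links, with a +1-day
allowance for the truncation bias of the lag distribution) checks the day
arithmetic at scale, not any claim about real publication behavior.

## Problem sizes

Tests run on 200-trial corpora (seconds-scale); the parameter-recovery
check uses 800 trials to plant ≥ 500 links. The acceptance script uses the
same sizes. All randomness flows from a single integer seed; identical
corpus and configuration give byte-identical ranked output, which the CLI
records in a run manifest (config snapshot, input digests, tool version).

## Known limitations

- Registry references lacking PMIDs are counted but not resolved; no fuzzy
  citation matching.
- No semantic deduplication of preprint/journal versions of one article.
- Intervention grouping is lexical; without a synonym table, spelling
  variants of one intervention form separate groups.
- Live registry/literature fetching is out of scope; the readers accept
  files in the standard formats.
- The attention score's absolute values are meaningful only relative to one
  configuration; comparisons across configs are not supported.
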