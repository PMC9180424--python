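# Methods

## Overview

`hazetol` estimates how well a population tolerates haze episodes by fusing
two branches of evidence. The *provincial* branch scores each region-year
with a weighted sum of 18 standardized indicators organized in three rule
layers (ecological environment: C1–C5; social economy: C6–C13; social
media: C14–C18). The *prefecture* branch condenses a scored microblog
corpus and PM2.5 into a single ratio per region-season, then tracks its
5-class trajectory over time. Everything downstream of raw text operates on
explicit, typed intermediates (token lists, season aggregates, weight
vectors), so each stage can be validated in isolation.

## Text preprocessing

Cleaning removes URLs, @mentions, hashtag markup (both the paired
`#topic#` form, which may contain spaces, and bare `#tag`s) and emoji,
defined as Unicode pictograph/emoticon codepoint blocks so no lexicon is
needed; whitespace is then collapsed. Cleaning is idempotent. Tokenization
is an injected callable; the default splits on whitespace/punctuation and
lowercases, which is adequate for the synthetic vocabulary and for Latin
scripts. A dictionary-based segmenter for Chinese can be plugged in without
touching any downstream contract. Stop-word filtering is an
order-preserving set removal against a plain-text list (a small English
default ships with the package).

No deduplication or advertisement-detection heuristics are implemented:
there is no principled rule to encode, and silent heuristics would be
harder to audit than their absence.

## Sentiment model

A multinomial naive-Bayes classifier with additive smoothing
`P(w|c) = (n_{w,c} + α) / (N_c + αV)` (α = 1 by default, V the training
vocabulary size) produces the positive-class posterior in [0, 1], computed
in the log domain and renormalized through a max-shifted logsumexp, so
complementarity `P(pos|d) + P(neg|d) = 1` holds to machine precision.
Out-of-vocabulary tokens fall back on the smoothed floor `α/(N_c + αV)`.
α = 0 is rejected at training time: a single unseen-in-class token would
zero out an entire posterior.

Polarity uses the strict rule: positive iff score > 0.5; a score of exactly
0.5 counts as negative. Season aggregates (`WEp`, `WEN`, `AEp`, `AEN`) are
computed per (region, winter season), where the winter labelled Y spans
December Y through February Y+1; an empty polarity group yields count 0 and
an explicitly flagged undefined mean, never a placeholder number.

## Keywords, topic index, perception index

TF-IDF uses tf = count/document-length and idf = ln(N/df) with no offsets
(a ubiquitous term scores exactly 0); ties rank lexicographically. The
dialect is deliberately minimal and is fixed by the tested examples.

The **topic index** is a co-word statistic: build the document-level
co-occurrence network (edge weight = number of documents containing both
tokens, counted once per document), then divide the total weight of edges
incident to a haze seed-term set by the number of documents. This exact
functional form is a package design choice — the underlying idea, a
co-occurrence-network intensity of haze discussion, admits many
formalizations and no canonical one exists. The chosen form is invariant
to corpus duplication and to token order/repetition within documents,
which are the properties the tests pin down.

The **perception index** is the weighted sum (default equal weights) of
three min-max standardized components: haze-post share, haze-post count,
and topic index. It is dataset-relative by construction: 1 means "at the
maximum of every component in this panel". User counts are not a component
(only post-level data exist in the pipeline).

Indicators C14–C18 per region-season: C14 = post count, C16 = mean
sentiment score, C18 = topic index, and C15/C17 are Pearson correlations of
daily post count and daily mean sentiment against daily mean PM2.5 within
one winter. Correlations need ≥ 3 paired days and non-degenerate variance;
otherwise they are flagged missing, never silently defaulted.

## AHP–entropy weighting

Judgment matrices are validated as square, positive, unit-diagonal and
reciprocal (`a_ij·a_ji = 1` within 1e-3 relative; offending cells are
listed). Weights are the principal right eigenvector, computed by power
iteration (relative tolerance 1e-12, max 10 000 iterations — Perron–
Frobenius guarantees convergence for positive matrices); λmax is the
converged eigenvalue functional Σ(Aw) under Σw = 1. The tests cross-check
against a dense `numpy.linalg.eig` oracle to 1e-8 for all orders up to 9.
`CI = (λmax − n)/(n − 1)` and `CR = CI/RI(n)` with the standard tabulated
RI values; CR is defined as 0 for n ≤ 2 where RI = 0. Matrices with
CR ≥ 0.1 are reported inconsistent (reports carry λmax, CI, RI, CR).

Hierarchy composition multiplies the rule-layer weight by the within-group
weight; the bundled fixtures reproduce a topic-index absolute weight of
≈ 0.25. Note one subtlety of the shipped ecological matrix: its printed row
order (temperature first) does not follow the C1..C5 indicator numbering
(air quality first), so the package maps matrix rows to indicator columns
by an explicit per-group label list rather than by position in the panel.

Range standardization maps benefit columns to `(x−min)/(max−min)` and cost
columns to `(max−x)/(max−min)`; exact zeros are then replaced by 0.01 so
the entropy shares stay strictly positive, and constant columns map to all
ones — they carry zero information and receive zero entropy weight, which
matches the method's intent better than an error. Which of the 18
indicators are cost-type is an analysis input, not a fact of the system;
the shipped default treats pressure-type indicators (C1 PM2.5 level, C5
pollution days, C6 population density, C8 secondary-industry share) as
costs and the rest as benefits.

Entropy weights: `P_ij = Y_ij/Σ_i Y_ij`,
`e_j = −(1/ln m) Σ_i P_ij ln P_ij` with m the number of evaluation objects
(this base makes `e_j ∈ [0, 1]` exactly), `S_j = (1−e_j)/Σ_j(1−e_j)`.
Combination weights are the closed-form normalized geometric mean
`ω_j = √(ω1_j ω2_j)/Σ_k √(ω1_k ω2_k)` — the geometric mean is the
closed-form solution of the usual "stay close to both" optimization, so no
separate optimizer is involved. The composite score is the weighted sum of
standardized values, with per-indicator contributions retained.

## Tolerance index and classes

`T = (WEp·AEp)/(WEN·(1−AEN)·C_PM2.5)`. T is linear in WEp and AEp,
inversely proportional to WEN and to PM2.5, and *increases* in AEN: since
negative posts score below 0.5, a higher mean negative score means milder
negativity and hence more tolerance. T is undefined — a flagged missing
value — when either polarity group is empty or AEN = 1; silently patching
an epsilon in would distort the class binning. Classes 1–5 are
equal-interval over the pooled range of all defined T values in the panel
(right-open intervals, last closed), so codes are comparable across
seasons; a degenerate single-value range takes the top class. Raw T is
emitted alongside the class code; no additional standardization of T is
applied before classification.

## Trajectory coding

`C = Σᵢ Pᵢ·10^(q−i)` with states 1–9 as positional digits (stored as digit
strings in outputs; integers are exact for q ≤ 18). Decoding validates the
digit count and rejects zero digits. Change types are assigned from the
sequence of successive differences with zeros (plateaus) dropped and
equal-sign runs collapsed: empty → no change, (−,+) → decline–rise,
(−,+,−) → decline–rise–decline, (+,−,+) → rise–decline–rise, everything
else → complex. Two consequences worth noting: internal plateaus do not
break a single decline–rise shape, and purely monotone sequences fall into
*complex* because the five-type taxonomy has no monotone class. The
classifier is total over {1..5}^q and invariant to any strictly increasing
relabeling of states.

## Synthetic-data generator

The generator *is* the study conditions, not a tuning surface.

* **PM2.5**: daily winter values per region, lognormal with the log-mean
  chosen so the arithmetic mean equals the configured region level
  (`μ = ln m − σ²/2`; σ = 0.3 by default), strictly positive and
  right-skewed like real pollution series. The seven default region levels
  are 90, 88, 75, 80, 86, 60, 67 µg/m³ — the printed winter means of the
  studied period reused as regional levels; winters run 90 days from
  1 December.
* **Corpus**: daily post counts are Poisson with a log link on
  standardized log PM2.5 (slope 0.4 — volume rises with pollution); each
  post's latent class is Bernoulli with
  `P(positive) = σ(logit(0.55) − 0.8·z)`, i.e. sentiment degrades as PM2.5
  rises; tokens are multinomial draws from class-conditional Zipf-tilted
  distributions over a 200-token vocabulary in which haze terms are
  up-weighted in negative posts and clear-weather terms in positive ones.
  This is exactly the generative family the naive-Bayes scorer assumes, so
  classifier recovery is well-posed. Generated posts carry their latent
  class as a ground-truth label for validation; the scorer never reads it.
  Default sizes are 2 000 labeled training posts and roughly 10 000
  scoring posts — a desk-scale emulation of a much larger annotated corpus.
* **Panel**: C1/C5 derive from the generated PM2.5 (seasonal mean; days
  above 75 µg/m³), C2–C4 are synthetic winter weather, C6–C13 are draws
  around persistent region levels within plausible published ranges (the
  true distributional forms of these yearbook indicators are not
  documented anywhere; the ranges are conventions), and C14–C18 are
  computed from the generated corpus through the sentiment and keyword
  modules — the panel is internally consistent with the corpus.
* **Class raster**: per-unit Markov chains over states 1–5 with a
  persistence parameter (1 freezes sequences; 1/5 is the uniform
  transition).

All randomness flows from one seed through named substreams
(`default_rng([seed, stream])`), so an identical configuration yields a
byte-identical serialized bundle.

What the generator does **not** emulate: real linguistic content (tokens
are symbolic), holiday effects and other calendar structure, spatial
autocorrelation between neighbouring regions, user-level behaviour
(re-posting, bots, ad spam), and measurement error in the yearbook
indicators. Passing tests therefore demonstrate that the pipeline recovers
the statistical couplings it assumes — not that those couplings hold in
any particular real corpus.

## Numerical choices and degenerate inputs

* Power iteration tolerance 1e-12 (relative, sup-norm), max 10 000 steps;
  non-convergence raises rather than returning a stale vector.
* Naive-Bayes scores are renormalized from max-shifted exponentials, so
  long documents cannot underflow.
* Score exactly 0.5 → negative; unseen tokens → smoothed floor; empty
  documents → prior.
* Equal-interval binning: right-open intervals, last closed; single-value
  range → top class; missing T → missing class → missing trajectory state
  → missing change type (flags propagate, never convert to numbers).
* Entropy: tiny negative `1 − e_j` from round-off (≤ 1e-12) is clipped to
  zero; an all-uniform panel is a hard error.
* Reciprocity tolerance 1e-3 relative on `a_ij·a_ji` accommodates the
  5-decimal rounding of published matrices.

## Problem sizes

Default test and pipeline runs use 3–7 regions, 3–7 winters of 30–90 days
and corpora of 10³–10⁴ posts; the replicate-based recovery check uses 100
seeds at ≈ 5 000–6 000 posts each. These sizes make every statistical
property it asserts stable while keeping a full run in the tens of seconds
on one core.

## Known limitations

* The published socio-economic block of the reference weight table cannot
  be reconciled with its own judgment matrix (its column also does not sum
  to 1), so only the ecological and social-media blocks serve as
  reproduction anchors; the package computes all three blocks from the
  matrices and documents the discrepancy rather than reverse-engineering
  the printed numbers.
* The topic index and perception index are documented proxies (see above);
  results using them are comparable within a dataset, not across different
  formalizations.
* The tokenizer default is not a Chinese segmenter; for real Weibo text a
  dictionary-based segmenter must be injected.
* Equal-interval classes depend on the pooled range, so adding a season
  can relabel earlier seasons' classes; this is inherent to the method,
  not an implementation artifact.
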