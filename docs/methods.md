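# Methods

This note documents the statistical procedures implemented in
`vapelens`, the assumptions behind them, the parameters that matter,
and what the synthetic-data tests do and do not establish.

## Corpus construction

Posts are matched against three keyword taxonomies (e-cigarette terms,
144-keyword-style health lists in nine categories, flavor lists in
seven categories). Matching is case-insensitive on token boundaries;
a multi-word keyword matches as a contiguous token sequence and, at any
position, the longest matching keyword wins (so "sore throat" never
also counts as "throat"). Hyphens are tokenized away but keyword
variants are kept as distinct list entries ("e-juice" is the token
sequence `e juice`; "ejuice" is a single token), mirroring the explicit
enumeration of spelling variants in curated lists.

**Disambiguation.** Semantically overloaded keywords carry a
sentence-level context rule: a "tobacco" hit survives only if the same
sentence contains one of ten context terms (*flavor*, *e-liquid*,
*juice*, …), separating tobacco-*flavor* discussion from combustible
tobacco. Sentences are split on `.!?` followed by whitespace, and on
newlines; this is deliberately simple and documented rather than
delegated to a parser dependency.

**Cleaning.** URLs and email addresses are stripped before matching; a
post that is empty afterwards, or whose tokens are less than 50 %
ASCII-alphabetic (a cheap English heuristic, pluggable), is dropped.

**Precision auditing** draws a seeded sample of matching posts per
keyword with the hit sentence highlighted, for manual relevance
labeling; precision is relevant/sampled.

**Keyword enrichment** uses Apriori frequent-itemset mining (absolute
min-support, itemsets up to size 3 by default) over per-post token
sets. Candidates are non-seed tokens co-occurring with a seed keyword
in a frequent itemset, ranked by best co-itemset support. They are a
review queue for a human curator; nothing is ever auto-appended to a
taxonomy.

## Temporal trends

Counts are aggregated per UTC calendar month (timestamps are epoch
seconds, so month boundaries are unambiguous); a post increments each
of its categories once regardless of keyword multiplicity (a
mention-count mode exists for sensitivity analysis). Category series
are normalized by total monthly corpus volume; a month with zero total
yields a missing proportion, not zero. Percentage shares are reported
to two decimals; the default quantization is rounding, with truncation
available — published tables are not always consistent about which
convention they used, so both are first-class.

## Sentiment

Scores come from a valence lexicon: raw valences of lexicon hits are
summed (negation within a three-token window multiplies by −0.74;
optional boosters add ±0.292 per exclamation mark and ±0.733 for
ALL-CAPS emphasis) and the sum *s* is squashed to [−1, 1] as
*s/√(s² + 15)* — the published compound-score design. The bundled
lexicon is a small synthetic stand-in sufficient for hermetic tests; an
adapter for the reference VADER implementation exposes the same
`score(text)` interface when that package is installed.

Because symptom words are intrinsically negative ("headache" −1.7),
every health keyword that carries nonzero lexicon valence is replaced
by the neutral placeholder `X` before scoring (configurably, all health
keywords). Neutralization is idempotent and exact on token boundaries.

Propensity discretizes the score: positive at ≥ +0.05, negative at
≤ −0.05, neutral strictly between. Within each category the positive
and negative proportions are compared with a pooled two-proportion
z-test; note the two proportions share a denominator (the same post
set), so the independent-samples test is an approximation used for
fidelity to standard practice rather than statistical purism. P-values
are Bonferroni-adjusted across the categories tested (m defaults to
the number of categories; 9 in the canonical taxonomy).

## Topics

Preprocessing lowercases, lemmatizes (pluggable; the bundled fallback
is a conservative suffix-stripper handling plurals and -ing/-ed forms)
and removes stopwords. Frequent adjacent pairs are merged into single
terms when the count-based phrase score

    score(a, b) = (count(a,b) − min_count) · V / (count(a) · count(b))

exceeds a threshold (defaults min_count = 20, threshold = 10, V the
vocabulary size); merging is greedy left-to-right and non-overlapping,
and a second pass builds trigrams from merged bigrams.

LDA is fit by collapsed Gibbs sampling implemented in this package so
that runs are hermetic and bit-reproducible from a seed: each token's
topic is resampled from p(z=k|·) ∝ (n_dk+α)(n_kw+β)/(n_k+Vβ) with
counts excluding the current token. Defaults α = 50/K, β = 0.01; the
study-scale default K = 100 with 1000 sweeps is scaled down in tests
(K ≤ 20, ≤ 300 sweeps) purely for runtime. One uniform variate per
token per sweep is pre-drawn from a seeded generator, so the
numba-compiled and pure-Python kernels produce identical assignments.

Topic labeling (flavor/health/other by counting taxonomy keywords among
the top-n terms, flavor winning ties) is a reproducible proxy for what
is, in the original workflow, a manual judgement; its counts should be
read as approximations of a human labeling.

## Associations (GEE)

Posts with **exactly one distinct flavor keyword** and at least one
health keyword yield one entry per distinct health keyword:
(user, post, flavor category, health category). For each health
category *h*, the outcome of an entry is y = 1{health = h} and the
design is a cell-means indicator over flavor categories (no
intercept), so each coefficient is directly the log-odds of
co-mentioning *h* for that flavor and probabilities are read off as
expit(β_f). Across exhaustive health categories the per-flavor
probabilities sum to 1 under the independence working model — a useful
internal consistency check. The response definition is a modeling
choice made here (the alternative — P(flavor ∧ health per post) — is
not identifiable from an entry list); it matches the row structure of
a flavor × health probability heatmap.

Estimation solves the generalized estimating equations with an
exchangeable (compound-symmetry) working correlation over each user's
entries: Fisher scoring initialized at the independence solution, with
the dispersion φ and correlation α re-estimated each step from Pearson
residuals by the standard moment estimators (α is truncated at its
feasibility bound −1/(m_max−1) from below). The reported covariance is
the robust sandwich B⁻¹MB⁻¹, so inference is valid even when the
working correlation is wrong — which is exactly the situation the
generator creates (random effects, not exchangeable errors).
Convergence is max |Δβ| < 1e-6 within 100 iterations. Flavor levels
with fewer entries than a threshold (default 10) are excluded as
too-small cells; levels with constant outcome sit on the parameter
boundary and are reported as probability 0/1 with a flag instead of a
diverging coefficient.

Pairwise flavor contrasts within a category use the single-step Tukey
adjustment on the studentized range at infinite degrees of freedom
(GEE inference is asymptotic, so ν = ∞ rather than a finite-df HSD):
p_adj = P(Q_{k,∞} ≥ |z|√2). At k = 2 this is identical to the
unadjusted two-sided normal p-value; for k > 2 it is conservative for
every contrast. Separate binary models are fitted per health category
rather than one joint multinomial model; the per-category fits are the
directly interpretable objects and impose no cross-category
constraints.

## Synthetic generator

The generator emulates the structure the analysis assumes, not the
surface of real social-media text:

- **Users and volume** — n_users (default 500 for unit work, 2000–2500
  in recovery tests) with Poisson(4) posts each over a 2013-01…2019-04
  monthly window, volume following a configurable multiplier series
  (default: linear growth ×2 across the window).
- **Flavors** — each post carries at most one flavor keyword by
  construction (default category frequencies: Fruit 0.20, Sweet 0.15,
  Menthol/Mint 0.12, Mixed 0.12, Tobacco 0.08, Beverage 0.08; the
  remaining 0.25 of posts mention no flavor). Tobacco templates embed a
  context word so the disambiguation rule passes. A contamination rate
  can inject second flavors to exercise the exclusion rule.
- **Co-mentions** — a flavor×health matrix gives P(health category |
  flavor) per post; the default anchors the handful of co-mention
  probabilities reported for this kind of corpus (e.g. Menthol-
  Respiratory 0.200, Menthol-Throat 0.344, Sweet-Throat 0.301) and
  fills the remaining cells so each conditional row sums to 1 over the
  eight modeled symptom categories.
- **Within-user correlation** — each user draws one N(0, sd) logit
  effect *per health category* (plus a scalar effect on the any-health
  propensity); the conditional row is shifted cellwise and
  renormalized. A single shift shared by all categories would cancel in
  the renormalization and induce essentially no correlation (measured
  α ≈ 0.01); the per-category construction yields α ≈ 0.09–0.16 at
  sd = 1.5, which is what a compound-symmetry working model is meant to
  absorb. Because the GEE is population-averaged, the recoverable truth
  is the *marginal* matrix E_b[row_u], computed by seeded Monte Carlo
  integration (400k draws; error < 5e-4 per cell) in
  `marginal_comention_matrix`; at sd = 0 it equals the configured
  matrix exactly.
- **Sentiment** — post text is assembled from templated sentences whose
  polarity is drawn per health category (default 55/15/30
  positive/neutral/negative; Cancer 15/10/75), using words with known
  bundled-lexicon valences, so planted propensity mixes are recovered
  up to binomial error.

What a green test therefore establishes: correct arithmetic and
estimating-equation algebra, planted-parameter recovery under the
generator's assumptions, and end-to-end plumbing. What it does not
establish: robustness to real linguistic variety (sarcasm, typos,
code-switching), to keyword-list incompleteness, or to confounding —
the generator has no demographics, no device covariates, and no
scare-story dynamics, and co-mention is not causation.

## Numerical choices

- Two-proportion z-test: pooled variance; degenerate tables (pooled
  proportion 0 or 1) return p = 1 with a flag. z² equals the 1-df
  chi-square without continuity correction.
- Tie-breaks: top topic terms break probability ties lexicographically;
  itemsets sort by (size, −support, lexicographic).
- Quantized percentage display: round-half-even by default; truncation
  mode available.
- All stage seeds derive from one root seed (SHA-256 fan-out, kept
  below 2³¹); no stage touches global random state.

## Known limitations

- The bundled lexicon is tiny; real-corpus scores require the reference
  VADER lexicon through the adapter.
- The suffix-stripping lemmatizer under-stems irregular forms; plug in
  a real lemmatizer for production text.
- The independent-samples z-test on overlapping positive/negative
  denominators is anti-conservative; treat borderline category
  significance with care.
- Separate per-category GEEs do not enforce that fitted probabilities
  sum to 1 across categories under the exchangeable working model
  (they do exactly under independence, and approximately otherwise).
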