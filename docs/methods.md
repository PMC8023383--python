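# Methods

## Problem and scope

The package implements the analysis pattern used to monitor public
vaccine sentiment on social media: collect posts, keep the on-topic ones,
classify each as negative / neutral / positive, and summarize the labels
over time, across platforms, and over geography. Platform data
collection itself is out of scope (the collection adapters are the
user's concern); everything from filtering onward is implemented and
tested against synthetic corpora with known ground truth.

## Thematic and geographic filtering

A post is retained iff its raw text matches at least one stage-1
(COVID-related) term AND at least one stage-2 (vaccine-related) term.
Matching defaults to word-bounded and case-insensitive on the raw,
un-preprocessed text; both choices are exposed as options
(`match_mode`, `case_sensitive`) because neither convention is forced
by the problem. Word boundaries are implemented as `(?<!\w)term(?!\w)`
so hyphenated terms such as `covid-19` anchor correctly. Consequence of
no stemming: `immunise` does not match `immunised`; inflected forms must
be listed explicitly in the term files. The stage-2 default list is the
six-term vaccine vocabulary (vaccine, vaccination, immunise, immunize,
immunisation, immunization); the stage-1 COVID list is a small editable
default since topic vocabularies are corpus-specific. Geographic
filtering is exact membership of the record's country code; posts with
no country are tallied separately as "no-location" rather than silently
merged with off-target countries. Duplicate texts are kept unless the
explicit dedupe flag is set.

## Preprocessing

Fixed order: strip URLs → drop `#`/`@` tokens → lowercase → tokenize on
non-word characters with apostrophes kept inside words → drop stop
words → drop empties. Hashtags are removed as whole tokens (an option
retains the bare word); mentions are always removed as they are handles,
not content. The pipeline is idempotent on its own output, which is
property-tested. No stemming, lemmatization, or emoji handling.

## The hybrid ensemble

Two lexicon polarities are averaged with weights (0.45, 0.55) — the
second scorer weighted marginally higher — and ternarized with a neutral
band τ = 0.05; band boundaries (|s| = τ) resolve to neutral. τ is a
convention for compound-score ternarization, not an estimated quantity.
The lexicon label is fused with a classifier label through a total
9-entry rule table; the default — lexicon wins iff it says positive,
classifier wins otherwise — encodes the sensitivity pattern this model
family exhibits (lexicons better on positive posts, trained classifiers
better on neutral and negative). Because deployed rule sets vary, the
table is fully overridable in configuration, and a custom table must
cover all nine pairs at load time.

Backends are contracts. The bundled lexicon scorer returns the mean
valence of in-lexicon tokens (0 when none match) from a CSV valence
table; adapters to VADER and TextBlob request raw text (they use
punctuation and capitalization cues) and import their packages lazily.
The classifier slot takes any callable text → label (+ optional
probability vector, validated for coherence); tests and the default
pipeline use a deterministic keyword-triggered mock, and a
pretrained-transformer adapter is provided but never exercised by the
suite. A backend failure marks that post as errored and the corpus run
continues; errors are counted in the audit output.

## Validation

A simple random sample without replacement of floor(fraction·n) posts
(default fraction 0.10, optional per-platform stratification) is
exported as an annotation sheet and re-imported with labels filled. The
confusion matrix convention is rows = true class, columns = predicted,
ordered (negative, neutral, positive); row normalization leaves
zero-count rows all-zero and flags them. Per-class one-vs-rest
sensitivity TP/(TP+FN) and specificity TN/(TN+FP) report NaN — not
zero — on undefined denominators. No auto-tuning of weights, τ, or the
rule table is performed from validation results; they are exposed as
configuration instead, since any particular optimization recipe would be
an invention.

## Trends and statistics

Weeks are ISO weeks with Monday start. Per (country, platform, week),
proportions are class count over total; weeks with no posts are emitted
with n = 0 and a missing proportion — missing weeks are dropped pairwise
in correlations rather than zero-filled, because zero-filling fabricates
signal. Overall percentages are half-up rounded to two decimals.
Cross-platform country figures are the **unweighted** arithmetic mean of
the two platform percentages, averaged in decimal arithmetic so printed
two-decimal inputs stay exact (mean(27.95, 17.04) = 22.495 → 22.50,
which binary-float averaging would round to 22.49). Post-volume
weighting is deliberately not used: the unweighted mean is the
aggregation that reproduces published overall-vs-per-platform figures.
Pearson r uses the standard product-moment estimator (scipy); constant
series return NaN with a warning rather than a fabricated 0.
`trend_strength` is r between a series' proportions and integer week
index: sign gives direction, magnitude strength.

## Mining and geography

N-grams are contiguous within-post sequences over cleaned tokens; no
grams cross post boundaries, so the total count is
Σ_posts max(0, len − n + 1), which is property-tested. Tables are sorted
by descending count with lexicographic tie-break, making top-k
selection deterministic. Region aggregation averages ternary label
values per region — mean = (n_pos − n_neg)/n, bounded in [−1, 1] — with
a continuous-score option; the class band τ_geo = 0.05 mirrors the
ensemble's neutral band, and regions with fewer than min_posts = 10
labeled posts are reported as low-coverage rather than mapped, to avoid
single-post regions dominating a choropleth. GeoJSON export joins onto
a user-supplied FeatureCollection keyed by region id; no basemaps or
geometries are bundled.

## Synthetic corpus generator

The generator is first-class, tested code, and its defaults are the
study conditions used throughout the suite:

- **Window**: 2020-03-01 to 2020-11-22, timestamps uniform within the
  range (weekly aggregation makes finer temporal structure irrelevant).
- **Trend**: class probabilities (negative, neutral, positive) are
  piecewise-linear in ISO-week index between knots — the simplest
  structure that can express observed peaks and inflexions. The default
  curve rises in positive share from 0.47 to 0.62 with a negative bump
  (0.15 → 0.24) in the mid-October week, the qualitative shape reported
  for this period, and baseline shares chosen so the emitted overall
  percentages land near the published ballpark (negative share ~17% on
  the unmultiplied platform).
- **Platform effect**: one platform (default Twitter) has its negative
  probability multiplied by 2.0, then the vector is renormalized —
  producing the roughly two-fold Twitter-vs-Facebook negativity gap.
- **Regions**: an additive offset δ per region moves probability mass
  from negative to positive (pos += δ, neg −= δ, clipped, renormalized);
  |δ| is capped at 0.5 so probabilities stay valid. Default offsets are
  ±0.03–0.06 across five GB counties and five US states.
- **Text**: a bag of class-conditional valenced tokens (5–12 per post)
  joined by spaces, plus an optional URL token (p = 0.2) and hashtag
  token (p = 0.25); with probability `keyword_inclusion_prob`
  (default 0.9) one stage-1 and one stage-2 keyword are inserted, giving
  the thematic filter exact ground truth. Token pools avoid the filter
  keywords so inclusion is controlled solely by that probability.
- **Determinism**: one `numpy` generator seeded from the config; two
  runs with identical configs produce byte-identical corpora.

What the generator does **not** emulate: grammar, sarcasm, negation
scope, code-switching, bots, engagement counts, or share networks.
Passing tests therefore demonstrate that the pipeline machinery is
correct and recovers planted statistical structure — not that any
particular backend is accurate on real discourse; that question is
exactly what the annotation-validation stage answers on real data.

## Problem sizes and numerical choices

Recovery checks run at the sizes where their statistical tolerances are
meaningful: trend recovery uses 38 ISO weeks at ~1,000 posts/week
(binomial SE ≈ 0.016 per week against a planted positive ramp
0.30 → 0.70, giving expected r ≈ 0.99 against the ≥ 0.95 bar); the
platform-ratio check uses n = 20,000 with a constant base negative share
g = 0.2, where the renormalized theoretical ratio is 2/(1+g) ≈ 1.67;
sensitivity recovery uses n = 2,000 with planted error rates
(0.10, 0.20, 0.05) and a 3-binomial-SE band. Distributional recovery is
a chi-square goodness-of-fit at n = 10,000 (p > 0.01, fixed seed).
Probability vectors must sum to 1 within 1e-9; ensemble weights within
1e-9; classifier probability vectors within 1e-6.

## Known limitations

- Lexicon and classifier quality on real text is entirely a backend
  property; the bundled scorers are small valence tables intended for
  testing and illustration, not deployment.
- Country/region fields are taken at face value; no location inference
  from profiles or geocoding of place names.
- No changepoint detection or smoothing on trends; event attribution
  around inflexion points is left to the analyst (the n-gram tables
  support it).
- The English stop-word list and keyword defaults presume an English
  corpus; there is no language detection.
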