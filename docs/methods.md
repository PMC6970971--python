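# Methods

This note documents the models and procedures implemented in `calotext`,
the parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not show.

## Text normalization

A post is reduced to lowercase alphabetic content tokens in five stages:
emoticon/emoji conversion to textual names, lowercasing, tokenization with
stopword removal, special-character stripping, and digit removal. Three
tables are shipped in-package and versioned with the code so that output
never drifts with an external library release: an emoticon/emoji map
(symbol → name, longest symbol wins), a curated English stopword list, and
a contraction rule table (`gonna` → `gon na`, …). Hashtagged text is kept
(`#rofl` → `rofl`) because hashtags often carry the food signal; URLs and
@mentions are deleted outright since their residues are non-lexical noise.
Unicode is NFKC-normalized before anything else.

Two asymmetries are deliberate. First, the emoticon stage case-folds plain
words while leaving hashtag tokens and the inserted emoticon names to the
dedicated lowercase stage; this matches the staged outputs the pipeline is
specified against and is observable via `clean_steps()`. Second, a token
that is reduced *to* a stopword by stripping (`0I` → `i`) is dropped in a
final filter, which makes the whole pipeline idempotent: re-cleaning its
own output is a no-op (property-tested on random text).

Sentence-like boundaries (`. ! ?`) seen in the raw text are recorded as
token offsets on the cleaned post. Downstream phrase matching never crosses
a recorded boundary. The splitter is deliberately crude (it will split
"Mr. Smith"); for short informal posts this costs little and avoids a
sentence-segmentation dependency.

## Lexicons and the vegan rule

Food entries carry per-100 g nutrients (fat, energy, carbohydrate) with
energy read as kcal, consistent with the activity lexicon's kcal values.
Lexicon keys are canonicalized with the same normalization applied to
posts, plus heuristic plural folding (`potatoes` → `potato`,
`fries` → `fry`; -ss/-us/-is endings left alone), so cleaned post tokens
and lexicon keys live in one space and canonicalization is a fixed point.
Duplicate canonical names are merged by the arithmetic mean of each
nutrient with a warning — a deliberate policy for multi-source lexicons
where collisions are expected and no source is privileged. Rows with
negative, non-finite or non-numeric nutrients are rejected and counted.

A food is tagged vegan iff the token `vegan` appears in its name or its
category is vegetable, fruit or juice; everything else is non-vegan. When
the table has no category column the category is inferred from packaged
keyword lists (vegetable/fruit/juice names). Keyword membership is an
approximation — `sweet potato` is correctly a vegetable, but a novel
compound whose head noun is absent from the lists falls back to `other`.

Nutrient profiles are Gaussian kernel density estimates (Scott's-rule
bandwidth via `scipy.stats.gaussian_kde`) evaluated on a 512-point grid
spanning `[min − 3h, max + 3h]`, then renormalized on the grid so each
curve's trapezoidal integral is exactly 1 (the estimate is explicitly a
*normalized* KDE; without renormalization up to ~0.1% of kernel mass can
leak past the grid edges for very small groups). A group with one distinct
value but ≥ 2 points is rendered as a point-mass limit using a tiny
fallback bandwidth (`max(|v|, 1) × 10⁻³`); fewer than 2 data points is a
degenerate-input error, and an empty group in a vegan split is skipped
with a warning rather than failing the other group.

## Multiword expressions and idiom masking

An inventory form is stored stopword-free and singular (`apple of my eye`
→ `apple eye`): because cleaning removes the function-word linkers anyway,
matching adjacent content tokens against stopword-free forms is equivalent
to linker-aware matching on raw text, and one normalization path serves
both posts and inventory. Matching is greedy leftmost-longest over each
sentence span with candidate length capped at 4 content tokens (longer
gold entries are truncated with a warning; none of the packaged entries
need more after linker removal). Plural folding happens at match time
only; surface tokens are preserved in all outputs.

Greedy leftmost-longest is exact for per-edge dominance (the match at any
left edge is the longest available there) but not globally optimal for
total coverage; the test suite checks the per-edge property exhaustively
against a brute-force enumerator on all sequences of length ≤ 6 over a
10-form inventory. Inventory relatedness is boolean membership; a graded
relatedness score is a noted extension point.

Idiom masking runs before any caloric or labeling use of the tokens:
idiom-tagged forms are matched first and every covered token position is
masked. Masked positions are invisible to mention counting and to weak
labels, and matching never bridges a masked position. This gives idioms
strict precedence over food compounds sharing tokens.

The packaged gold inventory (~100 entries) contains common English food
idioms and multiword food/activity compounds. It is a fixture-scale
curated list, not a download of the supersense-tagged corpora that a
production system would train on.

## Classification

Features are unigrams plus matched phrases as single features (a matched
phrase consumes its unigrams). The tf-idf dialect is pinned: raw counts,
smoothed idf `ln((1+N)/(1+df)) + 1`, L2-normalized rows — exactly
scikit-learn's `TfidfVectorizer` defaults, which the implementation uses
with an identity analyzer over pre-built feature lists. Model families:
multinomial naive Bayes, logistic regression (lbfgs, max_iter 2000),
random forest (100 trees), linear-kernel SVM. All are deterministic given
the constructor seed; the estimator follows the scikit-learn protocol
(`fit`/`predict`, `get_params`, fitted attributes with trailing
underscores) and composes with sklearn model selection.

Confusion matrices use the fixed class order (food, non-food), rows =
true classes; the false-positive rate is the row-normalized
[non-food, food] cell. Learning curves hold out a fixed stratified 20%
split, then for each training size average held-out accuracy over seeds;
sizes must be strictly increasing.

When no human labels exist, weak supervision labels a post `food` iff at
least one unmasked token or phrase hits the food lexicon. Idiom masking
participates: a post that is only "a piece of cake" is weak-labeled
non-food. Synthetic gold labels override weak labels in tests.

## Caloric engine

`C_in` and `C_out` are mention-weighted means (sums normalized by total
mention frequency), making `C_rat = C_in / C_out` a dimensionless
intensity comparable across regions of different posting volume. The
caloric value of a food mention is its per-100 g energy — a proxy, since
posts do not reveal portion size; this is a stated limitation, not a
modeling claim. Activity values are kcal per mention at a reference body
weight of 80.7 kg (configurable); supplying a subject weight rescales
burns linearly by `subject/reference`.

Undefined quantities are signalled (`UndefinedCaloricResult`) rather than
coerced: a scope with zero activity mentions has no ratio. In regional
summaries such regions are flagged (`undefined-ratio`, or `insufficient`
below a minimum mention count) and excluded from ratio maps and population
shares. Rankings sort by descending count with lexicographic tie-breaks.
The population share above a threshold is
`100 × Σ pop(r : C_rat(r) ≥ t) / Σ pop(r)` over regions with defined
ratios; a summarized region without a population entry is an error.

Aggregation order is fixed (sorted phrase keys) in both the engine and the
generator's recorded truth, so exact-recovery tests compare floats for
equality rather than within a tolerance.

## Synthetic corpora and what they show

The generator emits per-region posts assembled from neutral chatter plus
injected food mentions, activity mentions and food-word idioms, roughened
with natural casing, stopword linkers, digits, hashtags (p = 0.1) and
emoticons (p = 0.2) so cleaning is genuinely exercised. Defaults: a post
carries a food slot with p = 0.45 and an activity slot with p = 0.35;
chatter length is 2 + Poisson(4); `idiom_rate` is the probability that a
food slot carries an idiom instead of a true mention. Mixes must sum to 1
and reference only known lexicon phrases. Ground truth (per-region C_in /
C_out / C_rat, per-post gold labels, the full mention log) is computed
from what was *emitted*, not from the sampling distribution, so recovery
tests are exact rather than Monte-Carlo. `verify_truth` re-derives the
truths from the mention log with an independent per-mention average.

Benchmark sizes used by the acceptance checks: exact ratio recovery on 10
regions × 5,000 posts (tests) and 10 × 2,000 (acceptance script); the
idiom-masking benefit on 3 regions × 400 posts per seed over 20 seeds;
classifier sanity on a 10,000-post separable corpus with a 20% hold-out.
These sizes give stable results at interactive runtimes; nothing in the
method depends on them.

What passing these benchmarks does **not** show: the generator's chatter
vocabulary is disjoint from the lexicons by construction, so the synthetic
corpora contain no lexical ambiguity (no "turkey" the country vs the
bird), no misspellings, no code-switching, and no covariance between
region and writing style. Synthetic classifier accuracies near 100% are a
property of the separable benchmark, not a claim about real posts.
Similarly, the idiom-masking benefit is demonstrated for idioms present in
the inventory; idioms outside it still bias the counts.

## Known limitations

- Portion size is not modeled; one mention of pizza counts as 100 g worth
  of energy regardless of quantity.
- Plural folding is heuristic; irregular plurals (`children`, `geese`) are
  not folded, and a few overfolds are accepted (`gas` → `ga` is prevented
  by the -ss/-us/-is guard, but rare cases remain).
- The sentence splitter treats every `. ! ?` as a boundary.
- Category inference for the vegan rule is keyword-based and approximate.
- Weak labels inherit every lexicon gap: a food absent from the lexicon
  yields a non-food label.
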