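# Methods

## The model

A word co-occurrence network treats the sentence as the unit of context.
Let `x_w` be the vector of per-sentence occurrence counts of lemma `w` over
the `S` analysable sentences of a corpus. The association between two
lemmas is Spearman's rank correlation

    rho(i, j) = Pearson( rank(x_i), rank(x_j) ),

with average ranks for ties. An undirected edge is kept when
`rho >= rho_min` (default 0.1; inclusive and one-sided, so negative
associations are never edges at the default). The network's nodes are
exactly the words with at least one retained edge; a word's degree
centrality is its number of incident edges; clusters of words with many
internal and few external links are candidate themes, ranked by member
count. The pipeline ranks and summarises clusters; naming themes is a human
judgement and stays outside the code.

Two readings of "occurrence" are supported: per-sentence counts (default)
and binary presence (`binary=True`). For corpora where a word rarely
repeats within a sentence the two coincide; for binary vectors the
average-rank transform is affine, so Spearman equals the Pearson phi
coefficient of the raw vectors — a property the test suite checks to
1e-12 against both a brute-force rank oracle and `scipy.stats.spearmanr`.

## Preprocessing assumptions

* **Sentence delimiters** are `.`, `!`, `?`, `;` and newline; consecutive
  delimiters collapse. This is a declared convention, configurable in
  principle, not a linguistic claim.
* **Word tokens** are maximal runs of Unicode letters with internal
  apostrophes. Digits and other symbols separate tokens, so "COVID-19"
  tokenizes as "COVID".
* **Short-answer filter**: a respondent whose answer has fewer than
  `min_words = 4` raw word tokens (counted before any cleaning, matching
  the screening order) is excluded; exactly 4 words is retained. Retained
  respondents define the denominator of all corpus statistics, including
  documents that later lose every token to cleaning (these are flagged
  `empty-after-cleaning` and merely contribute no occurrence-matrix rows).
* **Cleaning** removes stop-list lemmas, the POS classes {adverb,
  proper-noun, determiner/indefinite-adjective, numeral,
  punctuation/symbol}, and a drop-pattern standing in for truncated or
  malformed forms: length-1 lemmas and lemmas containing non-letter
  characters. Lemmatization is pluggable — a dictionary lemmatizer (TSV
  lexicon; unknown surfaces fall back to the lowercased surface with POS
  "other") or an external tagger's token/POS/lemma file mapped onto the
  closed 9-tag set.
* **Reporting rounding** is half away from zero: one decimal for
  percentages, nearest integer for per-respondent means.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_words` | 4 | short-answer exclusion threshold (raw words, strict `<`) |
| `min_sentence_freq` | 5 | a lemma must occur in at least this many sentences to enter the matrix (applied once) |
| `rho_min` | 0.1 | inclusive edge-retention threshold on Spearman's rho |
| `binary` | off | presence/absence instead of counts |
| `cluster_method` | components | `components` or `greedy-modularity` (CNM agglomeration) |

`min_sentence_freq` is the one materially discretionary constant: a ~79k
word corpus yielding a ~70-node network implies heavy sparsification before
correlation, but no published rule; it is therefore an explicit, logged
parameter rather than an implicit heuristic. Connected components are the
default clustering because at `rho_min = 0.1` on well-separated themes the
thresholded graph is already detached; greedy modularity is provided for
connected graphs, is deterministic, and always refines components.
Stochastic community detection (Louvain with random move order, label
propagation) is deliberately excluded: run-to-run determinism is
prioritised, and all tie-breaks (equal cluster size, equal degree) resolve
lexicographically.

An undefined correlation (a constant occurrence column) never becomes an
edge: such columns are dropped with a log message before the pairwise
computation. Threshold comparison uses an absolute slack of 1e-9 so that a
pair whose exact coefficient equals `rho_min` is retained despite the
binary floating-point representation of 0.1.

## Synthetic corpora

The generator emulates the statistical structure of a large open-ended
maternal-survey corpus, with defaults fixed once as the package's study
conditions:

* 2010 respondents; 6.2% give short non-informative answers (excluded
  downstream); the rest write 1–3 sentences (P = 0.25/0.50/0.25, mean 2.0)
  of ~20 raw words (Poisson(20) clipped to [5, 60]), ~40% of which are
  stop-words — so roughly 76k words and 3.8k sentences per corpus, within a
  few percent of the reference scale (79 204 words, 3833 sentences).
* K = 8 disjoint planted topics of 9 pseudo-lemmas each over a 120-word
  background vocabulary; 80% of sentences are topical. A topical sentence
  contains at least 2 distinct words of its topic (co-occurrence is
  sentence-scoped, so this is what creates recoverable signal); its filler
  and all background-sentence content words are drawn independently from
  the background vocabulary.
* Words are letter-only consonant–vowel pseudo-lemmas so the tokenizer and
  drop-pattern pass them through; one seeded random substream per
  respondent makes corpora reproducible even under partial regeneration.
* Metadata tables can be drawn from categorical distributions or assigned
  with exact per-category counts (e.g. the packaged reference sample counts
  for n = 2010), so reporting arithmetic can be checked against a known
  table.

What the generator does **not** emulate: real grammar and morphology,
polysemy, overlapping or correlated themes (an overlap requires explicitly
overlapping `topic_vocabularies`), respondent-level topic preferences, and
the heavy-tailed word frequencies of natural language. Passing recovery
tests therefore show that the pipeline's machinery is correct under
separation — disjoint vocabularies, independent background — not that real
survey themes are always recoverable; on real text the separation
assumption is an empirical question.

With these defaults the expected behaviour, recomputed by
`scripts/acceptance.py` and the acceptance tests, is: exact recovery of all
K planted topics as K detached clusters (adjusted Rand index 1) in ≥ 95% of
seeds at n = 2000, and essentially zero retained pairs in the null control
(pure background, 100 words × 4000 sentences), where the standard error of
rho is ≈ 0.016 and the 0.1 threshold sits more than 6 standard errors out.

Recovery is scored over the intersection of planted and clustered words;
planted words missing from the network and clustered words outside the
planted sets are reported separately rather than folded into the index.

## Numerical and design notes

* Pairwise correlation rank-transforms each column once and computes a
  single rank-correlation matrix product — identical to per-pair
  `spearman_pair` to 1e-12 (tested), but O(SV² ) instead of O(S V² log S).
* The per-sentence frequency cut is applied once; it is not iterated after
  columns are removed.
* Cluster layout places ranked clusters into disjoint grid cells with a
  seeded Fruchterman–Reingold embedding inside each cell; coordinates are
  rounded to 4 decimals and the SVG serializer emits elements in sorted
  order with no timestamps, so a fixed seed gives byte-identical output.
* The SVG is written directly (circle/line/text elements with explicit
  radius and stroke-opacity) so the encoding contract is assertable
  attribute-by-attribute; the PNG is a matplotlib rendering of the same
  layout and style.
* Degenerate inputs: an empty corpus, an all-empty-sentence corpus, an
  empty edge list and an unknown cluster method raise errors naming the
  problem; a constant degree range or a single retained rho value maps to
  the midpoint area / maximum opacity respectively.

## Known limitations

* Edge retention thresholds the coefficient, not its significance; at a few
  hundred sentences, sampling noise alone can clear 0.1 and attach
  background words to clusters (visible in the small worked example).
  The cure at realistic scale is the sentence count, not a p-value.
* Sentence splitting is rule-based; abbreviations ("dr.") split spuriously.
* The dictionary lemmatizer is only as good as its lexicon; unknown words
  keep their surface form, which fragments counts across inflections
  unless an external tagger's annotations are supplied.
* `min_sentence_freq` interacts with corpus size: at fixed vocabulary,
  larger corpora pass more rare words into the candidate set.
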