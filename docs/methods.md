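# Methods

## Problem setting

Fact-checking chatbots on closed messaging platforms (LINE, WhatsApp)
receive streams of user-reported suspicious messages. The same rumor
circulates as thousands of near-identical copies with small edits — a swapped
authority figure, a new festival date, two rumors pasted together. The
analysis unit is therefore the *rumor group*: a cluster of messages that are
identical or lightly edited variants of one narrative. This package groups a
message corpus into rumor groups and provides the downstream analytics a
rumor-propagation study needs: keyword-based topical tagging with human
confirmation, script-origin flagging with a chi-square independence test,
daily report series with resurfacing peaks, quoted-party attribution, and
exact-variant timelines.

## Distance

For tokenized messages A and B with distinct-token sets tok(A), tok(B):

    d(A, B) = 1 − |tok(A) ∩ tok(B)| / max(|tok(A)|, |tok(B)|)

Binary presence (not counts) is deliberate: near-duplicate detection cares
about which words appear, not how often. Normalizing by the **larger** set is
the load-bearing choice: if A is wholly contained in a much longer composite
message B, overlap/min(|A|,|B|) would call them identical, while overlap/max
keeps them apart — exactly what is needed so that combined rumors do not
bridge their parent groups. d is symmetric, zero iff the token sets are
equal, and 1 iff they are disjoint. The normalizer is configurable
(`max`/`min`/`union`) because the right choice is corpus-dependent in
principle; everything downstream defaults to `max`.

Pairwise matrices are computed by sparse binary incidence algebra
(docs × vocabulary, blockwise `X @ X.T`), which is algebraically identical to
the two-set formula; the test suite asserts elementwise agreement with the
naive computation to 1e-12.

## Clustering

**Threshold HAC.** Agglomerative clustering on the precomputed matrix
(scipy linkage + a flat cut at λ): merging continues while the smallest
inter-cluster linkage distance is ≤ λ and stops when every remaining pair is
farther apart, so the number of groups is data-driven. Default λ = 0.6: two
messages sharing a clear majority of their tokens belong together. The
linkage is configurable (average/complete/single, all valid for a
precomputed non-Euclidean distance); **average** is the default as the
middle ground — single-linkage chains through combined messages, complete
linkage shatters groups with one outlier edit. Flat cuts of a monotone
linkage are verified against a brute-force O(n³) agglomeration oracle on
small random matrices.

**Hybrid HAC+KNN.** Pure HAC is quadratic in time and memory, which hurts at
social-media scale. The hybrid algorithm:

1. sample ⌊u·n⌋ documents uniformly without replacement (seeded);
2. build the sample distance matrix and run threshold HAC on it;
3. demote sample clusters of size 1 to the unassigned sentinel −1;
4. train a k-nearest-neighbor classifier on the sample labels (−1
   included) and predict every holdout document;
5. pool all documents labeled −1 and re-run threshold HAC on that pool,
   with fresh label ids offset past every first-pass id (documents still
   alone after the second pass keep their own fresh id: a group of size 1).

With u = 1 the holdout is empty and the result is exactly the pure-HAC
partition (the second pass cannot merge first-pass singletons, because the
final HAC state already has all inter-cluster distances > λ). This reduction
is asserted exactly on 50 seeded corpora.

**KNN vote rule.** The classifier uses the same set-overlap distance,
uniform votes over the k = 5 nearest sampled documents, ties toward the
smallest label id. One refinement matters: *a neighbor farther than λ
carries no vote, and a document with no neighbor within λ is predicted −1.*
λ is the algorithm's own definition of how far group membership reaches; a
plain majority vote would propagate labels across distances the clustering
itself refuses to merge. Without the rule, holdout documents whose true
group-mates were all left out of the sample (noise singletons, tiny groups)
acquire arbitrary labels from incidental small overlaps — e.g. two otherwise
unrelated messages that share a couple of injected script-marker characters
sit at distance ≈ 0.97, close enough to out-vote nothing at all. With the
rule such documents flow to the second HAC pass, which reconstructs them the
same way pure HAC does. Neighbors at distance exactly 1.0 (zero shared
tokens) never vote regardless of λ.

Degenerate cases: u·n < 2 is a parameter error; a sample with no
non-singleton cluster skips the classifier and sends everything to the
second pass.

## Evaluation

The fidelity protocol scores the hybrid partition against pure HAC on the
same corpus as gold standard, with **pairwise co-membership** metrics: over
all unordered document pairs, precision = co-clustered pairs that are also
co-clustered in gold / all predicted co-pairs; recall mirrors it; F is the
harmonic mean. Pairwise metrics are the standard partition-comparison choice
and match the intended reading that recall measures completeness of groups
and precision measures errors introduced into groups. Conventions: a
prediction with no co-pair has precision 1 against a gold with no co-pair
and 0 otherwise (recall symmetric). The implementation (via the pair
confusion matrix) is tested against direct pair enumeration.

`fidelity_benchmark` repeats the hybrid run over a grid of train portions
with derived seeds and reports mean and a 95% normal-approximation interval
per metric, plus wall-clock seconds (hardware-dependent, for orientation
only — runtimes are never an acceptance quantity).

## Annotation

- **COVID tagging**: keyword matching runs on the *raw* text, lowercased
  substring semantics, because the 33-term default lexicon mixes Chinese
  terms with latin ones ("covid", "2019-ncov") that the character filter
  would delete. A group is a *candidate* when strictly more than 60% of its
  messages contain a keyword (6/10 fails, 7/10 passes); candidates are
  explicitly marked as requiring manual confirmation, and a confirmed
  group's relatedness propagates to every member message regardless of its
  own keywords. The threshold is configurable; 0 flags any group with ≥ 1
  keyword message, 1 flags none.
- **Script origin**: a message is flagged when it contains at least one
  simplified-only codepoint (packaged table of ≈ 330 simplified→traditional
  pairs, restricted to codepoints that are not themselves traditional
  characters) or a mainland-usage phrase (small editable default list).
  Both lexicons are plain-text package data and are best treated as
  starting points — real studies should curate them.
- **Chi-square with Yates' continuity correction** on the 2×2 of
  COVID-relatedness × script flag: χ² = n(|ad−bc| − n/2)² /
  ((a+b)(c+d)(a+c)(b+d)), clamped at 0 when |ad−bc| ≤ n/2, p from χ²(1).
  Cross-checked against `scipy.stats.chi2_contingency(correction=True)`.
  p-values below 0.001 are formatted "<.001".
- **Percentages** are rounded half-up to one decimal (table style);
  quartiles of group-size distributions use linear interpolation and the
  standard deviation is the ddof=1 sample estimate (the conventions are
  stated because published tables rarely state theirs).

## Trends

Daily series bin report timestamps by calendar day in a configurable
timezone (default UTC+8, the study setting), zero-filling gaps. A *peak* is
a day with at least `min_count` (default 10) reports that strictly exceeds
every other day within ± `window` (default 3) days — resurfacing is a
narrative judgement, so the operational definition is deliberately simple
and its parameters are part of any reported result; flat stretches have no
strict maximum and thus no peak. Attribution counts messages containing any
alias of a party (a message may credit several parties — composite rumors
do). Variant timelines key messages by whitespace-normalized exact text and
report first-seen date and count in order of appearance; they are the
quantitative scaffold for manual change-log curation, not a substitute
for it. Societal-event overlays are joined from a user CSV for display
only — no event detection is attempted.

## Synthetic corpora

The generator plants a known partition with the statistical features the
pipeline assumes about a reported-message corpus:

- **Group sizes**: Zipf rank-frequency (p_r ∝ r^−α, default α = 1,
  multinomial allocation), giving the long-tailed shape where a few rumors
  dominate and most groups are small; or fixed sizes for controlled tests.
- **Near-duplicate variants**: each group has a template of distinct
  synthetic tokens (disjoint across groups); each message mutates every
  template token independently with probability `mutation_rate`
  (substitute / insert / delete, equiprobable; noise tokens are fresh
  symbols private to the group). A template token survives unmutated with
  probability s = 1 − 2m/3, so the expected within-group distance is
  ≈ 1 − s² (within the loose bound 2m) while between-group distances are
  exactly 1 — `expected_separation` returns these closed forms and a
  Monte-Carlo test holds the generator to them.
- **Singleton noise** (default ≈ 7.5% of messages) with entirely private
  vocabulary, **combined messages** concatenating two mutated templates
  (excluded from planted-partition scoring — they genuinely belong to no
  single group), **report-date bursts** (1–4 per group, Gaussian around
  random centers, or an explicit burst spec), and **script markers**:
  simplified-only characters appended at a known rate so the script-origin
  annotator has planted ground truth.
- Tokens are whitespace-separated synthetic symbols, so generator
  correctness never depends on a Chinese segmenter dictionary; timestamps
  are ISO-8601 UTC+8.

What the generator does *not* emulate — and hence what passing tests do not
show: real lexical drift (paraphrase, translation, OCR noise), message
length heterogeneity, topical correlation between groups, shared boilerplate
(greetings, chain-letter framing) that pulls real between-group distances
below 1, and report behavior driven by actual events. Results on synthetic
corpora bound the algorithmic fidelity of the hybrid approximation, not
end-to-end grouping quality on real text.

## Preprocessing choices

Pipeline order is fixed: character filter → tokenize → stop-word removal →
minimum-length filter (default 20 tokens, counted after stop-word removal —
the stricter of the two possible readings). The character filter keeps CJK
ideograph blocks only (simplified and traditional share them; no script
normalization is attempted, since simplified codepoints are themselves a
signal for the script-origin annotator) and can be disabled for
synthetic/latin corpora. Tokenizers are pluggable callables; packaged
options are whitespace splitting, a per-character CJK fallback, and a jieba
adapter when that library is importable. The length filter exists because
set-overlap distances are unstable on short texts — the method is explicitly
not suited to short messages.

## Problem sizes

Default test and benchmark corpora are 10,000 messages (250 groups) for the
fidelity check and a few hundred messages elsewhere — large enough to
exercise the long-tailed regime and the sparse matrix path, small enough to
iterate on. Pure HAC on 10,000 documents needs ≈ 800 MB for the dense
distance matrix; the hybrid at u = 0.4 needs a fraction of that, which is
the point of the algorithm.

## Known limitations

- Set-overlap distance degrades on short texts and on heavy paraphrase;
  it sees edits, not meaning.
- The λ-reach vote rule means label propagation abstains aggressively in
  sparse neighborhoods; corpora where true group-mates routinely sit at
  distances just above λ would push work into the second pass (correct but
  slower), and λ itself is a judgement call.
- Keyword tagging and script flagging are lexicon-bound; the packaged
  lexicons are defaults, not curated instruments, and candidate flags are
  inputs to human adjudication, never verdicts.
- Peak detection parameters are conventions; different (window, floor)
  choices give different peak lists on the same series.
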