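# rumorgroups

Clustering and propagation analytics for rumor messages on closed social
platforms.

Fact-checking chatbots on closed messaging platforms receive large streams of
user-reported suspicious messages in which the same rumor circulates as
thousands of near-identical copies with small edits. `rumorgroups` groups
such a corpus into **rumor groups** — clusters of identical or lightly edited
variants of one narrative — and provides the analytics a rumor-propagation
study needs on top of the grouping: topical keyword tagging with human
confirmation, script-origin flagging with a chi-square independence test,
daily report series with resurfacing peaks, quoted-party attribution counts,
and exact-variant timelines. It is written for infodemiology /
misinformation researchers working with reported-message dumps (CSV or JSON
Lines), and ships a seeded synthetic-corpus generator so every stage is
testable without access to proprietary platform data.

## Method

Messages are preprocessed (script filter → tokenization → stop-word removal →
minimum-length filter) into distinct-token sets, and compared with the
set-overlap distance

    d(A, B) = 1 − |tok(A) ∩ tok(B)| / max(|tok(A)|, |tok(B)|),

which is 0 for identical token sets, 1 for disjoint ones, and — by
normalizing with the larger set — keeps a short message far from a long
composite message that merely contains it.

Grouping is threshold **hierarchical agglomerative clustering** (HAC):
clusters merge bottom-up until every inter-cluster linkage distance exceeds a
threshold λ (default 0.6), so the number of groups is data-driven. Because
pure HAC is quadratic, the scalable path is a **classification-based
clustering** algorithm: run HAC exactly on a random train portion *u* of the
corpus, demote sample singletons to an unassigned sentinel (−1), propagate
sample labels to the rest with a k-nearest-neighbor classifier over the same
distance (neighbors beyond λ carry no vote; documents with no neighbor in
reach stay unassigned), and re-cluster the unassigned pool in a second HAC
pass with fresh label ids. At *u* = 1 it reduces exactly to pure HAC, and its
fidelity against the pure-HAC gold standard is measured with pairwise
co-membership precision/recall/F.

Group annotation includes the >60% keyword rule for topical (COVID-19)
candidacy, simplified-script/mainland-phrase origin flags, and the Yates-
corrected chi-square test χ² = n(|ad−bc| − n/2)² / ((a+b)(c+d)(a+c)(b+d))
on the resulting 2×2 contingency table.

## Worked example

```python
from rumorgroups import (SynthSpec, generate_corpus, preprocess, distance_matrix,
                         hac_cluster, hybrid_cluster, ClusterParams, pairwise_prf,
                         group_table, ContingencyTable2x2, chi_square_yates,
                         format_p_value)
from rumorgroups.corpus_io import messages_from_frame

# a synthetic corpus: 12 planted rumor groups with Zipf sizes, 40 singleton
# noise messages, 3 combined two-rumor messages
spec = SynthSpec(n_groups=12, n_group_messages=500, n_singletons=40,
                 combined_pairs=3, seed=7)
corpus = generate_corpus(spec)
messages = messages_from_frame(corpus.messages)
docs = preprocess(messages, tokenizer="whitespace", stopwords=(), char_filter=None)
print(f"{len(docs)} documents survive preprocessing")

gold = hac_cluster(distance_matrix(docs), lambda_threshold=0.6)
pred = hybrid_cluster(docs, ClusterParams(train_portion_u=0.4, seed=1))
score = pairwise_prf(pred, gold)
print(f"hybrid vs HAC: precision={score.precision:.4f} "
      f"recall={score.recall:.4f} F={score.f_score:.4f}")

table = group_table(pred)
print("largest groups:", table["size"].head(5).tolist())

stat, df, p = chi_square_yates(ContingencyTable2x2(16957, 25872, 15776, 37768))
print(f"chi2({df}) = {stat:.1f}, p {format_p_value(p)}")
```

Output:

```
543 documents survive preprocessing
hybrid vs HAC: precision=1.0000 recall=1.0000 F=1.0000
largest groups: [163, 76, 46, 45, 35]
chi2(1) = 1088.0, p <.001
```

All 543 messages end up in exactly one group; clustering only 40% of the
corpus exactly and propagating labels to the rest reproduces the pure-HAC
partition perfectly on this well-separated corpus (on 10,000-message corpora
the agreement stays above 99%, see below). The largest planted group
dominates, as Zipf sizes dictate. The chi-square line tests independence of
topic and script origin in a 96,373-message contingency table: χ²₁ = 1088.0
means the association is far beyond chance.

The same pipeline is available from the shell:

```bash
rumorgroups simulate --seed 7 --out corpus/
rumorgroups cluster --input corpus/messages.csv --tokenizer whitespace \
    --char-filter none --lambda 0.6 --u 0.4 --seed 1 --output assignments.csv
rumorgroups tag --assignments assignments.csv --messages corpus/messages.csv
rumorgroups script-stats --assignments assignments.csv --messages corpus/messages.csv
rumorgroups trends --assignments assignments.csv --messages corpus/messages.csv \
    --group-id 0 --peaks-window 3 --min-count 10
```

See `docs/methods.md` for the model, parameter semantics, design decisions
and limitations.

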