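# Methods

## The indexing model

`meshindex` assigns Medical Subject Headings (MeSH) to an article by label
transfer from its nearest textual neighbors. The premise is that similar
documents should be indexed with similar headings. The pipeline has four
stages:

1. **Retrieval.** Every training article (title + abstract, one field) is
   tokenized (lowercase, alphanumeric runs) and stored as a tf-idf vector:
   `w(t, d) = tf(t, d) · ln(|D| / df(t))`, raw term count times unsmoothed
   log inverse document frequency. A query document is weighted with the
   *index's* idf table (document frequencies from the training corpus only)
   and ranked against all stored documents by cosine similarity
   `sim(q, d) = V(q)·V(d) / (|V(q)||V(d)|)`. The top **X** documents are
   returned; ties break on ascending document id, and a query whose id is
   already indexed never retrieves itself.

2. **Candidate scoring.** Every heading of every retrieved neighbor is a
   candidate. A heading `l` supported by `tf(l)` neighbors with cosine
   scores `s_1..s_tf` receives

       score(l) = tf(l) · ( Σᵢ sᵢ / maxᵢ sᵢ )

   — neighbor frequency times the similarity mass, normalized by the best
   supporting similarity so that documents with many headings do not
   dominate. Since Σ ≥ max, every supported candidate scores ≥ 1.
   Optional external suggestions (an upstream indexer's output, consumed as
   a `doc_id → [ui]` JSON file) extend the candidate set; a suggestion with
   no neighbor support is treated as one pseudo-supporting document at the
   maximum hit score, so it scores exactly 1. This convention is ours: it
   keeps the scoring function total while preserving the documented
   behavior that any threshold below 1 filters nothing.

3. **Selection.** Candidates scoring strictly greater than the threshold
   **T** are kept, ranked by score. Defaults are X=10 and T=5, the best
   operating point reported for this family of systems. Selection is
   antitone in T, which produces the precision/recall trade-off the sweep
   driver (`meshindex sweep`) measures.

4. **Broader-heading rule (off by default).** Cataloging guidelines say
   that when 3 or more proposed headings share an ancestor, they should be
   replaced by their lowest common ancestor. We apply this to a fixpoint:
   find all descriptor ancestors with ≥ `min_group` (default 3) proposed
   descendants, fire the group whose LCA is deepest (ties: smallest
   witnessing tree-number code), consume its members, insert the LCA with
   the maximum score of the consumed members, and repeat. Each step removes
   at least `min_group − 1` labels, so termination is guaranteed, and the
   reached fixpoint is idempotent. The rule is off by default because it
   trades recall for generality (see "Synthetic data vs reality" below).

## The thesaurus graph

A descriptor carries a unique id, unique name, and ≥ 1 dot-separated tree
numbers; the proper-prefix relation on tree numbers defines ancestry.
Category letters alone (e.g. `C`) are not descriptors; depth-1 codes like
`C04` are forest roots. Ancestor/descendant queries enumerate prefix
owners; shortest paths run over the undirected parent/child code graph
(networkx BFS, cached per source code). Codes of one multi-branch
descriptor are *not* merged into one node: a path between two headings
follows tree positions only.

**LCA with multiple branches.** The lowest common ancestor of a set is the
deepest descriptor in the intersection of their self-inclusive ancestor
closures. Depth is measured over the codes that witness the common
ancestry; when no single code covers every member (ancestry through
different branches of a multi-parent descriptor), depth falls back to the
minimum over members of the deepest code witnessing that member, so
`depth(lca(S)) ≤ min_s max-depth(s)` always holds. Ties break on the
lexicographically smallest witnessing code. A descriptor counts as its own
ancestor for LCA purposes only, so `lca(u, descendant-of-u) = u`, while
`ancestors()` returns proper ancestors by default.

The descriptor-level ancestor relation is validated to be acyclic at
construction (topological-order check); duplicate ids, names or tree-number
ownership are integrity errors. Descriptors with no tree number (real-world
check tags) are rejected unless `allow_orphans=True` keeps them isolated.

## Evaluation

Flat precision/recall/F1 are micro-averaged (counts pooled over documents)
by default; a macro variant (per-document means) is exposed because
published tables do not always state their basis.

The hierarchical LCA measures reward near-misses. Per document, each
predicted heading finds its nearest gold heading by shortest path, and the
prediction set is augmented with every descriptor on the chain from the
prediction up to the LCA of the pair; the gold set is augmented
symmetrically toward the predictions. LCA-P and LCA-R are overlaps of the
augmented sets, averaged per document; LCA-F is their harmonic mean. This
is a reconstruction of the LCA measure family implemented by
hierarchical-evaluation toolkits — the exact graph-construction details of
those tools (path cost weights, multi-parent handling) are not fully
published, so toy golden cases in the test suite pin this implementation's
behavior: perfect predictions score 1; on a hierarchy-free thesaurus the
LCA measures collapse to the flat (macro) ones; predicting a gold leaf's
parent strictly beats predicting an unrelated heading of the same depth.

## Synthetic data: what it emulates, what it does not

The generator produces a thesaurus and corpora with the structure the
method needs to be testable without a 10⁷-document bibliographic index:

- **Hierarchy:** 12 roots, child counts ≤ 3, depth ≤ 6 (a scaled-down
  stand-in for MeSH's 16 branches and 9 levels, average depth ≈ 4.5); 10%
  of non-root descriptors get a second tree number grafted under another
  root, mimicking multi-parent headings. Grafts that would make the
  ancestor relation cyclic are skipped.
- **Labels:** per document, Poisson(12.5) headings (clipped ≥ 1) — the
  reported MEDLINE average is 12–13 — drawn 90% from one "topic" root's
  subtree (`theme_purity`) and 10% uniformly, emulating topical coherence.
- **Text:** each descriptor owns a disjoint 20-word signature vocabulary;
  each of 150 document words comes from the signature of a uniformly chosen
  document label, or from a 1000-word background vocabulary with
  probability `noise_rate` (default 0.1). Words are drawn with replacement
  so term frequency is informative. At `noise_rate=1` text is independent
  of labels, and pipeline F1 collapses to the random-neighbor baseline.

Both generators are deterministic under (config, seed); numpy `default_rng`
streams are derived from the seed (corpus stream = `2·seed + 1` so a
thesaurus and its corpus never share a stream).

What passing tests on this data do **not** show: real biomedical language
(synonymy, polysemy, stopword structure), realistic label sparsity
(~12/27,000 headings vs ~12/250 here), or the real cost profile of the
broader rule. On synthetic corpora the topical coherence that makes label
transfer learnable also means almost every prediction set has ≥ 3 headings
under one root, so the broader rule fires constantly and recall drops far
more than the ~5 points observed on real data. The rule's *semantics* are
exercised by fixture and oracle tests; its end-to-end cost on this data is
a property of the generator, not of the rule.

## Numerical and degenerate-case choices

- Unsmoothed idf `ln(|D|/df)` is the default (the literal formula);
  `smooth_idf=True` selects `ln((1+|D|)/(1+df)) + 1`, which is
  cross-checked against scikit-learn's transformer in the tests.
- A one-document corpus has all idf = 0, hence all-zero vectors; zero
  vectors have cosine similarity 0 everywhere (warning, not an error), so
  batch runs stay total.
- All-zero supporting similarities score `tf` (the Σ/max ratio is taken as
  1 per supporting document).
- Selection uses strict `> T`; ties in every ranking break on ascending
  id/code for determinism.
- All file writes are write-then-rename atomic; index files, thesaurus
  serializations and prediction files are byte-stable across reruns.

## Problem sizes

Default experiment sizes (2,000 training / 200 test documents, ~250
descriptors) keep the full pipeline — generation, indexing, prediction,
both metric families — around ten seconds, while being large enough that
the mean label count and retrieval statistics are stable (mean label-set
size within 3 standard errors of its target at n = 2,000).

## Known limitations

- The exact analyzer of production search engines (stopwords, stemming,
  BM25-era scoring) is deliberately not reproduced; this package implements
  the classic tf-idf/cosine vector space model. A stopword list can be
  supplied but is off by default.
- The LCA measures are a reconstruction (see above), suitable for ranking
  systems relative to each other on the same data rather than for exact
  comparison with scores produced by external toolkits.
- How suggestion-only candidates were scored in the original
  neighbor-transfer systems is unpublished; our pseudo-support convention
  is documented above and isolated behind `from_suggestion`.
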