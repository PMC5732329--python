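# meshindex

Retrieval-based semantic indexing of biomedical articles with Medical
Subject Headings (MeSH).

Manually assigning MeSH headings to the thousands of articles added to
MEDLINE every day is slow, expert work. `meshindex` implements a
retrieval-based assistant for that task: it rests on the assumption that
*similar documents should be indexed with similar headings*. Given an
unlabeled article, it retrieves the most similar indexed articles in a
tf-idf vector space, transfers and scores their headings, thresholds the
ranking, and can optionally apply the cataloguers' "specific vs broader
headings" rule over the MeSH hierarchy. It is aimed at researchers in
biomedical text mining who want a transparent, fully in-process baseline
for multilabel hierarchical classification experiments.

## The method

Documents (title + abstract) are vectors of tf-idf weights
`w(t,d) = tf(t,d) · ln(|D|/df(t))`; a query `q` is ranked against every
indexed document `d` by cosine similarity
`sim(q,d) = V(q)·V(d) / (|V(q)||V(d)|)`. The headings of the top **X**
neighbors become candidates, and a candidate `l` supported by `tf(l)`
neighbors with similarities `s_1..s_tf` is scored

    score(l) = tf(l) · ( Σᵢ sᵢ / maxᵢ sᵢ )

Candidates with `score(l) > T` are selected (defaults X=10, T=5; any
T < 1 selects everything, since every supported candidate scores ≥ 1).
With `apply_rule=True`, any ≥3 selected headings sharing an ancestor are
replaced by their lowest common ancestor (LCA), computed on the
tree-number forest of the thesaurus.

Predictions are evaluated with flat micro-averaged precision/recall/F1 and
with hierarchical LCA-P/LCA-R/LCA-F, which credit near-misses by
augmenting predicted and gold sets along paths to their lowest common
ancestors. See `docs/methods.md` for the full model description and
design choices.

## Worked example

The package ships a synthetic-data generator that emulates the structure
the method relies on — a multi-branch thesaurus and documents whose
vocabulary is driven by their labels (≈12.5 headings per document, 10%
background noise by default):

```python
from meshindex import GeneratorConfig, build_index, evaluate, predict
from meshindex.synth import generate_train_test

cfg = GeneratorConfig(seed=1)                    # noise_rate=0.1, 12.5 labels/doc
thesaurus, train, test = generate_train_test(cfg, n_train=2000, n_test=200)

index = build_index(train)
predictions = [predict(index, q, x=10, t=5.0) for q in test]
gold = {d.doc_id: d.labels for d in test}

report = evaluate(predictions, gold, thesaurus=thesaurus)
print(f"P={report.precision:.4f}  R={report.recall:.4f}  F1={report.f1:.4f}")
print(f"LCA-P={report.lca_p:.4f}  LCA-R={report.lca_r:.4f}  LCA-F={report.lca_f:.4f}")
```

prints

    P=0.6294  R=0.7072  F1=0.6660
    LCA-P=0.6886  LCA-R=0.6631  LCA-F=0.6756

i.e. at the default operating point roughly 63% of proposed headings are
correct and 71% of the curators' headings are recovered; the LCA variants
are higher than flat precision/recall here because many misses land close
to a gold heading in the hierarchy. Individual predictions are ranked
`(ui, score)` pairs — e.g. the first test document receives 8 headings led
by `('D000015', 32.42)`, a heading supported by many high-similarity
neighbors.

The same pipeline is available from the shell:

    meshindex synth --out-thesaurus th.tsv --out-corpus train.json \
                    --out-test test.json --n-docs 2000 --n-test 200 --seed 1
    meshindex index --corpus train.json --out index.json
    meshindex predict --index index.json --queries test.json --out preds.json
    meshindex evaluate --predictions preds.json --gold test.json \
                       --thesaurus th.tsv --out report.json
    meshindex sweep --index index.json --queries test.json \
                    --x-values 10,20 --t-values 0,1.5,5 --out sweep.tsv
    meshindex thesaurus-query --thesaurus th.tsv --op lca --ui D000012 --ui D000031

`sweep` reproduces the X × T experiment grid (precision rises and recall
falls as T grows); `thesaurus-query` answers ancestor, descendant, LCA and
shortest-path lookups, mirroring how a graph database over MeSH is used
interactively.

## Layout

    src/meshindex/
      mesh_graph.py    thesaurus parsing, ancestors/descendants, LCA, paths
      vsm_index.py     tokenizer, tf-idf inverted index, cosine top-X search
      label_scorer.py  candidate assembly, scoring function, threshold, predict()
      broader_rule.py  ≥3-headings-share-an-ancestor replacement fixpoint
      eval_metrics.py  flat and LCA-based precision/recall/F
      synth.py         synthetic thesaurus + corpus generators
      io.py, cli.py    file dialects (corpus JSON, thesaurus TSV/JSON) and CLI
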