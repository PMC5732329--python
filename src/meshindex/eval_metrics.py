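"""Flat and hierarchical (LCA-based) precision / recall / F-measure.

Flat scores are micro-averaged by default: true positives, predicted counts
and gold counts are pooled over all documents before dividing.  A macro
(per-document mean) variant is available because published tables do not
always state their averaging basis.

The hierarchical scores reward near-misses that land close to a gold
heading in the thesaurus.  For each document, every predicted heading is
connected to its nearest gold heading (shortest path in the tree-number
forest), and the prediction set is augmented with all headings on the path
from the prediction up to the lowest common ancestor of the pair; the gold
set is augmented symmetrically toward its nearest predicted heading.
LCA-precision and LCA-recall are then set overlaps of the augmented sets,
averaged per document, with the F-measure the harmonic mean of the two.
This is a reconstruction of the LCA measure family popularized by
hierarchical-evaluation toolkits; toy golden cases pin its behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import UnknownDescriptorError
from .label_scorer import Prediction
from .mesh_graph import Thesaurus

LabelSets = Mapping[str, Iterable[str]]


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    f1: float
    lca_p: float
    lca_r: float
    lca_f: float
    n_documents: int

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "lca_p": self.lca_p,
            "lca_r": self.lca_r,
            "lca_f": self.lca_f,
            "n_documents": self.n_documents,
        }


def _f(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def _as_sets(predictions: LabelSets | Iterable[Prediction]) -> dict[str, frozenset[str]]:
    if isinstance(predictions, Mapping):
        return {d: frozenset(ls) for d, ls in predictions.items()}
    return {p.doc_id: p.label_set for p in predictions}


def flat_prf(
    predictions: LabelSets | Iterable[Prediction],
    golds: LabelSets,
    average: str = "micro",
) -> tuple[float, float, float]:
    """Precision, recall, F1 of predicted label sets against gold sets.

    Every predicted document must have a gold set.  Documents present in
    *golds* but missing from *predictions* count as empty predictions.
    """
    preds = _as_sets(predictions)
    gold = {d: frozenset(ls) for d, ls in golds.items()}
    missing = set(preds) - set(gold)
    if missing:
        raise KeyError(f"no gold labels for predicted documents: {sorted(missing)[:5]}")
    if not gold:
        return (0.0, 0.0, 0.0)

    if average == "micro":
        tp = sum(len(preds.get(d, frozenset()) & g) for d, g in gold.items())
        n_pred = sum(len(preds.get(d, frozenset())) for d in gold)
        n_gold = sum(len(g) for g in gold.values())
        p = tp / n_pred if n_pred else 0.0
        r = tp / n_gold if n_gold else 0.0
    elif average == "macro":
        ps, rs = [], []
        for d, g in gold.items():
            pr = preds.get(d, frozenset())
            tp = len(pr & g)
            if not pr and not g:
                ps.append(1.0)
                rs.append(1.0)
            else:
                ps.append(tp / len(pr) if pr else 0.0)
                rs.append(tp / len(g) if g else 0.0)
        p = sum(ps) / len(ps)
        r = sum(rs) / len(rs)
    else:
        raise ValueError(f"unknown average {average!r}")
    return (p, r, _f(p, r))


def _augment(
    sources: frozenset[str], targets: frozenset[str], thesaurus: Thesaurus
) -> set[str]:
    """Expand *sources* along paths toward their nearest element of *targets*.

    Each source contributes itself plus every descriptor on the prefix chain
    from itself up to the LCA with its nearest target.  Sources with no
    connected target (or no common ancestor) contribute only themselves.
    """
    aug: set[str] = set()
    for s in sorted(sources):
        aug.add(s)
        if s in targets or not targets:
            continue
        best_g, best_d = None, math.inf
        for g in sorted(targets):
            d = thesaurus.shortest_path_length(s, g)
            if d < best_d:
                best_g, best_d = g, d
        if best_g is None or math.isinf(best_d):
            continue
        lca = thesaurus.lca_detail({s, best_g})
        if lca is None:
            continue
        # walk from the deepest code of s that extends the LCA's witnessing
        # code up to that ancestor position, collecting owned descriptors
        s_codes = sorted(thesaurus[s].codes)
        for code in s_codes:
            if code == lca.code or code.startswith(lca.code + "."):
                aug.update(thesaurus.path_descriptors(code, lca.code))
                break
    return aug


def lca_prf(
    predictions: LabelSets | Iterable[Prediction],
    golds: LabelSets,
    thesaurus: Thesaurus,
) -> tuple[float, float, float]:
    """Hierarchical LCA precision / recall / F (per-document mean)."""
    preds = _as_sets(predictions)
    gold = {d: frozenset(ls) for d, ls in golds.items()}
    missing = set(preds) - set(gold)
    if missing:
        raise KeyError(f"no gold labels for predicted documents: {sorted(missing)[:5]}")
    if not gold:
        return (0.0, 0.0, 0.0)
    for d, labels in list(preds.items()) + list(gold.items()):
        for l in labels:
            if l not in thesaurus:
                raise UnknownDescriptorError(f"document {d!r}: label {l!r}")

    ps, rs = [], []
    for d, g in gold.items():
        pr = preds.get(d, frozenset())
        if not pr and not g:
            ps.append(1.0)
            rs.append(1.0)
            continue
        aug_pred = _augment(pr, g, thesaurus)
        aug_gold = _augment(g, pr, thesaurus)
        inter = aug_pred & aug_gold
        ps.append(len(inter) / len(aug_pred) if aug_pred else 0.0)
        rs.append(len(inter) / len(aug_gold) if aug_gold else 0.0)
    p = sum(ps) / len(ps)
    r = sum(rs) / len(rs)
    return (p, r, _f(p, r))


def evaluate(
    predictions: LabelSets | Iterable[Prediction],
    golds: LabelSets,
    thesaurus: Thesaurus | None = None,
    average: str = "micro",
) -> EvalReport:
    """Full report: flat P/R/F1 plus LCA variants when a thesaurus is given."""
    preds = _as_sets(predictions)
    p, r, f1 = flat_prf(preds, golds, average=average)
    if thesaurus is not None:
        lp, lr, lf = lca_prf(preds, golds, thesaurus)
    else:
        lp = lr = lf = 0.0
    return EvalReport(p, r, f1, lp, lr, lf, n_documents=len(golds))
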