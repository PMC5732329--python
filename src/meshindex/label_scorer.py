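"""Candidate label assembly, scoring and threshold selection.

Given the retrieved neighbors of a query document, every MeSH heading of
every neighbor becomes a candidate label.  A candidate ``l`` supported by
``tf(l)`` neighbors with cosine scores ``s_1..s_tf`` receives

    score(l) = tf(l) × ( Σ_i s_i / max_i s_i )

i.e. the neighbor frequency times the score sum normalized by the maximum
supporting score.  Because Σ ≥ max, every supported candidate scores at
least 1, so any threshold T < 1 selects the whole candidate set.  Only
candidates with score strictly greater than T are kept.

External suggestions (e.g. from an upstream indexing tool) extend the
candidate set: a suggestion with no neighbor support is treated as a single
pseudo-supporting document at the maximum hit score, so it scores exactly 1
and survives any T < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import broader_rule
from .errors import UnknownDocumentError
from .mesh_graph import Thesaurus
from .vsm_index import InvertedIndex, LabeledDocument, RetrievalHit

DEFAULT_X = 10
DEFAULT_T = 5.0


@dataclass
class CandidateLabel:
    """A proposed heading with its neighbor support."""

    ui: str
    supporting_scores: list[float] = field(default_factory=list)
    from_suggestion: bool = False

    @property
    def tf(self) -> int:
        """Number of retrieved documents annotated with this heading."""
        return len(self.supporting_scores)

    @property
    def score(self) -> float:
        return score_label(self)


def score_label(c: CandidateLabel) -> float:
    """tf × (Σ supporting scores / max supporting score); requires tf ≥ 1."""
    if c.tf < 1:
        raise ValueError(f"candidate {c.ui!r} has no supporting documents")
    total = sum(c.supporting_scores)
    peak = max(c.supporting_scores)
    if peak <= 0.0:
        # all supporting similarities are zero (degenerate corpus): the
        # normalized ratio is taken as 1 per supporting document
        return float(c.tf)
    return float(c.tf * (total / peak))


@dataclass(frozen=True)
class Prediction:
    """Selected headings for one document, ordered by score descending."""

    doc_id: str
    labels: tuple[tuple[str, float], ...]

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(ui for ui, _ in self.labels)

    def __len__(self) -> int:
        return len(self.labels)


def collect_candidates(
    hits: Sequence[RetrievalHit],
    label_store: Mapping[str, frozenset[str]],
    suggestions: Iterable[str] | None = None,
) -> list[CandidateLabel]:
    """One candidate per distinct heading across all hits' label sets.

    ``tf(l)`` counts the hits whose document carries ``l``.  Suggestions
    absent from every hit are added as pseudo-supported candidates (see
    module docstring); suggestions that coincide with neighbor-supported
    candidates only set the ``from_suggestion`` flag.
    """
    by_ui: dict[str, CandidateLabel] = {}
    max_hit = max((h.score for h in hits), default=1.0)
    for hit in hits:
        try:
            labels = label_store[hit.doc_id]
        except KeyError:
            raise UnknownDocumentError(
                f"retrieved document {hit.doc_id!r} has no stored labels"
            ) from None
        for ui in labels:
            cand = by_ui.setdefault(ui, CandidateLabel(ui))
            cand.supporting_scores.append(hit.score)
    for ui in suggestions or ():
        cand = by_ui.get(ui)
        if cand is None:
            by_ui[ui] = CandidateLabel(
                ui, supporting_scores=[max_hit], from_suggestion=True
            )
        else:
            cand.from_suggestion = True
    return [by_ui[ui] for ui in sorted(by_ui)]


def select_labels(
    candidates: Iterable[CandidateLabel], t: float, doc_id: str = ""
) -> Prediction:
    """Exactly the candidates with score > *t*, score descending, ties by ui."""
    scored = [(c.ui, c.score) for c in candidates]
    kept = [(ui, s) for ui, s in scored if s > t]
    kept.sort(key=lambda p: (-p[1], p[0]))
    return Prediction(doc_id=doc_id, labels=tuple(kept))


def predict(
    index: InvertedIndex,
    query_doc: LabeledDocument,
    x: int = DEFAULT_X,
    t: float = DEFAULT_T,
    suggestions: Iterable[str] | None = None,
    thesaurus: Thesaurus | None = None,
    apply_rule: bool = False,
    min_group: int = 3,
) -> Prediction:
    """End-to-end pipeline for one query document.

    search → collect candidates → score → threshold, then optionally the
    broader-heading replacement rule over *thesaurus* (required when
    *apply_rule* is set; a replacement inherits the maximum score of the
    members it consumed).
    """
    hits = index.search(query_doc, x)
    candidates = collect_candidates(hits, index.label_store, suggestions)
    prediction = select_labels(candidates, t, doc_id=query_doc.doc_id)
    if not apply_rule:
        return prediction
    if thesaurus is None:
        raise ValueError("apply_rule requires a thesaurus")
    rewritten = broader_rule.rewrite_scored(
        dict(prediction.labels), thesaurus, min_group, missing="skip"
    )
    ordered = sorted(rewritten.items(), key=lambda p: (-p[1], p[0]))
    return Prediction(doc_id=query_doc.doc_id, labels=tuple(ordered))
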