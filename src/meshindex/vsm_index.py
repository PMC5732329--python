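"""In-process vector-space retrieval over a labeled document corpus.

Documents are tokenized, weighted with tf-idf and stored as rows of a sparse
matrix; a query document is weighted with the *index's* idf table and ranked
against every stored document by cosine similarity.  This stands in for a
search-engine retrieval stage: the index also stores each document's MeSH
labels so that neighbors' labels can be transferred to the query.

The default weighting is the literal ``tf × ln(|D| / df)`` (raw term count
times unsmoothed log inverse document frequency).  A ``smooth_idf`` switch
selects ``ln((1+|D|)/(1+df)) + 1`` for comparison with library
implementations.
"""

from __future__ import annotations

import json
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .errors import IntegrityError, UnknownDocumentError

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on any non-alphanumeric run; deterministic."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class LabeledDocument:
    """A corpus article: id (PMID role), text fields and gold MeSH labels."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    journal: str | None = None
    year: int | None = None
    labels: frozenset[str] = frozenset()

    @property
    def text(self) -> str:
        """Title and abstract concatenated into the single indexed field."""
        return f"{self.title} {self.abstract}".strip()


@dataclass(frozen=True)
class RetrievalHit:
    doc_id: str
    score: float  # cosine similarity in [0, 1]


def cosine_similarity(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    """dot(a, b) / (‖a‖·‖b‖) over sparse term→weight mappings.

    An empty or all-zero vector yields similarity 0 (flagged with a warning)
    rather than an error, so degenerate corpora keep batch runs total.
    """
    na = np.sqrt(sum(v * v for v in a.values()))
    nb = np.sqrt(sum(v * v for v in b.values()))
    if na == 0.0 or nb == 0.0:
        warnings.warn("cosine similarity of a zero vector defined as 0", stacklevel=2)
        return 0.0
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    dot = sum(v * large.get(t, 0.0) for t, v in small.items())
    return float(dot / (na * nb))


class InvertedIndex:
    """tf-idf weighted document vectors with a document→labels store."""

    FORMAT = "meshindex-vsm-1"

    def __init__(
        self,
        doc_ids: Sequence[str],
        labels: Mapping[str, frozenset[str]],
        counts: Sequence[Mapping[str, int]],
        smooth_idf: bool = False,
    ) -> None:
        if len(doc_ids) != len(set(doc_ids)):
            seen: set[str] = set()
            for d in doc_ids:
                if d in seen:
                    raise IntegrityError(f"duplicate doc_id {d!r}")
                seen.add(d)
        self.doc_ids = list(doc_ids)
        self.smooth_idf = bool(smooth_idf)
        self._row = {d: i for i, d in enumerate(self.doc_ids)}
        self._labels = {d: frozenset(labels.get(d, frozenset())) for d in self.doc_ids}
        self._counts = [dict(c) for c in counts]

        vocab = sorted({t for c in self._counts for t in c})
        self.vocabulary = {t: j for j, t in enumerate(vocab)}
        n_docs, n_terms = len(self.doc_ids), len(vocab)
        df = np.zeros(n_terms, dtype=np.int64)
        tf = sparse.lil_matrix((n_docs, n_terms), dtype=np.float64)
        for i, c in enumerate(self._counts):
            for term, k in c.items():
                j = self.vocabulary[term]
                tf[i, j] = k
                df[j] += 1
        self.df = df
        self.idf = self._idf(df, n_docs)
        self.weights = sparse.csr_matrix(tf.multiply(self.idf))
        norms = np.sqrt(np.asarray(self.weights.multiply(self.weights).sum(axis=1)).ravel())
        self.norms = norms

    def _idf(self, df: np.ndarray, n_docs: int) -> np.ndarray:
        if len(df) == 0:
            return np.zeros(0)
        if self.smooth_idf:
            return np.log((1.0 + n_docs) / (1.0 + df)) + 1.0
        with np.errstate(divide="ignore"):
            return np.where(df > 0, np.log(n_docs / np.maximum(df, 1)), 0.0)

    # -- queries -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.doc_ids)

    def __contains__(self, doc_id: object) -> bool:
        return doc_id in self._row

    def labels_of(self, doc_id: str) -> frozenset[str]:
        try:
            return self._labels[doc_id]
        except KeyError:
            raise UnknownDocumentError(doc_id) from None

    @property
    def label_store(self) -> Mapping[str, frozenset[str]]:
        return self._labels

    def term_weights(self, doc_id: str) -> dict[str, float]:
        """The stored tf-idf vector of a document as a term→weight mapping."""
        try:
            i = self._row[doc_id]
        except KeyError:
            raise UnknownDocumentError(doc_id) from None
        terms = {j: t for t, j in self.vocabulary.items()}
        row = self.weights.getrow(i).tocoo()
        return {terms[j]: v for j, v in zip(row.col, row.data) if v != 0.0}

    def query_vector(self, text: str) -> dict[str, float]:
        """Weight a query with the index's idf table; unknown terms dropped."""
        counts = Counter(tokenize(text))
        out = {}
        for term, k in counts.items():
            j = self.vocabulary.get(term)
            if j is None:
                continue
            w = k * self.idf[j]
            if w != 0.0:
                out[term] = float(w)
        return out

    def search(self, query_doc: LabeledDocument | str, x: int) -> list[RetrievalHit]:
        """Top-*x* most cosine-similar stored documents, score descending.

        Ties break on ascending doc_id.  If the query's own doc_id is stored
        in the index it is excluded (self-match guard for cross-validation).
        """
        if x < 1:
            raise ValueError("x must be >= 1")
        if len(self) == 0:
            warnings.warn("search against an empty index", stacklevel=2)
            return []
        if isinstance(query_doc, LabeledDocument):
            text, exclude = query_doc.text, query_doc.doc_id
        else:
            text, exclude = query_doc, None

        qvec = self.query_vector(text)
        qnorm = np.sqrt(sum(v * v for v in qvec.values()))
        n = len(self)
        if qnorm == 0.0:
            scores = np.zeros(n)
        else:
            q = np.zeros(len(self.vocabulary))
            for term, v in qvec.items():
                q[self.vocabulary[term]] = v
            dots = self.weights @ q
            denom = self.norms * qnorm
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.where(denom > 0, dots / denom, 0.0)
            scores = np.clip(scores, 0.0, 1.0)

        order = sorted(
            (i for i in range(n) if self.doc_ids[i] != exclude),
            key=lambda i: (-scores[i], self.doc_ids[i]),
        )
        return [RetrievalHit(self.doc_ids[i], float(scores[i])) for i in order[:x]]

    # -- persistence ---------------------------------------------------------

    def to_payload(self) -> dict:
        return {
            "format": self.FORMAT,
            "smooth_idf": self.smooth_idf,
            "vocabulary": sorted(self.vocabulary),
            "df": self.df.tolist(),
            "documents": [
                {
                    "doc_id": d,
                    "labels": sorted(self._labels[d]),
                    "counts": {t: self._counts[i][t] for t in sorted(self._counts[i])},
                }
                for i, d in enumerate(self.doc_ids)
            ],
        }

    def save(self, path: str | Path) -> None:
        from .io import atomic_write  # local import to avoid a cycle

        atomic_write(path, json.dumps(self.to_payload(), sort_keys=True) + "\n")

    @classmethod
    def from_payload(cls, payload: Mapping) -> "InvertedIndex":
        if payload.get("format") != cls.FORMAT:
            raise IntegrityError(
                f"unrecognized index format {payload.get('format')!r}"
            )
        docs = payload["documents"]
        return cls(
            doc_ids=[rec["doc_id"] for rec in docs],
            labels={rec["doc_id"]: frozenset(rec["labels"]) for rec in docs},
            counts=[rec["counts"] for rec in docs],
            smooth_idf=payload.get("smooth_idf", False),
        )

    @classmethod
    def load(cls, path: str | Path) -> "InvertedIndex":
        return cls.from_payload(json.loads(Path(path).read_text(encoding="utf-8")))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InvertedIndex):
            return NotImplemented
        return (
            self.doc_ids == other.doc_ids
            and self._labels == other._labels
            and self._counts == other._counts
            and self.smooth_idf == other.smooth_idf
        )


def build_index(
    corpus: Iterable[LabeledDocument], smooth_idf: bool = False
) -> InvertedIndex:
    """Tokenize a corpus and build the tf-idf inverted index."""
    docs = list(corpus)
    return InvertedIndex(
        doc_ids=[d.doc_id for d in docs],
        labels={d.doc_id: d.labels for d in docs},
        counts=[Counter(tokenize(d.text)) for d in docs],
        smooth_idf=smooth_idf,
    )
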