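"""Readers and writers for the plain-text interchange formats.

Corpus files use a BioASQ-style JSON dialect: an object with a
``documents`` array whose records carry ``pmid``, ``title``,
``abstractText``, ``journal``, ``year`` and ``meshMajor`` (heading names or
descriptor uis).  Key names can be overridden for other dialects.  All
writes are atomic (write to a temporary file, then rename), so interrupted
runs never leave truncated outputs.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ThesaurusParseError
from .eval_metrics import EvalReport
from .label_scorer import Prediction
from .mesh_graph import Thesaurus
from .vsm_index import LabeledDocument

DEFAULT_KEYS = {
    "documents": "documents",
    "doc_id": "pmid",
    "title": "title",
    "abstract": "abstractText",
    "journal": "journal",
    "year": "year",
    "labels": "meshMajor",
}


def atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def resolve_labels(
    entries: Iterable[str], thesaurus: Thesaurus
) -> tuple[frozenset[str], list[str]]:
    """Map heading names or uis to uis; returns (resolved, unresolvable)."""
    resolved, bad = set(), []
    for entry in entries:
        if entry in thesaurus:
            resolved.add(entry)
        else:
            ui = thesaurus.by_name(entry)
            if ui is None:
                bad.append(entry)
            else:
                resolved.add(ui)
    return frozenset(resolved), bad


def read_corpus(
    path: str | Path,
    thesaurus: Thesaurus | None = None,
    keys: Mapping[str, str] | None = None,
    strict_labels: bool = True,
) -> list[LabeledDocument]:
    k = {**DEFAULT_KEYS, **(keys or {})}
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ThesaurusParseError(f"{path}: invalid corpus JSON: {exc}") from None
    records = payload[k["documents"]] if isinstance(payload, dict) else payload
    docs = []
    for i, rec in enumerate(records):
        if k["doc_id"] not in rec:
            raise ThesaurusParseError(f"{path}: record {i} missing {k['doc_id']!r}")
        raw_labels = rec.get(k["labels"], [])
        if thesaurus is not None:
            labels, bad = resolve_labels(raw_labels, thesaurus)
            if bad and strict_labels:
                raise ThesaurusParseError(
                    f"{path}: record {i} ({rec[k['doc_id']]}): "
                    f"unresolvable headings {bad[:5]}"
                )
        else:
            labels = frozenset(raw_labels)
        docs.append(
            LabeledDocument(
                doc_id=str(rec[k["doc_id"]]),
                title=rec.get(k["title"], "") or "",
                abstract=rec.get(k["abstract"], "") or "",
                journal=rec.get(k["journal"]),
                year=rec.get(k["year"]),
                labels=labels,
            )
        )
    return docs


def write_corpus(
    path: str | Path,
    docs: Sequence[LabeledDocument],
    keys: Mapping[str, str] | None = None,
) -> None:
    k = {**DEFAULT_KEYS, **(keys or {})}
    records = [
        {
            k["doc_id"]: d.doc_id,
            k["title"]: d.title,
            k["abstract"]: d.abstract,
            k["journal"]: d.journal,
            k["year"]: d.year,
            k["labels"]: sorted(d.labels),
        }
        for d in docs
    ]
    atomic_write(path, json.dumps({k["documents"]: records}, sort_keys=True) + "\n")


def write_thesaurus(path: str | Path, thesaurus: Thesaurus, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        atomic_write(path, thesaurus.to_tsv())
    elif fmt == "json":
        atomic_write(path, thesaurus.to_json())
    else:
        raise ValueError(f"unknown thesaurus format {fmt!r}")


def read_suggestions(path: str | Path) -> dict[str, frozenset[str]]:
    """JSON mapping doc_id → array of descriptor uis."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return {str(d): frozenset(uis) for d, uis in payload.items()}


def write_predictions(
    path: str | Path, predictions: Sequence[Prediction], thesaurus: Thesaurus | None = None
) -> None:
    records = []
    for p in predictions:
        labels = [{"ui": ui, "score": score} for ui, score in p.labels]
        if thesaurus is not None:
            for entry in labels:
                d = thesaurus.get(entry["ui"])
                if d is not None:
                    entry["name"] = d.name
        records.append({"pmid": p.doc_id, "labels": labels})
    atomic_write(path, json.dumps(records, sort_keys=True) + "\n")


def read_predictions(path: str | Path) -> list[Prediction]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        Prediction(
            doc_id=str(rec["pmid"]),
            labels=tuple((e["ui"], float(e["score"])) for e in rec["labels"]),
        )
        for rec in payload
    ]


def write_report(path: str | Path, report: EvalReport) -> None:
    atomic_write(path, json.dumps(report.to_dict(), sort_keys=True, indent=2) + "\n")
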