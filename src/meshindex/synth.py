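"""Synthetic thesauri and labeled corpora for desk-scale experiments.

The generator emulates the statistical structure the retrieval method
relies on: a multi-branch concept hierarchy (some descriptors placed in two
branches, as in MeSH), and documents whose vocabulary is driven by their
label sets, so that textually similar documents carry overlapping labels.

Defaults mirror the conditions of large-scale biomedical indexing scaled to
desk size: ~12.5 headings per article on average, a forest a handful of
levels deep, and topically coherent documents — each article samples most
of its headings from one branch of the hierarchy, the way a real article's
headings cluster around its subject area.  Every descriptor owns a small
disjoint *signature vocabulary*; each document word is drawn from the
signature of one of its labels, or, with probability ``noise_rate``, from a
shared background vocabulary.  At ``noise_rate=1`` text is independent of
labels and label transfer collapses to chance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .mesh_graph import Descriptor, Thesaurus, make_descriptor
from .vsm_index import LabeledDocument

_ROOT_LETTERS = "ABCDEFGHJKLMNPQRSTUVWXYZ"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for both generators; identical config + seed ⇒ identical output."""

    # hierarchy shape
    n_roots: int = 12
    branching_factor: int = 3
    max_depth: int = 6
    leaf_prob: float = 0.35  # chance a node at depth ≥ 2 stays a leaf
    multi_parent_fraction: float = 0.1
    # corpus shape
    n_docs: int = 1000
    labels_per_doc_mean: float = 12.5
    theme_purity: float = 0.9  # fraction of labels drawn from the topic branch
    signature_vocab_size: int = 20
    words_per_doc: int = 150
    background_vocab_size: int = 1000
    noise_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        for name in (
            "n_roots",
            "branching_factor",
            "max_depth",
            "n_docs",
            "signature_vocab_size",
            "words_per_doc",
            "background_vocab_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def generate_thesaurus(cfg: GeneratorConfig) -> Thesaurus:
    """Random prefix forest with ``n_roots`` roots and bounded depth.

    A ``multi_parent_fraction`` of non-root descriptors receive a second
    tree number grafted under a node of a different root, reproducing the
    multi-parent structure of real concept hierarchies.
    """
    rng = np.random.default_rng(cfg.seed)
    codes: list[str] = []  # primary code per descriptor, generation order
    frontier: list[str] = []
    for i in range(cfg.n_roots):
        letter = _ROOT_LETTERS[i % len(_ROOT_LETTERS)]
        root = f"{letter}{i + 1:02d}"
        codes.append(root)
        frontier.append(root)

    children: dict[str, list[str]] = {}
    while frontier:
        code = frontier.pop(0)
        depth = code.count(".") + 1
        if depth >= cfg.max_depth:
            continue
        if depth >= 2 and rng.random() < cfg.leaf_prob:
            continue
        k = int(rng.integers(1, cfg.branching_factor + 1))
        comps = rng.choice(np.arange(100, 1000), size=k, replace=False)
        for comp in sorted(int(c) for c in comps):
            child = f"{code}.{comp:03d}"
            codes.append(child)
            children.setdefault(code, []).append(child)
            frontier.append(child)

    # graft second parents across roots, refusing any graft that would make
    # the descriptor-level ancestor relation cyclic
    import networkx as nx

    owner = {c: i for i, c in enumerate(codes)}
    dag = nx.DiGraph()
    dag.add_nodes_from(range(len(codes)))
    for c in codes:
        if "." in c:
            dag.add_edge(owner[c.rsplit(".", 1)[0]], owner[c])

    extra: dict[str, str] = {}
    used = set(codes)
    non_roots = [c for c in codes if "." in c]
    n_multi = int(round(cfg.multi_parent_fraction * len(non_roots)))
    if n_multi and len(codes) > 1:
        picks = rng.choice(len(non_roots), size=min(n_multi, len(non_roots)), replace=False)
        for idx in sorted(int(i) for i in picks):
            target = non_roots[idx]
            root = target.split(".", 1)[0]
            hosts = [c for c in codes if c.split(".", 1)[0] != root
                     and c.count(".") + 1 < cfg.max_depth]
            if not hosts:
                continue
            host = hosts[int(rng.integers(len(hosts)))]
            if owner[host] == owner[target] or nx.has_path(
                dag, owner[target], owner[host]
            ):
                continue
            for _ in range(20):
                comp = int(rng.integers(100, 1000))
                second = f"{host}.{comp:03d}"
                if second not in used:
                    extra[target] = second
                    used.add(second)
                    dag.add_edge(owner[host], owner[target])
                    break

    descriptors = []
    for n, code in enumerate(codes):
        ui = f"D{n:06d}"
        tns = [code] + ([extra[code]] if code in extra else [])
        descriptors.append(make_descriptor(ui, f"Heading {n:04d}", tns))
    return Thesaurus(descriptors)


def _signature_word(ui: str, j: int) -> str:
    return f"{ui.lower()}w{j:02d}"


def generate_corpus(
    thesaurus: Thesaurus, cfg: GeneratorConfig, id_offset: int = 0
) -> list[LabeledDocument]:
    """Documents whose words are emitted by their (hierarchy-themed) labels.

    Per document: pick a topic root uniformly; draw a Poisson label count
    (mean ``labels_per_doc_mean``, clipped to ≥ 1); fill the label set
    mostly from the topic root's subtree (``theme_purity``), the rest from
    the whole thesaurus.  Each of ``words_per_doc`` words comes from the
    signature vocabulary of a uniformly chosen document label, or from the
    background vocabulary with probability ``noise_rate``.
    """
    if len(thesaurus) == 0:
        raise ValueError("thesaurus is empty")
    rng = np.random.default_rng(cfg.seed * 2 + 1)
    all_uis = sorted(thesaurus.uis)
    roots = sorted({tn.root for d in thesaurus for tn in d.tree_numbers})
    by_root: dict[str, list[str]] = {}
    for ui in all_uis:
        for tn in thesaurus[ui].tree_numbers:
            by_root.setdefault(tn.root, [])
            if ui not in by_root[tn.root]:
                by_root[tn.root].append(ui)

    docs: list[LabeledDocument] = []
    for i in range(cfg.n_docs):
        root = roots[int(rng.integers(len(roots)))]
        pool = by_root[root]
        k = max(1, int(rng.poisson(cfg.labels_per_doc_mean)))
        k = min(k, len(all_uis))
        labels: set[str] = set()
        while len(labels) < k:
            if rng.random() < cfg.theme_purity and len(labels & set(pool)) < len(pool):
                labels.add(pool[int(rng.integers(len(pool)))])
            else:
                labels.add(all_uis[int(rng.integers(len(all_uis)))])
        label_list = sorted(labels)

        words = []
        for _ in range(cfg.words_per_doc):
            if rng.random() < cfg.noise_rate:
                words.append(f"noise{int(rng.integers(cfg.background_vocab_size)):05d}")
            else:
                ui = label_list[int(rng.integers(len(label_list)))]
                words.append(_signature_word(ui, int(rng.integers(cfg.signature_vocab_size))))
        docs.append(
            LabeledDocument(
                doc_id=str(1_000_000 + id_offset + i),
                title=" ".join(words[:8]),
                abstract=" ".join(words[8:]),
                journal=f"Journal of Branch {root}",
                year=2016,
                labels=frozenset(label_list),
            )
        )
    return docs


def generate_train_test(
    cfg: GeneratorConfig, n_train: int, n_test: int
) -> tuple[Thesaurus, list[LabeledDocument], list[LabeledDocument]]:
    """One thesaurus plus disjoint train/test corpora drawn from it."""
    thesaurus = generate_thesaurus(cfg)
    train = generate_corpus(thesaurus, cfg.with_(n_docs=n_train))
    test = generate_corpus(
        thesaurus, cfg.with_(n_docs=n_test, seed=cfg.seed + 1), id_offset=n_train
    )
    return thesaurus, train, test
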