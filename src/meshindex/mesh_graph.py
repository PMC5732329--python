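"""MeSH-style thesaurus: descriptors, tree numbers and hierarchy queries.

A descriptor (main heading) carries a unique id, a unique name and one or
more *tree numbers* — dot-separated codes such as ``C04.557.386`` that locate
the heading in the concept hierarchy.  The proper-prefix relation on tree
numbers defines ancestry, so a descriptor with several tree numbers lives in
several branches at once ("each child can have more than one parent").

Category letters on their own (the 16 top-level MeSH branches, e.g. ``C``)
are not descriptors here; depth-1 codes like ``C04`` are the roots of the
forest.

Two plain-text serializations are supported:

* TSV — one record per line, ``ui<TAB>name<TAB>tn1;tn2;...``
* JSON — an array of objects with keys ``ui``, ``name``, ``treeNumbers``
  (optional ``synonyms``)
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import networkx as nx

from .errors import IntegrityError, ThesaurusParseError, UnknownDescriptorError

_COMPONENT_RE = re.compile(r"^[A-Za-z0-9]+$")


@dataclass(frozen=True, order=True)
class TreeNumber:
    """A dot-separated hierarchy code; the prefix relation encodes ancestry."""

    code: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ThesaurusParseError("empty tree number")
        for part in self.code.split("."):
            if not _COMPONENT_RE.match(part):
                raise ThesaurusParseError(
                    f"malformed tree number {self.code!r}: bad component {part!r}"
                )

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(self.code.split("."))

    @property
    def depth(self) -> int:
        return self.code.count(".") + 1

    @property
    def root(self) -> str:
        """Depth-1 code heading this branch (e.g. ``C04`` for ``C04.557.386``)."""
        return self.code.split(".", 1)[0]

    def parent_code(self) -> str | None:
        if "." not in self.code:
            return None
        return self.code.rsplit(".", 1)[0]

    def prefixes(self, proper: bool = True) -> list[str]:
        """All prefix codes, shallowest first (excluding self iff *proper*)."""
        parts = self.code.split(".")
        stop = len(parts) - 1 if proper else len(parts)
        return [".".join(parts[: i + 1]) for i in range(stop)]

    def is_prefix_of(self, other: "TreeNumber | str", proper: bool = True) -> bool:
        other_code = other.code if isinstance(other, TreeNumber) else other
        if self.code == other_code:
            return not proper
        return other_code.startswith(self.code + ".")

    def __str__(self) -> str:
        return self.code


@dataclass(frozen=True)
class Descriptor:
    """A main heading: unique id, unique name and ≥1 hierarchy positions."""

    ui: str
    name: str
    tree_numbers: frozenset[TreeNumber]
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.ui:
            raise ThesaurusParseError("descriptor with empty ui")
        if not self.name:
            raise ThesaurusParseError(f"descriptor {self.ui}: empty name")

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(tn.code for tn in self.tree_numbers)

    @property
    def max_depth(self) -> int:
        return max(tn.depth for tn in self.tree_numbers) if self.tree_numbers else 0

    def sorted_codes(self) -> list[str]:
        return sorted(tn.code for tn in self.tree_numbers)


def make_descriptor(
    ui: str, name: str, codes: Iterable[str], synonyms: Iterable[str] = ()
) -> Descriptor:
    return Descriptor(
        ui=ui,
        name=name,
        tree_numbers=frozenset(TreeNumber(c) for c in codes),
        synonyms=frozenset(synonyms),
    )


class LCAResult(NamedTuple):
    ui: str
    depth: int
    code: str  # deepest (then lexicographically smallest) witnessing code


class Thesaurus:
    """A set of descriptors plus the prefix forest over their tree numbers.

    Hierarchy queries (ancestors, descendants, LCA, shortest path) are
    answered from the in-memory prefix index; a :mod:`networkx` graph over
    tree-number codes backs the path queries.
    """

    def __init__(
        self, descriptors: Iterable[Descriptor], allow_orphans: bool = False
    ) -> None:
        self._descriptors: dict[str, Descriptor] = {}
        self._by_name: dict[str, str] = {}
        self.tree_index: dict[str, str] = {}
        for d in descriptors:
            if d.ui in self._descriptors:
                raise IntegrityError(f"duplicate descriptor ui {d.ui!r}")
            if d.name in self._by_name:
                raise IntegrityError(f"duplicate descriptor name {d.name!r}")
            if not d.tree_numbers:
                if not allow_orphans:
                    raise IntegrityError(
                        f"descriptor {d.ui!r} has no tree numbers "
                        "(pass allow_orphans=True to keep it as an isolated node)"
                    )
                warnings.warn(
                    f"descriptor {d.ui!r} kept as isolated node (no tree numbers)",
                    stacklevel=2,
                )
            for tn in d.tree_numbers:
                owner = self.tree_index.get(tn.code)
                if owner is not None:
                    raise IntegrityError(
                        f"tree number {tn.code} claimed by both {owner!r} and {d.ui!r}"
                    )
                self.tree_index[tn.code] = d.ui
            self._descriptors[d.ui] = d
            self._by_name[d.name] = d.ui
        self._code_graph: nx.Graph | None = None
        self._sssp_cache: dict[str, dict[str, int]] = {}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        """The descriptor-level ancestor relation must admit a topological
        order; multi-parent placements may otherwise smuggle in a cycle."""
        g = nx.DiGraph()
        g.add_nodes_from(self._descriptors)
        for code, child in self.tree_index.items():
            tn = TreeNumber(code)
            for prefix in tn.prefixes(proper=True):
                parent = self.tree_index.get(prefix)
                if parent is not None and parent != child:
                    g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise IntegrityError(
                f"cyclic ancestor relation through {[e[0] for e in cycle]}"
            )

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._descriptors)

    def __contains__(self, ui: object) -> bool:
        return ui in self._descriptors

    def __iter__(self) -> Iterator[Descriptor]:
        return iter(self._descriptors.values())

    def __getitem__(self, ui: str) -> Descriptor:
        return self._require(ui)

    @property
    def uis(self) -> list[str]:
        return list(self._descriptors)

    def get(self, ui: str) -> Descriptor | None:
        return self._descriptors.get(ui)

    def by_name(self, name: str) -> str | None:
        """Resolve a heading name to its ui, or None."""
        return self._by_name.get(name)

    def _require(self, ui: str) -> Descriptor:
        try:
            return self._descriptors[ui]
        except KeyError:
            raise UnknownDescriptorError(ui) from None

    # -- hierarchy queries ---------------------------------------------------

    def ancestors(self, ui: str, include_self: bool = False) -> set[str]:
        """Descriptors owning a proper prefix of any tree number of *ui*.

        Equals the transitive closure of the parent relation.  Prefix codes
        with no owning descriptor are skipped silently.
        """
        d = self._require(ui)
        result: set[str] = set()
        for tn in d.tree_numbers:
            for prefix in tn.prefixes(proper=True):
                owner = self.tree_index.get(prefix)
                if owner is not None:
                    result.add(owner)
        result.discard(ui)
        if include_self:
            result.add(ui)
        return result

    def descendants(self, ui: str) -> set[str]:
        """Inverse of :meth:`ancestors`: never contains *ui* itself."""
        d = self._require(ui)
        result: set[str] = set()
        for code, owner in self.tree_index.items():
            if owner == ui:
                continue
            for tn in d.tree_numbers:
                if tn.is_prefix_of(code, proper=True):
                    result.add(owner)
                    break
        return result

    def lowest_common_ancestor(self, uis: Iterable[str]) -> str | None:
        detail = self.lca_detail(uis)
        return detail.ui if detail is not None else None

    def lca_detail(self, uis: Iterable[str]) -> LCAResult | None:
        """Deepest descriptor in the intersection of self-inclusive ancestor
        closures of *uis*, or None if the closures are disjoint.

        Depth of a candidate is taken over the tree-number codes that witness
        the common ancestry; ties break on the lexicographically smallest
        witnessing code.
        """
        members = sorted(set(uis))
        if len(members) < 2:
            raise ValueError("lowest_common_ancestor needs at least 2 descriptors")
        closures = [self.ancestors(u, include_self=True) for u in members]
        common = set.intersection(*closures)
        if not common:
            return None
        best: LCAResult | None = None
        for cand in sorted(common):
            depth, code = self._witness_depth(cand, members)
            if (
                best is None
                or depth > best.depth
                or (depth == best.depth and code < best.code)
            ):
                best = LCAResult(cand, depth, code)
        return best

    def _witness_depth(self, cand: str, members: list[str]) -> tuple[int, str]:
        """Depth of *cand* restricted to codes witnessing the common ancestry.

        A code witnesses the full set when it is a proper prefix of a tree
        number of every member other than *cand* itself; the depth is then
        the deepest such code.  When no single code covers every member —
        ancestry holds through different branches — the depth falls back to
        the minimum over members of the deepest code witnessing that member,
        so it never exceeds any member's own depth.
        """
        d = self._require(cand)
        witness: dict[str, list[TreeNumber]] = {}
        for u in members:
            if u == cand:
                continue
            other = self._require(u)
            witness[u] = [
                tn
                for tn in d.tree_numbers
                if any(tn.is_prefix_of(o, proper=True) for o in other.tree_numbers)
            ]
        full = [
            tn
            for tn in d.tree_numbers
            if all(tn in ws for ws in witness.values())
        ]
        if full:
            depth = max(tn.depth for tn in full)
            code = min(tn.code for tn in full if tn.depth == depth)
            return depth, code
        depths = [max(tn.depth for tn in ws) for ws in witness.values() if ws]
        if cand in members:
            depths.append(d.max_depth)
        depth = min(depths) if depths else d.max_depth
        pool = sorted({tn.code for ws in witness.values() for tn in ws})
        code = pool[0] if pool else min(d.sorted_codes())
        return depth, code

    def shortest_path_length(self, ui1: str, ui2: str) -> float:
        """Minimum number of parent/child edges between any tree number of
        *ui1* and any of *ui2* in the prefix forest; ``inf`` if disconnected.
        """
        d1, d2 = self._require(ui1), self._require(ui2)
        if ui1 == ui2:
            return 0
        best = math.inf
        for tn1 in d1.tree_numbers:
            dist = self._sssp(tn1.code)
            for tn2 in d2.tree_numbers:
                best = min(best, dist.get(tn2.code, math.inf))
        return best

    @property
    def code_graph(self) -> nx.Graph:
        """Undirected graph over tree-number codes (including implied
        prefixes) with parent-child edges."""
        if self._code_graph is None:
            g = nx.Graph()
            for code in self.tree_index:
                tn = TreeNumber(code)
                chain = tn.prefixes(proper=False)
                g.add_node(chain[0])
                for a, b in zip(chain, chain[1:]):
                    g.add_edge(a, b)
            self._code_graph = g
        return self._code_graph

    def _sssp(self, code: str) -> dict[str, int]:
        if code not in self._sssp_cache:
            self._sssp_cache[code] = dict(
                nx.single_source_shortest_path_length(self.code_graph, code)
            )
        return self._sssp_cache[code]

    def path_descriptors(self, from_code: str, to_code: str) -> list[str]:
        """Descriptors owning each code on the prefix chain from *to_code*
        (an ancestor position, self-inclusive) down to *from_code*."""
        tn = TreeNumber(from_code)
        chain = tn.prefixes(proper=False)
        start = TreeNumber(to_code).depth - 1
        out = []
        for code in chain[start:]:
            owner = self.tree_index.get(code)
            if owner is not None:
                out.append(owner)
        return out

    # -- serialization -------------------------------------------------------

    def to_tsv(self) -> str:
        lines = []
        for ui in sorted(self._descriptors):
            d = self._descriptors[ui]
            lines.append(f"{d.ui}\t{d.name}\t{';'.join(d.sorted_codes())}")
        return "\n".join(lines) + ("\n" if lines else "")

    def to_json(self) -> str:
        records = [
            {
                "ui": d.ui,
                "name": d.name,
                "treeNumbers": d.sorted_codes(),
                **({"synonyms": sorted(d.synonyms)} if d.synonyms else {}),
            }
            for d in (self._descriptors[ui] for ui in sorted(self._descriptors))
        ]
        return json.dumps(records, indent=2, sort_keys=True) + "\n"

    def ancestors_record(self, ui: str) -> dict:
        """JSON-ready ancestor listing, names included."""
        return {
            "ui": ui,
            "name": self._require(ui).name,
            "ancestors": [
                {"ui": a, "name": self._require(a).name}
                for a in sorted(self.ancestors(ui))
            ],
        }


def parse_thesaurus(
    source: str | Path, allow_orphans: bool = False
) -> Thesaurus:
    """Parse a thesaurus from TSV or JSON text (or a path to either).

    Format is sniffed from the first non-blank character: ``[`` or ``{``
    means JSON, anything else the TSV dialect.  Malformed rows raise
    :class:`ThesaurusParseError` naming the offending row; duplicate uis,
    names or tree numbers raise :class:`IntegrityError`.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and source and "\n" not in source
        and "\t" not in source and not source.lstrip().startswith(("[", "{"))
        and Path(source).is_file()
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    stripped = text.lstrip()
    if stripped.startswith(("[", "{")):
        return _parse_json(stripped, allow_orphans)
    return _parse_tsv(text, allow_orphans)


def _parse_tsv(text: str, allow_orphans: bool) -> Thesaurus:
    descriptors = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ThesaurusParseError(
                f"row {lineno}: expected ui<TAB>name<TAB>treeNumbers, got {line!r}"
            )
        ui, name, codes_field = parts[0], parts[1], parts[2]
        codes = [c for c in codes_field.split(";") if c]
        try:
            descriptors.append(make_descriptor(ui, name, codes))
        except ThesaurusParseError as exc:
            raise ThesaurusParseError(f"row {lineno}: {exc}") from None
    return Thesaurus(descriptors, allow_orphans=allow_orphans)


def _parse_json(text: str, allow_orphans: bool) -> Thesaurus:
    try:
        records = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ThesaurusParseError(f"invalid JSON thesaurus: {exc}") from None
    if isinstance(records, dict):
        records = records.get("descriptors", [])
    descriptors = []
    for i, rec in enumerate(records):
        try:
            descriptors.append(
                make_descriptor(
                    rec["ui"],
                    rec["name"],
                    rec.get("treeNumbers", []),
                    rec.get("synonyms", []),
                )
            )
        except ThesaurusParseError as exc:
            raise ThesaurusParseError(f"record {i}: {exc}") from None
        except KeyError as exc:
            raise ThesaurusParseError(f"record {i}: missing key {exc}") from None
    return Thesaurus(descriptors, allow_orphans=allow_orphans)
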