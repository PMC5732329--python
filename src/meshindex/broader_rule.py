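"""The curators' "Specific Headings vs Broader Headings" heuristic.

When three or more proposed headings share a common ancestor in the
thesaurus, they are replaced by their lowest common ancestor.  The rule is
applied to a fixpoint: the deepest qualifying group fires first, its members
are consumed, the replacement is inserted, and the search repeats until no
group of ``min_group`` or more remains.  Each pass strictly shrinks the
label set (≥ min_group − 1 labels removed per replacement), so termination
is guaranteed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import UnknownDescriptorError
from .mesh_graph import Thesaurus


@dataclass(frozen=True)
class ReplacementGroup:
    """≥ min_group labels sharing an ancestor, annotated with their LCA."""

    members: frozenset[str]
    ancestor: str  # lowest common ancestor of the members
    depth: int  # witnessing depth of that LCA
    code: str  # deepest witnessing tree-number code (tie-break key)


def find_groups(
    labels: Iterable[str],
    thesaurus: Thesaurus,
    min_group: int = 3,
    missing: str = "error",
) -> list[ReplacementGroup]:
    """Groups of ≥ *min_group* labels sharing a proper ancestor descriptor.

    Each group is annotated with the LCA of its members (which may be deeper
    than the shared ancestor that formed it); groups with identical member
    sets are merged.  Sorted deepest LCA first, then by witnessing code.

    *missing* controls labels absent from the thesaurus: ``"error"`` raises,
    ``"skip"`` drops them with a warning.
    """
    known: list[str] = []
    for l in set(labels):
        if l in thesaurus:
            known.append(l)
        elif missing == "skip":
            warnings.warn(f"label {l!r} not in thesaurus; skipped", stacklevel=2)
        else:
            raise UnknownDescriptorError(l)

    members_by_ancestor: dict[str, set[str]] = {}
    for l in known:
        for a in thesaurus.ancestors(l, include_self=False):
            members_by_ancestor.setdefault(a, set()).add(l)

    groups: dict[frozenset[str], ReplacementGroup] = {}
    for members in members_by_ancestor.values():
        ms = frozenset(members)
        if len(ms) < min_group or ms in groups:
            continue
        lca = thesaurus.lca_detail(ms)
        assert lca is not None  # a shared proper ancestor exists by construction
        groups[ms] = ReplacementGroup(ms, lca.ui, lca.depth, lca.code)
    # tie-break is total (member list last) so the firing order never
    # depends on set iteration order
    return sorted(
        groups.values(), key=lambda g: (-g.depth, g.code, sorted(g.members))
    )


def apply_broader_rule(
    labels: Iterable[str],
    thesaurus: Thesaurus,
    min_group: int = 3,
    missing: str = "error",
) -> set[str]:
    """Fixpoint of the replacement rule over a label set."""
    scores = {l: 0.0 for l in labels}
    return set(rewrite_scored(scores, thesaurus, min_group, missing=missing))


def rewrite_scored(
    scores: Mapping[str, float],
    thesaurus: Thesaurus,
    min_group: int = 3,
    missing: str = "error",
) -> dict[str, float]:
    """Apply the rule to a label→score mapping.

    A replacement LCA inherits the maximum score of the members it consumed,
    so the downstream ranking stays total.  Labels never grouped pass
    through with their score unchanged.
    """
    current = dict(scores)
    while True:
        groups = find_groups(current, thesaurus, min_group, missing=missing)
        if not groups:
            return current
        g = groups[0]  # deepest LCA first
        member_scores = [current.pop(m) for m in sorted(g.members) if m in current]
        inherited = max(member_scores) if member_scores else 0.0
        current[g.ancestor] = max(inherited, current.get(g.ancestor, 0.0))
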