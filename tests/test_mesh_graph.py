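"""Thesaurus parsing and hierarchy queries against brute-force oracles."""

import math

import networkx as nx
import pytest
from hypothesis import given
from hypothesis import strategies as st

from meshindex import (
    IntegrityError,
    ThesaurusParseError,
    Thesaurus,
    UnknownDescriptorError,
    make_descriptor,
    parse_thesaurus,
)
from meshindex.synth import GeneratorConfig, generate_thesaurus

from conftest import LYMPHOMA, LYMPHOMA_TSV, LYMPHOPROLIFERATIVE


def _small_thesaurus(seed: int) -> Thesaurus:
    cfg = GeneratorConfig(
        n_roots=3, branching_factor=3, max_depth=4, multi_parent_fraction=0.25,
        seed=seed,
    )
    return generate_thesaurus(cfg)


# -- oracles over the raw code table ----------------------------------------

def _codes_of(t: Thesaurus) -> dict[str, set[str]]:
    return {d.ui: set(d.codes) for d in t}


def oracle_ancestors(codes: dict[str, set[str]], tree_index: dict[str, str],
                     ui: str) -> set[str]:
    """Enumerate every proper dot-prefix of every code and look up its owner."""
    out = set()
    for code in codes[ui]:
        parts = code.split(".")
        for i in range(1, len(parts)):
            owner = tree_index.get(".".join(parts[:i]))
            if owner is not None:
                out.add(owner)
    out.discard(ui)
    return out


# -- parsing -----------------------------------------------------------------

class TestParsing:
    def test_lymphoma_record_three_tree_numbers(self, lymphoma_thesaurus):
        d = lymphoma_thesaurus[LYMPHOMA]
        assert d.name == "Lymphoma"
        assert d.codes == {"C04.557.386", "C15.604.515.569", "C20.683.515.761"}
        assert {c.split(".")[0] for c in d.codes} == {"C04", "C15", "C20"}

    def test_empty_source_gives_empty_thesaurus(self):
        assert len(parse_thesaurus("")) == 0

    def test_duplicate_tree_number_rejected(self):
        text = "D1\tAlpha\tC04.557\nD2\tBeta\tC04.557\n"
        with pytest.raises(IntegrityError, match="C04.557"):
            parse_thesaurus(text)

    def test_duplicate_ui_rejected(self):
        text = "D1\tAlpha\tC04\nD1\tBeta\tC05\n"
        with pytest.raises(IntegrityError, match="duplicate descriptor ui"):
            parse_thesaurus(text)

    def test_malformed_tree_number_names_row(self):
        text = "D1\tAlpha\tC04\nD2\tBeta\tC05..7\n"
        with pytest.raises(ThesaurusParseError, match="row 2"):
            parse_thesaurus(text)

    def test_descriptor_without_tree_numbers_rejected_by_default(self):
        with pytest.raises(IntegrityError, match="no tree numbers"):
            Thesaurus([make_descriptor("D1", "Alpha", [])])
        with pytest.warns(UserWarning):
            t = Thesaurus([make_descriptor("D1", "Alpha", [])], allow_orphans=True)
        assert "D1" in t

    def test_json_dialect_roundtrip(self, lymphoma_thesaurus):
        reparsed = parse_thesaurus(lymphoma_thesaurus.to_json())
        assert reparsed.to_tsv() == lymphoma_thesaurus.to_tsv()

    def test_tsv_roundtrip_bit_identical(self):
        assert parse_thesaurus(LYMPHOMA_TSV).to_tsv() == LYMPHOMA_TSV


# -- ancestors / descendants -------------------------------------------------

class TestAncestry:
    def test_lymphoma_proper_ancestors_match_printed_expansion(
        self, lymphoma_thesaurus
    ):
        t = lymphoma_thesaurus
        names = {t[a].name for a in t.ancestors(LYMPHOMA)}
        assert names == {
            "Neoplasms",
            "Neoplasms by Histologic Type",
            "Hemic and Lymphatic Diseases",
            "Lymphatic Diseases",
            "Lymphoproliferative Disorders",
            "Immune System Diseases",
            "Immunoproliferative Disorders",
        }
        # the expansion names 8 hierarchy positions; Lymphoproliferative
        # Disorders occupies two of them as one descriptor
        positions = {
            p
            for c in t[LYMPHOMA].codes
            for p in _proper_prefixes(c)
            if p in t.tree_index
        }
        assert len(positions) == 8

    def test_depth_one_descriptor_has_no_proper_ancestors(self, lymphoma_thesaurus):
        assert lymphoma_thesaurus.ancestors("D009369") == set()
        assert lymphoma_thesaurus.ancestors("D009369", include_self=True) == {"D009369"}

    def test_unknown_ui_raises(self, lymphoma_thesaurus):
        with pytest.raises(UnknownDescriptorError):
            lymphoma_thesaurus.ancestors("D999999")

    def test_descendants_contains_lymphoma(self, lymphoma_thesaurus):
        assert LYMPHOMA in lymphoma_thesaurus.descendants(LYMPHOPROLIFERATIVE)

    def test_leaf_has_no_descendants(self, lymphoma_thesaurus):
        assert lymphoma_thesaurus.descendants(LYMPHOMA) == set()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ancestors_equal_prefix_enumeration_oracle(self, seed):
        t = _small_thesaurus(seed)
        codes = _codes_of(t)
        for ui in t.uis:
            assert t.ancestors(ui) == oracle_ancestors(codes, t.tree_index, ui)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_ancestors_descendants_mutually_inverse(self, seed):
        t = _small_thesaurus(seed)
        uis = t.uis
        for u in uis:
            desc = t.descendants(u)
            for v in uis:
                assert (v in desc) == (u in t.ancestors(v))
            assert u not in desc

    def test_ancestor_relation_is_acyclic(self):
        t = _small_thesaurus(7)
        g = nx.DiGraph()
        g.add_nodes_from(t.uis)
        for u in t.uis:
            for a in t.ancestors(u):
                g.add_edge(a, u)
        assert nx.is_directed_acyclic_graph(g)


def _proper_prefixes(code: str) -> list[str]:
    parts = code.split(".")
    return [".".join(parts[:i]) for i in range(1, len(parts))]


# -- lowest common ancestor ---------------------------------------------------

class TestLCA:
    def test_lymphoma_vs_lymphoproliferative(self, lymphoma_thesaurus):
        got = lymphoma_thesaurus.lowest_common_ancestor(
            {LYMPHOMA, LYMPHOPROLIFERATIVE}
        )
        assert got == LYMPHOPROLIFERATIVE

    def test_disjoint_roots_have_no_lca(self):
        t = parse_thesaurus("D1\tAlpha\tA01\nD2\tBeta\tB01\n")
        assert t.lowest_common_ancestor({"D1", "D2"}) is None

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_lca_depth_matches_pairwise_common_prefix_oracle(self, seed):
        # single-parent forest: common ancestry is exactly common code prefixes
        t = generate_thesaurus(
            GeneratorConfig(
                n_roots=3, branching_factor=3, max_depth=4,
                multi_parent_fraction=0.0, seed=seed,
            )
        )
        codes = _codes_of(t)
        uis = sorted(t.uis)
        import random

        rng = random.Random(seed)
        for _ in range(60):
            u, v = rng.sample(uis, 2)
            expected = 0
            for c1 in codes[u]:
                for c2 in codes[v]:
                    p1, p2 = c1.split("."), c2.split(".")
                    k = 0
                    while k < min(len(p1), len(p2)) and p1[k] == p2[k]:
                        k += 1
                    # the common prefix must be an owned position to count
                    while k and ".".join(p1[:k]) not in t.tree_index:
                        k -= 1
                    expected = max(expected, k)
            detail = t.lca_detail({u, v})
            if expected == 0:
                assert detail is None
            else:
                assert detail is not None and detail.depth == expected

    def test_lca_symmetric_and_depth_bounded(self):
        t = _small_thesaurus(9)
        import random

        rng = random.Random(1)
        for _ in range(40):
            group = rng.sample(sorted(t.uis), 3)
            a = t.lowest_common_ancestor(group)
            assert a == t.lowest_common_ancestor(list(reversed(group)))
            if a is not None:
                depth = t.lca_detail(group).depth
                assert depth <= min(t[u].max_depth for u in group)

    def test_lca_of_descriptor_and_its_descendant_is_the_descriptor(
        self, lymphoma_thesaurus
    ):
        t = lymphoma_thesaurus
        assert t.lowest_common_ancestor({"D007154", LYMPHOMA}) == "D007154"


# -- shortest path -----------------------------------------------------------

class TestShortestPath:
    def test_direct_child_distance_one(self, lymphoma_thesaurus):
        assert (
            lymphoma_thesaurus.shortest_path_length(LYMPHOMA, LYMPHOPROLIFERATIVE)
            == 1
        )

    def test_identity_distance_zero(self, lymphoma_thesaurus):
        assert lymphoma_thesaurus.shortest_path_length(LYMPHOMA, LYMPHOMA) == 0

    def test_disconnected_is_infinite(self):
        t = parse_thesaurus("D1\tAlpha\tA01\nD2\tBeta\tB01\n")
        assert math.isinf(t.shortest_path_length("D1", "D2"))

    @pytest.mark.parametrize("seed", [0, 4])
    def test_matches_bfs_over_explicit_edge_list(self, seed):
        t = _small_thesaurus(seed)
        g = nx.Graph()
        for code in t.tree_index:
            parts = code.split(".")
            chain = [".".join(parts[: i + 1]) for i in range(len(parts))]
            g.add_node(chain[0])
            for a, b in zip(chain, chain[1:]):
                g.add_edge(a, b)
        codes = _codes_of(t)
        import random

        rng = random.Random(seed)
        for _ in range(40):
            u, v = rng.sample(sorted(t.uis), 2)
            best = math.inf
            for c1 in codes[u]:
                for c2 in codes[v]:
                    try:
                        best = min(best, nx.shortest_path_length(g, c1, c2))
                    except nx.NetworkXNoPath:
                        pass
            assert t.shortest_path_length(u, v) == best


# -- export ------------------------------------------------------------------

def test_ancestors_record_lists_names(lymphoma_thesaurus):
    rec = lymphoma_thesaurus.ancestors_record(LYMPHOMA)
    assert rec["ui"] == LYMPHOMA and rec["name"] == "Lymphoma"
    assert {e["name"] for e in rec["ancestors"]} >= {
        "Neoplasms",
        "Immune System Diseases",
    }


@given(st.integers(min_value=0, max_value=10_000))
def test_generated_thesauri_satisfy_invariants(seed):
    """Every generated forest parses back and keeps tree-number ownership unique."""
    t = _small_thesaurus(seed % 50)
    reparsed = parse_thesaurus(t.to_tsv())
    assert reparsed.to_tsv() == t.to_tsv()
    owned = [c for d in t for c in d.codes]
    assert len(owned) == len(set(owned)) == len(t.tree_index)
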