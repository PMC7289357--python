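"""Category subgraph construction: seeding, election, extension, constraint."""

import pytest

from goslice.categorize import (
    CONSERVATIVE,
    CategorySpec,
    Subgraph,
    build_category,
    extend_comprehensive,
    extend_conservative,
    recreate_edges,
    seed_by_keywords,
    select_representative,
)
from goslice.errors import CategorizationError, UnknownTermError
from goslice.obo import parse_obo

from conftest import A, B, C, D, E, F, G

# A hand-written mini cell-component ontology.  "cell nucleus" has four
# descendants; "nuclear membrane" has one; "aggresome body" is isolated;
# two decoy terms mention keywords only in their definitions.
MINI_OBO = """\
[Term]
id: GO:0000001
name: cell nucleus
def: "Membrane-bounded organelle holding chromatin." []

[Term]
id: GO:0000002
name: nuclear membrane
def: "Double membrane around the cell nucleus." []
is_a: GO:0000001

[Term]
id: GO:0000003
name: nuclear pore
def: "Channel through the nuclear membrane." []
is_a: GO:0000002

[Term]
id: GO:0000004
name: nucleolus body
def: "Dense region inside the organelle." []
relationship: part_of GO:0000001

[Term]
id: GO:0000005
name: chromatin region
def: "Unnamed subregion." []
relationship: part_of GO:0000001

[Term]
id: GO:0000006
name: aggresome body
def: "An isolated inclusion." []

[Term]
id: GO:0000007
name: stray granule
def: "A decoy whose definition mentions the nucleus keyword." []

[Term]
id: GO:0000008
name: unrelated filament
def: "Another decoy mentioning nuclear import." []
"""

NUC, NM, NP, NO, CR, AGG, DEC1, DEC2 = (f"GO:{i:07d}" for i in range(1, 9))


@pytest.fixture
def mini():
    return parse_obo(MINI_OBO)


def _seeded_subgraph(graph, keywords):
    seeded = seed_by_keywords(graph, keywords)
    sg = Subgraph(
        spec=CategorySpec(name="test", keywords=tuple(keywords)),
        supergraph=graph,
        seeded_ids=frozenset(seeded),
    )
    sg.node_ids = set(seeded)
    sg.refresh_links()
    return sg


class TestSeeding:
    def test_no_match_gives_empty_set(self, mini):
        assert seed_by_keywords(mini, ["zzzz"]) == set()

    def test_substring_matches_names(self, mini):
        hits = seed_by_keywords(mini, ["nucle"])
        # matches names AND definitions containing the substring
        assert {NUC, NM, NP, NO} <= hits

    def test_definition_only_match_included(self, mini):
        assert DEC1 in seed_by_keywords(mini, ["nucleus"])
        assert DEC2 in seed_by_keywords(mini, ["nuclear"])

    def test_empty_keyword_list_rejected(self, mini):
        with pytest.raises(ValueError):
            seed_by_keywords(mini, [])


class TestRecreateEdges:
    def test_single_term_has_no_edges(self, seven_graph):
        assert recreate_edges(seven_graph, {A}) == []

    def test_orientation_preserved_and_endpoints_filtered(self, seven_graph):
        edges = recreate_edges(seven_graph, {A, B, D})
        pairs = {(e.parent_id, e.child_id) for e in edges}
        # has_part edge A->D retained with D as child; C part_of A absent
        assert pairs == {(A, B), (A, D)}

    def test_unknown_seed_rejected(self, seven_graph):
        with pytest.raises(UnknownTermError):
            recreate_edges(seven_graph, {"nope"})


class TestRepresentative:
    def test_most_descendants_wins(self, mini):
        sg = _seeded_subgraph(mini, ["nucleus", "nuclear"])
        # "cell nucleus" has 4 subgraph descendants, "nuclear membrane" 1
        assert select_representative(sg, ["nucleus", "nuclear"]) == NUC

    def test_tie_breaks_to_smallest_id(self):
        text = (
            "[Term]\nid: Z:2\nname: blob two\n\n"
            "[Term]\nid: Z:1\nname: blob one\n\n"
            "[Term]\nid: Z:3\nname: child\nis_a: Z:1\n\n"
            "[Term]\nid: Z:4\nname: child\nis_a: Z:2\n"
        )
        g = parse_obo(text)
        sg = _seeded_subgraph(g, ["blob", "child"])
        assert select_representative(sg, ["blob"]) == "Z:1"

    def test_isolated_keyword_named_node_elects_itself(self, mini):
        sg = _seeded_subgraph(mini, ["aggresome"])
        assert select_representative(sg, ["aggresome"]) == AGG

    def test_no_keyword_in_any_name_raises(self, mini):
        # decoys are seeded via definitions only: nothing can represent them
        seeded = seed_by_keywords(mini, ["import"])  # matches DEC2 def only
        sg = _seeded_subgraph(mini, ["import"])
        assert seeded == {DEC2} and sg.node_ids == {DEC2}
        with pytest.raises(CategorizationError):
            select_representative(sg, ["import"])


class TestExtension:
    def test_leaf_representative_adds_nothing(self, mini):
        sg = _seeded_subgraph(mini, ["aggresome"])
        sg.representative_ids = (AGG,)
        before = set(sg.node_ids)
        extend_comprehensive(mini, sg)
        assert sg.node_ids == before

    def test_comprehensive_adds_unseeded_descendants(self, mini):
        # seed only by "nucleus": NP ("nuclear pore") and CR are not seeded
        sg = _seeded_subgraph(mini, ["nucleus"])
        sg.representative_ids = (NUC,)
        assert NP not in sg.node_ids and CR not in sg.node_ids
        extend_comprehensive(mini, sg)
        assert {NUC, NM, NP, NO, CR} <= sg.node_ids

    def test_conservative_adds_only_path_intermediates(self):
        # chain rep -> X -> L with X unseeded plus rep -> OFF not on a
        # leaf path: conservative adds X but never OFF
        text = (
            "[Term]\nid: R\nname: widget root\n\n"
            "[Term]\nid: X\nname: unrelated linker\nis_a: R\n\n"
            "[Term]\nid: L\nname: widget leaf\nis_a: X\n\n"
            "[Term]\nid: OFF\nname: offside\nis_a: R\n"
        )
        g = parse_obo(text)
        sg = _seeded_subgraph(g, ["widget"])
        sg.representative_ids = ("R",)
        extend_conservative(g, sg)
        assert "X" in sg.node_ids and "OFF" not in sg.node_ids

    def test_conservative_subset_of_comprehensive(self, mini):
        spec_a = CategorySpec(name="n", keywords=("nucleus",))
        spec_b = CategorySpec(
            name="n", keywords=("nucleus",), extension_mode=CONSERVATIVE
        )
        comp = build_category(mini, spec_a)
        cons = build_category(mini, spec_b)
        assert cons.member_ids <= comp.member_ids


class TestConstraintAndPipeline:
    def test_decoys_are_removed_at_constraint(self, mini):
        sg = build_category(mini, CategorySpec(name="n", keywords=("nucleus",)))
        assert sg.representative_ids == (NUC,)
        assert sg.member_ids == {NUC, NM, NP, NO, CR}
        assert DEC1 in sg.removed_seed_ids
        assert not (sg.removed_seed_ids & sg.member_ids)

    def test_removed_plus_seeded_members_partition_seeding(self, mini):
        sg = build_category(mini, CategorySpec(name="n", keywords=("nucleus",)))
        assert (sg.removed_seed_ids | (sg.seeded_ids & sg.member_ids)) == sg.seeded_ids
        # summary-row arithmetic: total = seeded + added - removed
        assert len(sg.member_ids) == (
            sg.seeded_count + sg.added_count - sg.removed_count
        )

    def test_bacterial_pattern_many_seeded_few_rooted(self):
        """Structural analogue of a keyword that seeds widely but roots
        narrowly: most seeded terms fall away at the constraint stage."""
        chunks = ["[Term]\nid: B:00\nname: flagellum rod root\n"]
        for i in range(1, 4):  # 3 genuine members under the root
            chunks.append(f"[Term]\nid: B:{i:02d}\nname: rod segment {i}\n"
                          f"is_a: B:00\n")
        for i in range(4, 20):  # 16 decoys seeded by definition only
            chunks.append(f"[Term]\nid: B:{i:02d}\nname: bystander {i}\n"
                          f'def: "Mentions flagellum in passing." []\n')
        g = parse_obo("\n".join(chunks))
        sg = build_category(g, CategorySpec(name="b", keywords=("flagellum",)))
        assert sg.seeded_count == 17  # root + 16 decoys
        assert sg.member_ids == {"B:00", "B:01", "B:02", "B:03"}
        assert sg.removed_count == 16 and sg.added_count == 3

    def test_disconnected_seeded_component_entirely_removed(self, mini):
        # both decoys seed on "mention"; neither roots to the aggresome rep
        sg = build_category(
            mini, CategorySpec(name="a", keywords=("aggresome", "mention"))
        )
        assert sg.member_ids == {AGG}
        assert sg.removed_seed_ids == {DEC1, DEC2}

    def test_seed_terms_bypass_election(self, seven_graph):
        sg = build_category(
            seven_graph, CategorySpec(name="all", seed_terms=(A,))
        )
        assert sg.representative_ids == (A,)
        assert sg.member_ids == {A, B, C, D, E, F, G}

    def test_multiple_seed_terms_union_members(self, seven_graph):
        sg = build_category(
            seven_graph, CategorySpec(name="two", seed_terms=(B, D))
        )
        assert sg.member_ids == {B, E, D, G}
        assert sg.members_by_representative[B] == {B, E}

    def test_rerun_is_deterministic(self, mini):
        spec = CategorySpec(name="n", keywords=("nucleus", "nuclear"))
        first = build_category(mini, spec)
        second = build_category(mini, spec)
        assert first.member_ids == second.member_ids
        assert first.representative_ids == second.representative_ids

    def test_spec_requires_keywords_or_seeds(self):
        with pytest.raises(ValueError):
            CategorySpec(name="empty")

    def test_subgraph_never_mutates_supergraph(self, mini):
        before = {t: set(n.parent_set) for t, n in mini.nodes.items()}
        build_category(mini, CategorySpec(name="n", keywords=("nucleus",)))
        assert {t: set(n.parent_set) for t, n in mini.nodes.items()} == before


def test_basic_scoping_never_grows_a_subgraph():
    """With has_part excluded, members can only shrink (same representative)."""
    from goslice.synth import FixtureSpec, generate_ontology
    from goslice.obo import GO_BASIC_RELATIONS

    fx = generate_ontology(FixtureSpec(n_categories=3, depth=3, branching=2,
                                       has_part_fraction=0.4, rng_seed=11))
    full = parse_obo(fx.obo_text)
    basic = parse_obo(fx.obo_text, allowed_relations=GO_BASIC_RELATIONS)
    for name, truth in fx.categories.items():
        spec = CategorySpec(name=name, seed_terms=(truth.root_id,))
        assert build_category(basic, spec).member_ids <= \
            build_category(full, spec).member_ids
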