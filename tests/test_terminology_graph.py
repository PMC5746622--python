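import itertools
import json
import random

import pytest

from sanops_alert.errors import GraphValidationError, LookupError_
from sanops_alert.terminology_graph import (
    Concept,
    Edge,
    RelationType,
    TerminologyGraph,
    TypedPath,
    find_paths,
    load_graph,
    rootward_closure_avoiding,
    rootward_neighbors,
    save_graph,
)

from conftest import CANDIDATES, make_random_graph

R = RelationType


def chain_graph(*relations):
    """A -> B -> C ... linear chain with the given relation types."""
    n = len(relations) + 1
    ids = [chr(ord("A") + i) for i in range(n)]
    concepts = [Concept(i, i) for i in ids]
    edges = [
        Edge(ids[i], ids[i + 1], rel) for i, rel in enumerate(relations)
    ]
    return TerminologyGraph("chain", concepts, edges)


# -- independent brute-force oracles ---------------------------------------


def brute_force_paths(graph, start, goal, max_length):
    """Exhaustive simple-walk enumeration via itertools over edge lists."""
    edges = list(graph.edges)
    found = []
    for length in range(1, max_length + 1):
        for combo in itertools.permutations(edges, length):
            if combo[0].source != start or combo[-1].target != goal:
                continue
            if any(a.target != b.source for a, b in zip(combo, combo[1:])):
                continue
            nodes = [combo[0].source] + [e.target for e in combo]
            if len(set(nodes)) != len(nodes):
                continue
            found.append(tuple(combo))
    return set(found)


def brute_force_bypass(graph, start, forbidden):
    """Enumerate every maximal rootward walk from start; check avoidance."""
    roots = graph.roots()
    if start == forbidden:
        return False
    if start in roots:
        return True
    edges = [e for e in graph.edges if e.rootward]
    stack = [(start, (start,))]
    while stack:
        node, seen = stack.pop()
        outs = [e for e in edges if e.source == node]
        if not outs and node in roots and forbidden not in seen:
            return True
        for e in outs:
            if e.target in seen:
                continue
            stack.append((e.target, seen + (e.target,)))
    return False


# -- construction and validation -------------------------------------------


class TestValidation:
    def test_minimal_single_concept(self, tmp_path):
        path = tmp_path / "mini.json"
        path.write_text(
            json.dumps(
                {"name": "t", "concepts": [{"id": "a", "label": "A"}],
                 "edges": []}
            )
        )
        g = load_graph(path)
        assert len(g) == 1 and "a" in g

    def test_dangling_edge_endpoint_names_edge(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            json.dumps(
                {
                    "name": "t",
                    "concepts": [{"id": "a", "label": "A"}],
                    "edges": [
                        {"source": "a", "target": "ghost", "relation": "is_a"}
                    ],
                }
            )
        )
        with pytest.raises(GraphValidationError, match="ghost"):
            load_graph(path)

    def test_malformed_json(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(json.JSONDecodeError):
            load_graph(path)

    def test_rootward_cycle_rejected(self):
        concepts = [Concept("a", "A"), Concept("b", "B")]
        edges = [Edge("a", "b", R.IS_A), Edge("b", "a", R.PART_OF)]
        with pytest.raises(GraphValidationError, match="cycle"):
            TerminologyGraph("t", concepts, edges)

    def test_has_part_cycle_with_part_of_is_legal(self):
        concepts = [Concept("a", "A"), Concept("b", "B")]
        edges = [Edge("a", "b", R.PART_OF), Edge("b", "a", R.HAS_PART)]
        g = TerminologyGraph("t", concepts, edges)
        assert len(g.edges) == 2

    def test_self_loop_rejected(self):
        with pytest.raises(GraphValidationError):
            Edge("a", "a", R.IS_A)

    def test_duplicate_concept_id_rejected(self):
        with pytest.raises(GraphValidationError, match="duplicate"):
            TerminologyGraph("t", [Concept("a", "A"), Concept("a", "A2")])

    def test_empty_label_rejected(self):
        with pytest.raises(GraphValidationError):
            Concept("a", "")

    def test_unknown_relation_rejected(self, tmp_path):
        path = tmp_path / "rel.json"
        path.write_text(
            json.dumps(
                {
                    "name": "t",
                    "concepts": [
                        {"id": "a", "label": "A"},
                        {"id": "b", "label": "B"},
                    ],
                    "edges": [
                        {"source": "a", "target": "b", "relation": "near"}
                    ],
                }
            )
        )
        with pytest.raises(GraphValidationError, match="relation"):
            load_graph(path)

    def test_loinc_fixture_sinus_structure(self, backends):
        # paranasal sinuses hang off the skeletal system, not head
        g = backends["loinc"].graph
        sinus = g.by_label("Paranasal sinuses").id
        neigh = rootward_neighbors(g, sinus)
        targets = {t for t, _ in neigh}
        assert g.by_label("Skeletal system").id in targets
        assert g.by_label("Head").id not in targets
        rels = {rel for _, rel in neigh}
        assert rels == {R.IS_A}


# -- serialization ---------------------------------------------------------


class TestSerialization:
    def test_round_trip_no_edges(self, tmp_path):
        g = TerminologyGraph("t", [Concept("a", "A"), Concept("b", "B")])
        path = tmp_path / "g.json"
        save_graph(g, path)
        assert load_graph(path).structurally_equal(g)

    @pytest.mark.parametrize("name", CANDIDATES + ("sanops",))
    def test_round_trip_fixture(self, name, backends, tmp_path):
        g = backends[name].graph
        path = tmp_path / f"{name}.json"
        save_graph(g, path)
        g2 = load_graph(path)
        # structural-equality oracle: sorted concept and edge lists
        assert g2.concepts == g.concepts
        assert g2.edges == g.edges
        assert g2.name == g.name

    def test_relation_types_preserved(self, tmp_path):
        g = chain_graph(R.HAS_PART, R.CONSTITUTIONAL_PART_OF, R.REGIONAL_PART_OF)
        path = tmp_path / "rels.json"
        save_graph(g, path)
        assert [e.relation for e in load_graph(path).edges] == [
            e.relation for e in g.edges
        ]

    def test_stable_ordering_on_save(self, tmp_path):
        concepts = [Concept("z", "Z"), Concept("a", "A"), Concept("m", "M")]
        edges = [Edge("z", "a", R.IS_A), Edge("a", "m", R.PART_OF)]
        g = TerminologyGraph("t", concepts, edges)
        path = tmp_path / "o.json"
        save_graph(g, path)
        payload = json.loads(path.read_text())
        assert [c["id"] for c in payload["concepts"]] == ["a", "m", "z"]
        assert payload["edges"][0]["source"] == "a"

    def test_round_trip_random_graphs(self, tmp_path):
        rng = random.Random(11)
        for i in range(25):
            g = make_random_graph(rng, rng.randint(2, 15), 10, 3, f"r{i}")
            path = tmp_path / "g.json"
            save_graph(g, path)
            assert load_graph(path).structurally_equal(g)

    def test_unwritable_path(self, backends):
        with pytest.raises(OSError):
            save_graph(backends["loinc"].graph, "/nonexistent-dir/out.json")


# -- rootward_neighbors ----------------------------------------------------


class TestRootwardNeighbors:
    def test_no_outgoing_rootward_edges(self):
        g = chain_graph(R.IS_A)
        assert rootward_neighbors(g, "B") == set()

    def test_chain_queried_at_head(self):
        g = chain_graph(R.IS_A, R.IS_A)
        assert rootward_neighbors(g, "A") == {("B", R.IS_A)}

    def test_has_part_is_not_rootward(self):
        g = chain_graph(R.HAS_PART)
        assert rootward_neighbors(g, "A") == set()

    def test_unknown_concept(self):
        g = chain_graph(R.IS_A)
        with pytest.raises(LookupError_):
            rootward_neighbors(g, "nope")

    def test_snomed_temporal_bone_two_routes(self, backends):
        g = backends["snomed"].graph
        tb = g.by_label("Temporal bone structure").id
        head = g.by_label("Head structure").id
        neigh = {t for t, _ in rootward_neighbors(g, tb)}
        assert len(neigh) == 2
        to_head = [t for t in neigh if find_paths(g, t, head, 5)]
        avoiding = [
            t for t in neigh if rootward_closure_avoiding(g, t, head)
        ]
        assert to_head and avoiding


# -- find_paths ------------------------------------------------------------


class TestFindPaths:
    def test_single_part_of_edge(self):
        g = chain_graph(R.PART_OF)
        paths = find_paths(g, "A", "B", 5)
        assert len(paths) == 1
        (p,) = paths
        assert p.uniform and p.relation_set == {R.PART_OF}
        assert len(p) == 1

    def test_fma_esophagus_to_chest_mixed(self, backends):
        g = backends["fma"].graph
        eso = g.by_label("Esophagus").id
        chest = g.by_label("Chest").id
        paths = find_paths(g, eso, chest, 15)
        assert paths
        for p in paths:
            assert not p.uniform
            assert p.relation_set >= {R.HAS_PART, R.PART_OF}

    def test_loinc_cervical_spine_to_neck_empty(self, backends):
        g = backends["loinc"].graph
        cs = g.by_label("Cervical spine").id
        neck = g.by_label("Neck").id
        assert find_paths(g, cs, neck, 15) == []

    def test_unknown_concept(self):
        g = chain_graph(R.IS_A)
        with pytest.raises(LookupError_):
            find_paths(g, "A", "nope", 5)

    def test_max_length_cuts_long_paths(self):
        g = chain_graph(R.IS_A, R.IS_A, R.IS_A)
        assert find_paths(g, "A", "D", 2) == []
        assert len(find_paths(g, "A", "D", 3)) == 1

    def test_agrees_with_brute_force_on_random_graphs(self):
        rng = random.Random(42)
        for i in range(40):
            n = rng.randint(3, 8)
            g = make_random_graph(rng, n, rng.randint(2, 8),
                                  rng.randint(0, 3), f"bf{i}")
            start, goal = rng.sample([c.id for c in g.concepts], 2)
            max_length = 4
            got = {tuple(p.edges) for p in find_paths(g, start, goal, max_length)}
            expected = brute_force_paths(g, start, goal, max_length)
            assert got == expected

    def test_monotone_under_edge_addition(self):
        rng = random.Random(5)
        for i in range(30):
            g = make_random_graph(rng, 8, 6, 2, f"m{i}")
            ids = [c.id for c in g.concepts]
            start, goal = rng.sample(ids, 2)
            before = {tuple(p.edges) for p in find_paths(g, start, goal, 6)}
            # add one new rootward edge consistent with the index ordering
            i1 = rng.randrange(0, 7)
            j1 = rng.randrange(i1 + 1, 8)
            g2 = TerminologyGraph(
                g.name,
                g.concepts,
                set(g.edges) | {Edge(f"N{i1}", f"N{j1}", R.IS_A)},
            )
            after = {tuple(p.edges) for p in find_paths(g2, start, goal, 6)}
            assert before <= after


# -- rootward_closure_avoiding ---------------------------------------------


class TestBypass:
    def test_linear_chain_through_forbidden(self):
        g = chain_graph(R.IS_A, R.IS_A)  # A -> B -> C
        assert rootward_closure_avoiding(g, "A", "B") is False

    def test_start_is_root(self):
        g = chain_graph(R.IS_A)
        assert rootward_closure_avoiding(g, "B", "A") is True

    def test_start_equals_forbidden(self):
        g = chain_graph(R.IS_A)
        assert rootward_closure_avoiding(g, "A", "A") is False

    def test_snomed_sinus_bypasses_head(self, backends):
        g = backends["snomed"].graph
        sinus = g.by_label("Paranasal sinus structure").id
        head = g.by_label("Head structure").id
        assert rootward_closure_avoiding(g, sinus, head) is True

    def test_dead_end_branch_is_not_a_bypass(self):
        # A -> B -> C(root); A -> D, D's only continuation is B
        concepts = [Concept(x, x) for x in "ABCD"]
        edges = [
            Edge("A", "B", R.IS_A),
            Edge("B", "C", R.IS_A),
            Edge("A", "D", R.IS_A),
            Edge("D", "B", R.IS_A),
        ]
        g = TerminologyGraph("t", concepts, edges)
        assert rootward_closure_avoiding(g, "A", "B") is False
        assert rootward_closure_avoiding(g, "A", "C") is False
        assert rootward_closure_avoiding(g, "A", "D") is True

    def test_agrees_with_brute_force_on_random_graphs(self):
        rng = random.Random(99)
        for i in range(150):
            n = rng.randint(3, 12)
            g = make_random_graph(rng, n, rng.randint(2, 14),
                                  rng.randint(0, 4), f"bp{i}")
            ids = [c.id for c in g.concepts]
            start = rng.choice(ids)
            forbidden = rng.choice(ids)
            assert rootward_closure_avoiding(g, start, forbidden) == \
                brute_force_bypass(g, start, forbidden)


class TestTypedPath:
    def test_non_chaining_edges_rejected(self):
        with pytest.raises(GraphValidationError):
            TypedPath((Edge("a", "b", R.IS_A), Edge("c", "d", R.IS_A)))

    def test_empty_path_rejected(self):
        with pytest.raises(GraphValidationError):
            TypedPath(())

    def test_endpoints_and_concepts(self):
        p = TypedPath((Edge("a", "b", R.IS_A), Edge("b", "c", R.PART_OF)))
        assert p.start == "a" and p.end == "c"
        assert p.concepts() == ("a", "b", "c")
        assert not p.uniform
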