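"""Component tree: construction, numbering, coloring, GraphML export."""

import networkx as nx
import numpy as np
import pytest

from ccdyn.consensus import build_stack, graph_at_k
from ccdyn.graph_io import SubjectGraph
from ccdyn.tree import (
    assign_colors,
    build_component_tree,
    tree_to_networkx,
    write_tree_graphml,
)

from conftest import make_random_subjects, stack_from_counts


def components_at_k(subjects, k):
    """Multi-vertex components of G_k rebuilt from scratch (oracle)."""
    from conftest import edges_at_k_bruteforce

    g = nx.Graph()
    g.add_edges_from(edges_at_k_bruteforce(subjects, k))
    return {frozenset(c) for c in nx.connected_components(g) if len(c) > 1}


def recolor_bruteforce(tree):
    """Independent bottom-up recomputation of the coloring rules."""
    colors = {}
    fresh = 0
    for s in tree.numbered_nodes:  # creation order
        numbered = [c for c in tree.children[s] if isinstance(c, int)]
        if not numbered:
            fresh += 1
            colors[s] = fresh
        else:
            sizes = {c: len(tree.members[c]) for c in numbered}
            best = min(c for c in numbered if sizes[c] == max(sizes.values()))
            colors[s] = colors[best]
        for c in tree.children[s]:
            if isinstance(c, str):
                colors[c] = colors[s]
    return colors


class TestConstruction:
    def test_single_edge_single_subject(self):
        sg = SubjectGraph.from_edges("s", [("a", "b", 1.0)])
        tree = build_component_tree(build_stack([sg]))
        assert tree.n_numbered == 1
        assert tree.children[1] == ("a", "b")
        assert tree.birth_k[1] == 1
        assert tree.members[1] == {"a", "b"}
        assert tree.parent == {"a": 1, "b": 1}

    def test_pair_then_attachment_mirrors_recursive_merging(self):
        # two leaves merge into a numbered node; a third leaf then attaches,
        # forming a new parent of {numbered node, named leaf} whose label is
        # larger (it was born at a smaller k)
        _, stack = stack_from_counts(
            {("lh_a", "lh_b"): 3, ("lh_b", "lh_c"): 2}, n_subjects=3
        )
        tree = build_component_tree(stack)
        assert tree.n_numbered == 2
        assert tree.children[1] == ("lh_a", "lh_b")
        assert tree.children[2] == (1, "lh_c")
        assert tree.parent[1] == 2
        assert tree.birth_k[1] == 3 and tree.birth_k[2] == 2
        assert tree.birth_k[1] > tree.birth_k[2]

    def test_unchanged_component_spawns_no_node(self):
        # the ab component persists from k=2 to k=1 untouched; only the new
        # cd pair creates a node at k=1
        _, stack = stack_from_counts(
            {("a", "b"): 2, ("c", "d"): 1}, n_subjects=2
        )
        tree = build_component_tree(stack)
        assert tree.n_numbered == 2
        assert tree.members[1] == {"a", "b"}
        assert tree.members[2] == {"c", "d"}
        assert tree.birth_k == {1: 2, 2: 1}
        assert tree.roots == [1, 2]

    def test_internal_edge_spawns_no_node(self):
        _, stack = stack_from_counts(
            {("a", "b"): 2, ("b", "c"): 2, ("a", "c"): 1}, n_subjects=2
        )
        tree = build_component_tree(stack)
        assert tree.n_numbered == 1  # the triangle-closing edge adds nothing

    def test_same_step_siblings_ordered_by_smallest_member(self):
        _, stack = stack_from_counts(
            {("x", "y"): 1, ("a", "b"): 1, ("m", "n"): 1}, n_subjects=1
        )
        tree = build_component_tree(stack)
        assert tree.members[1] == {"a", "b"}
        assert tree.members[2] == {"m", "n"}
        assert tree.members[3] == {"x", "y"}

    def test_root_members_equal_union_components(self, rng):
        for _ in range(5):
            subjects = make_random_subjects(rng, 6, 14, edge_prob=0.12)
            stack = build_stack(subjects)
            tree = build_component_tree(stack)
            roots = {tree.members[r] for r in tree.roots}
            assert roots == components_at_k(subjects, 1)

    def test_every_numbered_node_is_a_component_at_birth(self, rng):
        for _ in range(5):
            subjects = make_random_subjects(rng, 7, 12, edge_prob=0.12)
            tree = build_component_tree(build_stack(subjects))
            for s in tree.numbered_nodes:
                assert tree.members[s] in components_at_k(subjects, tree.birth_k[s])

    def test_members_are_disjoint_union_of_children(self, rng):
        subjects = make_random_subjects(rng, 8, 15, edge_prob=0.12)
        tree = build_component_tree(build_stack(subjects))
        for s in tree.numbered_nodes:
            parts = [
                tree.members[c] if isinstance(c, int) else frozenset([c])
                for c in tree.children[s]
            ]
            assert sum(len(p) for p in parts) == len(tree.members[s])
            assert frozenset().union(*parts) == tree.members[s]

    def test_labels_and_birth_k_monotone_along_paths(self, rng):
        subjects = make_random_subjects(rng, 8, 15, edge_prob=0.12)
        tree = build_component_tree(build_stack(subjects))
        for child, par in tree.parent.items():
            if isinstance(child, int):
                assert child < par
                assert tree.birth_k[child] > tree.birth_k[par]

    def test_each_named_leaf_appears_once(self, rng):
        subjects = make_random_subjects(rng, 6, 12, edge_prob=0.15)
        stack = build_stack(subjects)
        tree = build_component_tree(stack)
        leaves = [c for ch in tree.children.values() for c in ch if isinstance(c, str)]
        assert len(leaves) == len(set(leaves))
        non_isolated = {v for e in stack.support for v in e}
        assert set(leaves) == non_isolated


class TestColors:
    def test_de_novo_pair_gets_fresh_shared_color(self):
        _, stack = stack_from_counts({("a", "b"): 1}, n_subjects=1)
        tree = assign_colors(build_component_tree(stack))
        assert tree.colors["a"] == tree.colors["b"] == tree.colors[1] == 1

    def test_attaching_leaf_inherits_existing_components_color(self):
        _, stack = stack_from_counts(
            {("a", "b"): 3, ("b", "c"): 2}, n_subjects=3
        )
        tree = assign_colors(build_component_tree(stack))
        assert tree.colors[2] == tree.colors[1]
        assert tree.colors["c"] == tree.colors[1]

    def test_merge_takes_largest_childs_color(self):
        # sizes 3 vs 2: the triple's color wins in the merge
        counts = {
            ("a", "b"): 4, ("b", "c"): 3,   # triple, color 1
            ("x", "y"): 2,                   # pair, color 2
            ("c", "x"): 1,                   # merge step
        }
        _, stack = stack_from_counts(counts, n_subjects=4)
        tree = assign_colors(build_component_tree(stack))
        triple = next(s for s in tree.numbered_nodes if tree.members[s] == {"a", "b", "c"})
        pair = next(s for s in tree.numbered_nodes if tree.members[s] == {"x", "y"})
        root = tree.roots[0]
        assert tree.colors[root] == tree.colors[triple] != tree.colors[pair]

    def test_equal_size_merge_prefers_older_child(self):
        counts = {
            ("a", "b"): 4,                   # pair 1 (older)
            ("x", "y"): 3,                   # pair 2
            ("b", "x"): 1,                   # merge of two size-2 components
        }
        _, stack = stack_from_counts(counts, n_subjects=4)
        tree = assign_colors(build_component_tree(stack))
        root = max(tree.numbered_nodes)
        assert tree.colors[root] == tree.colors[1]

    def test_matches_independent_recomputation(self, rng):
        for _ in range(6):
            subjects = make_random_subjects(rng, 7, 14, edge_prob=0.12)
            tree = assign_colors(build_component_tree(build_stack(subjects)))
            assert tree.colors == recolor_bruteforce(tree)

    def test_recoloring_is_idempotent(self, rng):
        subjects = make_random_subjects(rng, 6, 12, edge_prob=0.15)
        tree = assign_colors(build_component_tree(build_stack(subjects)))
        once = dict(tree.colors)
        assert assign_colors(tree).colors == once


class TestExport:
    def test_graphml_round_trip_attributes(self, tmp_path, rng):
        subjects = make_random_subjects(rng, 5, 10, edge_prob=0.2)
        tree = assign_colors(build_component_tree(build_stack(subjects)))
        path = tmp_path / "tree.graphml"
        write_tree_graphml(tree, path)
        g = nx.read_graphml(path)
        kinds = nx.get_node_attributes(g, "kind")
        assert set(kinds.values()) <= {"named", "numbered"}
        n_numbered = sum(1 for v in kinds.values() if v == "numbered")
        assert n_numbered == tree.n_numbered
        # edges point child -> parent
        for u, v in g.edges():
            assert g.nodes[v]["kind"] == "numbered"

    def test_export_is_deterministic(self, tmp_path, rng):
        subjects = make_random_subjects(rng, 5, 10, edge_prob=0.2)
        tree = assign_colors(build_component_tree(build_stack(subjects)))
        p1, p2 = tmp_path / "t1.graphml", tmp_path / "t2.graphml"
        write_tree_graphml(tree, p1)
        write_tree_graphml(tree, p2)
        assert p1.read_bytes() == p2.read_bytes()
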