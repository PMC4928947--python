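"""Component tree of the consensus sweep.

As ``k`` decreases, connected components of ``G_k`` are born (from isolated
vertices) and merge.  The component tree records this history:

* a *named node* — an ROI label — stands for a single-vertex component and
  is always a leaf;
* a *numbered node* stands for a multi-vertex component, labeled by
  consecutive positive integers in order of creation (so smaller labels were
  born at larger ``k``).

Whenever a step creates a multi-vertex component whose vertex set differs
from every component of the previous graph, a new numbered node is created
whose children are the previous components (numbered nodes) and previously
isolated vertices (named nodes) it absorbs.  A component that persists
unchanged across a step spawns no node.  Within one step, new nodes are
created in order of their lexicographically smallest member.

Colors trace lineages: a component born purely from isolated vertices gets
a fresh color; isolated vertices attaching to an existing component inherit
its color; when components merge, the parent takes the color of the child
with the largest member count (ties favor the older, smaller-labeled
child).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import networkx as nx

from .consensus import ConsensusStack
from .graph_io import Edge

#: A tree node: an ROI label (named leaf) or a positive integer (numbered).
Node = Union[str, int]


@dataclass
class ComponentTree:
    """Hierarchy of component births and merges along the sweep.

    ``children[s]`` lists node ``s``'s children (numbered ascending first,
    then named sorted); ``parent`` is the inverse, partial map (roots have
    no parent).  ``members[s]`` is the vertex set of the component that
    numbered node ``s`` was created for, and ``birth_k[s]`` the threshold at
    which it formed.  ``colors`` is empty until :func:`assign_colors` runs.
    """

    n_subjects: int
    n_numbered: int
    parent: dict[Node, int]
    children: dict[int, tuple[Node, ...]]
    birth_k: dict[int, int]
    members: dict[int, frozenset[str]]
    colors: dict[Node, int] = field(default_factory=dict)

    @property
    def numbered_nodes(self) -> range:
        return range(1, self.n_numbered + 1)

    @property
    def named_nodes(self) -> set[str]:
        return {c for ch in self.children.values() for c in ch if isinstance(c, str)}

    @property
    def roots(self) -> list[int]:
        return [s for s in self.numbered_nodes if s not in self.parent]


def build_component_tree(stack: ConsensusStack) -> ComponentTree:
    """Build the component tree by sweeping ``k = N .. 1``.

    Tracks, per vertex, the numbered node currently representing its
    component (or nothing while isolated).  Each step's new edges induce a
    grouping of the touched prior parts — numbered components and isolated
    vertices — and every group of two or more parts becomes one new
    numbered node.  A group of one part (edges internal to an existing
    component) leaves the vertex set unchanged and spawns nothing.
    """
    by_k = stack.edges_by_support()
    part_of: dict[str, int] = {}  # vertex -> current numbered component
    parent: dict[Node, int] = {}
    children: dict[int, tuple[Node, ...]] = {}
    birth_k: dict[int, int] = {}
    members: dict[int, frozenset[str]] = {}
    next_label = 1

    for k in range(stack.n_subjects, 0, -1):
        new_edges = by_k.get(k)
        if not new_edges:
            continue
        # Union-find over the prior parts touched by this step's edges.
        # A part key is ('n', numbered label) or ('v', vertex) for isolated.
        up: dict[tuple[str, object], tuple[str, object]] = {}

        def find(x: tuple[str, object]) -> tuple[str, object]:
            up.setdefault(x, x)
            while up[x] != x:
                up[x] = up[up[x]]
                x = up[x]
            return x

        def part_key(v: str) -> tuple[str, object]:
            comp = part_of.get(v)
            return ("v", v) if comp is None else ("n", comp)

        for a, b in new_edges:
            ra, rb = find(part_key(a)), find(part_key(b))
            if ra != rb:
                up[ra] = rb
        groups: dict[tuple[str, object], set[tuple[str, object]]] = {}
        for x in list(up):
            groups.setdefault(find(x), set()).add(x)
        merged = [parts for parts in groups.values() if len(parts) >= 2]

        def part_members(part: tuple[str, object]) -> frozenset[str]:
            kind, payload = part
            return frozenset([payload]) if kind == "v" else members[payload]  # type: ignore[index]

        merged.sort(key=lambda parts: min(min(part_members(p)) for p in parts))
        for parts in merged:
            label = next_label
            next_label += 1
            numbered = sorted(p[1] for p in parts if p[0] == "n")  # type: ignore[arg-type]
            named = sorted(p[1] for p in parts if p[0] == "v")  # type: ignore[arg-type]
            kids: tuple[Node, ...] = tuple(numbered) + tuple(named)
            union = frozenset().union(*(part_members(p) for p in parts))
            children[label] = kids
            birth_k[label] = k
            members[label] = union
            for child in kids:
                parent[child] = label
            for v in union:
                part_of[v] = label

    return ComponentTree(
        n_subjects=stack.n_subjects,
        n_numbered=next_label - 1,
        parent=parent,
        children=children,
        birth_k=birth_k,
        members=members,
    )


def assign_colors(tree: ComponentTree) -> ComponentTree:
    """Color the tree's nodes according to component lineage.

    Fresh colors are consecutive integers from 1 in node-creation order.
    Recomputes all colors from the structure, so the operation is
    idempotent.  Returns the same tree with ``colors`` filled in.
    """
    colors: dict[Node, int] = {}
    next_color = 1
    for s in tree.numbered_nodes:
        kids = tree.children[s]
        numbered_kids = [c for c in kids if isinstance(c, int)]
        if not numbered_kids:
            colors[s] = next_color  # born purely from isolated vertices
            next_color += 1
        else:
            # largest merged child wins; ties go to the older (smaller) label
            best = max(numbered_kids, key=lambda c: (len(tree.members[c]), -c))
            colors[s] = colors[best]
        for c in kids:
            if isinstance(c, str):
                colors[c] = colors[s]
    tree.colors = colors
    return tree


def tree_to_networkx(tree: ComponentTree) -> nx.DiGraph:
    """Render the tree as a directed graph with child→parent edges.

    Named nodes use the ROI label as node id; numbered node ``s`` uses id
    ``comp<s>``.  Node attributes: ``kind`` (named|numbered), ``label``,
    ``birth_k`` (numbered only) and ``color`` (if assigned).
    """
    g = nx.DiGraph()

    def node_id(n: Node) -> str:
        return f"comp{n}" if isinstance(n, int) else n

    for s in tree.numbered_nodes:
        attrs: dict[str, object] = {
            "kind": "numbered",
            "label": str(s),
            "birth_k": tree.birth_k[s],
        }
        if s in tree.colors:
            attrs["color"] = tree.colors[s]
        g.add_node(node_id(s), **attrs)
    for name in sorted(tree.named_nodes):
        attrs = {"kind": "named", "label": name}
        if name in tree.colors:
            attrs["color"] = tree.colors[name]
        g.add_node(name, **attrs)
    for child, par in sorted(tree.parent.items(), key=lambda cp: (str(cp[0]), cp[1])):
        g.add_edge(node_id(child), node_id(par))
    return g


def write_tree_graphml(tree: ComponentTree, path: Union[str, Path]) -> None:
    """Write the component tree to GraphML (edges point child→parent)."""
    nx.write_graphml(tree_to_networkx(tree), Path(path))
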