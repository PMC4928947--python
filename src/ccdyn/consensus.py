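"""Consensus stacks: per-edge support counts inducing every consensus graph G_k.

Given ``N`` subject braingraphs over a shared vertex set, the support count
``c(e)`` of an edge is the number of subjects whose graph contains it.  The
consensus graph ``G_k`` keeps exactly the edges with ``c(e) >= k``; the
family is nested, ``E(G_{k+1}) ⊆ E(G_k)``, with ``G_1`` the union and
``G_N`` the intersection of the subject edge sets.  Aggregated edge weights
(median by default) are carried along for export but play no role in the
dynamics, tree, or direction logic.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .graph_io import Edge, SubjectGraph

#: Supported per-edge weight aggregation models.
WEIGHT_MODELS = {
    "median": np.median,
    "mean": np.mean,
    "sum": np.sum,
}


@dataclass(frozen=True)
class ConsensusStack:
    """Support-count structure over a population of subject graphs.

    Attributes
    ----------
    n_subjects:
        Number of subjects ``N`` (after any per-subject weight filtering,
        every subject still counts toward ``N``).
    vertices:
        Union of all subjects' vertex labels; isolated vertices are retained
        in every ``G_k``.
    support:
        ``c(e)`` for every edge present in at least one subject; values lie
        in ``[1, N]``.
    agg_weight:
        Aggregated weight of each supported edge.
    """

    n_subjects: int
    vertices: frozenset[str]
    support: Mapping[Edge, int]
    agg_weight: Mapping[Edge, float]

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("a consensus stack needs at least one subject")
        for e, c in self.support.items():
            if not 1 <= c <= self.n_subjects:
                raise ValueError(
                    f"support c({e}) = {c} outside [1, {self.n_subjects}]"
                )

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(self.support)

    def edges_by_support(self) -> dict[int, list[Edge]]:
        """Group edges by support count; each group sorted lexicographically."""
        groups: dict[int, list[Edge]] = defaultdict(list)
        for e, c in self.support.items():
            groups[c].append(e)
        return {c: sorted(es) for c, es in groups.items()}


def build_stack(
    subjects: Sequence[SubjectGraph],
    min_edge_weight: float = 0.0,
    weight_model: str = "median",
) -> ConsensusStack:
    """Count, per edge, how many subjects contain it, and aggregate weights.

    Per-subject edges with weight strictly below ``min_edge_weight`` are
    discarded before counting (the filter acts on each subject's own weight,
    not on the aggregate).  ``weight_model`` is one of ``median`` (default),
    ``mean`` or ``sum``, applied over the weights of the subjects that
    contain the edge.
    """
    if not subjects:
        raise ValueError("at least one subject graph is required")
    try:
        aggregate = WEIGHT_MODELS[weight_model]
    except KeyError:
        raise ValueError(
            f"unknown weight model {weight_model!r}; choose from "
            f"{sorted(WEIGHT_MODELS)}"
        )
    vertices: set[str] = set()
    per_edge_weights: dict[Edge, list[float]] = defaultdict(list)
    for sg in subjects:
        vertices.update(sg.vertices)
        for e, w in sg.weights.items():
            if w >= min_edge_weight:
                per_edge_weights[e].append(w)
    support = {e: len(ws) for e, ws in per_edge_weights.items()}
    agg_weight = {e: float(aggregate(ws)) for e, ws in per_edge_weights.items()}
    return ConsensusStack(
        n_subjects=len(subjects),
        vertices=frozenset(vertices),
        support=support,
        agg_weight=agg_weight,
    )


def graph_at_k(stack: ConsensusStack, k: int) -> nx.Graph:
    """Return the consensus graph ``G_k``: all edges with support >= k.

    The full shared vertex set is retained, so vertices isolated at this
    threshold appear as degree-0 nodes.  Edge attribute ``weight`` carries
    the aggregated weight.
    """
    if not 1 <= k <= stack.n_subjects:
        raise ValueError(
            f"k = {k} outside the valid range [1, {stack.n_subjects}]"
        )
    g = nx.Graph()
    g.add_nodes_from(sorted(stack.vertices))
    for e in sorted(stack.support):
        if stack.support[e] >= k:
            g.add_edge(e[0], e[1], weight=stack.agg_weight[e])
    return g


def confidence_to_k(confidence_pct: float, n_subjects: int) -> int:
    """Map a minimum-edge-confidence percentage to the support threshold k.

    ``k = ceil(confidence_pct / 100 * N)``, clamped to ``[1, N]``.  With 96
    subjects a 26% confidence maps to k = 25 and 100% maps to k = N (the
    intersection graph).  The product is rounded to 9 decimals before taking
    the ceiling so that exactly representable percentages (e.g. 30% of 10)
    are not pushed up by floating-point noise.
    """
    if not 0 < confidence_pct <= 100:
        raise ValueError(
            f"confidence percentage must lie in (0, 100], got {confidence_pct}"
        )
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    k = math.ceil(round(confidence_pct * n_subjects / 100.0, 9))
    return min(max(k, 1), n_subjects)
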