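"""Shared fixtures: random populations and brute-force oracles.

The oracles deliberately avoid the package's sweep machinery: they recount
support and rebuild each consensus graph from the raw subject list, so
agreement with the incremental implementation is a genuine cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ccdyn.consensus import build_stack
from ccdyn.graph_io import Edge, SubjectGraph, canonical_edge


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def make_random_subjects(
    rng: np.random.Generator,
    n_subjects: int,
    n_vertices: int,
    edge_prob: float = 0.12,
) -> list[SubjectGraph]:
    """Independent Bernoulli random subject graphs over a shared label pool."""
    labels = [f"v{i:03d}" for i in range(n_vertices)]
    pairs = list(itertools.combinations(labels, 2))
    subjects = []
    for s in range(n_subjects):
        mask = rng.random(len(pairs)) < edge_prob
        triples = [
            (a, b, float(rng.uniform(0.5, 5.0)))
            for (a, b), keep in zip(pairs, mask)
            if keep
        ]
        subjects.append(SubjectGraph.from_edges(f"s{s:03d}", triples))
    return subjects


def stack_from_counts(counts: dict[tuple[str, str], int], n_subjects: int):
    """Build a stack whose support equals a prescribed count map.

    Subject ``i`` (0-based) contains edge ``e`` iff ``i < counts[e]``, so
    ``c(e) == counts[e]`` by construction.
    """
    subjects = []
    for i in range(n_subjects):
        triples = [
            (a, b, 1.0) for (a, b), c in counts.items() if i < c
        ]
        subjects.append(SubjectGraph.from_edges(f"s{i}", triples))
    return subjects, build_stack(subjects)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def support_bruteforce(subjects: list[SubjectGraph]) -> dict[Edge, int]:
    """Per-edge multiplicity by scanning the subject list edge by edge."""
    all_edges = set()
    for sg in subjects:
        all_edges |= sg.edges
    return {
        e: sum(1 for sg in subjects if e in sg.edges) for e in all_edges
    }


def edges_at_k_bruteforce(subjects: list[SubjectGraph], k: int) -> set[Edge]:
    """Edge set of G_k recomputed from scratch (empty set above N)."""
    return {e for e, c in support_bruteforce(subjects).items() if c >= k}


def degree_in(edges: set[Edge], vertex: str) -> int:
    return sum(1 for e in edges if vertex in e)


def classify_edge_bruteforce(subjects: list[SubjectGraph], edge: Edge) -> tuple[int, str]:
    """(appearance k, endpoint class) for one edge, rebuilt independently."""
    c = sum(1 for sg in subjects if edge in sg.edges)
    prev = edges_at_k_bruteforce(subjects, c + 1)
    a, b = edge
    iso_a = degree_in(prev, a) == 0
    iso_b = degree_in(prev, b) == 0
    if iso_a and iso_b:
        return c, "iso_iso"
    if iso_a or iso_b:
        return c, "iso_conn"
    return c, "conn_conn"


def direct_edge_bruteforce(
    subjects: list[SubjectGraph], edge: Edge
) -> tuple[int, str, tuple[str, str] | None]:
    """Apply the orientation rule to one edge with from-scratch graphs."""
    c, cls = classify_edge_bruteforce(subjects, edge)
    if cls != "iso_conn":
        reason = "isolated_edge" if cls == "iso_iso" else "connected_pair"
        return c, reason, None
    prev = edges_at_k_bruteforce(subjects, c + 1)
    a, b = edge
    if degree_in(prev, a) == 0:
        return c, "directed", (a, b)
    return c, "directed", (b, a)
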