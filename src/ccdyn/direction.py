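"""Edge orientation by the isolated-to-connected attachment rule.

Every edge ``e`` with support ``c`` appears at exactly one sweep transition,
``G_{c+1} → G_c``.  If exactly one endpoint ``v`` was isolated in
``G_{c+1}`` while the other endpoint ``u`` was already connected, the edge
is directed ``v → u`` — the attaching vertex points into the existing
network.  Edges whose endpoints were both isolated ("isolated edges") or
both connected cannot be directed by this rule and are reported with a
reason.  Under the atomic-step semantics each edge is judged once, so no
conflicting orientations can arise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator

from .consensus import ConsensusStack
from .dynamics import CONN_CONN, ISO_CONN, ISO_ISO, ccd_trajectory
from .graph_io import Edge, canonical_edge

REASON_ISOLATED_EDGE = "isolated_edge"
REASON_CONNECTED_PAIR = "connected_pair"


@dataclass(frozen=True)
class DirectedEdge:
    """An oriented edge: ``tail → head``, oriented at threshold ``k``."""

    tail: str
    head: str
    k: int

    @property
    def edge(self) -> Edge:
        return canonical_edge(self.tail, self.head)


@dataclass(frozen=True)
class DirectedEdgeSet:
    """Partition of the union graph's edges into directed and undirectable.

    ``undirectable`` holds ``(edge, k, reason)`` records where ``k`` is the
    transition at which the edge appeared and ``reason`` is
    ``isolated_edge`` (both endpoints previously isolated) or
    ``connected_pair`` (both previously connected).
    """

    n_subjects: int
    directed: tuple[DirectedEdge, ...]
    undirectable: tuple[tuple[Edge, int, str], ...]

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(d.edge for d in self.directed) | frozenset(
            e for e, _, _ in self.undirectable
        )

    @property
    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirectable)


def assign_directions(stack: ConsensusStack) -> DirectedEdgeSet:
    """Orient every orientable edge of the union graph ``G_1``.

    Reuses the sweep classification: an ``iso_conn`` edge at step ``k`` is
    directed from its isolated endpoint to its connected endpoint, with
    degrees judged in ``G_{k+1}`` only.  A vertex attaching with several
    simultaneous edges to previously connected vertices yields several
    directed edges, all tailed at that vertex.
    """
    trajectory = ccd_trajectory(stack)
    degree: Counter[str] = Counter()
    directed: list[DirectedEdge] = []
    undirectable: list[tuple[Edge, int, str]] = []
    for step in trajectory:
        for e in step.new_edges:
            cls = step.class_of[e]
            if cls == ISO_CONN:
                a, b = e
                tail, head = (a, b) if degree[a] == 0 else (b, a)
                directed.append(DirectedEdge(tail=tail, head=head, k=step.k))
            elif cls == ISO_ISO:
                undirectable.append((e, step.k, REASON_ISOLATED_EDGE))
            else:
                undirectable.append((e, step.k, REASON_CONNECTED_PAIR))
        for a, b in step.new_edges:
            degree[a] += 1
            degree[b] += 1
    return DirectedEdgeSet(
        n_subjects=stack.n_subjects,
        directed=tuple(directed),
        undirectable=tuple(undirectable),
    )


@dataclass(frozen=True)
class DirectionSummary:
    """Counts of directed and undirectable edges, overall and per k."""

    counts: dict[str, int]
    per_k: dict[int, dict[str, int]]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def direction_summary(ds: DirectedEdgeSet) -> DirectionSummary:
    """Tally the orientation outcome; counts sum to ``|E(G_1)|``."""
    counts = {"directed": len(ds.directed), REASON_ISOLATED_EDGE: 0, REASON_CONNECTED_PAIR: 0}
    per_k: dict[int, dict[str, int]] = {}

    def bucket(k: int) -> dict[str, int]:
        return per_k.setdefault(
            k, {"directed": 0, REASON_ISOLATED_EDGE: 0, REASON_CONNECTED_PAIR: 0}
        )

    for d in ds.directed:
        bucket(d.k)["directed"] += 1
    for _, k, reason in ds.undirectable:
        counts[reason] += 1
        bucket(k)[reason] += 1
    return DirectionSummary(counts=counts, per_k=per_k)
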