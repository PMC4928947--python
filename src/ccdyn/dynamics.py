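"""The consensus-connectome k-sweep and its isolation statistics.

Decreasing ``k`` from ``N`` to 1 adds, at each step, exactly the edges with
support ``c(e) = k``.  Every new edge is classified by the state of its two
endpoints in the *previous* consensus graph ``G_{k+1}`` (``G_{N+1}`` is the
empty graph):

* ``iso_iso``   — both endpoints were isolated (degree 0) in ``G_{k+1}``;
* ``iso_conn``  — exactly one endpoint was isolated;
* ``conn_conn`` — both endpoints were already connected.

All edges of one step appear atomically, so the classification never
depends on an ordering of edges within the step.  The headline statistic of
the buildup is the running count of ``iso_iso`` edges: a shrub-like growth,
where new edges attach to the existing graph, keeps it far below what
uniform-random edge addition produces.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from .consensus import ConsensusStack
from .graph_io import Edge

ISO_ISO = "iso_iso"
ISO_CONN = "iso_conn"
CONN_CONN = "conn_conn"
EDGE_CLASSES = (ISO_ISO, ISO_CONN, CONN_CONN)

#: Statistics over the per-step classification that can be accumulated.
STATISTICS = ("both_isolated", "any_isolated")


def classify_endpoints(deg_a: int, deg_b: int) -> str:
    """Classify a new edge from its endpoint degrees in the previous graph."""
    if deg_a == 0 and deg_b == 0:
        return ISO_ISO
    if deg_a == 0 or deg_b == 0:
        return ISO_CONN
    return CONN_CONN


@dataclass(frozen=True)
class CCDStep:
    """One step of the sweep: the edges appearing at threshold ``k``."""

    k: int
    new_edges: tuple[Edge, ...]
    class_of: Mapping[Edge, str]

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(self.class_of.values())
        return {cls: c.get(cls, 0) for cls in EDGE_CLASSES}


@dataclass(frozen=True)
class CCDTrajectory:
    """The full sweep, steps ordered ``k = N, N-1, ..., 1``."""

    n_subjects: int
    n_vertices: int
    steps: tuple[CCDStep, ...]

    def __iter__(self) -> Iterator[CCDStep]:
        return iter(self.steps)

    @property
    def step_sizes(self) -> tuple[int, ...]:
        """Number of new edges per step, in sweep order."""
        return tuple(len(s.new_edges) for s in self.steps)

    @property
    def n_edges_total(self) -> int:
        return sum(self.step_sizes)

    def per_step_counts(self, edge_class: str) -> np.ndarray:
        if edge_class not in EDGE_CLASSES:
            raise ValueError(f"unknown edge class {edge_class!r}")
        return np.array([s.counts[edge_class] for s in self.steps], dtype=np.int64)


def ccd_trajectory(stack: ConsensusStack) -> CCDTrajectory:
    """Sweep ``k = N .. 1`` and classify every newly appearing edge.

    Endpoint degrees are tracked incrementally: before processing step ``k``
    they equal the degrees in ``G_{k+1}``; all of the step's edges are
    classified against that snapshot and only then added.
    """
    by_k = stack.edges_by_support()
    degree: Counter[str] = Counter()
    steps: list[CCDStep] = []
    for k in range(stack.n_subjects, 0, -1):
        new_edges = tuple(by_k.get(k, ()))
        class_of = {
            (a, b): classify_endpoints(degree[a], degree[b]) for a, b in new_edges
        }
        for a, b in new_edges:
            degree[a] += 1
            degree[b] += 1
        steps.append(CCDStep(k=k, new_edges=new_edges, class_of=class_of))
    return CCDTrajectory(
        n_subjects=stack.n_subjects,
        n_vertices=len(stack.vertices),
        steps=tuple(steps),
    )


def _per_step_statistic(trajectory: CCDTrajectory, statistic: str) -> np.ndarray:
    if statistic == "both_isolated":
        return trajectory.per_step_counts(ISO_ISO)
    if statistic == "any_isolated":
        return trajectory.per_step_counts(ISO_ISO) + trajectory.per_step_counts(
            ISO_CONN
        )
    raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


def isolation_curve(
    trajectory: CCDTrajectory, statistic: str = "both_isolated"
) -> np.ndarray:
    """Cumulative count of isolation-class new edges per step, as an array.

    ``both_isolated`` (default) accumulates ``iso_iso`` edges; the
    alternative reading ``any_isolated`` accumulates edges with at least one
    previously isolated endpoint.
    """
    return np.cumsum(_per_step_statistic(trajectory, statistic))


def isolation_statistic(
    trajectory: CCDTrajectory, statistic: str = "both_isolated"
) -> list[tuple[int, int]]:
    """The buildup series as ``(step index ℓ, cumulative count)`` pairs.

    Step ``ℓ`` corresponds to threshold ``k = N - ℓ``, for ``ℓ = 0 .. N-1``.
    """
    curve = isolation_curve(trajectory, statistic)
    return [(ell, int(c)) for ell, c in enumerate(curve)]
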