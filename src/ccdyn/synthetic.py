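"""Synthetic braingraph populations with a known growth order.

The generator emulates the hypothesis behind the consensus dynamics: edges
present in more subjects are older.  A ground-truth growth sequence of
edge events is laid down first, then a population of subject graphs is
sampled so that an edge's support count decreases with its age rank, and
the consensus k-sweep replays the growth.  Event kinds:

* ``attach`` — a brand-new vertex ``v`` connects to an existing connected
  vertex ``u``; ground-truth direction ``v → u`` (recoverable by the
  orientation rule);
* ``de_novo_pair`` — two brand-new vertices connect to each other (an
  isolated edge; undirectable);
* ``internal`` — an edge between two already-connected vertices
  (undirectable).

The consensus sweep resolves age only to ``N`` support levels: when the
event count exceeds the subject count, consecutive events share a level and
appear atomically at the same ``k``.  So that the sweep replays the truth
*exactly*, attach and internal events are wired only to vertices connected
in strictly earlier support levels; with at most one event per level this
reduces to "any currently connected vertex".

Vertex labels follow an ROI-like scheme (``lh_region_<i>`` /
``rh_region_<i>``) so that I/O paths and the component tree's named leaves
are exercised realistically.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .direction import (
    REASON_CONNECTED_PAIR,
    REASON_ISOLATED_EDGE,
    DirectedEdgeSet,
)
from .graph_io import Edge, SubjectGraph, canonical_edge

ATTACH = "attach"
DE_NOVO_PAIR = "de_novo_pair"
INTERNAL = "internal"
EVENT_KINDS = (ATTACH, DE_NOVO_PAIR, INTERNAL)


def roi_labels(n_vertices: int) -> list[str]:
    """ROI-style synthetic labels, alternating hemispheres."""
    labels = []
    for i in range(n_vertices):
        side = "lh" if i % 2 == 0 else "rh"
        labels.append(f"{side}_region_{i // 2 + 1:03d}")
    return labels


def nested_thresholds(n_events: int, n_subjects: int) -> list[int]:
    """Evenly spaced age thresholds for nested-mode subjects.

    Subject ``s`` (0-based) contains exactly the edges with age rank below
    ``t_s = ceil((s+1) * n_events / n_subjects)``; the last subject holds
    the full truth graph and the support of the oldest edge is ``N``.
    """
    return [
        math.ceil((s + 1) * n_events / n_subjects) for s in range(n_subjects)
    ]


def support_levels(n_events: int, n_subjects: int) -> list[int]:
    """Support count of each age rank under the nested thresholds."""
    thresholds = nested_thresholds(n_events, n_subjects)
    return [sum(1 for t in thresholds if t > age) for age in range(n_events)]


@dataclass(frozen=True)
class PopulationConfig:
    """Conditions for one synthetic population.

    Defaults are a desk-scale population: 96 subjects over a 200-vertex
    parcellation with 300 growth events, dominated by attachment (0.8
    attach / 0.1 de-novo / 0.1 internal).  ``bernoulli`` mode includes edge
    ``e`` in a subject independently with probability ``p(age)``, linear
    from ``p_max`` down to ``p_min`` over age rank.
    """

    n_subjects: int = 96
    n_vertices: int = 200
    n_events: int = 300
    attach_fraction: float = 0.8
    de_novo_fraction: float = 0.1
    internal_fraction: float = 0.1
    mode: str = "nested"
    p_max: float = 0.95
    p_min: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_vertices < 2 or self.n_events < 1:
            raise ValueError("n_subjects, n_vertices >= 2 and n_events must be positive")
        total = self.attach_fraction + self.de_novo_fraction + self.internal_fraction
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"event-type fractions must sum to 1, got {total}")
        if min(self.attach_fraction, self.de_novo_fraction, self.internal_fraction) < 0:
            raise ValueError("event-type fractions must be nonnegative")
        if self.mode not in ("nested", "bernoulli"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= self.p_min <= self.p_max <= 1:
            raise ValueError("need 0 <= p_min <= p_max <= 1")


@dataclass(frozen=True)
class GrowthEvent:
    """One growth event; for ``attach``, ``source`` is the new vertex (tail)."""

    age: int
    kind: str
    source: str
    target: str

    @property
    def edge(self) -> Edge:
        return canonical_edge(self.source, self.target)


@dataclass(frozen=True)
class GrowthTruth:
    """The ground-truth event sequence, ordered by age rank."""

    events: tuple[GrowthEvent, ...]

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(ev.edge for ev in self.events)

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(v for ev in self.events for v in (ev.source, ev.target))

    def events_by_kind(self, kind: str) -> list[GrowthEvent]:
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        return [ev for ev in self.events if ev.kind == kind]


def generate_growth_truth(config: PopulationConfig) -> GrowthTruth:
    """Generate a seeded, deterministic growth sequence.

    The sequence starts with one de-novo pair.  Attach events pick their
    existing endpoint uniformly among vertices connected in strictly
    earlier support levels; internal events pick a uniformly random absent
    pair among those vertices.  Requested kinds that are infeasible at the
    current state (no fresh vertices left, no prior connected structure, no
    absent pair) fall back along attach → de-novo → internal, so valid
    configurations never fail.
    """
    rng = np.random.default_rng(config.seed)
    levels = support_levels(config.n_events, config.n_subjects)
    labels = roi_labels(config.n_vertices)
    fresh = list(reversed(labels))  # pop() yields labels in order
    connected: set[str] = set()
    edges: set[Edge] = set()
    prev_connected: list[str] = []  # sorted; connected before current level
    current_level: int | None = None
    kinds = np.array(EVENT_KINDS)
    probs = np.array(
        [config.attach_fraction, config.de_novo_fraction, config.internal_fraction]
    )
    events: list[GrowthEvent] = []

    def absent_pair_among_prev() -> Edge | None:
        n = len(prev_connected)
        if n < 2:
            return None
        n_pairs = n * (n - 1) // 2
        n_present = sum(
            1 for e in edges if e[0] in prev_set and e[1] in prev_set
        )
        if n_present >= n_pairs:
            return None
        for _ in range(200):  # rejection sampling; density is low in practice
            i, j = rng.choice(n, size=2, replace=False)
            e = canonical_edge(prev_connected[i], prev_connected[j])
            if e not in edges:
                return e
        for i in range(n):  # deterministic fallback scan
            for j in range(i + 1, n):
                e = canonical_edge(prev_connected[i], prev_connected[j])
                if e not in edges:
                    return e
        return None

    for age in range(config.n_events):
        if levels[age] != current_level:
            current_level = levels[age]
            prev_connected = sorted(connected)
            prev_set = set(prev_connected)
        wanted = DE_NOVO_PAIR if age == 0 else str(rng.choice(kinds, p=probs))
        can_attach = bool(fresh) and bool(prev_connected)
        can_de_novo = len(fresh) >= 2
        # resolve feasibility with the attach → de_novo → internal fallback ring
        order = {
            ATTACH: (ATTACH, DE_NOVO_PAIR, INTERNAL),
            DE_NOVO_PAIR: (DE_NOVO_PAIR, ATTACH, INTERNAL),
            INTERNAL: (INTERNAL, ATTACH, DE_NOVO_PAIR),
        }[wanted]
        event: GrowthEvent | None = None
        for kind in order:
            if kind == ATTACH and can_attach:
                v = fresh.pop()
                u = prev_connected[int(rng.integers(len(prev_connected)))]
                event = GrowthEvent(age=age, kind=ATTACH, source=v, target=u)
                break
            if kind == DE_NOVO_PAIR and can_de_novo:
                v, w = fresh.pop(), fresh.pop()
                event = GrowthEvent(age=age, kind=DE_NOVO_PAIR, source=v, target=w)
                break
            if kind == INTERNAL:
                pair = absent_pair_among_prev()
                if pair is not None:
                    event = GrowthEvent(
                        age=age, kind=INTERNAL, source=pair[0], target=pair[1]
                    )
                    break
        if event is None:
            raise ValueError(
                f"no feasible event at age {age}: vertex pool and prior "
                "structure are exhausted; increase n_vertices or reduce n_events"
            )
        events.append(event)
        edges.add(event.edge)
        connected.update(event.edge)
    return GrowthTruth(events=tuple(events))


def sample_subjects(
    truth: GrowthTruth, config: PopulationConfig
) -> list[SubjectGraph]:
    """Sample a population of subject graphs from the growth truth.

    ``nested`` mode is deterministic: subject ``s`` contains exactly the
    edges with age rank below its threshold, so support is a nonincreasing
    function of age (ties only where thresholds coincide).  ``bernoulli``
    mode includes each edge independently with probability ``p(age)``
    (linear from ``p_max`` to ``p_min``), seeded from ``config.seed``.
    All edge weights are 1.0.
    """
    n_events = len(truth.events)
    subjects: list[SubjectGraph] = []
    if config.mode == "nested":
        for s, t in enumerate(nested_thresholds(n_events, config.n_subjects)):
            triples = [
                (ev.source, ev.target, 1.0) for ev in truth.events[:t]
            ]
            subjects.append(SubjectGraph.from_edges(f"sub-{s + 1:04d}", triples))
    else:
        rng = np.random.default_rng([config.seed, 1])
        if n_events > 1:
            p = config.p_max + (config.p_min - config.p_max) * (
                np.arange(n_events) / (n_events - 1)
            )
        else:
            p = np.array([config.p_max])
        for s in range(config.n_subjects):
            mask = rng.random(n_events) < p
            triples = [
                (ev.source, ev.target, 1.0)
                for ev, keep in zip(truth.events, mask)
                if keep
            ]
            subjects.append(SubjectGraph.from_edges(f"sub-{s + 1:04d}", triples))
    return subjects


def random_subject_population(
    n_subjects: int, n_vertices: int, n_edges: int, seed: int
) -> list[SubjectGraph]:
    """A population of independent uniform random graphs ``G(V, m)``.

    Each subject draws ``n_edges`` distinct unordered pairs uniformly over
    the same ROI-labeled vertex pool — the no-growth-structure control for
    the real-vs-null comparison.
    """
    labels = roi_labels(n_vertices)
    i_idx, j_idx = np.triu_indices(n_vertices, k=1)
    if n_edges > i_idx.size:
        raise ValueError(f"n_edges={n_edges} exceeds {i_idx.size} possible pairs")
    rng = np.random.default_rng([seed, 2])
    subjects = []
    for s in range(n_subjects):
        chosen = rng.choice(i_idx.size, size=n_edges, replace=False)
        triples = [
            (labels[i_idx[c]], labels[j_idx[c]], 1.0) for c in chosen
        ]
        subjects.append(SubjectGraph.from_edges(f"rand-{s + 1:04d}", triples))
    return subjects


@dataclass(frozen=True)
class RecoveryReport:
    """How well the orientation rule recovered the generative growth.

    ``direction_accuracy`` is directed-and-correct over attach edges present
    in the union graph; ``None`` (with ``not_applicable`` set) when the
    truth has no attach edge in the population.  ``status_by_kind`` maps
    each event kind to counts over {directed, isolated_edge,
    connected_pair, absent}.
    """

    n_attach_total: int
    n_attach_present: int
    n_attach_directed: int
    n_attach_correct: int
    direction_accuracy: float | None
    status_by_kind: dict[str, dict[str, int]]

    @property
    def not_applicable(self) -> bool:
        return self.n_attach_present == 0


def recovery_report(ds: DirectedEdgeSet, truth: GrowthTruth) -> RecoveryReport:
    """Score an orientation result against the generative ground truth."""
    truth_edges = {ev.edge: ev for ev in truth.events}
    if not ds.edges <= set(truth_edges):
        extra = sorted(ds.edges - set(truth_edges))[:3]
        raise ValueError(
            f"directed edge set contains edges absent from the growth truth "
            f"(e.g. {extra}); vertex sets or populations are mismatched"
        )
    status: dict[Edge, str] = {e: reason for e, _, reason in ds.undirectable}
    directed_map = {d.edge: d for d in ds.directed}

    status_by_kind = {
        kind: Counter({"directed": 0, REASON_ISOLATED_EDGE: 0,
                       REASON_CONNECTED_PAIR: 0, "absent": 0})
        for kind in EVENT_KINDS
    }
    n_attach_total = n_attach_present = n_attach_directed = n_attach_correct = 0
    for ev in truth.events:
        if ev.kind == ATTACH:
            n_attach_total += 1
        if ev.edge in directed_map:
            status_by_kind[ev.kind]["directed"] += 1
        elif ev.edge in status:
            status_by_kind[ev.kind][status[ev.edge]] += 1
        else:
            status_by_kind[ev.kind]["absent"] += 1
            continue
        if ev.kind == ATTACH:
            n_attach_present += 1
            d = directed_map.get(ev.edge)
            if d is not None:
                n_attach_directed += 1
                if d.tail == ev.source and d.head == ev.target:
                    n_attach_correct += 1
    accuracy = (
        n_attach_correct / n_attach_present if n_attach_present else None
    )
    return RecoveryReport(
        n_attach_total=n_attach_total,
        n_attach_present=n_attach_present,
        n_attach_directed=n_attach_directed,
        n_attach_correct=n_attach_correct,
        direction_accuracy=accuracy,
        status_by_kind={k: dict(v) for k, v in status_by_kind.items()},
    )
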