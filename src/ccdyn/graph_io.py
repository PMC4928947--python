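"""Readers and writers for subject braingraphs and consensus graphs.

A subject braingraph is an undirected, weighted graph whose vertices are
anatomically labeled ROIs (e.g. ``lh_superiorfrontal_11``, ``Brain-Stem``)
and whose edges mark fiber tracts detected between two ROIs.  Two on-disk
dialects are supported:

* CSV edge lists with header ``source,target,weight`` (the ``weight`` column
  may be omitted, in which case every edge gets weight 1.0), UTF-8, LF line
  endings;
* GraphML, with the ROI label as the node id and the weight stored under the
  edge data key ``weight``.

Edges are stored canonically with lexicographically ordered endpoints, so
``(a, b)`` and ``(b, a)`` denote the same connection.  Writers emit records
in sorted order so that output files are byte-identical across runs.

CSV edge lists cannot represent isolated vertices; by convention the vertex
set of a population is the union of all subjects' vertex labels, and a
subject's own vertex set is the set of endpoints it mentions (plus, for
GraphML, any explicitly declared isolated nodes).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import networkx as nx

#: A canonical undirected edge: a pair of ROI labels with ``edge[0] < edge[1]``.
Edge = tuple[str, str]


class GraphParseError(ValueError):
    """A file could not be parsed as a subject graph."""


class GraphValidationError(ValueError):
    """A graph violates a structural invariant (self-loop, duplicate edge, ...)."""


def canonical_edge(u: str, v: str) -> Edge:
    """Return the canonical (lexicographically ordered) form of an edge.

    Raises
    ------
    GraphValidationError
        If ``u == v`` (self-loops are not valid braingraph edges).
    """
    if u == v:
        raise GraphValidationError(f"self-loop at vertex {u!r} is not allowed")
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class SubjectGraph:
    """One subject's undirected weighted braingraph.

    Parameters
    ----------
    subject_id:
        Identifier of the subject (for files, the file stem).
    vertices:
        All ROI labels of this subject, including isolated ones.
    weights:
        Mapping from canonical edge to its nonnegative fiber-derived weight.
        Treat as immutable after construction.
    """

    subject_id: str
    vertices: frozenset[str]
    weights: Mapping[Edge, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), w in self.weights.items():
            if a == b:
                raise GraphValidationError(
                    f"subject {self.subject_id!r}: self-loop at {a!r}"
                )
            if a > b:
                raise GraphValidationError(
                    f"subject {self.subject_id!r}: edge ({a!r}, {b!r}) is not canonical"
                )
            if a not in self.vertices or b not in self.vertices:
                raise GraphValidationError(
                    f"subject {self.subject_id!r}: edge ({a!r}, {b!r}) has an "
                    "endpoint outside the vertex set"
                )
            if w < 0:
                raise GraphValidationError(
                    f"subject {self.subject_id!r}: negative weight on ({a!r}, {b!r})"
                )

    @classmethod
    def from_edges(
        cls,
        subject_id: str,
        edges: Iterable[tuple[str, str, float]],
        extra_vertices: Iterable[str] = (),
    ) -> "SubjectGraph":
        """Build a graph from ``(source, target, weight)`` triples.

        Endpoints are canonicalized; duplicate unordered pairs are an error.
        """
        weights: dict[Edge, float] = {}
        vertices = set(extra_vertices)
        for u, v, w in edges:
            e = canonical_edge(u, v)
            if e in weights:
                raise GraphValidationError(
                    f"subject {subject_id!r}: duplicate edge ({e[0]!r}, {e[1]!r})"
                )
            weights[e] = float(w)
            vertices.update(e)
        return cls(subject_id=subject_id, vertices=frozenset(vertices), weights=weights)

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(self.weights)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubjectGraph):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.vertices == other.vertices
            and dict(self.weights) == dict(other.weights)
        )

    def __hash__(self) -> int:  # weights dict is unhashable; hash the edge set
        return hash((self.subject_id, self.vertices, frozenset(self.weights.items())))


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "graphml"):
            raise ValueError(f"unknown graph format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".graphml":
        return "graphml"
    raise ValueError(f"cannot infer graph format from file name {path.name!r}")


def read_subject_graph(path: Union[str, Path], format: str | None = None) -> SubjectGraph:
    """Read one subject graph from a CSV edge list or a GraphML file.

    The subject id is the file stem.  Malformed rows raise
    :class:`GraphParseError` naming the offending line; self-loops and
    duplicate unordered pairs raise :class:`GraphValidationError`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    return _read_graphml(path)


def _read_csv(path: Path) -> SubjectGraph:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GraphParseError(f"{path}: empty file, expected a header row")
        header = [h.strip() for h in header]
        if header[:2] != ["source", "target"] or len(header) > 3 or (
            len(header) == 3 and header[2] != "weight"
        ):
            raise GraphParseError(
                f"{path}: line 1: expected header 'source,target[,weight]', "
                f"got {','.join(header)!r}"
            )
        has_weight = len(header) == 3
        triples: list[tuple[str, str, float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise GraphParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            u, v = row[0].strip(), row[1].strip()
            if not u or not v:
                raise GraphParseError(f"{path}: line {lineno}: empty vertex label")
            if has_weight:
                try:
                    w = float(row[2])
                except ValueError:
                    raise GraphParseError(
                        f"{path}: line {lineno}: weight {row[2]!r} is not a number"
                    )
            else:
                w = 1.0
            triples.append((u, v, w))
    return SubjectGraph.from_edges(path.stem, triples)


def _read_graphml(path: Path) -> SubjectGraph:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # lxml/expat errors carry little location info
        raise GraphParseError(f"{path}: not valid GraphML: {exc}") from exc
    if g.is_multigraph():
        raise GraphValidationError(f"{path}: parallel edges are not allowed")
    triples = [
        (str(u), str(v), float(data.get("weight", 1.0))) for u, v, data in g.edges(data=True)
    ]
    return SubjectGraph.from_edges(
        path.stem, triples, extra_vertices=(str(n) for n in g.nodes)
    )


GraphLike = Union[SubjectGraph, nx.Graph]


def _as_records(graph: GraphLike) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Normalize a graph to sorted vertices and sorted canonical edge records."""
    if isinstance(graph, SubjectGraph):
        vertices = sorted(graph.vertices)
        records = sorted((a, b, float(w)) for (a, b), w in graph.weights.items())
    else:
        vertices = sorted(str(n) for n in graph.nodes)
        records = sorted(
            (*canonical_edge(str(u), str(v)), float(data.get("weight", 1.0)))
            for u, v, data in graph.edges(data=True)
        )
    return vertices, records


def write_graph(
    graph: GraphLike, path: Union[str, Path], format: str | None = None
) -> None:
    """Write a subject or consensus graph to CSV or GraphML.

    Records are emitted in canonical sorted order, so repeated writes of the
    same graph are byte-identical.  CSV output cannot carry isolated
    vertices; GraphML declares every vertex explicitly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    vertices, records = _as_records(graph)
    if fmt == "csv":
        with open(path, "w", newline="\n", encoding="utf-8") as fh:
            fh.write("source,target,weight\n")
            for a, b, w in records:
                fh.write(f"{a},{b},{repr(w)}\n")
    else:
        g = nx.Graph()
        g.add_nodes_from(vertices)
        for a, b, w in records:
            g.add_edge(a, b, weight=w)
        nx.write_graphml(g, path)


def read_population(
    directory: Union[str, Path], patterns: Sequence[str] = ("*.csv", "*.graphml")
) -> list[SubjectGraph]:
    """Read all subject graphs in a directory, sorted by file name.

    Returns one :class:`SubjectGraph` per matching file; raises
    ``FileNotFoundError`` if no file matches.
    """
    directory = Path(directory)
    files: list[Path] = []
    for pattern in patterns:
        files.extend(directory.glob(pattern))
    files = sorted(set(files))
    if not files:
        raise FileNotFoundError(f"no subject graph files found in {directory}")
    return [read_subject_graph(f) for f in files]
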