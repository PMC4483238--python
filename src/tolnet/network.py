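"""Directed immune interaction networks: representation, I/O, validation, knockout.

The model graph is a fixed, directed, unweighted network whose vertices are
immunological components (cells, cytokines, transport structures) plus one
*source* vertex representing the antigen entering the gut lumen.  An edge
``i -> j`` means component *i* stimulates / produces / transports to *j*;
the adjacency entry ``a_ij`` is 1 when the edge exists and 0 otherwise.

A *knockout* (KO) removes one vertex and every incident edge, mimicking the
genetic ablation of a component.  Vertex identity across a knockout is by
label, never by positional index: downstream flux comparisons re-align KO
results onto the healthy graph's label set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

COMPONENT_CLASSES = ("antigen", "cellular", "molecular")


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


@dataclass(frozen=True)
class Vertex:
    """One immunological component.

    Parameters
    ----------
    id
        1-based contiguous index within its network.
    label
        Unique human-readable name (e.g. ``"CD103+"``, ``"IL-10"``).
    component_class
        One of ``"antigen"``, ``"cellular"``, ``"molecular"``.
    """

    id: int
    label: str
    component_class: str

    def __post_init__(self) -> None:
        if not self.label:
            raise NetworkValidationError("vertex label must be non-empty")
        if self.component_class not in COMPONENT_CLASSES:
            raise NetworkValidationError(
                f"unknown component class {self.component_class!r} for {self.label!r}"
            )


@dataclass
class TopologySummary:
    """Elementary topological description of a network."""

    vertex_count: int
    edge_count: int
    out_degree_distribution: dict[int, int]
    in_degree_distribution: dict[int, int]
    mean_clustering_coefficient: float

    def to_dict(self) -> dict:
        return {
            "vertex_count": self.vertex_count,
            "edge_count": self.edge_count,
            "out_degree_distribution": {str(k): v for k, v in sorted(self.out_degree_distribution.items())},
            "in_degree_distribution": {str(k): v for k, v in sorted(self.in_degree_distribution.items())},
            "mean_clustering_coefficient": self.mean_clustering_coefficient,
        }


@dataclass
class DirectedNetwork:
    """A labelled directed graph with one designated walker source.

    ``vertices`` carry contiguous ids ``1..V``; ``edges`` is a set of ordered
    ``(i, j)`` id pairs.  ``provenance`` records how the instance was built
    (fixture name, generator repairs, ...).
    """

    vertices: list[Vertex]
    edges: set[tuple[int, int]]
    source_id: int
    provenance: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    #: knockouts may disconnect vertices entirely; such graphs are still
    #: walkable (isolated vertices act as never-visited sinks)
    allow_isolated: bool = False

    def __post_init__(self) -> None:
        self.edges = set(map(tuple, self.edges))
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if not self.vertices:
            raise NetworkValidationError("network has zero vertices")
        ids = [v.id for v in self.vertices]
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise NetworkValidationError("vertex ids must form a contiguous 1..V range")
        labels = [v.label for v in self.vertices]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NetworkValidationError(f"duplicate vertex labels: {dupes}")
        if self.source_id not in set(ids):
            raise NetworkValidationError(f"source id {self.source_id} is not a vertex")
        idset = set(ids)
        for i, j in self.edges:
            if i not in idset or j not in idset:
                raise NetworkValidationError(f"edge ({i}, {j}) references unknown vertex")
        # no isolated vertices: the network is connected in the sense that
        # every vertex touches at least one edge
        if not self.allow_isolated:
            touched = {i for e in self.edges for i in e}
            isolated = idset - touched
            if isolated:
                labs = [self.label_of(i) for i in sorted(isolated)]
                raise NetworkValidationError(f"isolated vertices: {labs}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(v.label for v in self.vertices)

    @property
    def source_label(self) -> str:
        return self.label_of(self.source_id)

    def label_of(self, vid: int) -> str:
        try:
            return self.vertices[vid - 1].label
        except IndexError:
            raise KeyError(f"unknown vertex id {vid}") from None

    def id_of(self, label: str) -> int:
        for v in self.vertices:
            if v.label == label:
                return v.id
        raise KeyError(f"unknown vertex label {label!r}")

    def adjacency(self) -> np.ndarray:
        """Binary adjacency matrix ``a_ij`` in vertex-id order (0-based array)."""
        V = self.n_vertices
        a = np.zeros((V, V), dtype=np.int8)
        for i, j in self.edges:
            a[i - 1, j - 1] = 1
        return a

    def out_degree(self, vid: int) -> int:
        """Number of edges leaving ``vid`` (row sum of the adjacency matrix)."""
        if not 1 <= vid <= self.n_vertices:
            raise KeyError(f"unknown vertex id {vid}")
        return sum(1 for (i, _) in self.edges if i == vid)

    def in_degree(self, vid: int) -> int:
        if not 1 <= vid <= self.n_vertices:
            raise KeyError(f"unknown vertex id {vid}")
        return sum(1 for (_, j) in self.edges if j == vid)

    def sinks(self) -> list[int]:
        """Vertex ids with out-degree zero."""
        outs = {i for (i, _) in self.edges}
        return [v.id for v in self.vertices if v.id not in outs]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in COMPONENT_CLASSES}
        for v in self.vertices:
            counts[v.component_class] += 1
        return counts

    # -- mutation -----------------------------------------------------------

    def knockout(self, vertex: int | str) -> "DirectedNetwork":
        """Return a new network with one vertex and its incident edges removed.

        ``vertex`` may be an id or a label; the source vertex cannot be
        knocked out.  Remaining vertices are re-indexed to a contiguous
        ``1..V-1`` range but keep their labels — identity is by label.
        """
        vid = self.id_of(vertex) if isinstance(vertex, str) else vertex
        if not 1 <= vid <= self.n_vertices:
            raise KeyError(f"unknown vertex id {vid}")
        if vid == self.source_id:
            raise ValueError("the source (antigen) vertex cannot be knocked out")
        removed_label = self.label_of(vid)

        keep = [v for v in self.vertices if v.id != vid]
        old_to_new = {v.id: k + 1 for k, v in enumerate(keep)}
        new_vertices = [
            Vertex(id=old_to_new[v.id], label=v.label, component_class=v.component_class)
            for v in keep
        ]
        new_edges = {
            (old_to_new[i], old_to_new[j])
            for (i, j) in self.edges
            if i != vid and j != vid
        }
        return DirectedNetwork(
            vertices=new_vertices,
            edges=new_edges,
            source_id=old_to_new[self.source_id],
            provenance=self.provenance + [f"knockout:{removed_label}"],
            allow_isolated=True,
        )

    # -- conversions --------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for v in self.vertices:
            g.add_node(
                v.id,
                label=v.label,
                component_class=v.component_class,
                is_source=int(v.id == self.source_id),
            )
        g.add_edges_from(self.edges)
        return g


# ---------------------------------------------------------------------------
# I/O: TSV edge list + vertex table, optional GraphML
# ---------------------------------------------------------------------------

def load_network(edge_list, vertex_table) -> DirectedNetwork:
    """Read a network from an edge-list stream/path and a vertex-table stream/path.

    The vertex table is TSV with columns ``id, label, component_class,
    is_source`` (``is_source`` in {0, 1}, exactly one row flagged).  The edge
    list is TSV with two columns ``source_label, target_label``; ``#`` starts
    a comment.  Edges naming labels absent from the vertex table are an error.
    """
    vdf = pd.read_csv(vertex_table, sep="\t", comment="#", dtype={"label": str})
    required = {"id", "label", "component_class", "is_source"}
    if not required.issubset(vdf.columns):
        raise NetworkValidationError(
            f"vertex table must have columns {sorted(required)}, got {list(vdf.columns)}"
        )
    if vdf.empty:
        raise NetworkValidationError("vertex table has zero vertices")
    sources = vdf.loc[vdf["is_source"] == 1, "id"].tolist()
    if len(sources) != 1:
        raise NetworkValidationError(
            f"exactly one vertex must be flagged is_source=1, found {len(sources)}"
        )
    vertices = [
        Vertex(id=int(r.id), label=str(r.label), component_class=str(r.component_class))
        for r in vdf.itertuples()
    ]
    labels = [v.label for v in vertices]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NetworkValidationError(f"duplicate vertex labels: {dupes}")
    label_to_id = {v.label: v.id for v in vertices}

    edf = pd.read_csv(
        edge_list, sep="\t", comment="#", header=None,
        names=["source_label", "target_label"], dtype=str, skip_blank_lines=True,
    )
    edges: set[tuple[int, int]] = set()
    for r in edf.itertuples():
        for lab in (r.source_label, r.target_label):
            if lab not in label_to_id:
                raise NetworkValidationError(f"edge references unknown label {lab!r}")
        edges.add((label_to_id[r.source_label], label_to_id[r.target_label]))
    return DirectedNetwork(vertices=vertices, edges=edges, source_id=int(sources[0]))


def write_network(net: DirectedNetwork, edge_list, vertex_table) -> None:
    """Write TSVs in the exact form :func:`load_network` reads (round-trips)."""
    vdf = pd.DataFrame(
        {
            "id": [v.id for v in net.vertices],
            "label": [v.label for v in net.vertices],
            "component_class": [v.component_class for v in net.vertices],
            "is_source": [int(v.id == net.source_id) for v in net.vertices],
        }
    )
    vdf.to_csv(vertex_table, sep="\t", index=False)
    rows = sorted(net.edges)
    edf = pd.DataFrame(
        {
            "source_label": [net.label_of(i) for i, _ in rows],
            "target_label": [net.label_of(j) for _, j in rows],
        }
    )
    edf.to_csv(edge_list, sep="\t", index=False, header=False)


def load_graphml(path) -> DirectedNetwork:
    """Read a network from GraphML carrying label/component_class/is_source."""
    g = nx.read_graphml(path)
    # GraphML node ids are strings; rebuild contiguous integer ids in stored order
    vertices = []
    mapping = {}
    source_id = None
    for k, (node, data) in enumerate(g.nodes(data=True)):
        vid = k + 1
        mapping[node] = vid
        vertices.append(
            Vertex(id=vid, label=data["label"], component_class=data["component_class"])
        )
        if int(data.get("is_source", 0)):
            source_id = vid
    if source_id is None:
        raise NetworkValidationError("GraphML carries no is_source=1 vertex")
    edges = {(mapping[u], mapping[v]) for u, v in g.edges()}
    return DirectedNetwork(vertices=vertices, edges=edges, source_id=source_id)


def write_graphml(net: DirectedNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def topology_summary(net: DirectedNetwork) -> TopologySummary:
    """Degree distributions and mean clustering coefficient.

    Clustering is computed on the undirected projection of the graph
    (self-loops dropped), the convention under which a fully reciprocal
    triangle scores 1.
    """
    out_counts: dict[int, int] = {}
    in_counts: dict[int, int] = {}
    for v in net.vertices:
        ko = net.out_degree(v.id)
        ki = net.in_degree(v.id)
        out_counts[ko] = out_counts.get(ko, 0) + 1
        in_counts[ki] = in_counts.get(ki, 0) + 1
    und = net.to_networkx().to_undirected()
    und.remove_edges_from(nx.selfloop_edges(und))
    cc = nx.average_clustering(und)
    return TopologySummary(
        vertex_count=net.n_vertices,
        edge_count=len(net.edges),
        out_degree_distribution=out_counts,
        in_degree_distribution=in_counts,
        mean_clustering_coefficient=float(cc),
    )
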