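"""Synthetic networks and closed-form fixtures.

The generator emulates the structural assumptions of the study network —
one source vertex, directed unweighted edges, no isolated vertices, and
(optionally) minimum out-degree 1, reachability of every vertex from the
source, and aperiodicity of the terminal recurrent class.  Constraints are
enforced by deterministic *repair* rather than pure rejection: a random
out-edge is added to any sink, a source edge to any unreachable vertex, and
a self-loop to a periodic terminal class.  Every repair is logged in the
network's ``provenance``.

The closed-form fixtures carry their hand-derived asymptotic flux in
``metadata["stationary"]`` so they can serve as oracles for the analytic and
simulated routes.
"""

from __future__ import annotations

import importlib.resources as resources
import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .markov import build_transition_matrix, recurrent_classes
from .network import DirectedNetwork, Vertex, load_network

FIXTURE_NAMES = (
    "cycle_source",
    "star_source",
    "looped_star",
    "chain_absorbing",
    "oral_tolerance",
)


@dataclass
class GeneratorSpec:
    """Parameters of the random-network generator."""

    V: int
    edge_probability: float = 0.3
    require_source_reach: bool = True
    require_min_out_degree_1: bool = True
    require_aperiodic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.V < 2:
            raise ValueError("V must be >= 2")
        if not 0.0 < self.edge_probability <= 1.0:
            raise ValueError("edge_probability must be in (0, 1]")


def generate_network(spec: GeneratorSpec) -> DirectedNetwork:
    """Random directed network satisfying every enabled constraint.

    Vertex 1 is the source, labelled ``"S"``; the others are ``"v2".."vV"``.
    Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, spec.V)))
    V = spec.V
    provenance = [f"generated:V={V},p={spec.edge_probability},seed={spec.seed}"]

    mask = rng.random((V, V)) < spec.edge_probability
    np.fill_diagonal(mask, False)  # no spontaneous self-loops
    edges = {(i + 1, j + 1) for i, j in zip(*np.nonzero(mask))}

    def out_neighbors(i: int) -> set[int]:
        return {b for (a, b) in edges if a == i}

    if spec.require_min_out_degree_1:
        for i in range(1, V + 1):
            if not out_neighbors(i):
                j = int(rng.integers(1, V + 1))
                while j == i:
                    j = int(rng.integers(1, V + 1))
                edges.add((i, j))
                provenance.append(f"repair:out-edge {i}->{j}")

    if spec.require_source_reach:
        g = nx.DiGraph(list(edges))
        g.add_nodes_from(range(1, V + 1))
        reach = nx.descendants(g, 1) | {1}
        for i in sorted(set(range(1, V + 1)) - reach):
            edges.add((1, i))
            provenance.append(f"repair:source-reach 1->{i}")

    # guard against vertices untouched by any edge (possible at tiny p
    # with the degree constraints off)
    touched = {i for e in edges for i in e}
    for i in sorted(set(range(1, V + 1)) - touched):
        edges.add((1, i))
        provenance.append(f"repair:isolated 1->{i}")

    vertices = [Vertex(1, "S", "antigen")] + [
        Vertex(i, f"v{i}", "cellular") for i in range(2, V + 1)
    ]
    net = DirectedNetwork(vertices=vertices, edges=edges, source_id=1, provenance=provenance)

    if spec.require_aperiodic:
        T = build_transition_matrix(net, "self_loop")
        for cls in recurrent_classes(T):
            sub = nx.DiGraph(
                (a, b) for (a, b) in ((i + 1, j + 1) for i, j in _positive_pairs(T.matrix))
                if a - 1 in cls and b - 1 in cls
            )
            sub.add_nodes_from(i + 1 for i in cls)
            if not nx.is_aperiodic(sub):
                v = cls[0] + 1
                net.edges.add((v, v))
                net.provenance.append(f"repair:self-loop {v}")
    return net


def _positive_pairs(M: np.ndarray):
    i, j = np.nonzero(M > 0)
    return zip(i.tolist(), j.tolist())


def _simple_net(labels, edges, stationary=None, name="") -> DirectedNetwork:
    vertices = [
        Vertex(k + 1, lab, "antigen" if k == 0 else "cellular")
        for k, lab in enumerate(labels)
    ]
    idx = {lab: k + 1 for k, lab in enumerate(labels)}
    net = DirectedNetwork(
        vertices=vertices,
        edges={(idx[a], idx[b]) for a, b in edges},
        source_id=1,
        provenance=[f"fixture:{name}"],
    )
    if stationary is not None:
        net.metadata["stationary"] = dict(zip(labels, stationary))
    return net


def make_fixture(name: str) -> DirectedNetwork:
    """Named test networks with hand-derived asymptotic flux in metadata.

    ``cycle_source``      S->A->B->C->A; periodic cycle, stationary (0, 1/3, 1/3, 1/3).
    ``star_source``       S->A, A->{B,C}, B->A, C->A; period-2 hub, stationary (0, 1/2, 1/4, 1/4).
    ``looped_star``       star_source plus A->A; aperiodic, stationary (0, 3/5, 1/5, 1/5).
    ``chain_absorbing``   S->A->B, B->B; all mass absorbs at B.
    ``oral_tolerance``    the packaged 33-vertex transcription (no closed form).
    """
    if name == "cycle_source":
        return _simple_net(
            ["S", "A", "B", "C"],
            [("S", "A"), ("A", "B"), ("B", "C"), ("C", "A")],
            stationary=[0.0, 1 / 3, 1 / 3, 1 / 3],
            name=name,
        )
    if name == "star_source":
        return _simple_net(
            ["S", "A", "B", "C"],
            [("S", "A"), ("A", "B"), ("A", "C"), ("B", "A"), ("C", "A")],
            stationary=[0.0, 1 / 2, 1 / 4, 1 / 4],
            name=name,
        )
    if name == "looped_star":
        return _simple_net(
            ["S", "A", "B", "C"],
            [("S", "A"), ("A", "A"), ("A", "B"), ("A", "C"), ("B", "A"), ("C", "A")],
            stationary=[0.0, 3 / 5, 1 / 5, 1 / 5],
            name=name,
        )
    if name == "chain_absorbing":
        return _simple_net(
            ["S", "A", "B"],
            [("S", "A"), ("A", "B"), ("B", "B")],
            stationary=[0.0, 0.0, 1.0],
            name=name,
        )
    if name == "oral_tolerance":
        return load_oral_tolerance()
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def load_oral_tolerance() -> DirectedNetwork:
    """Load the packaged oral-tolerance transcription with its manifest."""
    pkg = resources.files("tolnet") / "data"
    with (pkg / "oral_tolerance_manifest.json").open("r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    with (pkg / "oral_tolerance_edges.tsv").open("r", encoding="utf-8") as ef, (
        pkg / "oral_tolerance_vertices.tsv"
    ).open("r", encoding="utf-8") as vf:
        net = load_network(ef, vf)
    net.provenance.append("fixture:oral_tolerance")
    net.metadata["manifest"] = manifest
    return net
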