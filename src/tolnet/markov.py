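"""Markov-chain analytics for the source-injected random walk.

The walk's single-step law is the row-stochastic transition matrix
``t_ij = a_ij / k_i_out`` — a walker on vertex *i* moves to a uniformly
chosen out-neighbour.  Vertices with no out-edges (possible after a
knockout) are handled by a *sink policy*: ``self_loop`` pins the walker in
place (``t_ii = 1``), ``reject`` refuses to build the matrix.

Two analytic routes to the asymptotic flux are provided:

``stationary_flux``
    The unique probability vector ``pi`` with ``pi T = pi``, defined when the
    chain has a single recurrent class.  When additionally no other
    eigenvalue has unit magnitude (Perron–Frobenius applicability), the rows
    of ``T^k`` converge to ``pi``.

``expected_flux_cesaro`` / ``cesaro_limit``
    The time-averaged expected flux of the injection process, which exists
    for *every* chain: ``(1/t) * sum_{k<t} e_src T^k`` and its exact
    ``t -> inf`` limit (absorption probabilities into each recurrent class,
    weighted by the class's internal stationary vector).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .network import DirectedNetwork

SinkPolicy = Literal["self_loop", "reject"]

#: eigenvalue-magnitude tolerance used to count unit-modulus eigenvalues
DEFAULT_TOL = 1e-9


class SinkError(ValueError):
    """A sink vertex was found under the ``reject`` policy."""


class MultipleRecurrentClassesError(ValueError):
    """The chain has more than one recurrent class; ``pi T = pi`` is not unique."""


@dataclass
class TransitionMatrix:
    """Row-stochastic single-step law of the walk, in vertex-id order."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    source_index: int  # 0-based row of the source vertex
    sink_policy: SinkPolicy = "self_loop"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class EigenSpectrum:
    magnitudes: np.ndarray  # sorted non-increasing
    all_real: bool

    def to_dict(self) -> dict:
        return {"magnitudes": self.magnitudes.tolist(), "all_real": self.all_real}


@dataclass
class PerronFrobeniusVerdict:
    applicable: bool
    spectral_gap: float
    unique_recurrent_class: bool
    aperiodic: bool

    def to_dict(self) -> dict:
        return {
            "applicable": self.applicable,
            "spectral_gap": self.spectral_gap,
            "unique_recurrent_class": self.unique_recurrent_class,
            "aperiodic": self.aperiodic,
        }


def build_transition_matrix(
    net: DirectedNetwork, sink_policy: SinkPolicy = "self_loop"
) -> TransitionMatrix:
    """``t_ij = a_ij / k_i_out``; sinks become self-loops or raise."""
    a = net.adjacency().astype(float)
    k_out = a.sum(axis=1)
    sinks = np.flatnonzero(k_out == 0)
    if sinks.size and sink_policy == "reject":
        labs = [net.labels[i] for i in sinks]
        raise SinkError(f"sink vertices present under reject policy: {labs}")
    T = np.zeros_like(a)
    nz = k_out > 0
    T[nz] = a[nz] / k_out[nz, None]
    T[sinks, sinks] = 1.0
    return TransitionMatrix(
        matrix=T,
        labels=net.labels,
        source_index=net.source_id - 1,
        sink_policy=sink_policy,
    )


def eigen_spectrum(T: TransitionMatrix) -> EigenSpectrum:
    """Eigenvalue magnitudes of the transition matrix, sorted descending."""
    vals = np.linalg.eigvals(T.matrix)
    mags = np.sort(np.abs(vals))[::-1]
    return EigenSpectrum(magnitudes=mags, all_real=bool(np.allclose(vals.imag, 0.0)))


# ---------------------------------------------------------------------------
# Chain structure
# ---------------------------------------------------------------------------

def _support_graph(T: TransitionMatrix) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(T.n))
    i, j = np.nonzero(T.matrix > 0)
    g.add_edges_from(zip(i.tolist(), j.tolist()))
    return g


def recurrent_classes(T: TransitionMatrix) -> list[list[int]]:
    """Strongly-connected components with no outgoing probability (0-based)."""
    g = _support_graph(T)
    cond = nx.condensation(g)
    out: list[list[int]] = []
    for c in cond.nodes:
        if cond.out_degree(c) == 0:
            out.append(sorted(cond.nodes[c]["members"]))
    return sorted(out)


def check_perron_frobenius(
    T: TransitionMatrix, tol: float = DEFAULT_TOL
) -> PerronFrobeniusVerdict:
    """Is the eigenvector route valid: exactly one unit-magnitude eigenvalue
    and a single recurrent class?"""
    spec = eigen_spectrum(T)
    n_unit = int(np.sum(spec.magnitudes > 1.0 - tol))
    classes = recurrent_classes(T)
    unique = len(classes) == 1
    if unique:
        sub = _support_graph(T).subgraph(classes[0])
        aperiodic = nx.is_aperiodic(sub)
    else:
        aperiodic = all(
            nx.is_aperiodic(_support_graph(T).subgraph(c)) for c in classes
        )
    gap = float(1.0 - spec.magnitudes[1]) if T.n > 1 else 1.0
    return PerronFrobeniusVerdict(
        applicable=(n_unit == 1 and unique),
        spectral_gap=gap,
        unique_recurrent_class=unique,
        aperiodic=bool(aperiodic),
    )


# ---------------------------------------------------------------------------
# Asymptotic flux
# ---------------------------------------------------------------------------

def _class_stationary(P: np.ndarray, tol: float) -> np.ndarray:
    """Stationary row vector of an irreducible stochastic block.

    Dominant left eigenvector first; if the eigensolver cannot isolate the
    unit eigenvalue (near-periodic spectra), fall back to the balance
    equations ``x (P - I) = 0`` with the normalisation row appended.
    """
    m = P.shape[0]
    if m == 1:
        return np.ones(1)
    vals, vecs = np.linalg.eig(P.T)
    order = np.argsort(-vals.real)
    candidates = [i for i in order if abs(vals[i] - 1.0) < 1e-6]
    if len(candidates) == 1:
        v = vecs[:, candidates[0]].real
        v = np.abs(v)
        s = v.sum()
        if s > tol:
            pi = v / s
            if np.max(np.abs(pi @ P - pi)) < 1e-8:
                return pi
    # linear-system fallback
    A = np.vstack([P.T - np.eye(m), np.ones((1, m))])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def stationary_flux(T: TransitionMatrix, tol: float = DEFAULT_TOL) -> np.ndarray:
    """The unique ``pi`` with ``pi T = pi`` (zero on transient vertices).

    Raises :class:`MultipleRecurrentClassesError` when the chain has more
    than one recurrent class; use :func:`cesaro_limit` there.
    """
    classes = recurrent_classes(T)
    if len(classes) != 1:
        raise MultipleRecurrentClassesError(
            f"{len(classes)} recurrent classes; stationary distribution not unique"
        )
    idx = np.array(classes[0])
    pi = np.zeros(T.n)
    pi[idx] = _class_stationary(T.matrix[np.ix_(idx, idx)], tol)
    return pi


def _cesaro_pair(T: np.ndarray, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(T^t, sum_{k=0}^{t-1} T^k)`` by binary doubling.

    Uses the recursions ``S_{2m} = S_m + T^m S_m`` and
    ``S_{m+1} = S_m + T^m``, so the cost is O(log t) matrix products.
    """
    n = T.shape[0]
    A = T.copy()          # T^1
    S = np.eye(n)         # S_1 = T^0
    At = None
    St = None
    m = t
    while m:
        if m & 1:
            if At is None:
                At, St = A.copy(), S.copy()
            else:
                St = St + At @ S
                At = At @ A
        m >>= 1
        if m:
            S = S + A @ S
            A = A @ A
    return At, St


def expected_flux_cesaro(T: TransitionMatrix, source: int, t: int) -> np.ndarray:
    """Exact expected flux of the injection walk after ``t`` iterations.

    One walker is injected at the source each iteration (after all walkers
    step), so the walker ages present at time ``t`` are ``0..t-1`` and the
    expected flux is ``(1/t) * sum_{k=0}^{t-1} e_src T^k``.  ``source`` is a
    1-based vertex id.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    e = np.zeros(T.n)
    e[source - 1] = 1.0
    _, S = _cesaro_pair(T.matrix, t)
    return (e @ S) / t


def cesaro_limit(T: TransitionMatrix, source: int, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Exact ``t -> inf`` limit of :func:`expected_flux_cesaro`.

    Decompose the state space into transient states and recurrent classes;
    the limit is the absorption probability into each class (from the
    source) times that class's stationary vector.  Equals
    :func:`stationary_flux` whenever a single recurrent class exists.
    """
    classes = recurrent_classes(T)
    n = T.n
    rec = sorted(i for c in classes for i in c)
    rec_set = set(rec)
    trans = [i for i in range(n) if i not in rec_set]
    s = source - 1

    # probability of eventually landing in each recurrent class
    absorb = np.zeros(len(classes))
    if s in rec_set:
        for ci, c in enumerate(classes):
            if s in c:
                absorb[ci] = 1.0
    else:
        Q = T.matrix[np.ix_(trans, trans)]
        # R[:, ci] = one-step probability from transient state into class ci
        R = np.column_stack(
            [T.matrix[np.ix_(trans, c)].sum(axis=1) for c in classes]
        )
        B = np.linalg.solve(np.eye(len(trans)) - Q, R)
        absorb = B[trans.index(s)]

    pi = np.zeros(n)
    for ci, c in enumerate(classes):
        idx = np.array(c)
        pi[idx] = absorb[ci] * _class_stationary(T.matrix[np.ix_(idx, idx)], tol)
    return pi


def eigen_report(T: TransitionMatrix, tol: float = DEFAULT_TOL) -> str:
    """JSON report: eigenvalue magnitudes plus the applicability verdict."""
    spec = eigen_spectrum(T)
    verdict = check_perron_frobenius(T, tol)
    return json.dumps(
        {"spectrum": spec.to_dict(), "perron_frobenius": verdict.to_dict()}, indent=2
    )
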