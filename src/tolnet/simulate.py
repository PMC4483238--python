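"""Monte-Carlo simulation of the source-injected random walk.

Each iteration of one realization does, in this order:

1. every walker already on the network takes one independent step along a
   uniformly chosen out-edge (walkers on sinks stay in place);
2. one new walker spawns on the source (antigen) vertex;
3. occupancy is recorded.

After ``t`` iterations exactly ``t`` walkers are on the network
(``N(t) = t``); the flux vector is occupancy divided by ``N(t)``.  The
production path propagates *occupancy counts* (one multinomial draw per
vertex per step) rather than looping over walkers — distributionally
identical to the walker-by-walker loop, which is kept as
:func:`naive_realization` for cross-checks at small ``t``.

Reproducibility: realization ``r`` of a run seeded with ``s`` uses the
generator ``default_rng(SeedSequence((s, r)))``, so realizations are
independent of execution order and a run is bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .markov import SinkPolicy, build_transition_matrix
from .network import DirectedNetwork

Provenance = Literal["simulated", "cesaro", "stationary"]


@dataclass
class SimulationConfig:
    """Walk parameters.

    ``t`` is the number of iterations (= final walker count), ``L`` the
    number of independent realizations averaged by :func:`mean_flux`.
    Defaults are desk scale; the study scale is ``t = L = 10**4``.
    """

    t: int = 1000
    L: int = 100
    seed: int = 0
    sink_policy: SinkPolicy = "self_loop"
    spawn_order: Literal["step_then_spawn"] = "step_then_spawn"

    def __post_init__(self) -> None:
        if self.t < 1 or self.L < 1:
            raise ValueError("t and L must be >= 1")

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "L": self.L,
            "seed": self.seed,
            "sink_policy": self.sink_policy,
            "spawn_order": self.spawn_order,
        }


@dataclass
class FluxVector:
    """Per-vertex walker density ``f_i`` (sums to 1) on a label index."""

    labels: tuple[str, ...]
    values: np.ndarray
    provenance: str
    t: Optional[int] = None
    stderr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError("flux length does not match label index")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.values.tolist()))

    def value_of(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])

    def reindex(self, labels: tuple[str, ...]) -> "FluxVector":
        """Re-express on a (super)set of labels; missing labels carry flux 0."""
        pos = {l: k for k, l in enumerate(self.labels)}
        vals = np.array([self.values[pos[l]] if l in pos else 0.0 for l in labels])
        err = None
        if self.stderr is not None:
            err = np.array([self.stderr[pos[l]] if l in pos else 0.0 for l in labels])
        return FluxVector(tuple(labels), vals, self.provenance, self.t, err)

    def to_frame(self) -> pd.DataFrame:
        d = {"label": list(self.labels), "flux": self.values}
        if self.stderr is not None:
            d["stderr"] = self.stderr
        return pd.DataFrame(d)

    def write_tsv(self, path, header_meta: dict | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_meta:
                fh.write("# " + json.dumps(header_meta, sort_keys=True) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _realization_rng(seed: int, realization_index: int) -> np.random.Generator:
    """Documented counter scheme: generator ``SeedSequence((seed, r))``."""
    return np.random.default_rng(np.random.SeedSequence((seed, realization_index)))


def run_realization(
    net: DirectedNetwork, config: SimulationConfig, realization_seed: int = 0
) -> FluxVector:
    """One realization of the injected walk; returns the flux at time ``t``.

    ``realization_seed`` is the realization counter ``r`` combined with
    ``config.seed`` as documented in the module docstring.  Identical
    arguments give bitwise-identical output.
    """
    T = build_transition_matrix(net, config.sink_policy).matrix
    rng = _realization_rng(config.seed, realization_seed)
    V = net.n_vertices
    src = net.source_id - 1
    occ = np.zeros(V, dtype=np.int64)
    for _ in range(config.t):
        moving = occ.sum()
        if moving:
            # one multinomial per vertex, batched: draws[i, j] = walkers i -> j
            draws = rng.multinomial(occ, T)
            occ = draws.sum(axis=0)
        occ[src] += 1
    total = occ.sum()
    assert total == config.t, "walker conservation violated"
    return FluxVector(net.labels, occ / total, provenance="simulated", t=config.t)


def naive_realization(
    net: DirectedNetwork, config: SimulationConfig, realization_seed: int = 0
) -> FluxVector:
    """Walker-by-walker reference loop (O(t^2)); oracle for small ``t``."""
    T = build_transition_matrix(net, config.sink_policy).matrix
    rng = _realization_rng(config.seed, realization_seed)
    V = net.n_vertices
    src = net.source_id - 1
    positions: list[int] = []
    for _ in range(config.t):
        for k, pos in enumerate(positions):
            positions[k] = int(rng.choice(V, p=T[pos]))
        positions.append(src)
    occ = np.bincount(np.array(positions, dtype=int), minlength=V)
    return FluxVector(net.labels, occ / len(positions), provenance="simulated", t=config.t)


def mean_flux(net: DirectedNetwork, config: SimulationConfig) -> FluxVector:
    """Average flux over ``L`` realizations, with per-vertex Monte-Carlo
    standard error of the mean."""
    runs = np.empty((config.L, net.n_vertices))
    for r in range(config.L):
        runs[r] = run_realization(net, config, realization_seed=r).values
    mean = runs.mean(axis=0)
    if config.L > 1:
        stderr = runs.std(axis=0, ddof=1) / np.sqrt(config.L)
    else:
        stderr = np.zeros(net.n_vertices)
    return FluxVector(net.labels, mean, provenance="simulated", t=config.t, stderr=stderr)
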