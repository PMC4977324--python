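"""Exact posterior inference on a trained network.

``posterior_marginal`` runs variable elimination with a greedy min-fill
ordering; a fresh elimination state is constructed on every call, so no
evidence from a previous query can leak into the next (entering evidence
into an already-conditioned engine is a classic source of silently wrong
posteriors). ``brute_force_marginal`` is a deliberately independent code
path that materializes the full joint by array broadcasting and sums it;
it is the oracle the fast path is verified against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .parameters import TrainedNetwork

__all__ = [
    "Evidence",
    "PosteriorDistribution",
    "ImpossibleEvidenceError",
    "posterior_marginal",
    "brute_force_marginal",
    "engine_build_count",
]

#: Evidence is a mapping node-name -> observed state index (1 or 2).
Evidence = Mapping[str, int]

# Instrumentation: number of elimination states ever built. Experiment code
# asserts this advances once per query, i.e. engines are never reused.
_engine_builds = 0


def engine_build_count() -> int:
    return _engine_builds


class ImpossibleEvidenceError(ValueError):
    """The entered evidence has probability zero under the network."""


@dataclass(frozen=True)
class PosteriorDistribution:
    node: str
    probs: tuple[float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (2,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"invalid posterior for {self.node!r}: {self.probs}")

    def prob(self, state: int) -> float:
        return self.probs[state - 1]


def _validate_query(network: TrainedNetwork, evidence: Evidence, node: str) -> None:
    topo = network.topology
    if node not in topo:
        raise KeyError(f"unknown query node {node!r}")
    for n, s in evidence.items():
        if n not in topo:
            raise KeyError(f"evidence names unknown node {n!r}")
        if s not in (1, 2):
            raise ValueError(f"evidence state for {n!r} must be 1 or 2, got {s!r}")


def _cpt_factor(network: TrainedNetwork, name: str) -> tuple[tuple[str, ...], np.ndarray]:
    """A CPT as (variables, array); axes ordered (parents..., child)."""
    ct = network.table(name)
    k = len(ct.parents)
    # The column index encodes parents with the first-listed varying
    # fastest, so a column-major reshape recovers one axis per parent.
    arr = ct.probs.T.reshape((2,) * k + (2,), order="F")
    return ct.parents + (name,), arr


def _reduce(variables: tuple[str, ...], arr: np.ndarray, evidence: Evidence):
    keep = []
    index: list = []
    for v in variables:
        if v in evidence:
            index.append(evidence[v] - 1)
        else:
            index.append(slice(None))
            keep.append(v)
    return tuple(keep), arr[tuple(index)]


def _product(factors):
    """Multiply factors given as (vars, array) with broadcasting."""
    all_vars: list[str] = []
    for vs, _ in factors:
        for v in vs:
            if v not in all_vars:
                all_vars.append(v)
    out = np.ones((2,) * len(all_vars))
    for vs, arr in factors:
        order = [all_vars.index(v) for v in vs]
        arr_t = np.transpose(arr, np.argsort(order))  # axes into global order
        shape = [1] * len(all_vars)
        for pos in order:
            shape[pos] = 2
        out = out * arr_t.reshape(shape)
    return tuple(all_vars), out


def posterior_marginal(
    network: TrainedNetwork, evidence: Evidence, node: str
) -> PosteriorDistribution:
    """Exact Pr(node | evidence) by variable elimination (min-fill order)."""
    global _engine_builds
    _validate_query(network, evidence, node)
    _engine_builds += 1

    factors = []
    for name in network.topology.node_names:
        vs, arr = _reduce(*_cpt_factor(network, name), evidence)
        factors.append((vs, arr))

    hidden = [
        n
        for n in network.topology.node_names
        if n != node and n not in evidence
    ]
    # Greedy min-fill elimination ordering over the interaction graph.
    neighbors: dict[str, set[str]] = {n: set() for n in hidden + [node]}
    for vs, _ in factors:
        free = [v for v in vs if v in neighbors]
        for v in free:
            neighbors[v].update(u for u in free if u != v)
    order: list[str] = []
    remaining = set(hidden)
    while remaining:
        def fill_cost(v: str) -> tuple[int, str]:
            nb = [u for u in neighbors[v] if u in remaining or u == node]
            missing = sum(
                1
                for i, u in enumerate(nb)
                for w in nb[i + 1 :]
                if w not in neighbors[u]
            )
            return (missing, v)  # deterministic tie-break by name

        v = min(remaining, key=fill_cost)
        remaining.discard(v)
        nb = {u for u in neighbors[v] if u in remaining or u == node}
        for u in nb:
            neighbors[u].update(w for w in nb if w != u)
            neighbors[u].discard(v)
        order.append(v)

    for v in order:
        involved = [f for f in factors if v in f[0]]
        rest = [f for f in factors if v not in f[0]]
        vs, arr = _product(involved)
        arr = arr.sum(axis=vs.index(v))
        vs = tuple(u for u in vs if u != v)
        rest.append((vs, arr))
        factors = rest

    vs, arr = _product(factors)
    if vs == ():
        # node itself was part of the evidence: degenerate posterior
        z = float(arr)
        if z <= 0:
            raise ImpossibleEvidenceError("evidence has zero probability")
        probs = np.zeros(2)
        probs[evidence[node] - 1] = 1.0
        return PosteriorDistribution(node=node, probs=tuple(probs))
    marginal = arr if vs == (node,) else np.transpose(arr, [vs.index(node)])
    z = marginal.sum()
    if z <= 0 or not np.isfinite(z):
        raise ImpossibleEvidenceError("evidence has zero probability under the network")
    probs = marginal / z
    return PosteriorDistribution(node=node, probs=(float(probs[0]), float(probs[1])))


def brute_force_marginal(
    network: TrainedNetwork,
    evidence: Evidence,
    node: str,
    max_nodes: int = 24,
) -> PosteriorDistribution:
    """Marginal by summing the fully enumerated joint distribution.

    Independent of the elimination path: the joint is materialized as a
    dense (2, ..., 2) array, evidence applied by slicing, and all other
    axes summed out. Refuses networks above ``max_nodes``.
    """
    _validate_query(network, evidence, node)
    names = network.topology.node_names
    n = len(names)
    if n > max_nodes:
        raise ValueError(f"brute force refused: {n} nodes exceeds the {max_nodes}-node guard")
    axis = {name: i for i, name in enumerate(names)}

    joint = np.ones((2,) * n)
    for name in names:
        ct = network.table(name)
        arr = ct.probs.T.reshape((2,) * len(ct.parents) + (2,), order="F")
        shape = [1] * n
        perm = np.argsort([axis[v] for v in ct.parents + (name,)])
        arr = np.transpose(arr, perm)
        for v in ct.parents + (name,):
            shape[axis[v]] = 2
        joint = joint * arr.reshape(shape)

    index = tuple(
        evidence[name] - 1 if name in evidence else slice(None) for name in names
    )
    sub = joint[index]
    kept = [name for name in names if name not in evidence]
    if node in evidence:
        z = float(sub.sum())
        if z <= 0:
            raise ImpossibleEvidenceError("evidence has zero probability")
        probs = np.zeros(2)
        probs[evidence[node] - 1] = 1.0
        return PosteriorDistribution(node=node, probs=tuple(probs))
    marginal = sub.sum(axis=tuple(i for i, name in enumerate(kept) if name != node))
    z = marginal.sum()
    if z <= 0:
        raise ImpossibleEvidenceError("evidence has zero probability under the network")
    probs = marginal / z
    return PosteriorDistribution(node=node, probs=(float(probs[0]), float(probs[1])))
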