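"""Model topologies for the Wnt-pathway Bayesian networks.

Three fixed directed acyclic graphs are analysed:

``t1``
    Full model with prior biological knowledge and epigenetic information:
    18 gene nodes, 9 promoter-methylation nodes, 2 histone-mark nodes for
    DACT3, the beta-catenin/TCF4/LEF1 transcription complex (``TRCMPLX``)
    with its constituents, a latent tissue-status node ``Sample``, and the
    DVL2 concentration node (34 nodes).
``t2``
    ``t1`` with every methylation and histone node (and the arcs leaving
    them) removed (23 nodes).
``p1``
    Naive-Bayes variant: every gene's sole parent is ``TRCMPLX``, which is
    itself driven by ``BETACAT`` and ``TCF4``; there is no ``Sample`` node
    (21 nodes).

Every node is binary. State index 1 is the "low/off" pole (normal,
inactive, low concentration, non-methylated) and state index 2 the
"high/on" pole. Parent-list order is significant: it fixes the column
ordering of conditional probability tables (first-listed parent varies
fastest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx

__all__ = [
    "NodeSpec",
    "ModelTopology",
    "TopologyOptions",
    "build_topology",
    "enumerate_simple_paths",
    "is_d_separated",
    "GENE_NODES",
    "METHYLATION_NODES",
    "HISTONE_NODES",
    "VARIANTS",
]

VARIANTS = ("t1", "t2", "p1")

#: The 18 measured genes, in canonical order (two DKK3 probes are recorded).
GENE_NODES: tuple[str, ...] = (
    "DKK1",
    "DKK2",
    "DKK3-1",
    "DKK3-2",
    "DKK4",
    "DACT1",
    "DACT2",
    "DACT3",
    "SFRP1",
    "SFRP2",
    "SFRP3",
    "SFRP4",
    "SFRP5",
    "WIF1",
    "MYC",
    "CD44",
    "CCND1",
    "LEF1",
)

METHYLATION_NODES: tuple[str, ...] = (
    "MeDACT1",
    "MeDACT2",
    "MeSFRP1",
    "MeSFRP2",
    "MeSFRP4",
    "MeSFRP5",
    "MeDKK1",
    "MeDKK4",
    "MeWIF1",
)

HISTONE_NODES: tuple[str, ...] = ("H3K27me3", "H3K4me3")

_STATES = {
    "gene": ("ia", "a"),
    "methylation": ("nm", "m"),
    "histone": ("ia", "a"),
    "complex": ("ia", "a"),
    "concentration": ("lc", "hc"),
    "sample": ("n", "t"),
}


@dataclass(frozen=True)
class NodeSpec:
    """A binary node: name, category, state labels and ordered parents."""

    name: str
    category: str
    states: tuple[str, str]
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in _STATES:
            raise ValueError(f"unknown node category {self.category!r}")
        if len(self.states) != 2:
            raise ValueError(f"node {self.name!r} must have exactly 2 states")


@dataclass(frozen=True)
class TopologyOptions:
    """Structural toggles.

    ``include_me_dkk4``: the printed parent list for DKK4 is
    {Sample, TRCMPLX}; the surrounding text groups DKK4 with the
    methylation-regulated genes. The default follows the printed table;
    setting this flag adds the MeDKK4 -> DKK4 arc.
    """

    include_me_dkk4: bool = False


def _node(name: str, category: str, parents: Sequence[str] = ()) -> NodeSpec:
    return NodeSpec(name, category, _STATES[category], tuple(parents))


# Parent lists for the full model, exactly as printed (gene tables) with the
# transcription-machinery nodes alongside. DACT3's parents are ordered as its
# conditional table is laid out: (H3K27me3, H3K4me3, Sample).
_T1_GENE_PARENTS: dict[str, tuple[str, ...]] = {
    "DKK1": ("Sample", "MeDKK1", "TRCMPLX"),
    "DKK2": ("Sample",),
    "DKK3-1": ("Sample",),
    "DKK3-2": ("Sample",),
    "DKK4": ("Sample", "TRCMPLX"),
    "DACT1": ("Sample", "MeDACT1"),
    "DACT2": ("Sample", "MeDACT2"),
    "DACT3": ("H3K27me3", "H3K4me3", "Sample"),
    "SFRP1": ("Sample", "MeSFRP1", "TRCMPLX"),
    "SFRP2": ("Sample", "MeSFRP2"),
    "SFRP3": ("Sample",),
    "SFRP4": ("Sample", "MeSFRP4"),
    "SFRP5": ("Sample", "MeSFRP5"),
    "WIF1": ("Sample", "MeWIF1", "TRCMPLX"),
    "MYC": ("Sample", "TRCMPLX"),
    "CD44": ("Sample", "TRCMPLX"),
    "CCND1": ("Sample", "TRCMPLX"),
    "LEF1": ("Sample",),
}


@dataclass(frozen=True)
class ModelTopology:
    """A model variant's DAG: typed binary nodes plus derived edges."""

    variant: str
    nodes: tuple[NodeSpec, ...]
    options: TopologyOptions = field(default_factory=TopologyOptions)

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate node names in topology")
        known = set(names)
        for n in self.nodes:
            missing = [p for p in n.parents if p not in known]
            if missing:
                raise ValueError(f"node {n.name!r} has unknown parents {missing}")
        if not nx.is_directed_acyclic_graph(self.to_digraph()):
            raise ValueError("topology is not acyclic")

    # -- containers -------------------------------------------------------
    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            (p, n.name) for n in self.nodes for p in n.parents
        )

    def spec(self, name: str) -> NodeSpec:
        try:
            return next(n for n in self.nodes if n.name == name)
        except StopIteration:
            raise KeyError(f"unknown node {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return any(n.name == name for n in self.nodes)

    def __iter__(self) -> Iterator[NodeSpec]:
        return iter(self.nodes)

    def nodes_of_category(self, category: str) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.category == category)

    @property
    def gene_nodes(self) -> tuple[str, ...]:
        return self.nodes_of_category("gene")

    @property
    def methylation_nodes(self) -> tuple[str, ...]:
        return self.nodes_of_category("methylation")

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(n.name for n in self.nodes)
        g.add_edges_from((p, n.name) for n in self.nodes for p in n.parents)
        return g

    def skeleton(self) -> nx.Graph:
        """Undirected skeleton (path enumeration ignores arc direction)."""
        return self.to_digraph().to_undirected()

    def topological_order(self) -> tuple[str, ...]:
        # Deterministic: ties broken by the declared node order.
        index = {n.name: i for i, n in enumerate(self.nodes)}
        return tuple(
            nx.lexicographical_topological_sort(
                self.to_digraph(), key=lambda v: index[v]
            )
        )


def build_topology(
    variant: str, options: TopologyOptions | None = None
) -> ModelTopology:
    """Construct the DAG of one model variant.

    Raises ``ValueError`` for an unknown variant name.
    """
    options = options or TopologyOptions()
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown model variant {variant!r}; expected one of {VARIANTS}"
        )

    nodes: list[NodeSpec] = []
    if variant in ("t1", "t2"):
        nodes.append(_node("Sample", "sample"))
        nodes.append(_node("TCF4", "complex"))
        if variant == "t1":
            nodes.extend(_node(m, "methylation") for m in METHYLATION_NODES)
            nodes.extend(_node(h, "histone") for h in HISTONE_NODES)
        for gene in GENE_NODES:
            parents = _T1_GENE_PARENTS[gene]
            if variant == "t1" and gene == "DKK4" and options.include_me_dkk4:
                parents = ("Sample", "MeDKK4", "TRCMPLX")
            if variant == "t2":
                # Strip epigenetic parents; DKK1 keeps (Sample, TRCMPLX),
                # DACT3 collapses to (Sample,).
                parents = tuple(
                    p
                    for p in parents
                    if p not in METHYLATION_NODES and p not in HISTONE_NODES
                )
            nodes.append(_node(gene, "gene", parents))
        nodes.append(_node("DVL2", "concentration", ("DACT3",)))
        nodes.append(_node("BETACAT", "concentration", ("DACT1", "DVL2")))
        nodes.append(_node("TRCMPLX", "complex", ("TCF4", "LEF1", "BETACAT")))
    else:  # p1
        nodes.append(_node("BETACAT", "concentration"))
        nodes.append(_node("TCF4", "complex"))
        nodes.append(_node("TRCMPLX", "complex", ("BETACAT", "TCF4")))
        nodes.extend(_node(g, "gene", ("TRCMPLX",)) for g in GENE_NODES)
    return ModelTopology(variant=variant, nodes=tuple(nodes), options=options)


def enumerate_simple_paths(
    topology: ModelTopology, a: str, b: str
) -> list[list[str]]:
    """All simple paths between ``a`` and ``b`` on the undirected skeleton.

    Returned in lexicographic order of the node sequences.
    """
    for name in (a, b):
        if name not in topology:
            raise KeyError(f"unknown node {name!r}")
    if a == b:
        raise ValueError("endpoints must be distinct")
    paths = [list(p) for p in nx.all_simple_paths(topology.skeleton(), a, b)]
    return sorted(paths)


def is_d_separated(
    topology: ModelTopology,
    x: str,
    y: str,
    observed: Iterable[str] = (),
) -> bool:
    """Decide whether ``x`` and ``y`` are d-separated given ``observed``.

    Uses an active-trail (Bayes-ball style) reachability pass over the DAG:
    a path is blocked at a chain or fork node that is observed, and at a
    collider whose descendants (itself included) are all unobserved.
    """
    observed = set(observed)
    for name in (x, y, *observed):
        if name not in topology:
            raise KeyError(f"unknown node {name!r}")
    if x == y:
        raise ValueError("x and y must be distinct")
    if x in observed or y in observed:
        raise ValueError("query nodes may not be part of the observed set")

    g = topology.to_digraph()
    # Nodes with an observed descendant (or observed themselves): a collider
    # on a path unblocks exactly when it belongs to this set.
    obs_or_anc: set[str] = set(observed)
    for z in observed:
        obs_or_anc.update(nx.ancestors(g, z))

    # Reachability over (node, direction) states; direction "up" = arrived
    # from a child (travelling against arcs), "down" = arrived from a parent.
    start = [(x, "up"), (x, "down")]
    visited: set[tuple[str, str]] = set()
    frontier = list(start)
    while frontier:
        node, direction = frontier.pop()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node == y and node not in observed:
            return False  # active trail found -> d-connected
        if direction == "up":
            if node not in observed:
                # continue upward to parents, or turn downward to children
                frontier.extend((p, "up") for p in g.predecessors(node))
                frontier.extend((c, "down") for c in g.successors(node))
        else:  # arrived from a parent
            if node not in observed:
                # chain: keep descending
                frontier.extend((c, "down") for c in g.successors(node))
            if node in obs_or_anc:
                # collider opened by observation (of node or a descendant)
                frontier.extend((p, "up") for p in g.predecessors(node))
    return True
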