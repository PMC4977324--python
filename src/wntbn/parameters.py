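"""Fixed parameters, training configuration and the trained-network container.

The non-gene nodes of the networks carry fixed priors/CPTs taken from
normalized wet-lab measurements or expert assumption (methylation and
histone priors, DVL2 given DACT3, beta-catenin given DACT1 and DVL2, the
transcription-complex AND-gate, the 50/50 tissue prior). These ship as a
packaged JSON file and are applied verbatim; only gene-node tables are
estimated from training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

from .tables import ConditionalTable
from .topology import ModelTopology, TopologyOptions, build_topology

__all__ = [
    "DiscretizationModel",
    "TrainingConfig",
    "TrainedNetwork",
    "load_reference_parameters",
    "fixed_priors",
    "reference_network",
]


@dataclass(frozen=True)
class DiscretizationModel:
    """Per-gene expression thresholds (the training medians)."""

    thresholds: Mapping[str, float]

    def __post_init__(self) -> None:
        for g, t in self.thresholds.items():
            if not np.isfinite(t):
                raise ValueError(f"non-finite threshold for gene {g!r}")

    def threshold(self, gene: str) -> float:
        try:
            return self.thresholds[gene]
        except KeyError:
            raise KeyError(f"no discretization threshold for gene {gene!r}") from None


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of gene-CPT estimation.

    ``etgn`` is the assumed effect of the transcription complex on its
    target genes (the probability weight applied when the complex is on,
    i.e. 1 - p); the published sweep varies it over {0.5, ..., 0.9} and the
    headline setting is 0.9. ``smoothing_on`` selects whether the +1
    pseudo-count is added to the fraction-valued table (as the source
    prose states) or to count-scale entries (sensitivity switch).
    """

    etgn: float = 0.9
    smoothing_constant: float = 1.0
    smoothing_on: str = "fractions"
    fixed_priors: Mapping[str, ConditionalTable] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.etgn < 1.0:
            raise ValueError("etgn must lie strictly in (0, 1)")
        if self.smoothing_constant <= 0:
            raise ValueError("smoothing constant must be positive")
        if self.smoothing_on not in ("fractions", "counts"):
            raise ValueError("smoothing_on must be 'fractions' or 'counts'")

    @property
    def p(self) -> float:
        """Weight applied when the complex is off (1 - etgn)."""
        return 1.0 - self.etgn

    def with_etgn(self, etgn: float) -> "TrainingConfig":
        return replace(self, etgn=etgn)


@dataclass(frozen=True)
class TrainedNetwork:
    """Topology + full parameter set + per-gene discretization thresholds."""

    topology: ModelTopology
    parameters: Mapping[str, ConditionalTable]
    discretization: DiscretizationModel | None = None

    def __post_init__(self) -> None:
        for node in self.topology:
            ct = self.parameters.get(node.name)
            if ct is None:
                raise ValueError(f"no conditional table for node {node.name!r}")
            if ct.parents != node.parents:
                raise ValueError(
                    f"table parents {ct.parents} for {node.name!r} do not match "
                    f"topology parents {node.parents}"
                )
        extra = set(self.parameters) - set(self.topology.node_names)
        if extra:
            raise ValueError(f"tables for unknown nodes: {sorted(extra)}")

    def table(self, node: str) -> ConditionalTable:
        return self.parameters[node]


def _table_from_json(name: str, entry: dict, normalize: bool) -> ConditionalTable:
    probs = np.asarray(entry["probs"], dtype=float)
    if normalize:
        probs = probs / probs.sum(axis=0, keepdims=True)
    return ConditionalTable(node=name, parents=tuple(entry["parents"]), probs=probs)


def load_reference_parameters(normalize: bool = True) -> dict[str, dict[str, ConditionalTable]]:
    """Load the packaged parameter file.

    ``normalize`` renormalizes each column; the printed tables carry
    two-decimal rounding so a few columns sum to 0.99 or 1.01 verbatim.
    """
    text = resources.files("wntbn.data").joinpath("reference_parameters.json").read_text()
    raw = json.loads(text)
    out: dict[str, dict[str, ConditionalTable]] = {}
    for section in ("fixed", "genes", "p1_fixed"):
        out[section] = {
            name: _table_from_json(name, entry, normalize)
            for name, entry in raw[section].items()
        }
    return out


def fixed_priors(variant: str) -> dict[str, ConditionalTable]:
    """Fixed (non-estimated) tables for a model variant."""
    params = load_reference_parameters()
    if variant == "t1":
        return dict(params["fixed"])
    if variant == "t2":
        keep = ("Sample", "TCF4", "DVL2", "BETACAT", "TRCMPLX")
        return {k: params["fixed"][k] for k in keep}
    if variant == "p1":
        return dict(params["p1_fixed"])
    raise ValueError(f"unknown model variant {variant!r}")


def reference_network(
    include_me_dkk4: bool = False, normalize: bool = True
) -> TrainedNetwork:
    """The full (t1) network parameterized with the printed tables.

    This is the generating model of the synthetic-cohort module and the
    substrate of the worked inference examples. Only t1 has a complete
    printed parameter set.
    """
    params = load_reference_parameters(normalize=normalize)
    topo = build_topology("t1", TopologyOptions(include_me_dkk4=include_me_dkk4))
    tables = dict(params["fixed"])
    tables.update(params["genes"])
    if include_me_dkk4:
        # The printed DKK4 table has no methylation dimension; replicate it
        # across both MeDKK4 states so the optional edge stays value-neutral.
        dkk4 = tables["DKK4"]
        probs = np.empty((2, 8))
        # column order (Sample, MeDKK4, TRCMPLX), Sample fastest
        for tr in (0, 1):
            for me in (0, 1):
                for s in (0, 1):
                    probs[:, s + 2 * me + 4 * tr] = dkk4.probs[:, s + 2 * tr]
        tables["DKK4"] = ConditionalTable(
            "DKK4", ("Sample", "MeDKK4", "TRCMPLX"), probs
        )
    return TrainedNetwork(topology=topo, parameters=tables)
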