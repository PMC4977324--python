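"""Exhaustive 2-holdout (leave-pair-out) experiment.

Every normal sample is paired with every tumor sample; the pair is held
out for testing and the network is retrained on the remaining samples, so
every training fold stays balanced up to one sample per class. For each
test sample, evidence is entered (all gene states in ``ge`` mode, or a
methylation configuration in ``me`` mode) and the posteriors of the
transcription complex being active and — in the models that carry it — of
the sample being tumorous are recorded. A fresh inference state is built
per query; stale evidence can never carry over between test cases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import inference
from .estimation import discretize, train_network
from .parameters import (
    DiscretizationModel,
    TrainedNetwork,
    TrainingConfig,
    fixed_priors,
)
from .synthetic import ExpressionDataset
from .topology import ModelTopology, TopologyOptions, build_topology

__all__ = [
    "SplitPlan",
    "HoldoutIteration",
    "HoldoutResult",
    "generate_pairs",
    "build_ge_evidence",
    "run_ge_experiment",
    "run_me_experiment",
    "methylation_configurations",
]


@dataclass(frozen=True)
class HoldoutIteration:
    normal_index: int
    tumor_index: int
    training_indices: tuple[int, ...]


@dataclass(frozen=True)
class SplitPlan:
    iterations: tuple[HoldoutIteration, ...]

    def __len__(self) -> int:
        return len(self.iterations)

    def __iter__(self):
        return iter(self.iterations)


@dataclass(frozen=True)
class HoldoutResult:
    """Posteriors for one test sample of one holdout iteration."""

    iteration: int
    normal_index: int
    tumor_index: int
    sample_index: int
    true_label: int
    p_trcmplx: float
    p_sample: float | None
    evidence: dict = field(default_factory=dict)
    me_config: tuple[int, ...] | None = None


def generate_pairs(labels: Sequence[int]) -> SplitPlan:
    """All (normal, tumor) index pairs, normal outer / tumor inner, each
    with the complementary training fold."""
    y = np.asarray(labels, dtype=int)
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("labels must be -1 or +1")
    normal_idx = np.flatnonzero(y < 0)
    tumor_idx = np.flatnonzero(y > 0)
    if normal_idx.size == 0 or tumor_idx.size == 0:
        raise ValueError("both classes must be present to form test pairs")
    all_idx = np.arange(y.size)
    iterations = []
    for i in normal_idx:
        for j in tumor_idx:
            train = tuple(int(k) for k in all_idx if k != i and k != j)
            iterations.append(
                HoldoutIteration(
                    normal_index=int(i), tumor_index=int(j), training_indices=train
                )
            )
    return SplitPlan(iterations=tuple(iterations))


def build_ge_evidence(
    test_values: dict[str, float],
    discretization: DiscretizationModel,
    topology: ModelTopology,
) -> dict[str, int]:
    """Median-threshold evidence over every gene node (and nothing else)."""
    evidence: dict[str, int] = {}
    for gene in topology.gene_nodes:
        if gene not in test_values:
            raise ValueError(f"missing test measurement for gene {gene!r}")
        evidence[gene] = discretize(test_values[gene], discretization.threshold(gene))
    return evidence


def methylation_configurations(
    topology: ModelTopology,
    subsample: int | None = None,
    seed: int = 0,
) -> list[tuple[int, ...]]:
    """All 2**M binary configurations of the methylation nodes (ordered as
    in the topology), or a seeded subsample of them."""
    m = len(topology.methylation_nodes)
    configs = [tuple(1 + b for b in bits) for bits in itertools.product((0, 1), repeat=m)]
    if subsample is not None and subsample < len(configs):
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(len(configs), size=subsample, replace=False))
        configs = [configs[k] for k in keep]
    return configs


def _train_fold(
    dataset: ExpressionDataset,
    iteration: HoldoutIteration,
    variant: str,
    config: TrainingConfig,
    topology: ModelTopology,
) -> TrainedNetwork:
    fold = dataset.subset(list(iteration.training_indices))
    return train_network(fold, variant, config, topology=topology)


def _query(network: TrainedNetwork, evidence: dict[str, int], variant: str):
    p_tr = inference.posterior_marginal(network, evidence, "TRCMPLX").prob(2)
    p_sa = (
        inference.posterior_marginal(network, evidence, "Sample").prob(2)
        if variant in ("t1", "t2")
        else None
    )
    return p_tr, p_sa


def run_ge_experiment(
    dataset: ExpressionDataset,
    variant: str,
    config: TrainingConfig | None = None,
    options: TopologyOptions | None = None,
) -> list[HoldoutResult]:
    """Gene-expression-evidence holdout: two results per iteration (one per
    test sample), deterministically ordered."""
    config = config or TrainingConfig()
    if config.fixed_priors is None:
        # load the packaged priors once rather than per training fold
        config = replace(config, fixed_priors=fixed_priors(variant))
    topology = build_topology(variant, options)
    plan = generate_pairs(dataset.labels)
    results: list[HoldoutResult] = []
    for it_no, it in enumerate(plan):
        try:
            network = _train_fold(dataset, it, variant, config, topology)
        except ValueError as exc:
            raise ValueError(f"iteration {it_no} (normal {it.normal_index}, "
                             f"tumor {it.tumor_index}): {exc}") from exc
        for test_idx in (it.normal_index, it.tumor_index):
            test_values = {
                g: float(dataset.matrix[r, test_idx])
                for r, g in enumerate(dataset.genes)
            }
            evidence = build_ge_evidence(test_values, network.discretization, topology)
            p_tr, p_sa = _query(network, evidence, variant)
            results.append(
                HoldoutResult(
                    iteration=it_no,
                    normal_index=it.normal_index,
                    tumor_index=it.tumor_index,
                    sample_index=test_idx,
                    true_label=int(dataset.labels[test_idx]),
                    p_trcmplx=p_tr,
                    p_sample=p_sa,
                    evidence=dict(evidence),
                )
            )
    return results


def run_me_experiment(
    dataset: ExpressionDataset,
    variant: str = "t1",
    config: TrainingConfig | None = None,
    options: TopologyOptions | None = None,
    subsample: int | None = None,
    seed: int = 0,
) -> list[HoldoutResult]:
    """Methylation-perturbation holdout: for each test pair, sweep binary
    methylation configurations as the only evidence and record both
    posteriors per configuration and test sample."""
    config = config or TrainingConfig()
    if config.fixed_priors is None:
        # load the packaged priors once rather than per training fold
        config = replace(config, fixed_priors=fixed_priors(variant))
    topology = build_topology(variant, options)
    me_nodes = topology.methylation_nodes
    if not me_nodes:
        raise ValueError(f"variant {variant!r} has no methylation nodes to perturb")
    configs = methylation_configurations(topology, subsample=subsample, seed=seed)
    plan = generate_pairs(dataset.labels)
    results: list[HoldoutResult] = []
    for it_no, it in enumerate(plan):
        network = _train_fold(dataset, it, variant, config, topology)
        for test_idx in (it.normal_index, it.tumor_index):
            for cfg in configs:
                evidence = dict(zip(me_nodes, cfg))
                p_tr, p_sa = _query(network, evidence, variant)
                results.append(
                    HoldoutResult(
                        iteration=it_no,
                        normal_index=it.normal_index,
                        tumor_index=it.tumor_index,
                        sample_index=test_idx,
                        true_label=int(dataset.labels[test_idx]),
                        p_trcmplx=p_tr,
                        p_sample=p_sa,
                        evidence=dict(evidence),
                        me_config=cfg,
                    )
                )
    return results
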