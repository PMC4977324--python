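"""Gene-CPT estimation from expression training data.

Each gene's continuous expression vector is discretized at its training
median (strictly below the median -> state 1/repressed, at or above ->
state 2/active; the same tie rule is used for test evidence). Class labels
are -1 (normal mucosa) and +1 (tumor). Per-class active/inactive counts
are turned into conditional probabilities by a rule determined by the
gene's parent signature, weighted by the assumed effect of the
transcription complex (ETGN) where the complex is a parent, and finally
pseudo-count smoothed so no deterministic 0/1 survives.

Count symbols used throughout (per gene, on the training fold):

=========  =====================================================
``a``      active (>= median) in normal samples
``b``      active in tumor samples
``c``      inactive (< median) in normal samples
``d``      inactive in tumor samples
=========  =====================================================

The three-parent rule's denominators are deliberately those of the source
derivation (e.g. A = #normal + actives-in-tumor), non-standard as they
are; they are applied verbatim rather than "corrected".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    DiscretizationModel,
    TrainedNetwork,
    TrainingConfig,
    fixed_priors,
)
from .tables import ConditionalTable, CountTable, column_index, smooth_and_normalize
from .topology import (
    HISTONE_NODES,
    METHYLATION_NODES,
    ModelTopology,
    TopologyOptions,
    build_topology,
)

__all__ = [
    "ClassStateCounts",
    "compute_threshold",
    "discretize",
    "tabulate_class_states",
    "estimate_cpt_sample_only",
    "estimate_cpt_sample_trcmplx",
    "estimate_cpt_sample_me_trcmplx",
    "estimate_cpt_sample_me",
    "estimate_cpt_dact3",
    "estimate_cpt_trcmplx_only",
    "estimate_gene_cpt",
    "train_network",
]


def compute_threshold(values: np.ndarray) -> float:
    """Sample median of a nonempty finite vector."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot compute a threshold from an empty vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("expression values must be finite")
    return float(np.median(v))


def discretize(value: float, threshold: float) -> int:
    """State 1 (inactive) strictly below the threshold, else state 2."""
    return 1 if value < threshold else 2


@dataclass(frozen=True)
class ClassStateCounts:
    """Per-class active/inactive bin sizes of one gene on a training fold."""

    a: int  # active in normal
    b: int  # active in tumor
    c: int  # inactive in normal
    d: int  # inactive in tumor

    @property
    def n_normal(self) -> int:
        return self.a + self.c

    @property
    def n_tumor(self) -> int:
        return self.b + self.d


def _check_labels(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be 1-D vectors of equal length")
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("labels must be -1 (normal) or +1 (tumor)")
    return v, y.astype(int)


def tabulate_class_states(
    values: np.ndarray, labels: np.ndarray, threshold: float
) -> ClassStateCounts:
    v, y = _check_labels(values, labels)
    active = v >= threshold
    return ClassStateCounts(
        a=int(np.sum(active & (y < 0))),
        b=int(np.sum(active & (y > 0))),
        c=int(np.sum(~active & (y < 0))),
        d=int(np.sum(~active & (y > 0))),
    )


def _fill(table: np.ndarray, col: int, row: int, value: float, den: float, counts: bool) -> None:
    """Set the rule-defined entry of a column and its complement.

    ``counts`` keeps the table on the count scale (complement =
    denominator - value) instead of the fraction scale (complement =
    1 - value); a dead column (zero denominator) is left all-zero.
    """
    if den <= 0:
        return
    if counts:
        table[row, col] = value
        table[1 - row, col] = den - value
    else:
        table[row, col] = value / den
        table[1 - row, col] = 1.0 - value / den


def _estimate(
    values: np.ndarray,
    labels: np.ndarray,
    node: str,
    parents: tuple[str, ...],
    filler,
    smoothing_constant: float,
    smoothing_on: str,
) -> ConditionalTable:
    v, y = _check_labels(values, labels)
    thr = compute_threshold(v)
    counts = tabulate_class_states(v, y, thr)
    table = np.zeros((2, 2 ** len(parents)))
    filler(table, counts, smoothing_on == "counts")
    ct = smooth_and_normalize(
        CountTable(node=node, parents=parents, table=table), smoothing_constant
    )
    return ct


# state-index shorthands used when composing column indices
_OFF, _ON = 1, 2
_NORMAL, _TUMOR = 1, 2
_UM, _M = 1, 2


def estimate_cpt_sample_only(
    values: np.ndarray,
    labels: np.ndarray,
    node: str = "gene",
    parents: tuple[str, ...] = ("Sample",),
    smoothing_constant: float = 1.0,
    smoothing_on: str = "fractions",
) -> ConditionalTable:
    """Single-parent rule: Pr(active | class) is the active fraction in
    that class (DKK2, DKK3-1/2, SFRP3, LEF1 in the full model; also the
    epigenetically orphaned genes once methylation nodes are stripped)."""

    def filler(t, cs: ClassStateCounts, counts_mode: bool) -> None:
        _fill(t, column_index([_NORMAL]), 1, cs.a, cs.n_normal, counts_mode)
        _fill(t, column_index([_TUMOR]), 1, cs.b, cs.n_tumor, counts_mode)

    return _estimate(values, labels, node, parents, filler, smoothing_constant, smoothing_on)


def estimate_cpt_sample_trcmplx(
    values: np.ndarray,
    labels: np.ndarray,
    p: float,
    node: str = "gene",
    parents: tuple[str, ...] = ("Sample", "TRCMPLX"),
    smoothing_constant: float = 1.0,
    smoothing_on: str = "fractions",
) -> ConditionalTable:
    """Two-parent rule for complex-driven genes (MYC, CCND1, CD44, DKK4).

    The class-conditional active fraction is weighted by ``p`` when the
    complex is off; the off-state probability in the complex-on block is
    the inactive fraction weighted by ``1 - p``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")

    def filler(t, cs: ClassStateCounts, counts_mode: bool) -> None:
        A, B = cs.n_normal, cs.n_tumor
        _fill(t, column_index([_NORMAL, _OFF]), 1, cs.a * p, A, counts_mode)
        _fill(t, column_index([_TUMOR, _OFF]), 1, cs.b * p, B, counts_mode)
        _fill(t, column_index([_NORMAL, _ON]), 0, (A - cs.a) * (1 - p), A, counts_mode)
        _fill(t, column_index([_TUMOR, _ON]), 0, (B - cs.b) * (1 - p), B, counts_mode)

    return _estimate(values, labels, node, parents, filler, smoothing_constant, smoothing_on)


def estimate_cpt_sample_me_trcmplx(
    values: np.ndarray,
    labels: np.ndarray,
    p: float,
    node: str = "gene",
    parents: tuple[str, ...] = ("Sample", "Me", "TRCMPLX"),
    smoothing_constant: float = 1.0,
    smoothing_on: str = "fractions",
) -> ConditionalTable:
    """Three-parent rule (DKK1, SFRP1, WIF1): a 2x2 methylation-by-class
    cross table supplies the frequencies. Expression below the median is
    read as repression by promoter methylation, above as activity of the
    unmethylated promoter. Denominators mix the two classes as derived:
    A = #normal + b, B = #tumor + a, C = #normal + d, D = #tumor + c.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")

    def filler(t, cs: ClassStateCounts, counts_mode: bool) -> None:
        A = cs.n_normal + cs.b
        B = cs.n_tumor + cs.a
        C = cs.n_normal + cs.d
        D = cs.n_tumor + cs.c
        for tr, w in ((_OFF, p), (_ON, 1 - p)):
            _fill(t, column_index([_NORMAL, _UM, tr]), 1, cs.a * w, A, counts_mode)
            _fill(t, column_index([_TUMOR, _UM, tr]), 1, cs.b * w, B, counts_mode)
            _fill(t, column_index([_NORMAL, _M, tr]), 0, cs.c * w, C, counts_mode)
            _fill(t, column_index([_TUMOR, _M, tr]), 0, cs.d * w, D, counts_mode)

    return _estimate(values, labels, node, parents, filler, smoothing_constant, smoothing_on)


def estimate_cpt_sample_me(
    values: np.ndarray,
    labels: np.ndarray,
    node: str = "gene",
    parents: tuple[str, ...] = ("Sample", "Me"),
    smoothing_constant: float = 1.0,
    smoothing_on: str = "fractions",
) -> ConditionalTable:
    """Two-parent {Sample, methylation} rule (DACT1/2, SFRP2/4/5).

    The source never derives this case explicitly; the rule is the
    three-parent cross-table rule with the complex factor removed.
    """

    def filler(t, cs: ClassStateCounts, counts_mode: bool) -> None:
        A = cs.n_normal + cs.b
        B = cs.n_tumor + cs.a
        C = cs.n_normal + cs.d
        D = cs.n_tumor + cs.c
        _fill(t, column_index([_NORMAL, _UM]), 1, cs.a, A, counts_mode)
        _fill(t, column_index([_TUMOR, _UM]), 1, cs.b, B, counts_mode)
        _fill(t, column_index([_NORMAL, _M]), 0, cs.c, C, counts_mode)
        _fill(t, column_index([_TUMOR, _M]), 0, cs.d, D, counts_mode)

    return _estimate(values, labels, node, parents, filler, smoothing_constant, smoothing_on)


def estimate_cpt_dact3(
    values: np.ndarray,
    labels: np.ndarray,
    node: str = "DACT3",
    parents: tuple[str, ...] = ("H3K27me3", "H3K4me3", "Sample"),
    smoothing_constant: float = 1.0,
    smoothing_on: str = "fractions",
) -> ConditionalTable:
    """Histone-mark rule: DACT3 is expressed when the repressive mark
    H3K27me3 is low and the activating mark H3K4me3 is high; every other
    mark configuration flips the class-conditional active fraction."""

    def filler(t, cs: ClassStateCounts, counts_mode: bool) -> None:
        for s, act, n in ((_NORMAL, cs.a, cs.n_normal), (_TUMOR, cs.b, cs.n_tumor)):
            for k27 in (1, 2):
                for k4 in (1, 2):
                    permissive = k27 == 1 and k4 == 2
                    value = act if permissive else n - act
                    _fill(t, column_index([k27, k4, s]), 1, value, n, counts_mode)

    return _estimate(values, labels, node, parents, filler, smoothing_constant, smoothing_on)


def estimate_cpt_trcmplx_only(
    values: np.ndarray,
    labels: np.ndarray,
    node: str = "gene",
    parents: tuple[str, ...] = ("TRCMPLX",),
    smoothing_constant: float = 1.0,
    smoothing_on: str = "fractions",
) -> ConditionalTable:
    """Naive-Bayes rule: the class label proxies the complex state
    (normal <-> off), with no ETGN weighting."""

    def filler(t, cs: ClassStateCounts, counts_mode: bool) -> None:
        _fill(t, column_index([_OFF]), 1, cs.a, cs.n_normal, counts_mode)
        _fill(t, column_index([_ON]), 1, cs.b, cs.n_tumor, counts_mode)

    return _estimate(values, labels, node, parents, filler, smoothing_constant, smoothing_on)


def estimate_gene_cpt(
    values: np.ndarray,
    labels: np.ndarray,
    node: str,
    parents: tuple[str, ...],
    config: TrainingConfig,
) -> ConditionalTable:
    """Dispatch on the parent signature to the matching estimation rule."""
    kwargs = dict(
        node=node,
        parents=parents,
        smoothing_constant=config.smoothing_constant,
        smoothing_on=config.smoothing_on,
    )
    pset = set(parents)
    has_me = any(p in METHYLATION_NODES for p in parents)
    has_histone = any(p in HISTONE_NODES for p in parents)
    if has_histone:
        return estimate_cpt_dact3(values, labels, **kwargs)
    if pset == {"TRCMPLX"}:
        return estimate_cpt_trcmplx_only(values, labels, **kwargs)
    if "Sample" in pset and "TRCMPLX" in pset and has_me:
        return estimate_cpt_sample_me_trcmplx(values, labels, config.p, **kwargs)
    if "Sample" in pset and "TRCMPLX" in pset:
        return estimate_cpt_sample_trcmplx(values, labels, config.p, **kwargs)
    if "Sample" in pset and has_me:
        return estimate_cpt_sample_me(values, labels, **kwargs)
    if pset == {"Sample"}:
        return estimate_cpt_sample_only(values, labels, **kwargs)
    raise ValueError(f"no estimation rule for gene {node!r} with parents {parents}")


def train_network(
    dataset,
    variant: str,
    config: TrainingConfig | None = None,
    options: TopologyOptions | None = None,
    topology: ModelTopology | None = None,
) -> TrainedNetwork:
    """Assign fixed priors and estimate every gene node's table.

    ``dataset`` is an ``ExpressionDataset`` (gene x sample matrix with
    -1/+1 labels) whose gene rows must cover the variant's gene nodes;
    both classes must be present in the training labels.
    """
    config = config or TrainingConfig()
    topo = topology or build_topology(variant, options)
    labels = np.asarray(dataset.labels)
    if not (np.any(labels < 0) and np.any(labels > 0)):
        raise ValueError("training data must contain both normal and tumor samples")

    priors = dict(config.fixed_priors) if config.fixed_priors else fixed_priors(variant)
    tables: dict[str, ConditionalTable] = {}
    thresholds: dict[str, float] = {}
    gene_rows = {g: i for i, g in enumerate(dataset.genes)}
    for node in topo:
        if node.category == "gene":
            if node.name not in gene_rows:
                raise ValueError(f"dataset has no expression row for gene {node.name!r}")
            values = np.asarray(dataset.matrix)[gene_rows[node.name]]
            thresholds[node.name] = compute_threshold(values)
            tables[node.name] = estimate_gene_cpt(
                values, labels, node.name, node.parents, config
            )
        else:
            try:
                prior = priors[node.name]
            except KeyError:
                raise ValueError(f"no fixed prior supplied for node {node.name!r}") from None
            if prior.parents != node.parents:
                raise ValueError(
                    f"fixed table for {node.name!r} declares parents {prior.parents}, "
                    f"topology expects {node.parents}"
                )
            tables[node.name] = prior
    return TrainedNetwork(
        topology=topo,
        parameters=tables,
        discretization=DiscretizationModel(thresholds),
    )
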