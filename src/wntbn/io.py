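"""File formats, run configuration and the end-to-end pipeline.

Plain-text formats throughout: the expression matrix is a TSV (gene rows,
sample columns, first column gene names), labels a two-column CSV
(sample id, label with -1/+1 or n/t tokens), trained networks and
topologies JSON documents, holdout results CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .evaluation import compute_roc, ks_two_sample, summarize_gene_trcmplx
from .holdout import HoldoutResult, run_ge_experiment, run_me_experiment
from .parameters import (
    DiscretizationModel,
    TrainedNetwork,
    TrainingConfig,
)
from .synthetic import ExpressionDataset, GeneratorConfig, generate_cohort
from .tables import ConditionalTable
from .topology import ModelTopology, NodeSpec, TopologyOptions, build_topology

__all__ = [
    "read_expression",
    "write_expression",
    "save_network",
    "load_network",
    "export_topology_edges",
    "topology_to_json",
    "topology_from_json",
    "results_to_frame",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("wntbn")

_LABEL_TOKENS = {"-1": -1, "1": 1, "+1": 1, "n": -1, "t": 1, "normal": -1, "tumor": 1}


def _parse_label(token: str, where: str) -> int:
    key = str(token).strip().lower()
    if key not in _LABEL_TOKENS:
        raise ValueError(f"unknown label token {token!r} at {where}")
    return _LABEL_TOKENS[key]


def _dedupe_genes(names: list[str]) -> tuple[str, ...]:
    """Duplicate gene symbols get -1/-2... suffixes (the source matrix
    carries two DKK3 probes distinguished this way)."""
    seen: dict[str, int] = {}
    for n in names:
        seen[n] = seen.get(n, 0) + 1
    counters: dict[str, int] = {}
    out = []
    for n in names:
        if seen[n] > 1:
            counters[n] = counters.get(n, 0) + 1
            out.append(f"{n}-{counters[n]}")
        else:
            out.append(n)
    return tuple(out)


def read_expression(matrix_path, labels_path) -> ExpressionDataset:
    """Read a genes x samples TSV plus a label file into a dataset."""
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    try:
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"expression file {matrix_path} is empty") from None
    if frame.empty:
        raise ValueError(f"expression file {matrix_path} has no data rows")
    bad = frame.columns[~frame.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        raise ValueError(f"non-numeric cells in columns {list(bad)} of {matrix_path}")
    matrix = frame.to_numpy(dtype=float)

    labels_frame = pd.read_csv(labels_path, header=None, dtype=str, comment="#")
    if labels_frame.shape[1] == 1:
        tokens = labels_frame.iloc[:, 0]
        sample_ids = tuple(frame.columns)
    else:
        sample_ids = tuple(labels_frame.iloc[:, 0].astype(str))
        tokens = labels_frame.iloc[:, 1]
    labels = np.array(
        [_parse_label(t, f"{labels_path}:{i + 1}") for i, t in enumerate(tokens)]
    )
    if labels.size != matrix.shape[1]:
        raise ValueError(
            f"{labels.size} labels for {matrix.shape[1]} sample columns "
            f"({labels_path} vs {matrix_path})"
        )
    return ExpressionDataset(
        genes=_dedupe_genes([str(g) for g in frame.index]),
        matrix=matrix,
        labels=labels,
        sample_ids=sample_ids,
    )


def write_expression(dataset: ExpressionDataset, matrix_path, labels_path) -> None:
    frame = pd.DataFrame(
        dataset.matrix, index=list(dataset.genes), columns=list(dataset.sample_ids)
    )
    frame.index.name = "gene"
    frame.to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"sample": list(dataset.sample_ids), "label": dataset.labels}
    ).to_csv(labels_path, header=False, index=False)


# -- network / topology serialization ------------------------------------


def topology_to_json(topology: ModelTopology) -> dict:
    return {
        "variant": topology.variant,
        "options": {"include_me_dkk4": topology.options.include_me_dkk4},
        "nodes": [
            {
                "name": n.name,
                "category": n.category,
                "states": list(n.states),
                "parents": list(n.parents),
            }
            for n in topology.nodes
        ],
    }


def topology_from_json(doc: Mapping) -> ModelTopology:
    nodes = tuple(
        NodeSpec(
            name=n["name"],
            category=n["category"],
            states=tuple(n["states"]),
            parents=tuple(n["parents"]),
        )
        for n in doc["nodes"]
    )
    options = TopologyOptions(**doc.get("options", {}))
    return ModelTopology(variant=doc["variant"], nodes=nodes, options=options)


def export_topology_edges(topology: ModelTopology, path) -> None:
    """One ``parent<TAB>child`` line per directed arc."""
    with open(path, "w") as fh:
        for parent, child in topology.edges:
            fh.write(f"{parent}\t{child}\n")


def save_network(network: TrainedNetwork, path) -> None:
    doc = {
        "topology": topology_to_json(network.topology),
        "parameters": {
            name: {"parents": list(ct.parents), "probs": ct.probs.tolist()}
            for name, ct in network.parameters.items()
        },
        "thresholds": dict(network.discretization.thresholds)
        if network.discretization
        else None,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_network(path) -> TrainedNetwork:
    doc = json.loads(Path(path).read_text())
    topology = topology_from_json(doc["topology"])
    params = {
        name: ConditionalTable(
            node=name, parents=tuple(entry["parents"]), probs=np.asarray(entry["probs"])
        )
        for name, entry in doc["parameters"].items()
    }
    disc = (
        DiscretizationModel(doc["thresholds"]) if doc.get("thresholds") else None
    )
    return TrainedNetwork(topology=topology, parameters=params, discretization=disc)


def results_to_frame(results: list[HoldoutResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        ev = json.dumps(r.evidence, sort_keys=True)
        rows.append(
            {
                "iteration": r.iteration,
                "normal_index": r.normal_index,
                "tumor_index": r.tumor_index,
                "sample_index": r.sample_index,
                "true_label": r.true_label,
                "p_trcmplx": r.p_trcmplx,
                "p_sample": r.p_sample if r.p_sample is not None else "",
                "evidence_hash": hashlib.sha1(ev.encode()).hexdigest()[:12],
            }
        )
    return pd.DataFrame(rows)


# -- pipeline --------------------------------------------------------------


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    variant: Literal["t1", "t2", "p1"] = "t1"
    evidence: Literal["ge", "me"] = "ge"
    etgn: float = Field(default=0.9, gt=0.0, lt=1.0)
    smoothing: Literal["fractions", "counts"] = "fractions"
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    seed: int = 0
    n_normal: int = Field(default=24, ge=1)
    n_tumor: int = Field(default=24, ge=1)
    sigma: float = Field(default=0.25, ge=0.0)
    me_subsample: int | None = None
    include_me_dkk4: bool = False
    matrix_path: str | None = None
    labels_path: str | None = None
    out_dir: str = "results"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**doc)


def run_pipeline(config: RunConfig) -> dict:
    """simulate-or-load -> holdout -> evaluate; writes all artifacts.

    Returns the summary dictionary that is also written to
    ``<out_dir>/summary.json``.
    """
    if config.evidence == "me" and config.variant != "t1":
        raise ValueError("methylation-perturbation evidence requires the t1 model")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info(
        "pipeline start: variant=%s evidence=%s etgn=%.2f smoothing=%s seed=%d",
        config.variant, config.evidence, config.etgn, config.smoothing, config.seed,
    )

    if config.matrix_path:
        if not config.labels_path:
            raise ValueError("labels_path is required when matrix_path is given")
        dataset = read_expression(config.matrix_path, config.labels_path)
    else:
        dataset, truth = generate_cohort(
            GeneratorConfig(
                n_normal=config.n_normal,
                n_tumor=config.n_tumor,
                sigma=config.sigma,
                seed=config.seed,
            )
        )
        write_expression(dataset, out / "expression.tsv", out / "labels.csv")
        truth.states.to_json(out / "truth.json", orient="index")

    tcfg = TrainingConfig(etgn=config.etgn, smoothing_on=config.smoothing)
    topts = TopologyOptions(include_me_dkk4=config.include_me_dkk4)
    if config.evidence == "ge":
        results = run_ge_experiment(dataset, config.variant, tcfg, topts)
    else:
        results = run_me_experiment(
            dataset, config.variant, tcfg, topts,
            subsample=config.me_subsample, seed=config.seed,
        )
    frame = results_to_frame(results)
    frame.to_csv(out / "holdout.csv", index=False)

    labels = [r.true_label for r in results]
    tr_scores = [r.p_trcmplx for r in results]
    summary: dict = {
        "variant": config.variant,
        "evidence": config.evidence,
        "etgn": config.etgn,
        "seed": config.seed,
        "iterations": int(frame["iteration"].nunique()),
        "n_results": len(results),
        "auc_trcmplx": compute_roc(tr_scores, labels).auc,
    }
    if config.variant in ("t1", "t2"):
        sa_scores = [r.p_sample for r in results]
        ks = ks_two_sample(tr_scores, sa_scores, alpha=config.alpha)
        summary.update(
            auc_sample=compute_roc(sa_scores, labels).auc,
            ks_statistic=ks.statistic,
            ks_pvalue=ks.pvalue,
            ks_h01=ks.h01,
        )
    if config.evidence == "ge":
        summarize_gene_trcmplx(results, dataset).to_csv(
            out / "gene_trcmplx_stats.csv", index=False
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    log.info("pipeline done: %s", summary)
    return summary
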