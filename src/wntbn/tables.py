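"""Conditional probability tables for binary nodes.

A table for a node with k parents is a 2 x 2**k matrix: row 0 holds the
probability of state 1 (the low/off pole), row 1 of state 2, one column per
ordered parent configuration. Column order follows the convention of the
printed tables: the first-listed parent varies fastest, so the column index
of a configuration (s_1, ..., s_k) with s_i in {1, 2} is
sum((s_i - 1) * 2**(i-1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

__all__ = [
    "CountTable",
    "ConditionalTable",
    "column_index",
    "parent_configurations",
    "smooth_and_normalize",
]

COLUMN_SUM_TOL = 1e-12


def column_index(states: Sequence[int]) -> int:
    """Column of an ordered parent configuration (first parent fastest)."""
    idx = 0
    for i, s in enumerate(states):
        if s not in (1, 2):
            raise ValueError(f"states must be 1 or 2, got {s!r}")
        idx += (s - 1) << i
    return idx


def parent_configurations(k: int) -> list[tuple[int, ...]]:
    """All 2**k parent configurations in column order."""
    # first parent fastest -> iterate last parent as the outer product axis
    return [tuple(reversed(cfg)) for cfg in product((1, 2), repeat=k)]


@dataclass(frozen=True)
class CountTable:
    """Raw (pre-smoothing) table of nonnegative frequencies or fractions."""

    node: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", t)
        expected = (2, 2 ** len(self.parents))
        if t.shape != expected:
            raise ValueError(
                f"table for {self.node!r} has shape {t.shape}, expected {expected}"
            )
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError(f"table for {self.node!r} has negative or non-finite entries")


@dataclass(frozen=True)
class ConditionalTable:
    """A node's distribution over its two states per parent configuration."""

    node: str
    parents: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        expected = (2, 2 ** len(self.parents))
        if p.shape != expected:
            raise ValueError(
                f"CPT for {self.node!r} has shape {p.shape}, expected {expected}"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"CPT for {self.node!r} has entries outside [0, 1]")
        sums = p.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError(f"CPT columns for {self.node!r} do not sum to 1: {sums}")

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    def column(self, states: Sequence[int]) -> np.ndarray:
        """Distribution of the node given an ordered parent configuration."""
        return self.probs[:, column_index(states)]

    def prob(self, state: int, parent_states: Sequence[int] = ()) -> float:
        if state not in (1, 2):
            raise ValueError("state must be 1 or 2")
        return float(self.probs[state - 1, column_index(parent_states)])


def smooth_and_normalize(t: CountTable, constant: float = 1.0) -> ConditionalTable:
    """Dirichlet pseudo-count smoothing: add ``constant`` to every entry and
    renormalize each parent-configuration column.

    Removes deterministic 0/1 values; an all-zero column becomes uniform.
    """
    if constant <= 0:
        raise ValueError("smoothing constant must be positive")
    smoothed = t.table + constant
    probs = smoothed / smoothed.sum(axis=0, keepdims=True)
    return ConditionalTable(node=t.node, parents=t.parents, probs=probs)
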