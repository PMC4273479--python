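"""Recurrent-CNV identification via the Poisson-binomial tail test.

Across a cohort, the per-window CNV indicators are collected into a binary
matrix M (m windows × n samples; a window is kept only when it is analyzable
in *every* sample).  Treating copy-number alterations as independent events
with per-sample rates p_j (the column means of M), the count K of samples
carrying a CNV at a window follows the Poisson-binomial distribution — the
law of a sum of independent, non-identical Bernoulli trials.  A window is
recurrent when its count reaches the smallest k whose upper-tail probability
P(K ≥ k) drops below the significance cutoff (0.01 by default).

The pmf is computed exactly by iterative convolution (O(n²), numerically
stable at cohort scale); tests cross-check it against exhaustive enumeration
of all 2^n outcomes for small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CNVMatrix",
    "RecurrentResult",
    "build_matrix",
    "poisson_binomial_pmf",
    "recurrence_cutoff",
    "flag_recurrent",
]


@dataclass
class CNVMatrix:
    """Binary window × sample CNV-status matrix for one state (gain or loss)."""

    windows: pd.DataFrame            # chrom, start, end of the retained rows
    samples: list[str]
    values: np.ndarray = field(repr=False)  # shape (m, n), entries 0/1
    state_kind: str = "gain"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")


@dataclass
class RecurrentResult:
    counts: np.ndarray               # per-window row sums k
    sample_rates: np.ndarray         # p_j per sample (column means)
    cutoff_count: int                # smallest k with P(K >= k) < alpha; n+1 if none
    tail_probabilities: np.ndarray   # P(K >= k) for k = 0..n
    flags: np.ndarray                # recurrent yes/no per window
    alpha: float = 0.01


def build_matrix(
    calls_by_sample: Mapping[str, pd.DataFrame], state: str = "gain"
) -> CNVMatrix:
    """Assemble the binary matrix from per-sample localized call tables.

    Each call table is the ``calls`` frame of a :class:`~aluscancnv.ght.CallResult`
    (columns chrom, start, end, state, ...) and contains only the windows
    analyzable in that sample.  Rows of the matrix are restricted to windows
    present in every sample's table; a cell is 1 iff that sample's call state
    equals ``state``.
    """
    if state not in ("gain", "loss"):
        raise ValueError(f"state must be 'gain' or 'loss', got {state!r}")
    samples = list(calls_by_sample)
    if not samples:
        raise ValueError("need at least one sample")
    keyed = {}
    common: pd.Index | None = None
    for s in samples:
        df = calls_by_sample[s]
        idx = pd.MultiIndex.from_arrays(
            [df["chrom"], df["start"], df["end"]], names=["chrom", "start", "end"]
        )
        if idx.has_duplicates:
            raise ValueError(f"sample {s!r} has duplicate windows in its call table")
        keyed[s] = pd.Series((df["state"] == state).to_numpy(np.int8), index=idx)
        common = idx if common is None else common.intersection(idx)
    common = common.sort_values()
    values = np.column_stack([keyed[s].reindex(common).to_numpy() for s in samples])
    windows = pd.DataFrame(
        {
            "chrom": common.get_level_values("chrom"),
            "start": common.get_level_values("start"),
            "end": common.get_level_values("end"),
        }
    )
    return CNVMatrix(windows=windows, samples=samples, values=values, state_kind=state)


def poisson_binomial_pmf(p_vector) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_j) trials.

    Iterative convolution: after processing j trials the vector holds
    P(K = 0..j).  Returns P(K = 0..n).
    """
    p = np.asarray(p_vector, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_vector must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("success probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for pj in p:
        nxt = np.zeros(pmf.size + 1)
        nxt[:-1] = pmf * (1.0 - pj)
        nxt[1:] += pmf * pj
        pmf = nxt
    return pmf


def recurrence_cutoff(p_vector, alpha: float = 0.01) -> int:
    """Smallest count k with upper-tail probability P(K ≥ k) < alpha.

    Returns n + 1 when even the extreme count K = n is not rare enough (then
    nothing can be flagged).
    """
    pmf = poisson_binomial_pmf(p_vector)
    tail = _upper_tail(pmf)
    below = np.nonzero(tail < alpha)[0]
    return int(below[0]) if below.size else len(pmf)  # len(pmf) == n + 1


def _upper_tail(pmf: np.ndarray) -> np.ndarray:
    """P(K >= k) for k = 0..n, computed by reverse cumulative sum."""
    return np.cumsum(pmf[::-1])[::-1]


def flag_recurrent(
    matrix: CNVMatrix, alpha: float = 0.01, bonferroni: bool = False
) -> RecurrentResult:
    """Flag windows whose cohort CNV count reaches the Poisson-binomial cutoff.

    Per-sample rates p_j are the column means of the matrix; the cutoff k* is
    the smallest count with tail probability < alpha (optionally alpha/m with
    the Bonferroni flag); a window is recurrent iff its row sum ≥ k*.
    """
    m, n = matrix.values.shape
    if n < 2:
        raise ValueError("recurrence testing needs at least 2 samples")
    rates = matrix.values.mean(axis=0).astype(float)
    level = alpha / m if bonferroni else alpha
    pmf = poisson_binomial_pmf(rates)
    tail = _upper_tail(pmf)
    below = np.nonzero(tail < level)[0]
    cutoff = int(below[0]) if below.size else n + 1
    counts = matrix.values.sum(axis=1).astype(np.int64)
    return RecurrentResult(
        counts=counts,
        sample_rates=rates,
        cutoff_count=cutoff,
        tail_probabilities=tail,
        flags=counts >= cutoff,
        alpha=level,
    )
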