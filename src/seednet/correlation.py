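"""Tie-aware Spearman rank correlation and thresholded pairwise screening.

Spearman rho is computed as the Pearson correlation of average ranks over
pairwise-complete observations.  The popular 6*sum(d^2)/(n(n^2-1)) shortcut
is deliberately not used: it is biased whenever ties are present.  Pairs
with too few complete observations, or with a zero-variance rank vector,
yield *undefined* (returned as None) rather than zero — an undefined pair
must neither create nor suppress an edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationEdge",
    "average_ranks",
    "spearman_rho",
    "pairwise_correlations",
    "correlations_vs_target",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_PAIRS",
]

DEFAULT_THRESHOLD = 0.65
DEFAULT_MIN_PAIRS = 4


@dataclass(frozen=True)
class CorrelationEdge:
    """An unordered gene pair with its Spearman rho in one dataset.

    Endpoints are stored in lexicographic order.
    """

    gene_a: str
    gene_b: str
    rho: float
    n_pairs: int
    dataset_id: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge on {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)
        if not abs(self.rho) <= 1 + 1e-12:
            raise ValueError(f"|rho| > 1: {self.rho}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    @property
    def sign(self) -> int:
        return 1 if self.rho >= 0 else -1


def average_ranks(values: Sequence[float]) -> np.ndarray:
    """Rank 1..n with tied values sharing the mean of the ranks they span."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("need a non-empty 1-d sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite entry in rank input")
    order = np.argsort(arr, kind="stable")
    ranks = np.empty(arr.size, dtype=float)
    sorted_vals = arr[order]
    i = 0
    while i < arr.size:
        j = i
        while j + 1 < arr.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        # positions i..j (0-based) share ranks i+1..j+1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> float | None:
    """Spearman rho over pairwise-complete observations, or None if undefined.

    Undefined when fewer than ``min_pairs`` complete pairs remain or when a
    ranked vector has zero variance.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    mask = np.isfinite(xa) & np.isfinite(ya)
    n = int(mask.sum())
    if n < max(min_pairs, 2):
        return None
    rx = average_ranks(xa[mask])
    ry = average_ranks(ya[mask])
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    sx = float(np.sqrt(np.dot(dx, dx)))
    sy = float(np.sqrt(np.dot(dy, dy)))
    if sx == 0.0 or sy == 0.0:
        return None
    # exact +/-1 anchors: identical or exactly reversed rank vectors
    if np.array_equal(rx, ry):
        return 1.0
    if np.array_equal(rx + ry, np.full(rx.size, rx.size + 1.0)):
        return -1.0
    rho = float(np.dot(dx, dy) / (sx * sy))
    return float(np.clip(rho, -1.0, 1.0))


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Average-rank each row of a complete (finite) matrix."""
    out = np.empty_like(values, dtype=float)
    for i in range(values.shape[0]):
        out[i] = average_ranks(values[i])
    return out


def correlations_vs_target(
    dataset: ExpressionDataset,
    target: str,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> dict[str, float]:
    """Spearman rho of every other gene in the dataset against ``target``.

    Returns gene -> rho for all defined pairs (the target itself excluded).
    Rows without missing values ride a vectorized rank-then-dot path; rows
    containing NaN fall back to the pairwise-complete scalar routine.
    """
    if target not in dataset:
        return {}
    tvals = dataset.row(target)
    out: dict[str, float] = {}

    t_finite = np.all(np.isfinite(tvals))
    finite_rows = np.all(np.isfinite(dataset.values), axis=1)
    if t_finite and dataset.n_conditions >= max(min_pairs, 2):
        idx = np.flatnonzero(finite_rows)
        idx = idx[idx != dataset.index_of(target)]
        if idx.size:
            ranks = _rank_rows(dataset.values[idx])
            rt = average_ranks(tvals)
            rt = rt - rt.mean()
            st = float(np.sqrt(np.dot(rt, rt)))
            if st > 0:
                centered = ranks - ranks.mean(axis=1, keepdims=True)
                norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
                with np.errstate(invalid="ignore", divide="ignore"):
                    rhos = centered @ rt / (norms * st)
                for k, gi in enumerate(idx):
                    if norms[k] > 0:
                        rho = float(np.clip(rhos[k], -1.0, 1.0))
                        if abs(rho) > 1.0 - 1e-9:
                            # re-derive through the scalar path so exact
                            # +/-1 anchors stay exact
                            rho = spearman_rho(
                                tvals, dataset.values[gi], min_pairs=min_pairs
                            )
                            if rho is None:
                                continue
                        out[dataset.genes[gi]] = rho
    # slow path: target has NaN, or individual gene rows have NaN
    slow = (
        range(dataset.n_genes)
        if not t_finite
        else np.flatnonzero(~finite_rows)
    )
    for gi in slow:
        gene = dataset.genes[gi]
        if gene == target:
            continue
        rho = spearman_rho(tvals, dataset.values[gi], min_pairs=min_pairs)
        if rho is not None:
            out[gene] = rho
    return out


def _complete_pair_count(x: np.ndarray, y: np.ndarray) -> int:
    return int((np.isfinite(x) & np.isfinite(y)).sum())


def pairwise_correlations(
    dataset: ExpressionDataset,
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    threshold: float = DEFAULT_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    strict: bool = False,
) -> list[CorrelationEdge]:
    """All unordered cross pairs with defined rho passing the threshold.

    Genes absent from the dataset are skipped silently (absence is reported
    by the caller).  ``strict`` switches |rho| >= threshold to > threshold.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    set_a = [g for g in dict.fromkeys(genes_a) if g in dataset]
    set_b = [g for g in dict.fromkeys(genes_b) if g in dataset]
    n_undefined = 0
    edges: list[CorrelationEdge] = []
    seen: set[tuple[str, str]] = set()
    for a in set_a:
        for b in set_b:
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            xa, xb = dataset.row(a), dataset.row(b)
            rho = spearman_rho(xa, xb, min_pairs=min_pairs)
            if rho is None:
                n_undefined += 1
                continue
            passes = abs(rho) > threshold if strict else abs(rho) >= threshold
            if passes:
                edges.append(
                    CorrelationEdge(
                        gene_a=key[0],
                        gene_b=key[1],
                        rho=rho,
                        n_pairs=_complete_pair_count(xa, xb),
                        dataset_id=dataset.dataset_id,
                    )
                )
    if n_undefined:
        logger.info(
            "dataset %s: %d undefined pair(s) skipped", dataset.dataset_id, n_undefined
        )
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    return edges
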