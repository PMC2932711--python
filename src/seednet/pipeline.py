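"""End-to-end convenience wrappers shared by the CLI, tests and scripts."""

from __future__ import annotations

from .candidates import (
    DEFAULT_MIN_SEEDS,
    CandidateRecord,
    aggregate_candidates,
    seed_correlate_list,
)
from .correlation import DEFAULT_MIN_PAIRS, DEFAULT_THRESHOLD
from .datasets import ExpressionDataset
from .esn import ExtractedSeedNetwork, extract_esn

__all__ = ["query_candidates", "run_extraction_and_query"]


def query_candidates(
    datasets: list[ExpressionDataset],
    query_seeds: set[str],
    seed_set: set[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    min_seeds: int = DEFAULT_MIN_SEEDS,
    strict: bool = False,
) -> list[CandidateRecord]:
    """Per-seed correlate lists over all datasets, aggregated to candidates.

    ``seed_set`` (excluded from candidacy) defaults to ``query_seeds`` but
    may be wider, e.g. the full projected seed set when only correlated
    seeds are queried.
    """
    if seed_set is None:
        seed_set = set(query_seeds)
    per_seed = {}
    for ds in datasets:
        for seed in sorted(query_seeds):
            per_seed[(seed, ds.dataset_id)] = seed_correlate_list(
                ds, seed, threshold=threshold, min_pairs=min_pairs, strict=strict
            )
    return aggregate_candidates(per_seed, seed_set=seed_set, min_seeds=min_seeds)


def run_extraction_and_query(
    datasets: list[ExpressionDataset],
    seed_genes: set[str],
    threshold: float = DEFAULT_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    min_seeds: int = DEFAULT_MIN_SEEDS,
    strict: bool = False,
    projected=None,
) -> tuple[ExtractedSeedNetwork, list[CandidateRecord]]:
    """Extract the ESN, then query with its correlated seeds."""
    esn = extract_esn(
        datasets, seed_genes, threshold=threshold, min_pairs=min_pairs,
        strict=strict, projected=projected,
    )
    records = query_candidates(
        datasets,
        query_seeds=esn.correlated_seeds(),
        seed_set=seed_genes,
        threshold=threshold,
        min_pairs=min_pairs,
        min_seeds=min_seeds,
        strict=strict,
    )
    return esn, records
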