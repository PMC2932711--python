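"""Guilt-by-association candidate generation.

Each dataset is queried for genes correlated (|rho| >= threshold, either
sign) with each seed gene; per-seed lists are aggregated across datasets and
genes correlated with at least ``min_seeds`` *distinct* seeds are kept.  A
seed supported in two datasets counts once toward the distinct-seed tally,
and a candidate may collect its seeds from different datasets.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

from .correlation import (
    DEFAULT_MIN_PAIRS,
    DEFAULT_THRESHOLD,
    correlations_vs_target,
)
from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Support",
    "CandidateRecord",
    "seed_correlate_list",
    "aggregate_candidates",
    "group_by_seed_signature",
    "core_seed_summary",
    "DEFAULT_MIN_SEEDS",
]

DEFAULT_MIN_SEEDS = 3


@dataclass(frozen=True)
class Support:
    seed: str
    dataset_id: str
    rho: float


@dataclass
class CandidateRecord:
    gene: str
    supports: list[Support] = field(default_factory=list)

    @property
    def seed_signature(self) -> tuple[str, ...]:
        return tuple(sorted({s.seed for s in self.supports}))

    @property
    def n_seeds(self) -> int:
        return len(self.seed_signature)


def seed_correlate_list(
    dataset: ExpressionDataset,
    seed: str,
    threshold: float = DEFAULT_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    strict: bool = False,
) -> list[tuple[str, float]]:
    """Genes in ``dataset`` whose |rho| vs ``seed`` passes the threshold.

    The seed itself is excluded.  An absent seed yields an empty list (the
    "NA" condition) and is logged, not raised.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if seed not in dataset:
        logger.info("seed %s absent from dataset %s", seed, dataset.dataset_id)
        return []
    rhos = correlations_vs_target(dataset, seed, min_pairs=min_pairs)
    if strict:
        hits = [(g, r) for g, r in rhos.items() if abs(r) > threshold]
    else:
        hits = [(g, r) for g, r in rhos.items() if abs(r) >= threshold]
    hits.sort(key=lambda t: t[0])
    return hits


def aggregate_candidates(
    per_seed_lists: dict[tuple[str, str], list[tuple[str, float]]],
    seed_set: set[str],
    min_seeds: int = DEFAULT_MIN_SEEDS,
) -> list[CandidateRecord]:
    """Merge per-(seed, dataset) hit lists into candidate records.

    Keys of ``per_seed_lists`` are (seed, dataset_id).  A gene qualifies
    when its supports span >= ``min_seeds`` distinct seeds over the union of
    all datasets; seed genes themselves never qualify.  Records are sorted
    by (n_seeds descending, gene ascending).
    """
    if min_seeds < 1:
        raise ValueError(f"min_seeds must be >= 1, got {min_seeds}")
    supports: dict[str, list[Support]] = {}
    for (seed, dataset_id) in sorted(per_seed_lists):
        for gene, rho in per_seed_lists[(seed, dataset_id)]:
            if gene in seed_set:
                continue
            supports.setdefault(gene, []).append(
                Support(seed=seed, dataset_id=dataset_id, rho=rho)
            )
    records = [
        CandidateRecord(gene=g, supports=sup)
        for g, sup in supports.items()
        if len({s.seed for s in sup}) >= min_seeds
    ]
    records.sort(key=lambda r: (-r.n_seeds, r.gene))
    return records


def group_by_seed_signature(
    records: list[CandidateRecord],
) -> dict[tuple[str, ...], dict]:
    """Group candidates by their sorted seed signature.

    Groups get letter labels a, b, c, ... (then aa, ab, ...) in order of
    first appearance under the record sort order.
    """
    groups: dict[tuple[str, ...], dict] = {}
    for rec in records:
        sig = rec.seed_signature
        if sig not in groups:
            groups[sig] = {"label": _letter_label(len(groups)), "genes": []}
        groups[sig]["genes"].append(rec.gene)
    return groups


def _letter_label(i: int) -> str:
    letters = string.ascii_lowercase
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = letters[rem] + label
    return label


def core_seed_summary(
    records: list[CandidateRecord],
    named_subsets: dict[str, set[str]] | None = None,
) -> dict:
    """Per-seed candidate counts, plus counts for named seed subsets.

    ``per_seed[s]`` counts candidates whose signature contains seed ``s``;
    ``subset_counts[name]`` counts candidates whose signature contains every
    member of the named subset (e.g. the Eya1/Notch1/Six3 core).
    """
    per_seed: dict[str, int] = {}
    for rec in records:
        for seed in rec.seed_signature:
            per_seed[seed] = per_seed.get(seed, 0) + 1
    subset_counts: dict[str, int] = {}
    for name, subset in (named_subsets or {}).items():
        subset_counts[name] = sum(
            1 for rec in records if subset <= set(rec.seed_signature)
        )
    return {"per_seed": per_seed, "subset_counts": subset_counts}
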