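"""Projection of the fly seed network onto mouse symbols and extraction of
the correlation-supported seed network (ESN) across expression datasets.

For each dataset, *all* pairs among the projected seed genes are screened —
not only pairs that realize a fly edge — because correlated paralog pairs
(e.g. Eya2-Eya3) are part of the extracted network even without a fly
counterpart.  Per-(gene, dataset) presence is tracked with three statuses:

- ``present_correlated``   gene has >=1 passing edge in that dataset
- ``present_uncorrelated`` gene is in the dataset but no edge passes
- ``absent``               gene is not measured in that dataset
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .correlation import (
    DEFAULT_MIN_PAIRS,
    DEFAULT_THRESHOLD,
    CorrelationEdge,
    pairwise_correlations,
)
from .datasets import ExpressionDataset, HomologMap, SeedNetworkSpec

logger = logging.getLogger(__name__)

__all__ = [
    "PRESENT_CORRELATED",
    "PRESENT_UNCORRELATED",
    "ABSENT",
    "ProjectedEdge",
    "ExtractedSeedNetwork",
    "FlyEdgeReport",
    "project_homologs",
    "extract_esn",
    "compare_to_fly",
]

PRESENT_CORRELATED = "present_correlated"
PRESENT_UNCORRELATED = "present_uncorrelated"
ABSENT = "absent"


@dataclass(frozen=True)
class ProjectedEdge:
    """A mouse gene pair realizing one fly seed-network edge."""

    mouse_a: str
    mouse_b: str
    sign: int
    fly_a: str
    fly_b: str

    @property
    def pair(self) -> tuple[str, str]:
        a, b = self.mouse_a, self.mouse_b
        return (a, b) if a <= b else (b, a)

    @property
    def fly_pair(self) -> tuple[str, str]:
        a, b = self.fly_a, self.fly_b
        return (a, b) if a <= b else (b, a)


@dataclass
class ExtractedSeedNetwork:
    seed_genes: set[str]
    presence: dict[tuple[str, str], str]  # (gene, dataset_id) -> status
    edges: list[CorrelationEdge]
    fly_support: dict[tuple[str, str], list[CorrelationEdge]] = field(
        default_factory=dict
    )
    threshold: float = DEFAULT_THRESHOLD

    def edges_in(self, dataset_id: str) -> list[CorrelationEdge]:
        return [e for e in self.edges if e.dataset_id == dataset_id]

    def correlated_seeds(self) -> set[str]:
        """Seed genes with >=1 passing edge in >=1 dataset (ESN node set).

        These are the query seeds for candidate generation; seeds that never
        correlate stay in presence reports but are not queried.
        """
        out: set[str] = set()
        for e in self.edges:
            out.add(e.gene_a)
            out.add(e.gene_b)
        return out

    def dataset_ids(self) -> list[str]:
        return sorted({d for (_, d) in self.presence})


def project_homologs(
    spec: SeedNetworkSpec, homologs: HomologMap
) -> tuple[set[str], list[ProjectedEdge]]:
    """Expand each fly edge to the cross product of its endpoints' homologs.

    Self-pairs arising from shared homologs (toy and ey both map to Pax6)
    are dropped.  Returns the merged mouse seed set and the projected edges,
    each tagged with its originating fly edge.
    """
    missing = sorted(n for n in spec.fly_nodes if n not in homologs)
    if missing:
        raise KeyError(f"fly node(s) missing from homolog map: {', '.join(missing)}")
    seed_set: set[str] = set()
    for fly in spec.fly_nodes:
        seed_set |= homologs[fly]
    projected: list[ProjectedEdge] = []
    for a, b, sign in spec.fly_edges:
        for ma in sorted(homologs[a]):
            for mb in sorted(homologs[b]):
                if ma == mb:
                    continue
                projected.append(
                    ProjectedEdge(mouse_a=ma, mouse_b=mb, sign=sign, fly_a=a, fly_b=b)
                )
    return seed_set, projected


def extract_esn(
    datasets: list[ExpressionDataset],
    seed_genes: set[str],
    threshold: float = DEFAULT_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    strict: bool = False,
    projected: list[ProjectedEdge] | None = None,
) -> ExtractedSeedNetwork:
    """Screen all seed-gene pairs in every dataset at |rho| >= threshold.

    When ``projected`` edges are supplied, each passing mouse edge is also
    indexed by the fly edge(s) it realizes (for the conservation report).
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    ids = [d.dataset_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError("dataset_id values must be unique")

    presence: dict[tuple[str, str], str] = {}
    all_edges: list[CorrelationEdge] = []
    for ds in sorted(datasets, key=lambda d: d.dataset_id):
        edges = pairwise_correlations(
            ds, seed_genes, seed_genes, threshold=threshold,
            min_pairs=min_pairs, strict=strict,
        )
        all_edges.extend(edges)
        touched = {g for e in edges for g in e.pair}
        for g in sorted(seed_genes):
            if g not in ds:
                presence[(g, ds.dataset_id)] = ABSENT
            elif g in touched:
                presence[(g, ds.dataset_id)] = PRESENT_CORRELATED
            else:
                presence[(g, ds.dataset_id)] = PRESENT_UNCORRELATED

    fly_support: dict[tuple[str, str], list[CorrelationEdge]] = {}
    if projected is not None:
        by_pair: dict[tuple[str, str], list[CorrelationEdge]] = {}
        for e in all_edges:
            by_pair.setdefault(e.pair, []).append(e)
        for pe in projected:
            fly_support.setdefault(pe.fly_pair, [])
            for e in by_pair.get(pe.pair, []):
                if e not in fly_support[pe.fly_pair]:
                    fly_support[pe.fly_pair].append(e)

    return ExtractedSeedNetwork(
        seed_genes=set(seed_genes),
        presence=presence,
        edges=all_edges,
        fly_support=fly_support,
        threshold=threshold,
    )


SUPPORTED = "supported"
UNSUPPORTED = "unsupported"
UNTESTABLE = "untestable"


@dataclass(frozen=True)
class FlyEdgeReport:
    fly_a: str
    fly_b: str
    fly_sign: int
    status: str  # supported | unsupported | untestable
    n_mouse_edges: int
    sign_agreement: bool | None  # None unless supported
    sign_conflict: bool  # supporting edges disagree in sign across datasets


def compare_to_fly(
    esn: ExtractedSeedNetwork,
    spec: SeedNetworkSpec,
    homologs: HomologMap,
) -> list[FlyEdgeReport]:
    """Classify each fly edge as supported / unsupported / untestable.

    Supported: >=1 realizing mouse edge in >=1 dataset, with a flag for
    whether any realizing edge's rho sign matches the fly sign.  Untestable:
    one endpoint's entire homolog set is absent from every dataset.
    """
    dataset_ids = esn.dataset_ids()

    def ever_present(gene: str) -> bool:
        return any(
            esn.presence.get((gene, d)) in (PRESENT_CORRELATED, PRESENT_UNCORRELATED)
            for d in dataset_ids
        )

    reports: list[FlyEdgeReport] = []
    for a, b, sign in spec.fly_edges:
        key = (min(a, b), max(a, b))
        support = esn.fly_support.get(key, [])
        if support:
            signs = {e.sign for e in support}
            reports.append(
                FlyEdgeReport(
                    fly_a=key[0], fly_b=key[1], fly_sign=sign,
                    status=SUPPORTED,
                    n_mouse_edges=len(support),
                    sign_agreement=sign in signs,
                    sign_conflict=len(signs) > 1,
                )
            )
            continue
        a_testable = any(ever_present(m) for m in homologs[a]) if a in homologs else False
        b_testable = any(ever_present(m) for m in homologs[b]) if b in homologs else False
        status = UNSUPPORTED if (a_testable and b_testable) else UNTESTABLE
        reports.append(
            FlyEdgeReport(
                fly_a=key[0], fly_b=key[1], fly_sign=sign,
                status=status, n_mouse_edges=0,
                sign_agreement=None, sign_conflict=False,
            )
        )
    return reports
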