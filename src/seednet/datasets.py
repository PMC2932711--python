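"""Readers, writers and domain types for expression matrices, homolog maps,
seed networks and annotation sets.

All tabular formats are plain TSV (UTF-8, tab-delimited, ``.`` decimal, no
quoting).  Gene symbols are canonicalized through a :class:`SymbolRegistry`
so that case variants and known synonyms collapse onto one symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SymbolRegistry",
    "ExpressionDataset",
    "HomologMap",
    "SeedNetworkSpec",
    "AnnotationSet",
    "normalize_symbol",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_homolog_map",
    "read_seed_network",
    "read_annotation_table",
    "write_network_sif",
    "default_synonyms",
    "packaged_homolog_map_path",
    "packaged_seed_network_path",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# symbol canonicalization


def default_synonyms() -> dict[str, str]:
    """Synonym table shipped with the package (alternate -> canonical)."""
    table = {}
    path = resources.files("seednet.data").joinpath("synonyms.tsv")
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            alt, canon = line.split("\t")[:2]
            table[alt.strip().casefold()] = canon.strip()
    return table


class SymbolRegistry:
    """Case-insensitive gene symbol canonicalizer with a synonym table.

    The first-seen casing of a symbol becomes the canonical spelling for all
    later case variants.  Synonyms are resolved before casing.
    """

    def __init__(self, synonyms: Mapping[str, str] | None = None):
        if synonyms is None:
            synonyms = default_synonyms()
        self._synonyms = {k.casefold(): v for k, v in synonyms.items()}
        self._canonical: dict[str, str] = {}

    def normalize(self, raw: str) -> str:
        if raw is None:
            raise ValueError("gene symbol must not be None")
        s = str(raw).strip()
        if not s:
            raise ValueError("gene symbol is empty or whitespace-only")
        s = self._synonyms.get(s.casefold(), s)
        key = s.casefold()
        if key not in self._canonical:
            self._canonical[key] = s
        return self._canonical[key]

    def normalize_all(self, symbols: Iterable[str]) -> list[str]:
        return [self.normalize(s) for s in symbols]


def normalize_symbol(raw: str, registry: SymbolRegistry | None = None) -> str:
    """Canonicalize one symbol; a fresh registry applies only synonyms."""
    if registry is None:
        registry = SymbolRegistry()
    return registry.normalize(raw)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ExpressionDataset:
    """One platform's genes x time-points measurement matrix.

    ``values`` is a float matrix with NaN for missing cells; rows follow
    ``genes``, columns follow ``conditions``.
    """

    dataset_id: str
    platform: str  # "count" | "continuous"
    genes: list[str]
    conditions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.platform not in ("count", "continuous"):
            raise ValueError(f"unknown platform tag {self.platform!r}")
        if len(self.conditions) < 2:
            raise FormatError(
                f"dataset {self.dataset_id!r}: need >=2 conditions, "
                f"got {len(self.conditions)}"
            )
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError(
                f"dataset {self.dataset_id!r}: matrix shape {self.values.shape} "
                f"does not match {len(self.genes)} genes x "
                f"{len(self.conditions)} conditions"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"dataset {self.dataset_id!r}: duplicate gene symbols")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.conditions)


@dataclass
class HomologMap:
    """Fly symbol -> set of canonical mouse symbols (one-to-many allowed)."""

    entries: dict[str, set[str]]
    synonym_table: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fly, mice in self.entries.items():
            if not mice:
                raise ValueError(f"fly gene {fly!r} maps to no mouse symbols")

    def mouse_symbols(self) -> set[str]:
        out: set[str] = set()
        for mice in self.entries.values():
            out |= mice
        return out

    def __getitem__(self, fly: str) -> set[str]:
        return self.entries[fly]

    def __contains__(self, fly: str) -> bool:
        return fly in self.entries


@dataclass
class SeedNetworkSpec:
    """Signed, undirected literature-curated edges among fly genes."""

    fly_nodes: set[str]
    fly_edges: list[tuple[str, str, int]]
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for a, b, sign in self.fly_edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if sign not in (1, -1):
                raise ValueError(f"edge ({a}, {b}): sign must be +1 or -1")
            if a not in self.fly_nodes or b not in self.fly_nodes:
                raise ValueError(f"edge ({a}, {b}): endpoint not in fly_nodes")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)


@dataclass
class AnnotationSet:
    """An annotation term with either explicit membership or counts only."""

    term_id: str
    universe_size: int
    annotated_size: int
    annotated_genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise ValueError("universe_size must be positive")
        if self.annotated_size < 0 or self.annotated_size > self.universe_size:
            raise ValueError("annotated_size must be in [0, universe_size]")
        if self.annotated_genes is not None:
            self.annotated_genes = frozenset(self.annotated_genes)
            if len(self.annotated_genes) != self.annotated_size:
                raise ValueError(
                    "annotated_genes inconsistent with annotated_size"
                )


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path: str | Path,
    dataset_id: str,
    platform: str,
    registry: SymbolRegistry | None = None,
) -> ExpressionDataset:
    """Read a genes x conditions TSV into an :class:`ExpressionDataset`.

    Header row carries condition labels (first cell blank or "gene"); one row
    per gene.  Empty cells become NaN.  Rows sharing a canonical symbol are
    collapsed to a single row by per-condition median, ignoring NaN.
    """
    path = Path(path)
    if registry is None:
        registry = SymbolRegistry()
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    conditions = [c.strip() for c in header[1:]]
    if len(conditions) < 2:
        raise FormatError(f"{path}: need >=2 condition columns, got {len(conditions)}")

    symbols: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        sym = registry.normalize(cells[0])
        vals = cells[1:]
        if len(vals) != len(conditions):
            raise FormatError(
                f"{path}:{lineno}: expected {len(conditions)} value cells, "
                f"got {len(vals)}"
            )
        parsed: list[float] = []
        for j, cell in enumerate(vals):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} for gene "
                    f"{sym!r}, column {conditions[j]!r}"
                ) from exc
        symbols.append(sym)
        rows.append(parsed)

    if not symbols:
        logger.warning("%s: header-only expression matrix (0 genes)", path)
        values = np.empty((0, len(conditions)))
        return ExpressionDataset(dataset_id, platform, [], conditions, values)

    frame = pd.DataFrame(rows, index=symbols, columns=conditions, dtype=float)
    if frame.index.has_duplicates:
        dup = sorted(set(frame.index[frame.index.duplicated()]))
        logger.info(
            "%s: collapsing %d duplicated symbol(s) by per-condition median: %s",
            path, len(dup), ", ".join(dup[:10]),
        )
        frame = frame.groupby(level=0, sort=True).median()
    # lexicographic row order makes the result independent of input row order
    frame = frame.sort_index(kind="stable")
    genes = list(frame.index)
    return ExpressionDataset(dataset_id, platform, genes, conditions, frame.to_numpy())


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset back to the TSV dialect read_expression_matrix accepts."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(dataset.conditions) + "\n")
        for gene, row in zip(dataset.genes, dataset.values):
            cells = [gene]
            for v in row:
                cells.append("" if np.isnan(v) else repr(float(v)))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# homolog map / seed network / annotations


def _split_mouse_field(field_text: str) -> list[str]:
    out = []
    for part in field_text.replace("/", ",").split(","):
        part = part.strip()
        if part:
            out.append(part)
    return out


def read_homolog_map(
    path: str | Path, registry: SymbolRegistry | None = None
) -> HomologMap:
    """Read a 2-column TSV: fly symbol, comma- or slash-separated mouse symbols."""
    path = Path(path)
    if registry is None:
        registry = SymbolRegistry()
    entries: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if lineno == 1 and cells[0].strip().casefold() in ("fly", "fly_gene"):
                continue
            if len(cells) < 2 or not cells[1].strip():
                raise FormatError(
                    f"{path}:{lineno}: fly symbol {cells[0]!r} has empty mouse field"
                )
            fly = registry.normalize(cells[0])
            mice = {registry.normalize(m) for m in _split_mouse_field(cells[1])}
            if fly in entries:
                logger.warning(
                    "%s:%d: duplicate fly symbol %r, merging mouse sets",
                    path, lineno, fly,
                )
                entries[fly] |= mice
            else:
                entries[fly] = mice
    return HomologMap(entries=entries, synonym_table=dict(registry._synonyms))


def read_seed_network(
    path: str | Path, registry: SymbolRegistry | None = None
) -> SeedNetworkSpec:
    """Read a 3-column TSV (gene_a, gene_b, sign as +/-/+1/-1[, provenance])."""
    path = Path(path)
    if registry is None:
        registry = SymbolRegistry()
    nodes: set[str] = set()
    edges: list[tuple[str, str, int]] = []
    provenance: dict[tuple[str, str], str] = {}
    sign_map = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1, "−": -1, "−1": -1}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if lineno == 1 and cells[0].strip().casefold() in ("gene_a", "gene a"):
                continue
            if len(cells) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            a = registry.normalize(cells[0])
            b = registry.normalize(cells[1])
            raw_sign = cells[2].strip()
            if raw_sign not in sign_map:
                raise FormatError(f"{path}:{lineno}: bad sign {raw_sign!r}")
            edges.append((a, b, sign_map[raw_sign]))
            nodes.add(a)
            nodes.add(b)
            if len(cells) > 3 and cells[3].strip():
                provenance[(min(a, b), max(a, b))] = cells[3].strip()
    return SeedNetworkSpec(fly_nodes=nodes, fly_edges=edges, provenance=provenance)


def read_annotation_table(
    path: str | Path, registry: SymbolRegistry | None = None
) -> dict[str, set[str]]:
    """Read a 2-column TSV (gene, term) into term -> gene-set mapping."""
    path = Path(path)
    if registry is None:
        registry = SymbolRegistry()
    terms: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if lineno == 1 and cells[0].strip().casefold() == "gene":
                continue
            if len(cells) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            gene = registry.normalize(cells[0])
            term = cells[1].strip()
            terms.setdefault(term, set()).add(gene)
    return terms


# ---------------------------------------------------------------------------
# network export


def write_network_sif(edges: Sequence, path: str | Path) -> None:
    """Write signed scored edges as SIF plus a companion score TSV.

    ``edges`` holds objects with gene_a, gene_b, rho, dataset_id attributes
    (see :class:`seednet.correlation.CorrelationEdge`).  The SIF relation is
    "pos" for rho >= 0 and "neg" otherwise.  The companion file is written
    next to ``path`` with suffix ``.scores.tsv``.
    """
    path = Path(path)
    scores_path = path.with_suffix(path.suffix + ".scores.tsv")
    with path.open("w", encoding="utf-8") as fh:
        for e in edges:
            rel = "pos" if e.rho >= 0 else "neg"
            fh.write(f"{e.gene_a} {rel} {e.gene_b}\n")
    with scores_path.open("w", encoding="utf-8") as fh:
        if edges:
            fh.write("gene_a\tgene_b\tdataset_id\trho\n")
            for e in edges:
                fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.dataset_id}\t{e.rho:.6g}\n")


# ---------------------------------------------------------------------------
# packaged reference inputs


def packaged_homolog_map_path() -> Path:
    return Path(str(resources.files("seednet.data").joinpath("homologs_fly_mouse.tsv")))


def packaged_seed_network_path() -> Path:
    return Path(str(resources.files("seednet.data").joinpath("fly_seed_network.tsv")))
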