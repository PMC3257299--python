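"""Domain types and strict TSV readers/writers for expression data.

All files are UTF-8, tab-delimited, "." decimal point, no quoting dialect.
The readers are deliberately strict — ragged rows, duplicated identifiers and
non-numeric cells are errors, never silently imputed — because the round-trip
``write -> read`` must be an identity on valid data.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class Site(enum.Enum):
    """Microarray facility; the study ran the foundational lines at two."""

    SITE_A = "SITE_A"
    SITE_B = "SITE_B"


class Treatment(enum.Enum):
    """Growth-medium treatment for hormone-transfer experiments."""

    NONE = "NONE"
    MS = "MS"
    IAA = "IAA"
    ACC = "ACC"


class GeneClass(enum.Enum):
    """Core-gene class: preferentially expressed in hair or non-hair cells."""

    HAIR = "HAIR"
    NONHAIR = "NONHAIR"


class Sign(enum.Enum):
    POS = "POS"
    NEG = "NEG"
    NA = "NA"


@dataclass(frozen=True)
class Sample:
    """One microarray sample.

    ``genotype`` is the set of knocked-out gene ids; empty means wild type.
    Genes knocked out but absent from the paired expression matrix are legal
    (mutated genes need not be on the chip) and are flagged at join time.
    """

    sample_id: str
    genotype: frozenset[str]
    site: Site
    replicate: int
    treatment: Treatment = Treatment.NONE

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate must be >= 1, "
                f"got {self.replicate}"
            )

    @property
    def is_wild_type(self) -> bool:
        return not self.genotype


@dataclass
class ExpressionMatrix:
    """Dense log2 expression values, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.sum(~np.isfinite(self.values)))
            raise ValueError(f"expression matrix contains {bad} non-finite values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self._gene_index[gene_id]]

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Column submatrix in the requested order; unknown ids raise KeyError."""
        try:
            cols = [self._sample_index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None
        return self.values[:, cols]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        rows = [self._gene_index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids),
                                self.values[rows].copy())

    def join(self, samples: Iterable[Sample]) -> dict[str, Sample]:
        """Join a sample sheet to this matrix, bijectively on sample_id.

        Returns sample_id -> Sample.  Also returns nothing for, but raises on,
        samples present on one side only — the join must be total.  Knockout
        genes absent from ``gene_ids`` are tolerated (flagged external).
        """
        by_id = {}
        for s in samples:
            if s.sample_id in by_id:
                raise ValueError(f"duplicate sample id in sheet: {s.sample_id!r}")
            by_id[s.sample_id] = s
        sheet_only = sorted(set(by_id) - set(self.sample_ids))
        matrix_only = sorted(set(self.sample_ids) - set(by_id))
        if sheet_only or matrix_only:
            raise ValueError(
                "sample sheet and expression matrix disagree; "
                f"sheet-only={sheet_only}, matrix-only={matrix_only}"
            )
        return by_id

    def external_knockouts(self, samples: Iterable[Sample]) -> set[str]:
        """Knocked-out genes not measured on the chip."""
        genes = set(self.gene_ids)
        out: set[str] = set()
        for s in samples:
            out |= set(s.genotype) - genes
        return out


@dataclass
class GeneSet:
    """Partition of core genes into HAIR and NONHAIR classes."""

    members: dict[str, GeneClass] = field(default_factory=dict)

    def genes(self, cls: GeneClass | None = None) -> set[str]:
        if cls is None:
            return set(self.members)
        return {g for g, c in self.members.items() if c is cls}

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    support: float
    sign: Sign = Sign.NA

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-edge not allowed: {self.source!r}")
        if not 0.0 <= self.support <= 1.0:
            raise ValueError(f"support must be in [0,1], got {self.support}")


@dataclass
class EdgeList:
    """Directed edges with consensus support fractions."""

    edges: list[Edge] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)

    def as_pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


def _split_strict(line: str, path: Path, lineno: int) -> list[str]:
    if "\r" in line:
        line = line.rstrip("\r")
    return line.split("\t")


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples log2 table.

    First column holds gene ids, header row holds sample ids.  Ragged rows,
    duplicate ids and non-numeric cells (including "NA") are errors naming
    the offending line or id.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise ValueError(f"{path}: empty file")
        cells = _split_strict(header.rstrip("\n"), path, 1)
        sample_ids = cells[1:]
        ncol = len(cells)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=2):
            cells = _split_strict(raw.rstrip("\n"), path, lineno)
            if len(cells) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: ragged row, {len(cells)} fields, "
                    f"expected {ncol}"
                )
            gene_ids.append(cells[0])
            try:
                row = [float(c) for c in cells[1:]]
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric expression value in row "
                    f"{cells[0]!r}"
                ) from None
            if not all(math.isfinite(v) for v in row):
                raise ValueError(
                    f"{path}:{lineno}: non-finite expression value in row "
                    f"{cells[0]!r}"
                )
            rows.append(row)
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# sample sheets

_SHEET_COLUMNS = ["sample_id", "genotype", "site", "replicate", "treatment"]


def read_sample_sheet(path: str | Path) -> list[Sample]:
    """Read a sample sheet; genotype field is semicolon-joined gene ids."""
    path = Path(path)
    samples: list[Sample] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = _split_strict(fh.readline().rstrip("\n"), path, 1)
        if header != _SHEET_COLUMNS:
            raise ValueError(
                f"{path}: expected header {_SHEET_COLUMNS}, got {header}"
            )
        for lineno, raw in enumerate(fh, start=2):
            cells = _split_strict(raw.rstrip("\n"), path, lineno)
            if len(cells) != len(_SHEET_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: ragged row, {len(cells)} fields"
                )
            sid, geno, site, rep, treat = cells
            if sid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            seen.add(sid)
            genotype = frozenset(g for g in geno.split(";") if g)
            try:
                samples.append(
                    Sample(sid, genotype, Site(site), int(rep), Treatment(treat))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return samples


def write_sample_sheet(samples: Sequence[Sample], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_SHEET_COLUMNS) + "\n")
        for s in samples:
            fh.write(
                "\t".join(
                    [
                        s.sample_id,
                        ";".join(sorted(s.genotype)),
                        s.site.value,
                        str(s.replicate),
                        s.treatment.value,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene sets


def read_gene_set(path: str | Path) -> GeneSet:
    path = Path(path)
    members: dict[str, GeneClass] = {}
    with open(path, encoding="utf-8") as fh:
        header = _split_strict(fh.readline().rstrip("\n"), path, 1)
        if header != ["gene_id", "gene_class"]:
            raise ValueError(f"{path}: expected header gene_id/gene_class")
        for lineno, raw in enumerate(fh, start=2):
            gene, cls = _split_strict(raw.rstrip("\n"), path, lineno)
            if gene in members:
                raise ValueError(f"{path}:{lineno}: duplicate gene {gene!r}")
            members[gene] = GeneClass(cls)
    return GeneSet(members)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tgene_class\n")
        for gene in sorted(gene_set.members):
            fh.write(f"{gene}\t{gene_set.members[gene].value}\n")


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path: str | Path) -> EdgeList:
    path = Path(path)
    edges: list[Edge] = []
    with open(path, encoding="utf-8") as fh:
        header = _split_strict(fh.readline().rstrip("\n"), path, 1)
        if header != ["from", "to", "support", "sign"]:
            raise ValueError(f"{path}: expected header from/to/support/sign")
        for lineno, raw in enumerate(fh, start=2):
            src, dst, support, sign = _split_strict(raw.rstrip("\n"), path, lineno)
            edges.append(Edge(src, dst, float(support), Sign(sign)))
    return EdgeList(edges)


def write_edge_list(net: EdgeList, path: str | Path, fmt: str = "tsv") -> None:
    """Write an edge list as TSV (default), GraphML or DOT.

    All three carry identical edge content; TSV is the round-trip format.
    """
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("from\tto\tsupport\tsign\n")
            for e in net.edges:
                fh.write(f"{e.source}\t{e.target}\t{repr(e.support)}\t{e.sign.value}\n")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        for e in net.edges:
            g.add_edge(e.source, e.target, support=e.support, sign=e.sign.value)
        nx.write_graphml(g, path)
    elif fmt == "dot":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("digraph consensus {\n")
            for e in net.edges:
                fh.write(
                    f'  "{e.source}" -> "{e.target}" '
                    f'[support={e.support:.3f}, sign={e.sign.value}];\n'
                )
            fh.write("}\n")
    else:
        raise ValueError(f"unknown edge-list format {fmt!r}")
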