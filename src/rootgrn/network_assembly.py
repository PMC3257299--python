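"""Perturbation signatures, regulatory clusters, and analysis utilities.

A gene's perturbation signature is its UP/DOWN/NONE response across the
mutant and hormone comparisons (fold change and q-value gated, with a
stricter FDR gate for the hormone treatments).  Regulatory clusters group
genes sharing an identical signature over a configured perturbation subset
*and* the same collapsed temporal zone; a gene is "robust" when it responds
in at least six perturbations of the downstream-mutant panel.

The module also houses the screen's supporting analyses: one-sided Fisher
exact overrepresentation, classical (Torgerson) MDS of samples, and an
IUPAC consensus scan of promoter windows for the root-hair element.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from rootgrn.core_data import ExpressionMatrix
from rootgrn.differential_expression import SamResult
from rootgrn.temporal_zones import CollapsedZone, ZoneAssignment


class Response(enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    NONE = "NONE"


@dataclass
class PerturbationSignature:
    gene_ids: list[str]
    perturbations: list[str]
    responses: dict[str, dict[str, Response]]  # gene -> perturbation -> call
    fc_min: float
    q_max: float
    hormone_q_max: float

    def of(self, gene_id: str, perturbation: str) -> Response:
        return self.responses[gene_id][perturbation]

    def tuple_over(
        self, gene_id: str, subset: Sequence[str]
    ) -> tuple[str, ...]:
        return tuple(self.responses[gene_id][p].value for p in subset)

    def restrict(self, genes: Iterable[str]) -> "PerturbationSignature":
        """Signature over a gene subset (e.g. the core set before
        clustering, which needs a zone for every gene)."""
        keep = [g for g in self.gene_ids if g in set(genes)]
        return PerturbationSignature(
            gene_ids=keep,
            perturbations=list(self.perturbations),
            responses={g: dict(self.responses[g]) for g in keep},
            fc_min=self.fc_min,
            q_max=self.q_max,
            hormone_q_max=self.hormone_q_max,
        )


def perturbation_signature(
    sam_results: Mapping[str, SamResult],
    fc_min: float = 2.0,
    q_max: float = 0.05,
    hormone_perturbations: Iterable[str] = (),
    hormone_fc_min: float = 2.0,
    hormone_q_max: float = 0.005,
) -> PerturbationSignature:
    """Call UP/DOWN/NONE per gene and perturbation.

    UP: fc >= fc_min and q < q_max; DOWN: fc <= 1/fc_min and q < q_max.
    Hormone comparisons (named in ``hormone_perturbations``) use the
    stricter hormone thresholds (default >2-fold at 0.5% FDR).
    """
    if not sam_results:
        raise ValueError("no perturbation comparisons supplied")
    hormones = set(hormone_perturbations)
    universes = {p: set(r.gene_ids) for p, r in sam_results.items()}
    first = next(iter(universes.values()))
    for p, u in universes.items():
        if u != first:
            raise ValueError(
                f"perturbation {p!r} covers a different gene universe; "
                f"symmetric difference {sorted(u ^ first)}"
            )
    responses: dict[str, dict[str, Response]] = {g: {} for g in first}
    for pert, res in sam_results.items():
        if res.q is None:
            raise ValueError(f"perturbation {pert!r} lacks q-values")
        f_min = hormone_fc_min if pert in hormones else fc_min
        q_lim = hormone_q_max if pert in hormones else q_max
        for g, fc, q in zip(res.gene_ids, res.fc, res.q):
            if q < q_lim and fc >= f_min:
                call = Response.UP
            elif q < q_lim and fc <= 1.0 / f_min:
                call = Response.DOWN
            else:
                call = Response.NONE
            responses[g][pert] = call
    return PerturbationSignature(
        gene_ids=sorted(first),
        perturbations=sorted(sam_results),
        responses=responses,
        fc_min=fc_min,
        q_max=q_max,
        hormone_q_max=hormone_q_max,
    )


@dataclass
class RegulatoryCluster:
    cluster_id: str
    members: list[str]
    shared_signature: dict[str, Response]
    collapsed_zone: CollapsedZone
    robust_flag: bool  # every member affected in >= robust_min of the panel

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have members")


def build_clusters(
    sig: PerturbationSignature,
    zones: ZoneAssignment,
    downstream_panel: Iterable[str],
    perturbation_subset: Sequence[str] | None = None,
    robust_min: int = 6,
) -> list[RegulatoryCluster]:
    """Partition genes by (signature over the subset, collapsed zone).

    The partition is exact: every gene lands in exactly one cluster.  The
    subset defaults to all perturbations; the published model derives its
    clusters from the regulatory-position comparisons only, so callers pass
    the relevant subset.  ``robust_flag`` is true when every member responds
    (non-NONE) in at least ``robust_min`` panel perturbations.
    """
    subset = list(perturbation_subset or sig.perturbations)
    panel = [p for p in downstream_panel]
    unknown = set(subset + panel) - set(sig.perturbations)
    if unknown:
        raise ValueError(f"unknown perturbations {sorted(unknown)}")
    if zones.collapsed is None:
        raise ValueError("zones must be collapsed before clustering")
    missing = set(sig.gene_ids) - set(zones.gene_ids)
    if missing:
        raise ValueError(f"genes without zone assignment: {sorted(missing)}")

    groups: dict[tuple[tuple[str, ...], str], list[str]] = {}
    for g in sig.gene_ids:
        key = (sig.tuple_over(g, subset), zones.collapsed_of(g).value)
        groups.setdefault(key, []).append(g)

    def robust(g: str) -> bool:
        n_hit = sum(1 for p in panel if sig.responses[g][p] is not Response.NONE)
        return n_hit >= robust_min

    clusters = []
    for i, (key, members) in enumerate(sorted(groups.items())):
        signature, zone = key
        clusters.append(
            RegulatoryCluster(
                cluster_id=f"C{i + 1:02d}",
                members=sorted(members),
                shared_signature={
                    p: Response(v) for p, v in zip(subset, signature)
                },
                collapsed_zone=CollapsedZone(zone),
                robust_flag=all(robust(g) for g in members),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# enrichment


def fisher_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided (overrepresentation) Fisher exact test per annotation term.

    Annotation gene sets are intersected with the universe.  Returns a frame
    sorted by raw p with a Benjamini-Hochberg column alongside.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    big_n, n = len(universe), len(selected)
    rows = []
    for term, genes in annotations.items():
        term_genes = set(genes) & universe
        big_k = len(term_genes)
        k = len(term_genes & selected)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((term, k, n, big_k, big_n, min(p, 1.0)))
    frame = pd.DataFrame(
        rows, columns=["term", "k", "n_selected", "term_size", "universe", "p"]
    ).sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    m = len(frame)
    if m:
        ranked = frame["p"].to_numpy() * m / np.arange(1, m + 1)
        frame["p_bh"] = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    else:
        frame["p_bh"] = []
    return frame


# ---------------------------------------------------------------------------
# classical MDS


def classical_mds(
    expr: ExpressionMatrix | np.ndarray, dim: int = 2
) -> np.ndarray:
    """Torgerson MDS of samples from Euclidean sample-sample distances.

    Accepts an expression matrix (samples are columns) or a square distance
    matrix.  Coordinates are the top-``dim`` eigenvectors of the
    double-centred Gram matrix scaled by sqrt(eigenvalue); each axis's sign
    is fixed so its largest-magnitude coordinate is positive.
    """
    if isinstance(expr, ExpressionMatrix):
        pts = expr.values.T  # samples x genes
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
    else:
        d = np.asarray(expr, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
    n = d.shape[0]
    if n < dim + 1:
        raise ValueError(f"need at least dim+1={dim + 1} samples, have {n}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.sum(vals > 1e-9 * max(vals.max(), 1.0)) < dim:
        raise ValueError(
            f"only {int(np.sum(vals > 0))} positive eigenvalues; cannot embed "
            f"in {dim} dimensions"
        )
    coords = vecs[:, :dim] * np.sqrt(np.maximum(vals[:dim], 0.0))
    for a in range(dim):
        i = int(np.argmax(np.abs(coords[:, a])))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    return coords


# ---------------------------------------------------------------------------
# promoter motif scan

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class MotifHit:
    position: int  # 1 kb window, 1-based relative to translation start (< 0)
    strand: str  # "+" or "-"


@dataclass
class ScanResult:
    hits: dict[str, list[MotifHit]] = field(default_factory=dict)

    def count(self, gene_id: str) -> int:
        return len(self.hits.get(gene_id, []))

    def genes_with_hit(self) -> set[str]:
        return {g for g, h in self.hits.items() if h}


def _iupac_regex(consensus: str) -> re.Pattern:
    parts = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in consensus")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping matches are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def rhe_scan(
    promoters: str | Path | Mapping[str, str],
    consensus: str,
    window: int = 1000,
) -> ScanResult:
    """Scan the window-proximal upstream subsequence of each promoter for an
    IUPAC consensus, on both strands.

    Promoter sequences are upstream regions whose last base abuts the
    translation start; only the final ``window`` nt are scanned.  Match
    positions are 1-based relative to the translation start (upstream is
    negative, so a match ending at the start reports position -len(motif));
    reverse-strand matches are reported by their plus-strand start.
    """
    motif = _iupac_regex(consensus)
    m = len(consensus)
    if isinstance(promoters, (str, Path)):
        from Bio import SeqIO

        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(promoters), "fasta")
        }
    else:
        seqs = {k: v.upper() for k, v in promoters.items()}

    result = ScanResult()
    for gene, seq in seqs.items():
        if not seq:
            raise ValueError(f"empty promoter sequence for {gene!r}")
        sub = seq[-window:]
        w = len(sub)
        hits: list[MotifHit] = []
        for match in motif.finditer(sub):
            hits.append(MotifHit(position=match.start() - w, strand="+"))
        rc = sub.translate(_COMPLEMENT)[::-1]
        for match in motif.finditer(rc):
            j = match.start()
            plus_start = w - j - m
            if plus_start < 0:
                continue
            hits.append(MotifHit(position=plus_start - w, strand="-"))
        hits.sort(key=lambda h: (h.position, h.strand))
        result.hits[gene] = hits
    return result
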