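"""Developmental-zone assignment from longitudinal-section profiles.

Genes are clustered on their expression profiles over the ordered root
sections (two roots, 12 sections each, earliest developmental position
first) with average-linkage hierarchical clustering on correlation distance;
the tree is cut into six clusters which are relabelled Zone 1..6 by
ascending median peak section, so the zone number is a permutation-invariant
function of the data.  For network assembly the six zones collapse to three:
{1,2} -> EARLY, {3,4} -> MID, {5,6} -> LATE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


class CollapsedZone(enum.Enum):
    EARLY = "EARLY"
    MID = "MID"
    LATE = "LATE"


#: fixed 2-to-1 collapse map over six zones.
COLLAPSE_MAP = {
    1: CollapsedZone.EARLY,
    2: CollapsedZone.EARLY,
    3: CollapsedZone.MID,
    4: CollapsedZone.MID,
    5: CollapsedZone.LATE,
    6: CollapsedZone.LATE,
}


@dataclass
class ZoneAssignment:
    gene_ids: list[str]
    zone: np.ndarray  # 1..n_zones
    peak_section: np.ndarray  # 1..n_sections, argmax of root-averaged profile
    collapsed: list[CollapsedZone] | None = None

    def zone_of(self, gene_id: str) -> int:
        return int(self.zone[self.gene_ids.index(gene_id)])

    def collapsed_of(self, gene_id: str) -> CollapsedZone:
        if self.collapsed is None:
            raise ValueError("collapse_zones has not been applied")
        return self.collapsed[self.gene_ids.index(gene_id)]


def assign_zones(
    sections: np.ndarray,
    gene_ids: Sequence[str],
    n_zones: int = 6,
    n_roots: int = 2,
) -> ZoneAssignment:
    """Cluster genes into temporal zones from a genes x (roots*sections)
    profile matrix.

    The two roots are replicate column blocks: they are concatenated for
    clustering and averaged for the peak section (argmax; ties resolve to
    the earlier section).
    """
    sections = np.asarray(sections, dtype=float)
    n_genes, n_cols = sections.shape
    if n_cols % n_roots:
        raise ValueError(f"{n_cols} columns not divisible by {n_roots} roots")
    n_sec = n_cols // n_roots
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length does not match profile rows")
    distinct = np.unique(sections, axis=0).shape[0]
    if n_zones > distinct:
        raise ValueError(
            f"n_zones={n_zones} exceeds the {distinct} distinct profiles"
        )

    sd = sections.std(axis=1, ddof=0)
    z = (sections - sections.mean(axis=1, keepdims=True)) / np.where(
        sd > 0, sd, 1.0
    )[:, None]
    dist = pdist(z, metric="correlation")
    tree = linkage(dist, method="average")
    raw = fcluster(tree, t=n_zones, criterion="maxclust")

    per_root = sections.reshape(n_genes, n_roots, n_sec).mean(axis=1)
    peak = per_root.argmax(axis=1) + 1  # first occurrence = earlier section

    # relabel clusters 1..n_zones by ascending median peak section
    labels = np.unique(raw)
    med = {
        c: (np.median(peak[raw == c]), peak[raw == c].mean(), c) for c in labels
    }
    ordered = sorted(labels, key=lambda c: med[c])
    remap = {c: i + 1 for i, c in enumerate(ordered)}
    zone = np.array([remap[c] for c in raw])
    return ZoneAssignment(list(gene_ids), zone, peak)


def collapse_zones(assignment: ZoneAssignment) -> ZoneAssignment:
    """Populate the EARLY/MID/LATE field by the fixed map; idempotent."""
    bad = sorted({int(z) for z in assignment.zone} - set(COLLAPSE_MAP))
    if bad:
        raise ValueError(f"zones {bad} outside the 6-zone collapse map")
    assignment.collapsed = [COLLAPSE_MAP[int(z)] for z in assignment.zone]
    return assignment
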