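"""The two-stage core-gene screen.

Stage 1 keeps genes significantly different between the hairy and hairless
mutant classes (q below threshold) in at least one of the two facility
datasets.  Stage 2 keeps, of those, genes changing at least ``fc_min``-fold
in *each* of the six individual comparisons (three hairy lines x two sites,
always oriented hairy/hairless) and in the same direction throughout; genes
up in every comparison are hair genes, genes down in every comparison are
non-hair genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rootgrn.core_data import (
    ExpressionMatrix,
    GeneClass,
    GeneSet,
    Sample,
    Site,
    Treatment,
)
from rootgrn.differential_expression import SamResult

log = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    stage1: set[str]
    stage2: GeneSet
    fc_table: pd.DataFrame  # genes x 6 linear ratios, hairy / hairless


def primary_screen(
    sam_site_a: SamResult,
    sam_site_b: SamResult,
    q_max: float = 0.01,
) -> set[str]:
    """Genes with q < q_max at site A or site B (the one-of-two-sites rule)."""
    genes_a, genes_b = set(sam_site_a.gene_ids), set(sam_site_b.gene_ids)
    if genes_a != genes_b:
        raise ValueError(
            "SAM results cover different gene universes; symmetric "
            f"difference: {sorted(genes_a ^ genes_b)}"
        )
    if sam_site_a.q is None or sam_site_b.q is None:
        raise ValueError("both SAM results need q-values (run estimate_fdr)")
    qa = dict(zip(sam_site_a.gene_ids, sam_site_a.q))
    qb = dict(zip(sam_site_b.gene_ids, sam_site_b.q))
    return {g for g in genes_a if qa[g] < q_max or qb[g] < q_max}


def select_core_genes(
    candidates: Iterable[str],
    fc_table: pd.DataFrame,
    fc_min: float = 2.0,
) -> GeneSet:
    """Apply the six-comparison same-direction fold-change filter.

    ``fc_table`` holds linear ratios oriented hairy/hairless, one column per
    comparison (expected: three hairy lines x two sites).  HAIR if every
    ratio is >= fc_min, NONHAIR if every ratio is <= 1/fc_min (ties at the
    threshold pass), otherwise excluded.  A candidate missing from the table
    or with a missing comparison is an error.
    """
    if fc_min <= 1.0:
        raise ValueError("fc_min must exceed 1")
    members: dict[str, GeneClass] = {}
    for gene in candidates:
        if gene not in fc_table.index:
            raise ValueError(f"candidate {gene!r} missing from fold-change table")
        ratios = fc_table.loc[gene].to_numpy(dtype=float)
        if np.any(~np.isfinite(ratios)) or np.any(ratios <= 0):
            raise ValueError(f"candidate {gene!r} has invalid fold-change values")
        if np.all(ratios >= fc_min):
            members[gene] = GeneClass.HAIR
        elif np.all(ratios <= 1.0 / fc_min):
            members[gene] = GeneClass.NONHAIR
    return GeneSet(members)


def six_comparison_fc_table(
    expr: ExpressionMatrix,
    samples: Sequence[Sample],
    hairy_genotypes: Sequence[frozenset[str]],
    hairless_genotype: frozenset[str],
    sites: Sequence[Site] = (Site.SITE_A, Site.SITE_B),
) -> pd.DataFrame:
    """Plain mean-ratio table for the stage-2 filter.

    Ratios are 2^(mean hairy - mean hairless), computed per hairy line and
    site from untreated replicates.  Plain means are used rather than any
    SAM-internal averaging; the choice is documented in the methods note.
    """
    expr.join(samples)

    def cols(genotype: frozenset[str], site: Site) -> list[str]:
        ids = [
            s.sample_id
            for s in samples
            if s.genotype == genotype
            and s.site == site
            and s.treatment == Treatment.NONE
        ]
        if not ids:
            raise ValueError(
                f"no untreated samples for genotype {sorted(genotype)} at "
                f"{site.value}"
            )
        return ids

    table = {}
    for genotype in hairy_genotypes:
        label = "+".join(sorted(genotype)) or "WT"
        for site in sites:
            hairy_mean = expr.sample_columns(cols(genotype, site)).mean(axis=1)
            hairless_mean = expr.sample_columns(
                cols(hairless_genotype, site)
            ).mean(axis=1)
            table[f"{label}_{site.value}"] = np.power(
                2.0, hairy_mean - hairless_mean
            )
    return pd.DataFrame(table, index=pd.Index(expr.gene_ids, name="gene_id"))


def run_screen(
    sam_site_a: SamResult,
    sam_site_b: SamResult,
    fc_table: pd.DataFrame,
    q_max: float = 0.01,
    fc_min: float = 2.0,
) -> ScreenResult:
    """Stage 1 then stage 2; genes lacking fold-change data are dropped with
    a warning rather than half-tested (the six-comparison rule is undefined
    for them)."""
    stage1 = primary_screen(sam_site_a, sam_site_b, q_max)
    testable = {g for g in stage1 if g in fc_table.index}
    dropped = stage1 - testable
    if dropped:
        log.warning(
            "dropping %d stage-1 genes lacking fold-change data: %s",
            len(dropped),
            sorted(dropped),
        )
    stage2 = select_core_genes(sorted(testable), fc_table, fc_min)
    return ScreenResult(stage1=stage1, stage2=stage2, fc_table=fc_table)
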