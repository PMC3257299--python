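"""End-to-end orchestration of the analysis over a simulated study.

Thin, importable wrappers that wire the stages together with the study's
canonical comparisons: per-site hairy-vs-hairless SAM for the primary
screen, per-mutant and per-hormone SAM for the perturbation signatures,
structure learning over the untreated samples, and zone assignment from the
section profiles.  The numbered scripts under ``analysis/`` and the
acceptance checks all run through these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rootgrn import bayes_network as bn
from rootgrn import synthetic_data as sd
from rootgrn.core_data import Sample, Site, Treatment
from rootgrn.core_filter import ScreenResult, run_screen, six_comparison_fc_table
from rootgrn.differential_expression import SamConfig, SamResult, estimate_fdr
from rootgrn.network_assembly import (
    PerturbationSignature,
    RegulatoryCluster,
    build_clusters,
    perturbation_signature,
)
from rootgrn.temporal_zones import ZoneAssignment, assign_zones, collapse_zones


def default_search_config(seed: int = 0, top_k: int = 1000) -> bn.SearchConfig:
    """Search settings used for the default study.

    Greedy hill climbing from 60 random restarts: the many independent
    climbs populate the top-K with structurally diverse near-optima, which
    is what the consensus support fractions need.  The simulated-annealing
    strategy remains available (and is benchmarked against exhaustive
    enumeration in the tests) but a long SA walk concentrates the top-K
    around a single basin, which blurs consensus support.
    """
    return bn.SearchConfig(strategy="GREEDY", restarts=60, top_k=top_k, seed=seed)


def _ids(samples: list[Sample], genotype: frozenset[str], site: Site | None,
         treatment: Treatment = Treatment.NONE) -> list[str]:
    return [
        s.sample_id
        for s in samples
        if s.genotype == genotype
        and (site is None or s.site == site)
        and s.treatment == treatment
    ]


@dataclass
class StudyAnalysis:
    """All derived results of one simulated study."""

    study: sd.SimulatedStudy
    sam_site_a: SamResult
    sam_site_b: SamResult
    screen: ScreenResult
    signatures: PerturbationSignature
    zones: ZoneAssignment
    clusters: list[RegulatoryCluster]
    data: bn.DiscreteDataset
    topk: bn.TopKList
    consensus: bn.ConsensusNetwork
    hormone_responsive: dict[str, set[str]] = field(default_factory=dict)


def site_screen(
    study: sd.SimulatedStudy,
    design: sd.DesignConfig,
    q_max: float = 0.01,
    fc_min: float = 2.0,
    sam_cfg: SamConfig | None = None,
) -> tuple[SamResult, SamResult, ScreenResult]:
    """Per-site hairy-vs-hairless SAM plus the two-stage core-gene screen."""
    expr, samples = study.expression, study.samples
    results = {}
    for site in (Site.SITE_A, Site.SITE_B):
        hairless = _ids(samples, design.hairless_line_genotype, site)
        hairy: list[str] = []
        for g in design.hairy_line_genotypes:
            hairy += _ids(samples, g, site)
        cfg = sam_cfg or SamConfig(seed=17 + (site is Site.SITE_B))
        results[site] = estimate_fdr(expr, hairless, hairy, cfg)
    fc = six_comparison_fc_table(
        expr, samples, design.hairy_line_genotypes, design.hairless_line_genotype
    )
    screen = run_screen(
        results[Site.SITE_A], results[Site.SITE_B], fc, q_max=q_max, fc_min=fc_min
    )
    return results[Site.SITE_A], results[Site.SITE_B], screen


def mutant_panel_comparisons(
    study: sd.SimulatedStudy, sam_cfg: SamConfig | None = None
) -> dict[str, SamResult]:
    """Each knockout genotype versus wild type, plus hormone-vs-vehicle in
    the transfer background.  Keys: "g05ko", ..., "IAA", "ACC"."""
    expr, samples = study.expression, study.samples
    wt = _ids(samples, frozenset(), None)
    out: dict[str, SamResult] = {}
    genotypes = sorted(
        {s.genotype for s in samples if s.genotype}, key=sorted
    )
    for genotype in genotypes:
        ids = _ids(samples, genotype, None)
        if len(ids) < 2:
            continue
        label = "+".join(sorted(genotype)).lower() + "ko"
        cfg = sam_cfg or SamConfig(seed=29)
        out[label] = estimate_fdr(expr, wt, ids, cfg)
    rescue_bg = (
        study.truth.rescue.background if study.truth.rescue else frozenset()
    )
    vehicle = _ids(samples, rescue_bg, None, Treatment.MS)
    for hormone, treatment in study.truth.hormone_treatment.items():
        treated = _ids(samples, rescue_bg, None, treatment)
        if len(vehicle) >= 2 and len(treated) >= 2:
            cfg = sam_cfg or SamConfig(seed=31)
            out[hormone] = estimate_fdr(expr, vehicle, treated, cfg)
    return out


def hormone_responsive_genes(
    comparisons: dict[str, SamResult],
    hormones: tuple[str, ...] = ("IAA", "ACC"),
    fc_min: float = 2.0,
    q_max: float = 0.005,
) -> dict[str, set[str]]:
    """Genes responding to each hormone (>= fc_min-fold at the stated FDR)."""
    out: dict[str, set[str]] = {}
    for h in hormones:
        res = comparisons.get(h)
        if res is None:
            continue
        up = {
            g
            for g, fc, q in zip(res.gene_ids, res.fc, res.q)
            if q < q_max and (fc >= fc_min or fc <= 1.0 / fc_min)
        }
        out[h] = up
    return out


def analyse_study(
    study: sd.SimulatedStudy,
    design: sd.DesignConfig,
    seed: int = 0,
    top_k: int = 1000,
    consensus_f: float = 0.40,
) -> StudyAnalysis:
    """Run every stage of the analysis on a simulated study."""
    sam_a, sam_b, screen = site_screen(study, design)

    comparisons = mutant_panel_comparisons(study)
    hormones = tuple(study.truth.hormone_treatment)
    signatures = perturbation_signature(
        comparisons, hormone_perturbations=hormones
    )
    responsive = hormone_responsive_genes(comparisons, hormones)

    zone_genes = study.truth.gene_nodes  # section profiles cover the pathway
    zones = collapse_zones(assign_zones(study.sections, zone_genes))
    clusters = build_clusters(
        signatures.restrict(zone_genes),
        zones,
        downstream_panel=list(signatures.perturbations),
        robust_min=6,
    )

    learn = sd.learning_subset(study)
    data = sd.discretize_study(learn)
    topk = bn.learn_structures(
        data, bn.ScoreConfig(), default_search_config(seed=seed, top_k=top_k)
    )
    consensus = bn.consensus_network(topk, consensus_f, data)

    return StudyAnalysis(
        study=study,
        sam_site_a=sam_a,
        sam_site_b=sam_b,
        screen=screen,
        signatures=signatures,
        zones=zones,
        clusters=clusters,
        data=data,
        topk=topk,
        consensus=consensus,
        hormone_responsive=responsive,
    )


def edge_recovery(
    consensus: bn.ConsensusNetwork, truth: sd.SyntheticTruth
) -> dict[str, float]:
    """Recall/precision of consensus edges against the ground-truth DAG."""
    true = truth.edges()
    found = consensus.edges.as_pairs()
    tp = found & true
    return {
        "n_true": len(true),
        "n_found": len(found),
        "n_correct": len(tp),
        "recall": len(tp) / len(true) if true else 1.0,
        "precision": len(tp) / len(found) if found else 1.0,
    }


def core_set_recovery(
    screen: ScreenResult, truth: sd.SyntheticTruth, design: sd.DesignConfig
) -> dict[str, float]:
    """Sensitivity/specificity of the screened core set for the genes wired
    downstream of the fate hub in the truth (the hub itself, being genuinely
    differential, is evaluated on neither side)."""
    hub = sd.DEFAULT_FATE_HUB
    descendants = set()
    stack = [hub]
    while stack:
        node = stack.pop()
        for child, parents in truth.parents.items():
            if node in parents and child not in descendants:
                if truth.node(child).kind == sd.GENE:
                    descendants.add(child)
                stack.append(child)
    universe = set(screen.fc_table.index)
    others = universe - descendants - {hub}
    called = screen.stage2.genes()
    tp = len(descendants & called)
    tn = len(others - called)
    return {
        "sensitivity": tp / len(descendants) if descendants else 1.0,
        "specificity": tn / len(others) if others else 1.0,
        "n_core": len(called),
    }
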