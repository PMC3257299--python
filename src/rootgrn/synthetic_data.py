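"""Ground-truth regulatory networks and simulation of the study design.

The simulator emulates the perturbation-transcriptome study the pipeline is
built for: four foundational mutant lines (three "hairy", one "hairless")
profiled in triplicate at two facilities, a panel of further knockout lines
in triplicate at one site, hormone-transfer samples in an initiation-mutant
background, two measured phenotype characters (root-hair length, fraction of
branched hairs), and longitudinal-section expression profiles over six
developmental zones.

A :class:`SyntheticTruth` is a discrete causal Bayesian network over gene,
hormone and phenotype nodes.  Knockouts are interventions: the knocked-out
node is clamped to state 0 and excluded from ancestral sampling, which is
what lets the downstream structure learner orient edges.  Expression is
emitted per gene as ``state_mean[state] + site_shift + N(0, sd)`` on the
log2 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from rootgrn.core_data import ExpressionMatrix, Sample, Site, Treatment

GENE = "gene"
HORMONE = "hormone"
PHENOTYPE = "phenotype"

#: log2 expression means for the three gene states (low, mid, high) and the
#: replicate noise SD.  The 3-unit spacing gives an 8-fold change per state
#: step, so triplicate designs have realistic power through the filter
#: cascade.
DEFAULT_STATE_MEANS = (6.0, 9.0, 12.0)
DEFAULT_STATE_SD = 0.5
#: additive site batch effect (log2 units) for the second facility.
DEFAULT_SITE_SHIFT = {Site.SITE_A: 0.0, Site.SITE_B: 0.3}


@dataclass(frozen=True)
class TruthNode:
    name: str
    kind: str  # GENE / HORMONE / PHENOTYPE
    arity: int


@dataclass(frozen=True)
class HormoneRescue:
    """Hormone override emulating the initiation-mutant rescue experiment.

    When a sample of the ``background`` genotype is under an active hormone
    treatment, that hormone's target hair genes are forced to
    ``forced_state`` when ancestral sampling reaches them (their descendants
    then sample from the overridden value).  This is a test-harness
    mechanism, not a mechanistic claim about hormone signalling.
    """

    background: frozenset[str]
    targets: dict[str, frozenset[str]]  # hormone node -> overridden genes
    forced_state: int = 2

    def targets_for(self, active_hormones: Iterable[str]) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for h in active_hormones:
            out |= self.targets.get(h, frozenset())
        return out


@dataclass
class SyntheticTruth:
    """Causal ground truth: DAG + CPTs + emission parameters."""

    nodes: list[TruthNode]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]  # shape (*parent arities, own arity)
    state_means: dict[str, np.ndarray]  # gene -> per-state log2 mean
    state_sd: float
    site_shift: dict[Site, float]
    knockout_lines: list[frozenset[str]]
    zone_of: dict[str, int]  # gene -> 1..6
    seed: int
    phenotype_value_means: dict[str, np.ndarray] = field(default_factory=dict)
    phenotype_value_sd: dict[str, float] = field(default_factory=dict)
    hormone_treatment: dict[str, Treatment] = field(default_factory=dict)
    rescue: HormoneRescue | None = None
    #: chip background: unregulated genes with stable per-gene baselines.
    #: They give the differential-expression stages a realistic null
    #: complement (a mostly-unchanged chip) but are not network nodes.
    background_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_name = {n.name: n for n in self.nodes}
        order = topological_order(self.parents, [n.name for n in self.nodes])
        self._topo = order
        for n in self.nodes:
            cpt = self.cpts[n.name]
            p_arities = tuple(self._by_name[p].arity for p in self.parents[n.name])
            if cpt.shape != p_arities + (n.arity,):
                raise ValueError(f"CPT shape mismatch for {n.name}")
            if not np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows of {n.name} do not sum to 1")
            if n.kind == PHENOTYPE and any(
                n.name in ps for ps in self.parents.values()
            ):
                raise ValueError(f"phenotype node {n.name} has outgoing edges")
            if n.kind == HORMONE and self.parents[n.name]:
                raise ValueError(f"hormone node {n.name} has incoming edges")
        for g, mu in self.state_means.items():
            if np.any(np.diff(np.asarray(mu)) <= 0):
                raise ValueError(f"state means of {g} not strictly increasing")

    # -- convenience views ---------------------------------------------------
    @property
    def gene_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.kind == GENE]

    @property
    def hormone_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.kind == HORMONE]

    @property
    def phenotype_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.kind == PHENOTYPE]

    def node(self, name: str) -> TruthNode:
        return self._by_name[name]

    @property
    def topological(self) -> list[str]:
        return list(self._topo)

    def edges(self) -> set[tuple[str, str]]:
        return {(p, c) for c, ps in self.parents.items() for p in ps}

    # -- serialization (JSON, text-only) -------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "nodes": [[n.name, n.kind, n.arity] for n in self.nodes],
            "parents": {k: list(v) for k, v in self.parents.items()},
            "cpts": {k: v.tolist() for k, v in self.cpts.items()},
            "state_means": {k: v.tolist() for k, v in self.state_means.items()},
            "state_sd": self.state_sd,
            "site_shift": {s.value: v for s, v in self.site_shift.items()},
            "knockout_lines": [sorted(l) for l in self.knockout_lines],
            "zone_of": self.zone_of,
            "seed": self.seed,
            "phenotype_value_means": {
                k: v.tolist() for k, v in self.phenotype_value_means.items()
            },
            "phenotype_value_sd": self.phenotype_value_sd,
            "hormone_treatment": {
                k: t.value for k, t in self.hormone_treatment.items()
            },
            "background_means": self.background_means,
            "rescue": None
            if self.rescue is None
            else {
                "background": sorted(self.rescue.background),
                "targets": {
                    h: sorted(g) for h, g in self.rescue.targets.items()
                },
                "forced_state": self.rescue.forced_state,
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        rescue = doc["rescue"]
        return cls(
            nodes=[TruthNode(*n) for n in doc["nodes"]],
            parents={k: tuple(v) for k, v in doc["parents"].items()},
            cpts={k: np.array(v) for k, v in doc["cpts"].items()},
            state_means={k: np.array(v) for k, v in doc["state_means"].items()},
            state_sd=doc["state_sd"],
            site_shift={Site(k): v for k, v in doc["site_shift"].items()},
            knockout_lines=[frozenset(l) for l in doc["knockout_lines"]],
            zone_of={k: int(v) for k, v in doc["zone_of"].items()},
            seed=doc["seed"],
            phenotype_value_means={
                k: np.array(v) for k, v in doc["phenotype_value_means"].items()
            },
            phenotype_value_sd=doc["phenotype_value_sd"],
            hormone_treatment={
                k: Treatment(v) for k, v in doc["hormone_treatment"].items()
            },
            background_means=doc.get("background_means", {}),
            rescue=None
            if rescue is None
            else HormoneRescue(
                frozenset(rescue["background"]),
                {h: frozenset(g) for h, g in rescue["targets"].items()},
                rescue["forced_state"],
            ),
        )


def topological_order(
    parents: Mapping[str, tuple[str, ...]], names: Sequence[str]
) -> list[str]:
    """Kahn topological sort; raises on cycles."""
    remaining = {n: set(parents[n]) for n in names}
    order: list[str] = []
    ready = sorted(n for n, ps in remaining.items() if not ps)
    while ready:
        n = ready.pop(0)
        order.append(n)
        del remaining[n]
        newly = []
        for m, ps in remaining.items():
            if n in ps:
                ps.discard(n)
                if not ps:
                    newly.append(m)
        for m in sorted(newly):
            ready.append(m)
    if remaining:
        raise ValueError(f"cycle among nodes {sorted(remaining)}")
    return order


# ---------------------------------------------------------------------------
# CPT construction helpers


def _smear(target: int, arity: int, fidelity: float) -> np.ndarray:
    """Distribution putting ``fidelity`` on target, remainder nearby-weighted."""
    p = np.zeros(arity)
    p[target] = fidelity
    others = [k for k in range(arity) if k != target]
    w = np.array([1.0 / (1 + abs(k - target)) for k in others])
    p[others] = (1 - fidelity) * w / w.sum()
    return p


def cpt_from_logic(
    parent_arities: Sequence[int],
    arity: int,
    fn: Callable[..., int],
    fidelity: float = 0.9,
    mid_fidelity: float | None = None,
) -> np.ndarray:
    """Build a CPT whose mode follows a deterministic parent logic.

    ``fidelity`` applies when every parent sits at an extreme state (fully
    off or fully saturated — the regime knockout lines live in);
    ``mid_fidelity`` (default: same) applies when any parent is at an
    intermediate level, where a graded transcriptional response is
    naturally more stochastic.
    """
    if mid_fidelity is None:
        mid_fidelity = fidelity
    shape = tuple(parent_arities) + (arity,)
    cpt = np.zeros(shape)
    if not parent_arities:
        return _smear(fn(), arity, fidelity)
    for idx in np.ndindex(*parent_arities):
        extreme = all(s == 0 or s == r - 1 for s, r in zip(idx, parent_arities))
        fid = fidelity if extreme else mid_fidelity
        cpt[idx] = _smear(int(fn(*idx)), arity, fid)
    return cpt


# ---------------------------------------------------------------------------
# default ground truth: the root-epidermis fate cascade


def default_truth(
    seed: int = 2012,
    fidelity: float = 0.98,
    mid_fidelity: float = 0.88,
    n_background: int = 193,
) -> SyntheticTruth:
    """Hand-designed 15-gene cascade emulating the fate-specification pathway.

    ``G01 -> G02 -> G03`` is the upstream activator cascade (the complex whose
    members the three hairy lines knock out); ``G04`` is the antagonist whose
    knockout is the hairless line; ``G05`` is the fate switch (activated by
    G03, repressed by G04) heading two effector branches: the non-hair branch
    G06 -> {G07 -> G08, G11} and the hair branch G09 -> G10 -> {G14, G15}.
    G14 drives hair length inversely, G15 drives branching inversely.  The
    hormone-responsive genes G12/G13 sit at baseline unless induced by the
    hormone-transfer override (which also rescues the late hair genes G10 and
    G15 in the G09-knockout background).

    Children of a common regulator deliberately carry *different* response
    logics (graded copy, graded inversion, high-threshold switch) so that
    sibling genes are not functional clones of each other — clones would make
    edge placement unidentifiable at the study's sample size.  The wild-type
    root state is broadly distributed for the same reason: observational
    variation in the top regulator propagates through the cascade and keeps
    every gene's marginal spread over its three states, which is what the
    equal-frequency discretizer downstream assumes.
    """
    genes = [f"G{i:02d}" for i in range(1, 16)]
    nodes = [TruthNode(g, GENE, 3) for g in genes]
    nodes += [TruthNode("IAA", HORMONE, 2), TruthNode("ACC", HORMONE, 2)]
    nodes += [TruthNode("P_LEN", PHENOTYPE, 4), TruthNode("P_BRANCH", PHENOTYPE, 2)]

    parents: dict[str, tuple[str, ...]] = {n.name: () for n in nodes}
    logic: dict[str, Callable[..., int]] = {}

    def wire(child: str, pars: tuple[str, ...], fn: Callable[..., int]) -> None:
        parents[child] = pars
        logic[child] = fn

    ident = lambda x: x  # graded copy
    rev = lambda x: 2 - x  # graded inversion
    twohigh = lambda x: 2 if x == 2 else 0  # high-threshold switch

    wire("G02", ("G01",), ident)
    wire("G03", ("G02",), ident)
    wire("G04", ("G01",), twohigh)
    # fate switch: off without activator; repressed to mid by the antagonist
    wire("G05", ("G03", "G04"), lambda a, r: 0 if a == 0 else (1 if r == 2 else 2))
    wire("G06", ("G05",), ident)  # non-hair branch head
    wire("G07", ("G06",), ident)
    wire("G08", ("G06",), twohigh)
    wire("G11", ("G06",), rev)
    wire("G09", ("G05",), rev)  # hair branch head
    wire("G10", ("G09",), ident)
    wire("G14", ("G09",), rev)  # hair-length driver (inverse on the phenotype)
    wire("G15", ("G09",), twohigh)  # branching driver (inverse on the phenotype)
    wire("P_LEN", ("G14",), lambda d: 3 - d if d > 0 else 3)
    wire("P_BRANCH", ("G15",), lambda d: 1 if d == 0 else 0)

    # The antagonist tracks the master regulator only loosely (flat noise at
    # every level); its independent variation is what identifies its
    # repressive input to the fate switch.  Terminal effector genes carry
    # flat moderate noise: their flips do not propagate (no downstream
    # targets) but provide the within-line variation that distinguishes a
    # direct regulator from a correlated sibling.
    leaf_fid = (0.92, 0.88)
    per_node_fidelity = {
        "G04": (0.85, 0.85),
        "G07": leaf_fid,
        "G08": leaf_fid,
        "G10": leaf_fid,
        "G11": leaf_fid,
        "G14": leaf_fid,
        "G15": leaf_fid,
    }

    by_name = {n.name: n for n in nodes}
    cpts: dict[str, np.ndarray] = {}
    for n in nodes:
        if n.kind == HORMONE:
            cpts[n.name] = np.array([1.0, 0.0])  # inactive unless treated
        elif n.name == "G01":
            # mostly-active master regulator with enough spread that
            # observational variation propagates through the cascade
            cpts[n.name] = np.array([0.10, 0.20, 0.70])
        elif n.name in ("G12", "G13"):
            # hormone-responsive reporters: strictly silent without stimulus
            cpts[n.name] = np.array([1.0, 0.0, 0.0])
        else:
            p_ar = [by_name[p].arity for p in parents[n.name]]
            fid, mid = per_node_fidelity.get(n.name, (fidelity, mid_fidelity))
            cpts[n.name] = cpt_from_logic(p_ar, n.arity, logic[n.name], fid, mid)

    # phenotype responses to their 3-state drivers, monotone-inverse
    cpts["P_LEN"] = np.array(
        [
            [0.04, 0.04, 0.12, 0.80],  # driver low  -> long hairs
            [0.05, 0.45, 0.45, 0.05],
            [0.80, 0.12, 0.04, 0.04],  # driver high -> short hairs
        ]
    )
    cpts["P_BRANCH"] = np.array([[0.05, 0.95], [0.25, 0.75], [0.95, 0.05]])

    zone_of = {
        "G01": 1, "G02": 1,
        "G03": 2, "G04": 2,
        "G05": 3, "G06": 3,
        "G07": 4, "G09": 4, "G10": 4,
        "G08": 5, "G14": 5, "G15": 5,
        "G11": 6, "G12": 6, "G13": 6,
    }
    knockout_lines = [
        frozenset({g}) for g in ("G01", "G02", "G03", "G04", "G05", "G06", "G09")
    ]
    # chip background: the screen needs a mostly-null gene universe for its
    # permutation FDR to be calibrated, as on a real array
    bg_rng = np.random.default_rng(seed)
    background_means = {
        f"B{i:03d}": float(m)
        for i, m in enumerate(bg_rng.uniform(6.0, 12.0, n_background), start=1)
    }
    return SyntheticTruth(
        nodes=nodes,
        parents=parents,
        cpts=cpts,
        state_means={g: np.array(DEFAULT_STATE_MEANS) for g in genes},
        state_sd=DEFAULT_STATE_SD,
        site_shift=dict(DEFAULT_SITE_SHIFT),
        knockout_lines=knockout_lines,
        zone_of=zone_of,
        seed=seed,
        phenotype_value_means={
            "P_LEN": np.array([120.0, 240.0, 360.0, 480.0]),  # µm
            "P_BRANCH": np.array([0.10, 0.60]),  # fraction branched
        },
        phenotype_value_sd={"P_LEN": 25.0, "P_BRANCH": 0.05},
        hormone_treatment={"IAA": Treatment.IAA, "ACC": Treatment.ACC},
        rescue=HormoneRescue(
            background=frozenset({"G09"}),
            targets={
                "IAA": frozenset({"G12", "G10", "G15"}),
                "ACC": frozenset({"G13", "G10", "G15"}),
            },
            forced_state=2,
        ),
        background_means=background_means,
    )


#: designated phenotype driver genes of the default truth.
DEFAULT_LENGTH_DRIVER = "G14"
DEFAULT_BRANCHING_DRIVER = "G15"
#: fate-hub node whose downstream genes define the recoverable core set.
DEFAULT_FATE_HUB = "G03"


# ---------------------------------------------------------------------------
# random truths (for search-oracle tests)


def generate_truth(
    n_genes: int,
    n_edges: int,
    n_hormones: int = 0,
    n_phenotypes: int = 0,
    seed: int = 0,
    dirichlet_alpha: float = 1.0,
    gene_arity: int = 3,
) -> SyntheticTruth:
    """Sample a random role-constrained DAG with Dirichlet CPTs.

    Genes get a random topological order; hormones are roots, phenotypes are
    leaves.  When the edge budget allows, each phenotype node is first given
    one gene "driver" parent; remaining edges are drawn uniformly from the
    feasible (order-respecting, role-respecting) pairs.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:02d}" for i in range(1, n_genes + 1)]
    hormones = [f"H{i}" for i in range(1, n_hormones + 1)]
    phens = [f"P{i}" for i in range(1, n_phenotypes + 1)]
    order = list(rng.permutation(genes))
    pos = {g: i for i, g in enumerate(order)}

    pool: list[tuple[str, str]] = []
    pool += [(a, b) for a in order for b in order if pos[a] < pos[b]]
    pool += [(h, g) for h in hormones for g in genes]
    pool += [(g, p) for g in genes for p in phens]
    if n_edges > len(pool):
        raise ValueError(
            f"{n_edges} edges infeasible: at most {len(pool)} under the "
            "acyclicity and role constraints"
        )
    chosen: set[tuple[str, str]] = set()
    if n_genes and n_edges >= n_phenotypes:
        for p in phens:  # designated drivers
            chosen.add((str(rng.choice(genes)), p))
    remaining = [e for e in pool if e not in chosen]
    extra = rng.choice(len(remaining), size=n_edges - len(chosen), replace=False)
    chosen |= {remaining[i] for i in extra}

    nodes = [TruthNode(g, GENE, gene_arity) for g in genes]
    nodes += [TruthNode(h, HORMONE, 2) for h in hormones]
    nodes += [TruthNode(p, PHENOTYPE, 2) for p in phens]
    by_name = {n.name: n for n in nodes}
    parents = {
        n.name: tuple(sorted(a for a, b in chosen if b == n.name)) for n in nodes
    }
    cpts: dict[str, np.ndarray] = {}
    for n in nodes:
        shape = tuple(by_name[p].arity for p in parents[n.name]) + (n.arity,)
        flat = rng.dirichlet([dirichlet_alpha] * n.arity,
                             size=int(np.prod(shape[:-1], dtype=int)))
        cpts[n.name] = flat.reshape(shape)

    # zones by topological depth, early regulators first
    depth = {g: 0 for g in genes}
    for g in order:
        gene_parents = [p for p in parents[g] if p in depth]
        if gene_parents:
            depth[g] = 1 + max(depth[p] for p in gene_parents)
    max_d = max(depth.values()) if depth else 0
    zone_of = {
        g: 1 + int(round(5 * d / max_d)) if max_d else 1 for g, d in depth.items()
    }
    means = np.linspace(6.0, 12.0, gene_arity)
    return SyntheticTruth(
        nodes=nodes,
        parents=parents,
        cpts=cpts,
        state_means={g: means.copy() for g in genes},
        state_sd=DEFAULT_STATE_SD,
        site_shift=dict(DEFAULT_SITE_SHIFT),
        knockout_lines=[],
        zone_of=zone_of,
        seed=seed,
        phenotype_value_means={p: np.array([100.0, 300.0]) for p in phens},
        phenotype_value_sd={p: 20.0 for p in phens},
    )


# ---------------------------------------------------------------------------
# study design


@dataclass(frozen=True)
class LineSpec:
    line_id: str
    genotype: frozenset[str]
    site: Site
    n_replicates: int
    treatment: Treatment = Treatment.NONE


@dataclass
class DesignConfig:
    lines: list[LineSpec]
    hairy_line_genotypes: list[frozenset[str]]
    hairless_line_genotype: frozenset[str]

    @property
    def n_samples(self) -> int:
        return sum(l.n_replicates for l in self.lines)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        doc = {
            "lines": [
                {
                    "line_id": l.line_id,
                    "genotype": sorted(l.genotype),
                    "site": l.site.value,
                    "n_replicates": l.n_replicates,
                    "treatment": l.treatment.value,
                }
                for l in self.lines
            ],
            "hairy_line_genotypes": [sorted(g) for g in self.hairy_line_genotypes],
            "hairless_line_genotype": sorted(self.hairless_line_genotype),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), "utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            lines=[
                LineSpec(
                    d["line_id"],
                    frozenset(d["genotype"]),
                    Site(d["site"]),
                    int(d["n_replicates"]),
                    Treatment(d["treatment"]),
                )
                for d in doc["lines"]
            ],
            hairy_line_genotypes=[
                frozenset(g) for g in doc["hairy_line_genotypes"]
            ],
            hairless_line_genotype=frozenset(doc["hairless_line_genotype"]),
        )


def default_design(include_hormone_transfer: bool = True) -> DesignConfig:
    """The study design: 66 untreated learning samples plus the
    hormone-transfer series.

    Learning samples are 4 foundational lines x 2 sites x 3 replicates plus
    14 single-site lines x 3 replicates (wild type in triplicate lines, the
    panel mutants, and one further replicate line of each foundational
    genotype) — seven distinct knockout genotypes in all.  The transfer
    series (MS vehicle, IAA, ACC in the G09 background, 3 replicates each)
    adds 9 arrays used for the hormone-response comparisons but not for
    structure learning.
    """
    foundational = ["G01", "G02", "G03", "G04"]
    lines: list[LineSpec] = []
    for g in foundational:
        for site in (Site.SITE_A, Site.SITE_B):
            lines.append(
                LineSpec(f"{g.lower()}ko_{site.value[-1]}", frozenset({g}), site, 3)
            )
    a = Site.SITE_A
    lines += [
        LineSpec("wt_1", frozenset(), a, 3),
        LineSpec("wt_2", frozenset(), a, 3),
        LineSpec("wt_3", frozenset(), a, 3),
        LineSpec("g05ko_1", frozenset({"G05"}), a, 3),
        LineSpec("g05ko_2", frozenset({"G05"}), a, 3),
        LineSpec("g05ko_3", frozenset({"G05"}), a, 3),
        LineSpec("g06ko_1", frozenset({"G06"}), a, 3),
        LineSpec("g06ko_2", frozenset({"G06"}), a, 3),
        LineSpec("g09ko_1", frozenset({"G09"}), a, 3),
        LineSpec("g09ko_2", frozenset({"G09"}), a, 3),
        LineSpec("g01ko_x", frozenset({"G01"}), a, 3),
        LineSpec("g02ko_x", frozenset({"G02"}), a, 3),
        LineSpec("g03ko_x", frozenset({"G03"}), a, 3),
        LineSpec("g04ko_x", frozenset({"G04"}), a, 3),
    ]
    if include_hormone_transfer:
        lines += [
            LineSpec("g09ko_ms", frozenset({"G09"}), a, 3, Treatment.MS),
            LineSpec("g09ko_iaa", frozenset({"G09"}), a, 3, Treatment.IAA),
            LineSpec("g09ko_acc", frozenset({"G09"}), a, 3, Treatment.ACC),
        ]
    return DesignConfig(
        lines=lines,
        hairy_line_genotypes=[frozenset({g}) for g in ("G01", "G02", "G03")],
        hairless_line_genotype=frozenset({"G04"}),
    )


def learning_sample_ids(study: "SimulatedStudy") -> list[str]:
    """The untreated samples used for structure learning (the hormone
    transfer series is analysed separately)."""
    return [
        s.sample_id for s in study.samples if s.treatment is Treatment.NONE
    ]


def learning_subset(study: "SimulatedStudy") -> "SimulatedStudy":
    """Restrict a simulated study to its untreated learning samples."""
    keep_ids = set(learning_sample_ids(study))
    mask = np.array([s.sample_id in keep_ids for s in study.samples])
    cols = np.nonzero(mask)[0]
    expr = ExpressionMatrix(
        list(study.expression.gene_ids),
        [study.expression.sample_ids[c] for c in cols],
        study.expression.values[:, cols].copy(),
    )
    return SimulatedStudy(
        expression=expr,
        samples=[s for s in study.samples if s.sample_id in keep_ids],
        states=study.states[:, cols],
        clamped=study.clamped[:, cols],
        phenotypes={k: v[cols] for k, v in study.phenotypes.items()},
        sections=study.sections,
        truth=study.truth,
    )


# ---------------------------------------------------------------------------
# simulation


@dataclass
class SimulatedStudy:
    expression: ExpressionMatrix
    samples: list[Sample]
    states: np.ndarray  # node x sample true states (truth node order)
    clamped: np.ndarray  # node x sample intervention mask
    phenotypes: dict[str, np.ndarray]  # phenotype node -> per-sample values
    sections: np.ndarray | None
    truth: SyntheticTruth

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.truth.nodes]

    def state_row(self, node: str) -> np.ndarray:
        return self.states[self.node_names.index(node)]


def _hormone_state(truth: SyntheticTruth, hormone: str, treatment: Treatment) -> int:
    return int(truth.hormone_treatment.get(hormone) == treatment)


def _rescue_targets(
    truth: SyntheticTruth, genotype: frozenset[str], treatment: Treatment
) -> frozenset[str]:
    if truth.rescue is None or genotype != truth.rescue.background:
        return frozenset()
    active = [
        h for h, t in truth.hormone_treatment.items() if t == treatment
    ]
    return truth.rescue.targets_for(active)


def simulate_dataset(
    truth: SyntheticTruth,
    design: DesignConfig,
    seed: int = 0,
    with_sections: bool = True,
) -> SimulatedStudy:
    """Ancestrally sample every design sample from the truth CPTs.

    Knocked-out nodes are clamped to state 0 and *not* drawn (intervention
    semantics); hormone nodes are set from the treatment; the hormone-rescue
    override, if configured, forces its target genes in treated background
    samples.  Knockout genes absent from the truth are flagged external and
    have no dynamic effect.
    """
    rng = np.random.default_rng(seed)
    names = [n.name for n in truth.nodes]
    idx = {n: i for i, n in enumerate(names)}
    known = set(names)
    for line in design.lines:
        external = line.genotype - known
        # external knockouts are legal but inert (gene not modelled/measured)
        del external

    samples: list[Sample] = []
    n_total = design.n_samples
    states = np.zeros((len(names), n_total), dtype=int)
    clamped = np.zeros((len(names), n_total), dtype=bool)
    col = 0
    for line in design.lines:
        for rep in range(1, line.n_replicates + 1):
            sid = f"{line.line_id}_r{rep}"
            samples.append(
                Sample(sid, line.genotype, line.site, rep, line.treatment)
            )
            rescue_targets = _rescue_targets(truth, line.genotype, line.treatment)
            for node in truth.topological:
                i = idx[node]
                spec = truth.node(node)
                if node in line.genotype:
                    states[i, col] = 0
                    clamped[i, col] = True
                    continue
                if spec.kind == HORMONE:
                    states[i, col] = _hormone_state(truth, node, line.treatment)
                    continue
                if node in rescue_targets:
                    states[i, col] = truth.rescue.forced_state
                    continue
                pstates = tuple(states[idx[p], col] for p in truth.parents[node])
                probs = truth.cpts[node][pstates]
                states[i, col] = rng.choice(spec.arity, p=probs)
            col += 1

    genes = truth.gene_nodes
    bg = sorted(truth.background_means)
    g_rows = [idx[g] for g in genes]
    expr = np.zeros((len(genes) + len(bg), n_total))
    for j, s in enumerate(samples):
        shift = truth.site_shift[s.site]
        for r, g in enumerate(genes):
            mu = truth.state_means[g][states[g_rows[r], j]]
            expr[r, j] = mu + shift + rng.normal(0.0, truth.state_sd)
        for r, g in enumerate(bg, start=len(genes)):
            expr[r, j] = (
                truth.background_means[g] + shift + rng.normal(0.0, truth.state_sd)
            )
    matrix = ExpressionMatrix(
        list(genes) + bg, [s.sample_id for s in samples], expr
    )

    phenotypes: dict[str, np.ndarray] = {}
    for p in truth.phenotype_nodes:
        mus = truth.phenotype_value_means[p]
        sd = truth.phenotype_value_sd[p]
        vals = mus[states[idx[p]]] + rng.normal(0.0, sd, size=n_total)
        if p == "P_BRANCH" or (mus.max() <= 1.0):
            vals = np.clip(vals, 0.0, 1.0)
        phenotypes[p] = vals

    sections = (
        simulate_section_profiles(truth, seed=seed + 1) if with_sections else None
    )
    return SimulatedStudy(
        expression=matrix,
        samples=samples,
        states=states,
        clamped=clamped,
        phenotypes=phenotypes,
        sections=sections,
        truth=truth,
    )


def simulate_section_profiles(
    truth: SyntheticTruth,
    n_sections: int = 12,
    n_roots: int = 2,
    amplitude: float = 4.0,
    baseline: float = 6.0,
    peak_width: float = 1.3,
    noise_sd: float = 0.3,
    seed: int = 1,
) -> np.ndarray:
    """Genes x (n_roots * n_sections) unimodal profiles.

    A gene in zone z peaks in the section band {2z-1, 2z} (Gaussian bump
    centred between them) in each root, plus Gaussian noise.  Columns are
    root 1 sections 1..12 followed by root 2 sections 1..12, the order the
    published figure plots them in.
    """
    rng = np.random.default_rng(seed)
    genes = truth.gene_nodes
    secs = np.arange(1, n_sections + 1, dtype=float)
    out = np.zeros((len(genes), n_roots * n_sections))
    for r, g in enumerate(genes):
        z = truth.zone_of[g]
        centre = 2 * z - 0.5
        bump = baseline + amplitude * np.exp(
            -((secs - centre) ** 2) / (2 * peak_width**2)
        )
        for root in range(n_roots):
            cols = slice(root * n_sections, (root + 1) * n_sections)
            out[r, cols] = bump + rng.normal(0.0, noise_sd, size=n_sections)
    return out


# ---------------------------------------------------------------------------
# bridges to the network learner


def node_specs(truth: SyntheticTruth):
    """NodeSpec list for the structure learner: genes free, hormones
    root-only, phenotypes leaf-only, arities as in the truth."""
    from rootgrn import bayes_network as bn

    specs = []
    for n in truth.nodes:
        if n.kind == GENE:
            specs.append(bn.gene_node(n.name, n.arity))
        elif n.kind == HORMONE:
            specs.append(bn.hormone_node(n.name))
        else:
            specs.append(bn.phenotype_node(n.name, n.arity))
    return specs


def discretize_study(study: SimulatedStudy):
    """Discretize a simulated study for structure learning."""
    from rootgrn import bayes_network as bn

    treatments = dict(study.truth.hormone_treatment)
    return bn.discretize_dataset(
        study.expression,
        study.samples,
        node_specs(study.truth),
        phenotypes=study.phenotypes,
        hormone_treatments=treatments,
    )


# ---------------------------------------------------------------------------
# noise-free oracles


def expected_states(
    truth: SyntheticTruth,
    genotype: frozenset[str] = frozenset(),
    treatment: Treatment = Treatment.NONE,
) -> dict[str, int]:
    """Modal (noise-free) states under a genotype/treatment: each node takes
    the argmax of its CPT row given its parents' modal states.  The oracle
    used by tests to predict which genes a perturbation should shift."""
    out: dict[str, int] = {}
    rescue_targets = _rescue_targets(truth, genotype, treatment)
    for node in truth.topological:
        spec = truth.node(node)
        if node in genotype:
            out[node] = 0
            continue
        if spec.kind == HORMONE:
            out[node] = _hormone_state(truth, node, treatment)
            continue
        if node in rescue_targets:
            out[node] = truth.rescue.forced_state
            continue
        pstates = tuple(out[p] for p in truth.parents[node])
        out[node] = int(np.argmax(truth.cpts[node][pstates]))
    return out


def truth_core_genes(
    truth: SyntheticTruth, design: DesignConfig, min_state_diff: int = 1
) -> dict[str, str]:
    """Expected core-set membership from noise-free states.

    A gene is a truth core gene if its modal state differs by at least
    ``min_state_diff`` in the same direction between the hairless genotype
    and every hairy genotype.  Returns gene -> "HAIR"/"NONHAIR".
    """
    hairless = expected_states(truth, design.hairless_line_genotype)
    hairy = [expected_states(truth, g) for g in design.hairy_line_genotypes]
    out: dict[str, str] = {}
    for g in truth.gene_nodes:
        diffs = [h[g] - hairless[g] for h in hairy]
        if all(d >= min_state_diff for d in diffs):
            out[g] = "HAIR"
        elif all(d <= -min_state_diff for d in diffs):
            out[g] = "NONHAIR"
    return out
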