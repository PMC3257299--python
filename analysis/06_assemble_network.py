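#!/usr/bin/env python
"""Perturbation signatures, hormone responses and regulatory clusters.

Compares every mutant line against wild type and the hormone transfers
against vehicle, calls UP/DOWN/NONE signatures (FC>2 at q<0.05; hormones at
0.5% FDR), groups core genes by shared signature and collapsed temporal
zone, and flags genes affected by most of the mutant panel.

Usage: python analysis/06_assemble_network.py [--seed 4]
"""

import argparse
from pathlib import Path

from rootgrn import synthetic_data as sd
from rootgrn.network_assembly import perturbation_signature, build_clusters
from rootgrn.pipeline import hormone_responsive_genes, mutant_panel_comparisons
from rootgrn.temporal_zones import assign_zones, collapse_zones

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=4)
    args = parser.parse_args()

    truth = sd.default_truth()
    study = sd.simulate_dataset(truth, sd.default_design(), seed=args.seed)
    comparisons = mutant_panel_comparisons(study)
    hormones = tuple(truth.hormone_treatment)
    sig = perturbation_signature(comparisons, hormone_perturbations=hormones)

    responsive = hormone_responsive_genes(comparisons, hormones)
    shared = responsive["IAA"] & responsive["ACC"]
    print(f"hormone-responsive genes: IAA {sorted(responsive['IAA'])}, "
          f"ACC {sorted(responsive['ACC'])}; shared: {sorted(shared)}")

    genes = truth.gene_nodes
    zones = collapse_zones(assign_zones(study.sections, genes))
    panel = sorted(k for k in comparisons if k.endswith("ko"))
    clusters = build_clusters(
        sig.restrict(genes), zones, panel, robust_min=6
    )

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tcollapsed_zone\trobust\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.collapsed_zone.value}\t"
                f"{int(c.robust_flag)}\t{';'.join(c.members)}\n"
            )

    print(f"{len(clusters)} regulatory clusters over {len(genes)} pathway genes:")
    for c in clusters:
        robust = " (robust)" if c.robust_flag else ""
        print(f"  {c.cluster_id} [{c.collapsed_zone.value}]{robust}: "
              f"{', '.join(c.members)}")


if __name__ == "__main__":
    main()
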