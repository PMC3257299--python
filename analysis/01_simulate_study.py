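#!/usr/bin/env python
"""Simulate the perturbation study from the default ground truth.

Generates the 66-sample learning design (four foundational mutant lines at
two facilities plus the single-site mutant panel) together with the
hormone-transfer series, the phenotype measurements and the
longitudinal-section profiles, and writes everything under results/ as TSV
plus the ground truth as JSON so later stages and readers can check any
number in this pipeline against the truth.

Usage: python analysis/01_simulate_study.py [--seed 4]
"""

import argparse
from pathlib import Path

import numpy as np

from rootgrn import synthetic_data as sd
from rootgrn.core_data import write_expression_table, write_sample_sheet

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=4)
    args = parser.parse_args()

    truth = sd.default_truth()
    design = sd.default_design()
    study = sd.simulate_dataset(truth, design, seed=args.seed)

    RESULTS.mkdir(exist_ok=True)
    write_expression_table(study.expression, RESULTS / "expression.tsv")
    write_sample_sheet(study.samples, RESULTS / "samples.tsv")
    truth.to_json(RESULTS / "truth.json")
    design.to_yaml(RESULTS / "design.yaml")

    with open(RESULTS / "sections.tsv", "w") as fh:
        cols = [f"root{r}_s{i}" for r in (1, 2) for i in range(1, 13)]
        fh.write("gene_id\t" + "\t".join(cols) + "\n")
        for g, row in zip(truth.gene_nodes, study.sections):
            fh.write(g + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")

    with open(RESULTS / "phenotypes.tsv", "w") as fh:
        fh.write("sample_id\thair_length_um\tbranching_fraction\n")
        for j, s in enumerate(study.samples):
            fh.write(
                f"{s.sample_id}\t{study.phenotypes['P_LEN'][j]:.1f}\t"
                f"{study.phenotypes['P_BRANCH'][j]:.3f}\n"
            )

    n_learning = sum(1 for s in study.samples if s.treatment.value == "NONE")
    print(f"simulated {len(study.samples)} arrays ({n_learning} learning + "
          f"{len(study.samples) - n_learning} hormone-transfer)")
    print(f"chip: {study.expression.n_genes} genes "
          f"({len(truth.gene_nodes)} pathway + {len(truth.background_means)} background)")
    print(f"truth: {len(truth.edges())} causal edges, "
          f"{len({s.genotype for s in study.samples if s.genotype})} knockout genotypes")
    print(f"written to {RESULTS}/")


if __name__ == "__main__":
    main()
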