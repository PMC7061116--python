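#!/usr/bin/env python
"""Planted-gene recovery on synthetic cohorts across noise levels.

For each noise rate, generates cohorts over a seed ensemble, runs the
full assignment + combination + prioritization pipeline, and reports the
mean sensitivity/specificity of recovering the planted pathogenic genes.
At zero noise recovery is perfect by construction; rising noise injects
spurious strong evidence into non-planted genes and erodes specificity.
Writes results/synthetic_recovery.tsv.
"""

from pathlib import Path

import pandas as pd

from bradyvar.acmg import classify_profile
from bradyvar.assignment import assign_codes
from bradyvar.prioritize import high_priority_genes, summarize_by_gene
from bradyvar.simulate import CohortSpec, gen_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
NOISE_RATES = (0.0, 0.1, 0.3, 0.5, 0.8)
SEEDS = range(1, 21)


def recover(cohort):
    def classify(rec):
        return classify_profile(
            assign_codes(rec.annotations, cohort.gene_configs[rec.gene]))

    summaries = summarize_by_gene(list(cohort.records),
                                  verdict_source="computed",
                                  classifier=classify)
    return set(high_priority_genes(summaries))


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for noise in NOISE_RATES:
        sens, spec = [], []
        for seed in SEEDS:
            cohort = gen_cohort(CohortSpec(
                n_genes=10, n_variants=60, n_planted=2, noise_rate=noise,
                seed=seed))
            recovered = recover(cohort)
            planted = set(cohort.planted_genes)
            negatives = set(cohort.genes) - planted
            sens.append(len(recovered & planted) / len(planted))
            spec.append(len(negatives - recovered) / len(negatives))
        rows.append({
            "noise_rate": noise,
            "n_seeds": len(sens),
            "mean_sensitivity": sum(sens) / len(sens),
            "mean_specificity": sum(spec) / len(spec),
        })
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "synthetic_recovery.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    print("\nspecificity declines with noise; sensitivity stays 1.0 because "
          "planted variants keep their guaranteed evidence")


if __name__ == "__main__":
    main()
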