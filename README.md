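# bradyvar

ACMG/AMP reclassification toolkit for the genetics of familial bradycardia
(sick sinus syndrome, atrioventricular block, progressive cardiac conduction
disease).

Pedigree studies of inherited bradycardia report candidate variants whose
clinical significance was often asserted before systematic evidence
standards existed. `bradyvar` reimplements, as a tested pipeline, the
reevaluation of those reports under the 2015 ACMG/AMP variant-classification
framework: it ships the curated literature dataset (99 variant records over
34 genes, from a screen of 1015 articles of which 88 were included),
recomputes the per-gene aggregation that yields the 13-gene high-priority
panel for familial bradycardia, and provides the full classification engine
so new annotated cohorts can be scored the same way.

## The model

Evidence for one variant is a set of codes from the 28-criterion ACMG/AMP
taxonomy — pathogenic codes PVS1, PS1–PS4, PM1–PM6, PP1–PP5 (very strong /
strong / moderate / supporting) and benign codes BA1, BS1–BS4, BP1–BP7
(stand-alone / strong / supporting). Classification depends only on the
per-strength counts (n_PVS, n_PS, n_PM, n_PP, n_BA, n_BS, n_BP), combined
through count-threshold lines such as

```
Pathogenic:         1 PVS1 + ≥1 PS   |  ≥2 PS  |  1 PS + ≥3 PM  | ...
Likely pathogenic:  1 PVS1 + 1 PM    |  1 PS + 1–2 PM  |  ≥3 PP | ...
Benign:             1 BA1  |  ≥2 BS
Likely benign:      1 BS + 1 BP  |  ≥2 BP
```

into the five tiers *pathogenic, likely pathogenic, uncertain significance,
likely benign, benign*. When satisfied combinations exist on both the
pathogenic and benign side, the evidence is contradictory and the result is
uncertain significance. Two rule dialects are built in: `paper_verbatim`
(the combination table exactly as printed in the review being reproduced,
including its `≥3 supporting` likely-pathogenic line) and `acmg2015` (the
standard guideline table). The engine is verified against a brute-force
oracle on all 33,600 admissible count vectors in both dialects.

Upstream of the engine, an assignment layer maps annotation facts to codes
— e.g. allele frequency < 0.001 ⇒ PM2, > 0.5% ⇒ BA1 (both comparisons
strict), null variant in a loss-of-function-mechanism gene ⇒ PVS1,
confirmed de novo ⇒ PS2 — and passes curator-asserted codes through
untouched. Downstream, per-gene aggregation flags a gene *high priority*
when any of its records is pathogenic or likely pathogenic.

## Worked example

Reproduce the headline numbers from the shipped curated dataset:

```
$ bradyvar reproduce
headline numbers (computed vs published)
  included_articles         88   (published: 88)
  variant_records           99   (published: 99)
  distinct_genes            34   (published: 34)
  high_priority_genes       13   (published: 13)
high-priority genes: ABCC9, ACTN2, CACNA1C, DES, HCN4, KCNH2, KCNQ1, LAMP2, LMNA, MECP2, NPPA, SCN5A, TRPM4
genes demoted to uncertain significance: APOB, CLCA2, GJC1, GLA, GNB2, JPH2, KCNJ3, MYBPC3, NKX2-5, NXF5, PDYN, PRKAG2, TTN
```

88 articles survived screening (1015 enrolled − 927 excluded); their 99
variant records span 34 genes; 13 genes carry at least one
pathogenic/likely-pathogenic record and form the recommended bradycardia
gene panel; 13 genes previously published as pathogenic have no record
stronger than uncertain significance in the reevaluated SNV table.

Audit a single evidence profile:

```
$ bradyvar explain PVS1 PM2 PS3
...
[pathogenic]
  MATCH  1 PVS1 + >=1 PS
...
matched lines: 4
classification: pathogenic
```

Classify your own cohort (TSV with `record_id`, `gene` and any
annotation columns `allele_frequency`, `consequence`, `de_novo`,
`segregates_in_family`, `functional_study`, `in_silico_verdict`,
`hotspot_or_domain`, `observed_healthy_recessive`, `manual_codes`,
optionally per-gene `lof_mechanism` / `missense_constrained`; or a VCF
carrying INFO keys `AF`, `GENE`, `CSQ_CLASS`, `DENOVO`, `SEGREGATION`,
`FUNC`, `INSILICO`, `MANUAL`):

```bash
bradyvar simulate -o sim/ --seed 1 --n-genes 5 --n-variants 30 --n-planted 2
bradyvar classify sim/cohort.tsv -o out/   # writes variants.tsv + gene_report.tsv
```

The numbered scripts under `analysis/` run the same library end to end
(headline reproduction, exhaustive engine audit, synthetic planted-gene
recovery, gene × phenotype overlap) and write their tables under
`results/`.

## Layout

- `src/bradyvar/acmg.py` — code taxonomy, rule dialects, combination engine
- `src/bradyvar/assignment.py` — annotation bundle → evidence codes
- `src/bradyvar/dataset.py` — curated fixture, screening ledger, VCF export
- `src/bradyvar/prioritize.py` — per-gene summaries, high-priority panel
- `src/bradyvar/simulate.py` — synthetic cohorts with planted genes
- `src/bradyvar/cli.py` — `bradyvar classify | reproduce | simulate | explain`
- `docs/methods.md` — modelling choices, conventions and limitations
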