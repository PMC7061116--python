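# Methods

## The combination engine

The engine classifies one variant from its evidence-code counts alone.
A profile is a set of distinct codes from the 28-criterion ACMG/AMP
taxonomy; its count vector (n_PVS, n_PS, n_PM, n_PP, n_BA, n_BS, n_BP) is
recomputed from the codes on demand, so the two can never drift apart.
Duplicate assertions of one code are rejected rather than counted twice:
each criterion applies at most once per variant.

Combination lines are stored as data (YAML per dialect) in the form
"minimum count per strength category", and a line matches when every
minimum is met. **Thresholds are lower bounds.** The printed tables mix
phrasings ("1 PVS1", "≥2 PS", "1–2 PM"); we read every number as *at
least*, for two reasons. First, exceeding a line's literal count always
lands in evidence territory covered by the same or a higher-tier line, so
the exact-count and at-least readings only differ where the exact reading
would *demote* a variant for having more pathogenic evidence (e.g.
2 PM + 2 PP is likely pathogenic but 3 PM + 2 PP would become uncertain),
which no sane evidence calculus intends. Second, the lower-bound reading
makes the tier provably monotone in pathogenic evidence on benign-free
profiles — a property the test suite checks by exhaustive enumeration of
all 420 benign-free count vectors and every single-step increment.

Evaluation order: the pathogenic side resolves to the strongest satisfied
tier (any pathogenic line, else any likely-pathogenic line); the benign
side likewise (BA1 or ≥2 BS ⇒ benign, else a likely-benign line). If both
sides hold, the evidence is contradictory and the classification is
uncertain significance with a flag; if neither holds, uncertain
significance without it. The contradiction pathway therefore requires a
*satisfied combination* on each side — a lone strong pathogenic code next
to BA1 does not contradict anything, because a single PS meets no
combination line, and the stand-alone BA1 line decides (⇒ benign). This is
the minimal operational reading of the printed clause; alternatives that
treat any pathogenic *code* as one side would let a single supporting code
veto a stand-alone benign call, which we judged wrong for a framework whose
benign side is anchored by a stand-alone criterion. Within a tier, line
order is irrelevant (lines are disjunctive); the order only shapes the
`explain` report.

Two dialects ship. `paper_verbatim` (the default) encodes the combination
table of the review this package reproduces exactly as printed: its
likely-pathogenic block contains "≥3 supporting" where the 2015 guideline
has "≥3 moderate", and its pathogenic block omits the guideline's
"PVS1 + 1 moderate + 1 supporting" line. `acmg2015` restores both. No
intent is guessed: the default reproduces the review, the alternative is a
configuration switch. Enumerating all 33,600 admissible count vectors, the
dialects disagree on 963 vectors (2.9%), all of them touched by one of the
two changed lines; the engine-vs-oracle audit (a literal line-by-line
translation, independent of the YAML machinery) covers both dialects over
the full enumeration.

## Evidence assignment

The assignment layer automates the codes that follow mechanically from a
small annotation bundle; everything else is curator input.

Frequency rules use the review's thresholds: PM2 for allele frequency
strictly below 0.001 (default `pm2_max_af`), BA1 strictly above 0.005
(default `ba1_min_af`). Both comparisons are strict — "under 0.001" and
">0.5%" exclude their boundary points — and the two defaults are required
to satisfy `pm2_max_af < ba1_min_af`, which makes PM2 and BA1 mutually
exclusive. An *absent* frequency counts as "absent from large population
studies" and yields PM2: the curated frameshift/deletion/splice tables
list no population frequency for variants that were nonetheless evaluated,
and absence-from-gnomAD is precisely the PM2 situation.

Structural rules: PVS1 for null consequences (nonsense, frameshift,
canonical ±1/±2 splice, large deletion) **only** in a gene configured with
`lof_mechanism = true` — without gene-level configuration the code is
withheld, since PVS1 is conditional on mechanism; PM4 for in-frame indels
and stop-loss; PP2 for missense in a `missense_constrained` gene.
Observation rules: PS2/PM6 for confirmed/unconfirmed de novo, PS3/BS3 for
functional-study direction, PP1/BS4 for segregation, PP3/BP4 for in-silico
direction, PM1 for hot-spot/domain location, BS2 for observation in a
healthy adult under recessive inheritance. Because each of these pairs is
driven by one enum, the auto rules can never emit both members of a pair.

Codes needing knowledge the bundle does not model (PS1, PS4, PM3, PM5,
PP4, PP5, BS1, BP1–BP3, BP5–BP7) pass through as manual assertions,
additive and never auto-revoked; set union prevents double counting when a
curator repeats an auto-assignable code. BS1 in particular is manual-only:
no disorder-specific frequency threshold is stated anywhere in the source
material, and we decline to invent one.

Splice records are mapped from their HGVS description: intronic offsets of
±1/±2 are canonical-splice (null-variant convention), deeper offsets are
other splice region.

## Curated dataset conventions

Each printed table row is one record — the convention under which the
published total of 99 is reproducible. Consequences: the SNV reported
independently by two studies (HCN4 15:73329719) is two records, as is the
twice-listed MYL4 c.234delC. Per-table counts are 73 (SNVs with published
rule-engine verdicts), 16 (frameshift), 1 (large deletion), 9 (splice).
Gene symbols are normalized ("NKX2.5" → "NKX2-5", "TGF beta 1" → "TGFB1")
with the printed spelling retained, which is what makes the distinct-gene
count come to 34. Irregular frameshift-table cells ("c.5368 GNA", rows
with no locus or verdict) are transcribed verbatim with absent fields; no
correction is attempted. Coordinates are 1-based GRCh38 as curated, and
the VCF 4.2 exporter writes exactly the coordinate-complete records (the
73 SNVs; the other tables lack alleles), with classification and source in
INFO. Fixtures carry SHA-256 sidecars verified on load.

The published per-variant verdicts in the SNV table were produced by an
external automated interpreter whose per-variant evidence profiles were
never published; they are therefore carried as data and are **not**
recomputed here. Prioritization consumes printed verdicts for the curated
dataset and computed verdicts for user or synthetic cohorts, selected by a
flag.

Slashed verdicts ("Pathogenic/likely pathogenic", "Benign/likely benign")
are kept as pairs; ranking uses the stronger side (further from
uncertain). P/LP therefore qualifies a gene as high priority — a reading
forced by the published 13-gene panel itself, which contains three genes
whose best record is slashed. "Conflicting interpretations of
pathogenicity" ranks as uncertain. Records without any verdict contribute
as uncertain, which is why the demoted-to-VUS list is computed over the
SNV table only. Two documented discrepancies in the source material are
reported as printed rather than harmonized: the prose list of
demoted-to-VUS genes includes DSG2 and LDB3, whose table verdicts are
Benign/likely benign and Benign (they are excluded here); and the prose
phenotype discussion names GJA5, GNB5 and DSP, which appear in no table
and hence not in the fixture.

Phenotype tokens map onto five categories (conduction disease, other
arrhythmia, cardiomyopathy/myopathy, nervous system, other). Assignments
of note: Timothy syndrome → other arrhythmia (long-QT spectrum); heart
failure, ASD, congenital cardiovascular disease, atrial dilatation and
FSGS → other. The mapping is total over the fixture; unknown tokens fall
back to *other* with a logged warning. The nervous-system category is
reachable (token "nerve system disease") but unused by the fixture, for
the GJA5/GNB5/DSP reason above.

## Synthetic cohorts

The generator exists to make the full pipeline testable without the
curated fixture. It emulates the *evidence structure* the assignment layer
consumes, not population genetics: no linkage, no site-frequency spectrum,
no sequence context. Passing recovery tests therefore demonstrate that the
pipeline is correct on well-posed evidence, not that real cohorts are this
clean.

Variants in planted genes draw bundles that provably classify at least
likely pathogenic at zero noise: either a null variant in a
loss-of-function gene with rarity (PVS1 + PM2), or a hot-spot missense
with forced segregation and in-silico support (PM1 + PM2 + PP1 + PP3);
optional extras (confirmed de novo, supporting functional study) can lift
them to pathogenic but are never needed. Non-planted variants are either
common and benign-leaning (allele frequency uniform on [0.01, 0.5] ⇒ BA1)
or rare with no further evidence (log-uniform on [1e-6, 5e-4] ⇒ PM2 only,
uncertain). Both frequency supports straddle their decision thresholds
with wide margins on purpose: boundary behaviour is the job of the
explicit boundary tests, not of random draws. `noise_rate` is the
probability that a non-planted variant instead receives spurious strong
evidence (confirmed de novo + supporting functional study ⇒ two strong
codes ⇒ pathogenic regardless of gene configuration); it degrades
specificity while sensitivity stays at 1 by construction. Defaults
(10 genes, 50 variants, noise 0) describe a small pedigree-literature-like
cohort; recovery experiments in the analysis scripts and acceptance run
use 8–10 genes, 48–60 variants and 20 replicates, sizes at which every
planted gene receives several variants and the seed ensemble is stable.
All randomness flows through a single explicit seed (one generator per
cohort); there is no global random state.

## Numerical and interface choices

- Classification depends only on count vectors; code identity within a
  strength class and insertion order are irrelevant (property-tested).
- Count bounds (n_PVS ≤ 1, …, n_BP ≤ 7) are enforced at classification
  time; out-of-range vectors raise rather than classify.
- The CLI exits 0 on clean runs, 2 on input problems (including skipped
  malformed rows), 3 on fixture-integrity failures. Diagnostics go to
  stderr, results to files/stdout. An empty input cohort is a clean run
  with empty outputs.
- `reproduce` is fully deterministic; `classify` is deterministic given
  its input.

## Known limitations

- The assignment layer models 15 of 28 codes automatically; the rest are
  curator pass-through, so a cohort annotated only with the bundle fields
  can never receive e.g. PS1 or PM5.
- No transcript-aware HGVS validation, no liftover, no live database
  queries; allele frequencies are taken as given.
- The demoted-to-VUS list and the high-priority panel are only as good as
  the printed verdicts they aggregate; this package reproduces, it does
  not re-adjudicate.
- Gene-specific rule refinements (strength modulation, points-based
  variants of the framework) are out of scope.
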