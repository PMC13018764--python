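# phenocompare

Per-participant comparison of parent-reported (PRD) and clinician-reported
(CRD) Human Phenotype Ontology term sets.  The package provides:

- **ontology** — an OBO flat-file parser building a validated `is_a` DAG
  with ancestor closure, descendant counts, information content (intrinsic
  descendant-count IC by default, corpus IC optional) and Lin term
  similarity (`2*IC(MICA) / (IC(a) + IC(b))`).
- **cohort_data** — long-format phenotype records (participant, source,
  body system, term) with TSV/JSON I/O, term resolution against the
  ontology (alt_id / replaced_by), deduplication and a load report.
- **scores** — the three per-participant scores: *quantity* (distinct term
  count), *detail* (ancestor-distance credit to the source reporting the
  more specific term, accumulated over all cross-source pairs) and
  *similarity* (symmetric best-match-average Lin similarity), plus the
  Parent-more / Doctor-more / Equal categories per scope.
- **stats** — McNemar's chi-square on discordant categories,
  Benjamini-Hochberg FDR, Welch one-way ANOVA and pairwise Welch t-tests
  with Holm adjustment; one adjustment family per analysis block.
- **reference_compare** — similarity of PRD / CRD / combined sets against
  a gene-to-phenotype reference list, with Welch ANOVA and gated pairwise
  follow-up per gene.
- **phenotype_query** — descendant-closure presence queries (e.g. seizure
  and any child code), four-way source stratification, subtype
  classification, term-frequency and unique-vocabulary tables.
- **synthetic_data** — a seeded generator of paired-source cohorts over the
  bundled ~55-term mini-ontology, with per-system detection rates,
  per-source specificity (exact term vs blurred ancestor) and
  common-phenotype noise, returning full ground truth for recovery tests.
- **cli** — `simulate`, `score`, `compare`, `query`, `refcompare` and
  `report` subcommands producing TSV tables plus a run manifest.

## CLI

```sh
phenocompare simulate --seed 7 --out-dir out/sim
phenocompare score --cohort out/sim/records.tsv --meta out/sim/meta.tsv \
    --scopes all --out-dir out/scored
phenocompare compare --scores out/scored/scores.tsv --meta out/sim/meta.tsv \
    --out-dir out/tests
phenocompare query --cohort out/sim/records.tsv --root-term HP:0001250 \
    --out-dir out/query
phenocompare report --in-dir out/scored --out-dir out/report
```

`--obo` accepts a real `hp.obo` path or the literal `fixture` (default) for
the bundled mini-ontology.  Exit codes: 2 for missing inputs, 3 for
validation failures.

## File formats

- Cohort records: TSV with header `participant_id  source  system  term_id`
  (`source` is `PRD` or `CRD`); JSON array-of-objects accepted.
- Metadata: TSV `participant_id  gene  gene_group`.
- Reference: TSV `gene  hpo_ids` with comma-separated HPO CURIEs.
- Ontology: OBO flat file (subset: `[Term]`, `id`, `name`, `is_a`,
  `alt_id`, `is_obsolete`, `replaced_by`).
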