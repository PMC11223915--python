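# varshare

A library and CLI implementing the backend of a multi-laboratory
hereditary-cancer variant-sharing database: per-lab dataset ingestion with
format mapping and pseudo-anonymization, record- and sample-level VCF
quality control, reference-based variant normalization, coverage-aware and
kinship-deduplicated allele frequencies, a tiered classification-concordance
ledger, and a three-phase discrepancy-resolution planner with revision
accounting. A deterministic fixtures module generates every input the
pipeline consumes, so nothing external is needed to build or test.

## Modules

| module | role |
|---|---|
| `varshare.core` | variant model, left/right indel normalization, canonical keys, cDNA coordinate mapping, main-transcript selection |
| `varshare.submission` | per-lab format specs (JSON), classification/individual table parsing, metadata validation, pseudonymization, version manifest |
| `varshare.record_qc` | per-record hard filters (FILTER/genotype/allele balance/depth/panel), VCF reading with caller-dialect adapters |
| `varshare.sample_qc` | Tukey-fence noisy/empty tests, duplicate scoring, robust pairwise kinship, relatedness clustering |
| `varshare.frequency` | AC/AN/AF per variant and metadata stratum, coverage-gated and cluster-deduplicated |
| `varshare.concordance` | latest-per-lab ledger, five/three/two-tier concordance, cohort summary, notification rule matching |
| `varshare.planner` | three-phase resolution assignment rules, scripted execution driver, revision accounting |
| `varshare.fixtures` | seeded synthetic references, cohorts (duplicates, kin pairs, noisy/empty samples) and classification fixtures |

## CLI

```sh
varshare make-fixture --seed 1 --out fixture/            # classification fixture
varshare make-fixture --recipe recipe.json --seed 1 --out cohort/
varshare ingest-classifications table.tsv --lab-spec spec.json --out ledger.tsv
varshare ingest-individuals table.tsv --lab-spec spec.json \
    --terms terms.txt --pseudonyms pmap.json --seed 1 --out individuals.tsv
varshare sample-qc --cohort cohort/manifest.json --seed 1 --out qc.tsv
varshare afreq --cohort cohort/manifest.json --strata sex --out af.tsv
varshare concordance-summary ledger.tsv --out-prefix summary
varshare plan ledger.tsv --phase 1 --seed 1 --out plan.tsv
varshare resolve fixture/ --seed 1 --out-prefix resolution
```

A cohort recipe is a JSON object with any of the `CohortRecipe` fields
(`n_unrelated`, `n_parent_offspring`, `n_duplicates`, `n_noisy`, `n_empty`,
`n_sites`, `maf`, ...); the seed always comes from `--seed`.

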