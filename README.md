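# lncsalt

Identification and characterization of long noncoding RNAs (lncRNAs) from
assembled transcripts and FPKM expression matrices, aimed at multi-tissue
salt-stress designs in paired plant species:

- **identify** — filtering cascade: expressed (FPKM ≥ 1 in at least one
  library) → length ≥ 200 nt → noncoding by a built-in coding-potential
  scorer (longest-ORF rule + Fickett TESTCODE statistic; score > 0 ⇒ coding
  ⇒ discarded). Precomputed external CPC/CNCI scores are honored when
  supplied.
- **classify** — strand-aware positional classes against coding gene models:
  `sense_overlap`, `antisense`, `intronic`, `lincRNA` (priority in that
  order), with host/nearest gene and distance.
- **expression** — per-tissue salt contrasts (0 vs 150, 0 vs 300,
  150 vs 300 mM) via pooled-variance t-tests on log2(FPKM + pseudocount);
  DE iff |log2FC| ≥ 1 and p < 0.05 (BH-adjusted column reported alongside);
  tissue-specificity index τ = Σᵢ(1 − xᵢ/x_max)/(n − 1); tissue-specific
  (τ > 0.9), housekeeping (τ < 0.1 and never salt-responsive) and
  tissue-specific-DE sets.
- **targets** — *cis*: genes within a 10-kb window of the lncRNA (intronic
  lncRNAs always pair with their host). *trans*: Smith–Waterman alignment of
  the lncRNA against the reverse complement of each mRNA gated at identity
  ≥ 95% and Karlin–Altschul E < 1e−5, then an RNA–RNA duplex minimum free
  energy gate (nearest-neighbor stacks, affine loop penalties) at
  ≤ −60 kcal/mol. Pairs are annotated with Spearman expression concordance.
- **homology** — cross-species lncRNA homologs as reciprocal best hits with
  an E-value gate; expression-pattern concordance of homolog pairs,
  species-specific DE sets, and per-tissue high-expression (FC > 4) pairs.
- **enrichment** — hypergeometric (upper-tail) term over-representation of
  predicted target genes with BH adjustment.
- **simulate** — a fully synthetic paired-species dataset generator with
  planted truth (positional classes, DE effects, tissue-specific profiles,
  homolog map, cis/trans target pairs) used by the test-suite and usable
  standalone.

All thresholds live in `PipelineConfig` and default to the conventional
values above; every output table records a hash of the configuration that
produced it, and the whole pipeline is byte-deterministic given a seed.

## CLI

Generate a synthetic dataset and run everything:

```sh
lncsalt simulate --out-dir data --n-genes 10 --n-lnc-per-class 5 --seed 7
lncsalt all --data-dir data --out-dir results
```

`results/` then contains per-species tables (`lncrnas_*.tsv`, `de_*.tsv`,
`tau_*.tsv`, `targets_*.tsv`, `enrichment_*.tsv`), the cross-species tables
(`homologs.tsv`, `species_specific.tsv`) and `summary.json` with per-stage
counts. Individual stages are available as `identify`, `classify`, `de`,
`tau`, `targets`, `compare` and `enrich` subcommands; thresholds can be
overridden with a YAML file via `--config`.

Input layout (written by `simulate`, readable from any source): per species
`annotation_{a,b}.gtf`, `transcripts_{a,b}.fa`, `expression_{a,b}.tsv`
(transcripts × samples FPKM), `samples_{a,b}.tsv` (sample sheet with
tissue/salt/replicate), optional `go_{a,b}.tsv` (gene → term).

## Notes

- The coding-potential scorer and the duplex energy model are deliberately
  reduced, self-contained stand-ins for external programs (CPC/CNCI and
  RNAplex respectively); they keep the published sign conventions and are
  validated against in-repo brute-force oracles, not against the external
  tools' outputs.
- The duplex energy threshold (−60) is interpreted as kcal/mol and is
  configurable (`duplex_energy_cut`).
- Cross-species FPKM values are compared directly, without between-species
  normalization.
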