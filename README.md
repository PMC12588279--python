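# finmix

Market-surveillance analysis toolkit for the dried shark-fin trade:
haplotype-based mixed-stock analysis (MSA), incidence-trend modelling of
survey data, and reconciliation of CITES-style trade ledgers with customs
records.

## What it does

- **`finmix.synthetic_data`** — seeded generators for every input the
  pipeline consumes: source-population baselines with known ground truth,
  market mixture samples, overlapping amplicon sequence sets, vendor-visit
  survey events, and trade/customs ledgers (including deliberately malformed
  records for filter testing).
- **`finmix.haplotyping`** — merges paired 388 + 168 bp amplicons into the
  full 535 bp mitochondrial control-region fragment with exact-overlap
  verification, collapses sequences into haplotype tables, and assigns
  market sequences to a baseline by exact match with `N` as a wildcard.
- **`finmix.population_structure`** — two-level AMOVA Phi-ST between
  population samples with permutation tests (random or exhaustive) and a
  distinct-vs-merge population delimitation rule with Bonferroni correction.
- **`finmix.mixed_stock`** — the analysis core: a Gibbs sampler for the
  Dirichlet-multinomial mixture model estimating source contributions to a
  market sample, with multi-chain Gelman-Rubin diagnostics (threshold 1.2),
  an independent EM conditional-MLE cross-check, and detected-but-unreported
  source summaries.
- **`finmix.market_trends`** — vendor-visit incidence statistics (presence of
  a species among 20 trimmings per visit), binomial-logit year-trend fits
  with Wald significance, and per-year proportional species contributions.
- **`finmix.trade_reconciliation`** — record filtering (kg / wild-caught /
  commercial-purpose fins only), importer-exporter report deduplication by
  the max rule, legal-share time series against customs totals, and the
  nation compliance-flagging logic.  Ships a packaged 90-nation exporter
  profile table (`finmix/data/hk_fin_exporters_2014_2022.csv`).
- **`finmix.pipeline` / `finmix.cli`** — end-to-end orchestration of a
  synthetic scenario with a reproducibility manifest.

## CLI

```bash
finmix run examples/scenario.yaml            # full pipeline + manifest
finmix simulate examples/scenario.yaml --seed 3 --out sim/
finmix msa --baseline base.csv --mixture mix.csv --iters 100000 \
       --burnin 50000 --chains 4 --seed 1
finmix trends --events events.csv --species "Sphyrna lewini" --alpha 0.05
finmix structure --candidate cand.fasta --baseline manifest.csv --perms 10000
finmix haplotype --frag-a A.fasta --frag-b B.fasta --baseline table.csv
finmix reconcile --cites cites.csv --customs customs.csv
```

All file formats are plain text: FASTA for sequences, CSV for matrices,
ledgers and survey events, YAML for scenario configs, JSON for summaries.

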