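# ccanet

Analysis pipeline for networks of co-occurring and anti-co-occurring
(mutually exclusive) cancer gene mutations ("CCA networks"):

- **pairstats** — per-gene mutation frequencies (raw and gene-length
  corrected) and per-pair contingency tables over co-sequenced samples,
  tested with a two-sided Fisher exact test; pairs at `p <= 0.02` become
  network edges, the odds ratio giving the direction (co vs anti).
  Benjamini–Hochberg q-values are reported alongside.
- **network** — CCA network construction plus topology metrics: degree,
  clustering coefficient `C = 2·(links among neighbors)/(k(k−1))`,
  connected components, unit-weight shortest-path distances, degree
  histograms, module label handling (and an experimental greedy detector).
- **signaling** — placement of co-occurring pairs in pathways and a typed
  cellular signaling network: pathway co-membership randomization test
  (uniform rewiring null, `p = (T+1)/(R+1)`), direct-interaction Fisher
  enrichment, and activation/repression/physical usage tests (chi-square
  goodness of fit plus link-resampling randomization with a joint null grid).
- **association** — the randomization engine, absolute mutation-frequency
  difference (AD) comparisons, absolute-Pearson expression similarity vs
  network distance (pairwise and distance-grouped Spearman), attribute
  correlations and the cellular-location gradient, and exact/asymptotic
  rank-sum tests.
- **module_analysis** — two-module contrasts: hypergeometric gene-set
  enrichment, methylation Fisher test, per-sample module mutation
  distribution with a mutation-count-preserving null, and module frequency
  comparison.
- **synthetic_data** — generators for every input with planted, recoverable
  structure (co/anti mutation pairs, typed signaling networks, expression
  profiles with distance-decaying similarity, annotation bundles).
- **io_formats** — TSV mutation tables (long and wide dialects), Pajek NET
  (edge value 1 = co, 2 = anti), GMT gene sets, typed signaling edge lists,
  expression matrices, gene metadata, gene lists and module labels. All
  writers round-trip.

## Test

```bash
python -m pytest tests/
```

One acceptance test (`test_criterion_4_supplementary_pajek_file`) requires
the journal's supplementary Pajek network file at
`data/pone.0013180.s001.net`; it fails with an explanatory message when the
file is absent (it is not redistributable and the build environment is
offline).

## CLI

```bash
# generate a synthetic input bundle
ccanet simulate --seed 7 --out-dir runs/inputs

# end-to-end: simulate -> pair tests -> network -> all analyses
ccanet run --simulate --seed 7 --reps 1000 --out-dir runs/demo

# individual stages
ccanet pairs     --mutations runs/inputs/mutations.tsv --out pairs.tsv
ccanet network   --mutations runs/inputs/mutations.tsv \
                 --metadata runs/inputs/metadata.tsv \
                 --export-pajek cca.net --metrics-out metrics.tsv
ccanet signaling --mutations runs/inputs/mutations.tsv \
                 --signaling runs/inputs/signaling.tsv \
                 --pathways runs/inputs/pathways.gmt --out signaling.json
ccanet assoc     --mutations runs/inputs/mutations.tsv \
                 --metadata runs/inputs/metadata.tsv --out assoc.json
ccanet modules   --mutations runs/inputs/mutations.tsv \
                 --labels runs/inputs/modules.tsv \
                 --methylated runs/inputs/methylated.txt --out modules.json
```

`ccanet run` also accepts a YAML config (`--config`) overriding cutoff,
replicate count, seed and all simulation parameters; a single seed fans out
to independent per-stage substreams.

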