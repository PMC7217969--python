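# slnet

Network meta-analysis and context-dependence scoring of synthetic-lethal
screens.

`slnet` integrates ranked hit lists from independent loss-of-function
screens over a protein-interaction network, asks whether the screens
converge at the pathway level even when they disagree at the gene level,
nominates candidate genes from dense network modules, scores isogenic
single-gene and combinatorial (query x array) knockdown screens across
growth conditions, and ranks candidates by a composite
context-independence score (score variance across conditions x genetic
suppressor count). A first-class synthetic-data generator produces every
input the pipeline consumes, so the whole analysis is testable without
external downloads.

## Package layout

| module | contents |
|---|---|
| `slnet.network` | interaction network + gene-set collections, GMT/TSV/SIF I/O, clique expansion, weight thresholding, seed-incident restriction |
| `slnet.simulate` | synthetic worlds: planted complexes, convergent studies, plate counts for single / pairwise / drug screens |
| `slnet.cross_study` | top-k hit lists, hypergeometric overlap, cross-study edge counts, permutation null (gene-resample or degree-rewire) |
| `slnet.mcode` | MCODE-style dense-module discovery, multi-study filtering, gene-set enrichment, network candidate extraction |
| `slnet.holdout` | percentile ranking of held-out screens, top-percentile accuracy |
| `slnet.screen` | NT-normalization, signed -log10(p) interaction scores, BH FDR, condition concordance, drug AUC |
| `slnet.emap` | plate-median Z-scoring, replicate averaging, interaction calls, suppressor counts, pathway bundles |
| `slnet.context` | composite context-independence ranking + rank-sum group comparison |
| `slnet.pipeline` / `slnet.cli` | config-driven orchestration and the `slnet` command |
| `slnet.benchmarks` | calibration and planted-recovery computations behind the acceptance report |

## CLI

```bash
slnet simulate --seed 1 --out demo                # generate a synthetic world
slnet integrate --studies demo/simulate/studies.tsv \
    --network demo/simulate/network.tsv --k 25 --n-perm 10000 \
    --null-mode gene-resample --seed 1 --out cross.tsv
slnet cluster --network demo/simulate/network.tsv \
    --studies demo/simulate/studies.tsv --gene-sets demo/simulate/truth.gmt \
    --k 25 --out modules.json
slnet score-screen --plates demo/simulate/screen_counts.csv \
    --mut-arm MUT,minimal --ctrl-arm CTRL,full --out scores.tsv
slnet score-emap --plates demo/simulate/emap_counts.csv --out-prefix emap
slnet rank-context --entries entries.tsv --out ranked.tsv
slnet run-all --seed 1 --out run_dir                  # everything end-to-end
```

`run-all` also accepts `--config cfg.yaml`; any key of
`slnet.pipeline.PipelineConfig` can be set there, unknown keys are
rejected before anything executes, and each stage directory carries a
`provenance.json` with the seed and config hash.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests (hypothesis) for
the structural invariants, and `tests/test_acceptance.py` with one test
per acceptance criterion (worked-example arithmetic, statistical
calibration, oracle equivalence, planted-structure recovery). Two
acceptance tests recompute counts from the source study's supplementary
data; they fail with an explanatory message unless those files are placed
under `data/supplementary/` (they are third-party downloads and are not
shipped):

* `data/supplementary/isogenic_screen_counts.csv` — long-form plate table
  (`plate_id, well, cell_line, condition, perturbation, replicate, count`)
  for the isogenic single-gene screen,
* `data/supplementary/emap_scores.tsv` — pairwise mean Z scores
  (`query_gene, array_gene, z_mean`).

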