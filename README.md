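# lumiscreen

Analysis pipeline for luminescent arrayed siRNA high-throughput screens,
with the accompanying transcriptomic and phosphoproteomic stages:

- **`lumiscreen.simulate`** — seeded generators for synthetic screens
  (384-well plates, randomized negative-control positions, multiplicative
  plate effects, planted activator/inhibitor genes), read-count tables,
  GMT gene-set libraries, and TMT phosphosite tables — each with a
  ground-truth table for recovery testing.
- **`lumiscreen.io`** — strict TSV/GMT readers and writers (plate maps,
  raw measurements, count tables, gene lists) with deterministic output
  ordering and JSON run-metadata sidecars.
- **`lumiscreen.hits`** — plate-by-plate normalization against the median
  of negative-control wells, per-replicate Z-scores
  (z = (x − mean)/sample SD over all test wells of a replicate),
  replicate-mean aggregation, and strict |Z| > 2 activator/inhibitor
  calling (activator: mean Z < −2, i.e. silencing lowered the signal),
  plus optional viability annotation.
- **`lumiscreen.expression`** — keep genes whose median read count
  strictly exceeds 20 and restrict the screened library to that set.
- **`lumiscreen.enrichment`** — over-representation analysis: exact
  Fisher/hypergeometric upper-tail p (rational arithmetic),
  Benjamini-Hochberg adjustment, a seeded permutation rank-deviation z,
  combined score ln(p)·z, and gene ratio k/K.
- **`lumiscreen.phospho`** — phosphosite filtering (reverse/contaminant
  removal, score difference > 5, localization probability > 0.5, both
  strict), per-sample log2 + median centering, pooled two-sample t tests,
  and the inclusive dual significance rule (p ≤ 0.05 and |Δ| ≥ 0.2).
- **`lumiscreen.pipeline` / `lumiscreen.cli`** — reproducible end-to-end
  runs; byte-identical outputs for identical configs and seeds.

## CLI

```sh
lumiscreen --help
lumiscreen simulate-screen --genes 3000 --plates 24 --activators 150 \
    --inhibitors 50 --seed 1 --out sim/
lumiscreen filter-expression --counts counts.tsv --min-median 20 --out expr/
lumiscreen call-hits --platemap sim/platemap.tsv \
    --measurements sim/measurements.tsv --threshold 2 --out hits/
lumiscreen enrich --query hits/genes.txt --gmt pathways.gmt \
    --universe universe.txt --alpha 0.05 --permutations 1000 --seed 1 --out enr/
lumiscreen phospho --table sites.tsv --test student \
    --order log-then-center --out ph/
lumiscreen run-all --config run.yaml
```

Exit codes: 0 success, 2 validation error, 3 degenerate data. Logs go to
stderr; results are TSV/JSON files stamped with a config hash and seed.

`run-all` reads a YAML config; minimal example:

```yaml
out_dir: results
seed: 1
screen:
  platemap: sim/platemap.tsv
  measurements: sim/measurements.tsv
  counts: counts.tsv        # optional expression prefilter
enrichment:
  gmt: [pathways.gmt]       # query defaults to the screen's hit genes
phospho:
  table: sites.tsv
```

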