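# m6avar

Analysis of m⁶A RNA methylation versus gene-expression variability in a
replicated two-tissue heat-stress design, with a seeded synthetic-data
generator providing ground truth for every stage.

The package is for computational biologists working with paired
RNA-seq/m⁶A-RIP-seq designs (e.g. *Arabidopsis* leaves and flowers under
control and heat stress, wild type and a demethylase mutant) who want a
tested, reproducible implementation of the analysis chain:

1. **Enrichment** — per-gene m⁶A score `E = log2((mean IP + c)/(mean input + c))`;
   a transcript is *methylated* when `E > 0`.
2. **Variability** — per-gene squared coefficient of variation over
   biological replicates, `CV² = (sd/mean)²` (sample sd); HVG/LVG classes by
   log2 CV² thresholds; variability quartiles.
3. **Peaks** — replicate-reproducibility filter (kept iff seen in both IP
   replicates), midpoint-based peak→gene assignment, composite
   5′UTR/CDS/3′UTR metagene density profiles.
4. **Motif** — RRACH (R = A/G, H = A/C/U) scan of the top-1000 enriched
   regions and a position frequency matrix.
5. **Inference** — methylated fraction per variability quartile, one-tailed
   Wilcoxon rank-sum comparisons against seeded size-matched random
   baselines, hypergeometric set overlaps, Pearson FC correlations, and the
   heat-response log2 FC matrix across tissue × genotype groups.

Inputs are standard formats: GTF gene models, genome FASTA, a gene × sample
FPKM TSV (sample metadata in `tissue.condition.genotype.fraction.repN`
column headers), scored BED peak calls per IP replicate, and optional
per-gene auxiliary score tables. Internal coordinates are 0-based half-open
everywhere; GTF is converted on read/write.

## Worked example

Generate the default synthetic study (2,000 genes; 3 input + 2 IP
replicates for every tissue × condition × genotype group) and run all
stages:

```python
from pathlib import Path
from m6avar import SimulationConfig, simulate, run_pipeline
from m6avar.cli import fixture_run_config

sim = SimulationConfig(seed=1, n_genes=2000)
simulate(sim, "demo/fixture")
cfg = fixture_run_config(sim, Path("demo/fixture"), Path("demo/out"))
report = run_pipeline(cfg)

assoc = report["stages"]["association"]
print(assoc["quartile_fractions"]["flower.CS.wt"]["fractions"])
print({k: round(v, 2) for k, v in assoc["heat_column_means"].items()})
print(report["stages"]["differential"])
print(report["stages"]["metagene"]["density_argmax"]["flower.CS.wt"])
```

prints

```
[0.888, 0.794, 0.688, 0.646]
{'leaf.wt': 2.82, 'flower.wt': 1.14, 'leaf.mutant': 2.45, 'flower.mutant': 0.6}
{'leaf': {'n_regulated': 23, 'rank_test_p': 0.527...}, 'flower': {'n_regulated': 252, 'rank_test_p': 0.0252...}}
0.745
```

Reading the numbers: the methylated fraction falls monotonically from the
least-variable quartile (Q1, 88.8%) to the most variable (Q4, 64.6%) — the
planted negative methylation–variability coupling is recovered. Heat
induction of the selected genes averages 2.82 log2 units in wild-type
leaves but is attenuated to 1.14 in flowers and 0.60 in mutant flowers.
The mutant gains ≥ two-fold m⁶A enrichment on 252 genes in flowers versus
23 in leaves (flower-specific hypermethylation), and the peak density peaks
at composite position 0.745, i.e. at the stop codon (CDS/3′UTR boundary,
0.75). All outputs (TSV tables, BED files, `report.json`, a checksum
manifest) are written under `demo/out/` and are byte-identical across
re-runs of the same config.

The same run is available from the shell:

```sh
m6avar simulate --outdir demo/fixture --seed 1 --n-genes 2000
m6avar run-all --config demo/fixture/run_config.yaml --outdir demo/out
```

plus per-stage subcommands (`variability`, `enrichment`, `peaks`,
`metagene`, `motif`, `associate`, `heat`, `report`).

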