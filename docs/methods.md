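# Methods

`m6avar` analyses the relationship between m⁶A RNA methylation and gene
expression variability in a replicated two-tissue heat-stress design, of the
kind produced by paired RNA-seq (input) and m⁶A-RIP-seq (IP) experiments on
*Arabidopsis* leaves and flowers. This note records the statistical model
behind each stage, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was open.

## Enrichment score and methylation call

For gene *g* in sample group *s* (a tissue × condition × genotype cell of
the design), the m⁶A enrichment is the log2 fold change of IP over input
abundance,

    E_{g,s} = log2( (mean IP FPKM + c) / (mean input FPKM + c) ),

with pseudocount `c = 0.1` FPKM (configurable). Replicates are averaged
before the ratio: the 2 IP vs 3 input replicates of the standard design
preclude pairing. A transcript is called *methylated* when `E > 0`
(strictly). The pseudocount bounds scores for dropout genes; with `c = 0`
and both means zero the score is undefined and flagged rather than raised.

With few replicates and a strict `> 0` cut, roughly half of all truly
unmethylated genes are called methylated by noise alone. This is a property
of the definition, not a defect of the implementation; group differences,
not absolute calls, carry the signal.

## Expression variability: CV² and HVG/LVG classes

Variability of gene *g* in group *s* is the squared coefficient of variation
of its input-fraction replicate FPKMs,

    CV² = (scale · sd / mean)²,

with the sample (n−1) standard deviation — standard for replicate-based
dispersion. Classification is on log2 CV²: above `hvg_min` → highly variable
(HVG), below `lvg_max` → lowly variable (LVG). Defaults ship as
`hvg_min = 5`, `lvg_max = −10`, `scale = 1`, with a caveat: with *n*
nonnegative replicates the sample CV² is bounded by *n*, so log2 CV² ≤ log2 3
≈ 1.58 for triplicates and the +5 threshold is unreachable under the
dimensionless reading. It is reachable under a percent-CV reading
(`cv_scale = 100`), so the scale is exposed rather than guessed. Analyses of
the synthetic fixture in this repository use `hvg_min = 0` with
`scale = 1` — matched to the generator's dispersion range so that both
classes are populated.

Degenerate cases: `sd = 0` with positive mean gives log2 CV² = −∞, which
satisfies any finite LVG bound — dropping such genes would silently delete
the most invariable ones. `mean = 0` is *undefined*, as are genes whose group
mean falls below a low-expression floor (`min_fpkm = 1`, configurable),
where CV² is numerically unstable.

Quartiles of variability (Q1 = least variable) are assigned by ascending
log2 CV² with ties broken by gene id; quartile sizes differ by at most one.

## Peak handling

Peaks arrive as scored BED intervals per IP replicate. A peak is
*reproducible* when it overlaps (≥ 1 bp) a peak of the other replicate; the
retained interval is the union of the pair, its score their mean, and each
confirming peak is consumed at most once, matching greedily in ascending
coordinate order. Peaks are assigned to the gene whose transcript span
contains their midpoint; ties between overlapping genes break by largest
span–peak overlap, then lexicographic gene id. Midpoint assignment is a
single unambiguous rule, invariant to peak-width differences between
samples.

## Metagene profile

Each assigned peak midpoint is projected, strand-aware, onto a composite
transcript axis: 5′UTR → [0, 0.25), CDS → [0.25, 0.75), 3′UTR → [0.75, 1).
Fixed region widths (configurable) keep curves directly comparable across
samples; a midpoint falling in a gap between annotated regions snaps to the
nearest region edge. The profile is a 100-bin histogram smoothed with a
Gaussian kernel (σ = 2 bins, reflecting boundaries — a transcript has ends,
and periodic smoothing would leak 3′UTR density into the 5′UTR) and
normalised to unit area. The stop codon sits at composite 0.75.

## RRACH motif

The m⁶A consensus 5-mer RRACH (R = A/G, H = A/C/U) is scanned in the top-N
(default 1000) highest-scoring peak regions, each read on the strand of its
assigned gene; overlapping matches all count, N never matches. Matches are
pooled with equal weight into a 5 × 4 position frequency matrix in the RNA
alphabet. The pattern forces structural zeros (C/U at positions 1–2, any
non-A at 3, non-C at 4, G at 5), asserted as invariants. Output is a
frequency TSV plus a transfac-style count block for external logo renderers.

## Inferential layer

* **Rank tests.** One-tailed Wilcoxon rank-sum (Mann–Whitney): exact null
  when n_x + n_y ≤ 20 and tie-free, otherwise normal approximation with tie
  and continuity corrections. The direction is always explicit — mutant
  enrichment *greater* than wild type; regulated genes' variability change
  *less* than baseline; candidate gene sets' auxiliary scores *greater*.
* **Random baselines** are size-matched draws without replacement from the
  universe minus the query set, seeded and returned for reproducibility.
* **Set overlaps** use the upper-tail hypergeometric probability
  P(X ≥ observed), with fold enrichment observed/expected.
* **Heat-response matrix.** log2 FC (heat / control, pseudocounted input
  means) per group, rows restricted to genes induced at least two-fold
  (inclusive) in wild-type leaves, columns ordered wt leaf, wt flower,
  mutant leaf, mutant flower.
* No multiple-testing correction is applied by default (one test per
  claim); a Benjamini–Hochberg helper is provided for batch enrichments.

## Synthetic-data generator

The generator emits a complete fixture — GTF, genome FASTA, expression TSV,
per-replicate peak BEDs, auxiliary scores, ground truth — as a pure function
of a seeded configuration (outputs are byte-identical across runs).

**Genome.** Single-transcript genes laid head-to-tail on one chromosome
with 500-nt spacers, random strands; region lengths drawn around means
(150, 900, 250) nt, sd 20%, floor 30 nt, CDS rounded to a codon multiple.

**Expression.** Gene baseline medians μ_g are lognormal
(log2 μ ~ N(4, 1.5), i.e. typical FPKM ≈ 16); per-gene log-scale dispersion
σ_g is lognormal (ln σ ~ N(ln 0.2, 1)), spanning quiet (<5% CV) to very
noisy (>100% CV) genes. Input replicates are lognormal draws
μ·exp(σ·z). IP replicates are modelled as aliquots of the same biological
material: the input level of the matching replicate times 2^E times a small
capture jitter (sd 0.1 log2 units). This shared-noise construction matters:
anchoring IP at the input *median* instead biases the measured enrichment by
−σ²/2·log2 e for dispersed genes (the arithmetic mean of lognormal
replicates exceeds the median) and fabricates a negative
methylation–variability trend even with all effects disabled; with the
aliquot model the null pipeline declares a monotone quartile trend at chance
rate (~1/24).

**Planted effects**, each independently switchable and recorded in the
ground-truth table:

| effect | default | meaning |
|---|---|---|
| methylation | leaf 0.3, flower 0.5 | per-tissue probability a gene carries an m⁶A site |
| enrichment E | Uniform(1, 4) log2 | IP/input fold of a methylated gene |
| coupling | 0.3 at E = 2.5 | dispersion multiplier `coupling^(E/2.5)`: methylation damps noise |
| mutant shift | +1.5 log2 on 25% of flower-methylated genes | flower-specific hypermethylation in the demethylase mutant |
| heat induction | +3 log2 in 200 genes | induction in heated wild-type leaves |
| attenuation | leaf 1.0 / flower 0.5 / mutant flower 0.25 | multiplier on heat induction per tissue × genotype |
| aux scores | shift +1.0 | methylated genes' auxiliary (e.g. stress-granule) scores |

The coupling is a smooth function of enrichment rather than a binary
methylated/unmethylated factor, so hypermethylated genes in the mutant
flower are damped further — which is exactly the signal the
regulated-genes-versus-random variability comparison must recover.

**Peaks.** Each gene has one fixed m⁶A site, drawn once near the CDS/3′UTR
junction (Gaussian, sd 50 nt, clipped into the transcript) and shared across
groups and replicates — a site is a transcript property, and per-group sites
would overwrite each other's planted motif bases. Methylated genes get one
100-nt peak per IP replicate at that site, score = planted E plus N(0, 0.1)
jitter; 10% of peak loci are made replicate-specific to exercise the
reproducibility filter (expected retention 90%). The GGACU motif is written
into the genome at every methylated site, strand-aware.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level sampling (no counts, no FASTQ, no
mapping bias), splicing isoforms and overlapping genes (a separate stress
fixture covers assignment tie-breaks), peak-caller artefacts (peaks are
emitted directly), background RRACH occurrences beyond uniform sequence,
batch effects, and any mean–variance trend — dispersion is independent of
expression level by construction, so the package's variability statistics
are validated for ranking and class recovery, not for mean-trend
correction, which is an explicit non-goal.

## Problem sizes and calibration

The study-scale fixture used for parameter-recovery checks has 2,000 genes
(8 groups × (3 input + 2 IP) = 40 samples), which makes every recovery
margin wide: ≥ 98% of mutant-shifted genes flagged in flower versus < 2%
in leaf at the two-fold threshold; metagene argmax within half a bin of the
stop-codon boundary. Null calibration runs 200 seeds at 150–200 genes with
all effects off and checks Kolmogorov–Smirnov uniformity of p-values and a
chance-level rate of monotone quartile trends. Unit fixtures use 250–300
genes.

## Known limitations

* Enrichment is gene-level (mean FPKM ratio), not exon-aware or
  isoform-resolved; peaks in transcript space are approximated by genomic
  midpoints within a three-region model.
* The exact-rank-test branch requires tie-free data; heavily tied small
  samples fall back to the tie-corrected normal approximation.
* The strict `E > 0` methylation call is noise-sensitive by design (it
  mirrors the definition it implements); downstream fractions should be
  compared between conditions, not interpreted absolutely.
* The hypergeometric overlap test and rank tests assume exchangeable genes;
  no correction for gene length, expression level or GC content is applied.
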