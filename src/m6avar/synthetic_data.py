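"""Seeded synthetic fixtures with the statistical structure the analysis assumes.

The generator emulates a two-tissue (leaf/flower) heat-stress MeRIP-seq +
RNA-seq design: 3 input (RNA-seq) replicates and 2 IP replicates per
(tissue, condition, genotype) group; tissue-specific methylation that is
stronger in flowers; a planted negative coupling between a gene's m6A
enrichment and its replicate-to-replicate dispersion (hence CV^2); a mutant
genotype with flower-specific hypermethylation of a gene subset; heat-induced
genes whose log2 induction is attenuated in flowers and further in mutant
flowers; and 100-nt peaks centred near the stop codon carrying an RRACH
motif instance.

Everything is a pure function of :class:`SimulationConfig`; each stage seeds
its own generator from ``(seed, stage_index)`` so outputs are byte-identical
across runs and stages can be re-run independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (
    CONDITIONS,
    GENOTYPES,
    TISSUES,
    ExpressionMatrix,
    GenomicInterval,
    GroupKey,
    Peak,
    PeakSet,
    SampleKey,
    TranscriptModel,
    write_gene_models,
)

CHROM = "chrS"

_DNA = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = dict(zip("ACGTN", "TGCAN"))


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-like conditions."""

    seed: int = 0
    n_genes: int = 2000
    # mean region lengths (utr5, cds, utr3) in nt
    region_lengths: tuple[int, int, int] = (150, 900, 250)
    n_input_reps: int = 3
    n_ip_reps: int = 2
    spacer: int = 500
    min_region: int = 30
    # methylation design
    frac_methylated_by_tissue: dict[str, float] = field(
        default_factory=lambda: {"leaf": 0.3, "flower": 0.5}
    )
    enrichment_range: tuple[float, float] = (1.0, 4.0)  # planted log2 IP/input
    # variability coupling: sigma multiplier reached at enrichment_scale log2 units
    coupling: float = 0.3
    enrichment_scale: float = 2.5
    # mutant (demethylase-deficient) genotype: flower-specific hypermethylation
    mutant_shift: float = 1.5  # extra log2 enrichment
    mutant_shift_fraction: float = 0.25  # of flower-methylated genes
    # heat response
    n_heat_genes: int = 200
    heat_log2fc: float = 3.0
    attenuation: dict[str, float] = field(
        default_factory=lambda: {
            "leaf.wt": 1.0,
            "flower.wt": 0.5,
            "leaf.mutant": 1.0,
            "flower.mutant": 0.25,
        }
    )
    # expression noise model (lognormal on FPKM)
    log2_median_loc: float = 4.0
    log2_median_scale: float = 1.5
    sigma_log_loc: float = float(np.log(0.2))  # ln of the log-scale sd
    sigma_log_scale: float = 1.0
    ip_jitter_sd: float = 0.1  # log2 units on IP replicates
    # peaks
    motif: str = "GGACU"
    peak_width: int = 100
    peak_center_sd: float = 50.0
    replicate_specific_fraction: float = 0.1
    score_jitter_sd: float = 0.1
    # auxiliary per-gene scores (e.g. stress-granule enrichment)
    aux_effect: float = 1.0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_input_reps < 2:
            raise ValueError(
                "need >= 2 input replicates per group (CV^2 undefined otherwise)"
            )
        if self.n_ip_reps < 1:
            raise ValueError("need >= 1 IP replicate per group")
        for t, p in self.frac_methylated_by_tissue.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"frac_methylated[{t}] must be in [0,1]")
        for k, a in self.attenuation.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"attenuation[{k}] must be in [0,1]")
        if not 0.0 <= self.replicate_specific_fraction <= 1.0:
            raise ValueError("replicate_specific_fraction must be in [0,1]")
        if self.coupling <= 0:
            raise ValueError("coupling must be > 0")
        if len(self.motif) != 5:
            raise ValueError("motif must be a 5-mer")

    def groups(self) -> list[GroupKey]:
        return [
            GroupKey(t, c, g) for t in TISSUES for c in CONDITIONS for g in GENOTYPES
        ]


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with every planted effect switched off (calibration)."""
    kwargs: dict = dict(
        seed=seed,
        coupling=1.0,
        mutant_shift=0.0,
        heat_log2fc=0.0,
        aux_effect=0.0,
        frac_methylated_by_tissue={"leaf": 0.4, "flower": 0.4},
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@dataclass
class GroundTruth:
    """Per-gene planted flags and parameters, consistent with emitted files."""

    table: pd.DataFrame  # index gene_id
    enrichment: pd.DataFrame  # gene x group label, planted log2 E
    sigma: pd.DataFrame  # gene x group label, effective log-scale dispersion
    peak_centers: dict[tuple[str, str], int]  # (group label, gene) -> center

    def methylated_genes(self, tissue: str) -> set[str]:
        return set(self.table.index[self.table[f"methylated_{tissue}"]])

    @property
    def shifted_genes(self) -> set[str]:
        return set(self.table.index[self.table["mutant_shifted"]])

    @property
    def heat_genes(self) -> set[str]:
        return set(self.table.index[self.table["heat_induced"]])

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.8g")


# ---------------------------------------------------------------------------
# Stage 1: genome + gene models
# ---------------------------------------------------------------------------

def generate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, TranscriptModel], dict[str, np.ndarray]]:
    """Lay single-transcript genes head-to-tail on one synthetic chromosome.

    Region lengths are drawn around the configured means (sd = 20% of mean,
    floor ``min_region``); CDS lengths are rounded to a multiple of 3.
    Returns the models and the genome as a mutable byte array per chromosome
    (motif planting edits it later).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    models: dict[str, TranscriptModel] = {}
    pos = config.spacer
    layout: list[tuple[str, int, tuple[int, int, int], str]] = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gene_id = f"g{i + 1:0{width}d}"
        lens = []
        for mean in config.region_lengths:
            n = int(round(rng.normal(mean, 0.2 * mean)))
            lens.append(max(config.min_region, n))
        # CDS length divisible by 3
        lens[1] = max(config.min_region, 3 * int(round(lens[1] / 3)))
        if lens[1] % 3:
            lens[1] += 3 - lens[1] % 3
        strand = "+" if rng.random() < 0.5 else "-"
        layout.append((gene_id, pos, tuple(lens), strand))
        pos += sum(lens) + config.spacer
    total = pos
    seq = rng.choice(_DNA, size=total)
    for gene_id, start, (l5, lc, l3), strand in layout:
        if strand == "+":
            b5 = GenomicInterval(CHROM, start, start + l5, strand)
            bc = GenomicInterval(CHROM, start + l5, start + l5 + lc, strand)
            b3 = GenomicInterval(CHROM, start + l5 + lc, start + l5 + lc + l3, strand)
        else:
            # transcript runs high -> low: utr5 occupies the highest coords
            b3 = GenomicInterval(CHROM, start, start + l3, strand)
            bc = GenomicInterval(CHROM, start + l3, start + l3 + lc, strand)
            b5 = GenomicInterval(CHROM, start + l3 + lc, start + l3 + lc + l5, strand)
        models[gene_id] = TranscriptModel(gene_id, utr5=[b5], cds=[bc], utr3=[b3])
    return models, {CHROM: seq}


def cds_utr3_boundary(model: TranscriptModel) -> int:
    """Genomic coordinate of the stop-codon-side CDS/3'UTR junction."""
    last_cds = model.cds[-1]
    return last_cds.end if model.strand == "+" else last_cds.start


# ---------------------------------------------------------------------------
# Stage 2: expression + ground truth
# ---------------------------------------------------------------------------

def generate_expression(
    config: SimulationConfig, models: dict[str, TranscriptModel]
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw replicate FPKMs for every gene x sample with planted structure.

    Input replicates of gene g in group s are lognormal with median mu_{g,s}
    and log-scale dispersion sigma_{g,s}; IP replicates are the input median
    times 2**E_{g,s} with small log2 jitter. Dispersion couples to planted
    enrichment as sigma_g * coupling**(E / enrichment_scale), so methylated
    genes (E ~ enrichment_scale) are damped by ~coupling and hypermethylated
    genes are damped further.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    genes = list(models)
    n = len(genes)

    median = 2.0 ** rng.normal(config.log2_median_loc, config.log2_median_scale, n)
    sigma0 = np.exp(rng.normal(config.sigma_log_loc, config.sigma_log_scale, n))

    methylated = {
        t: rng.random(n) < config.frac_methylated_by_tissue.get(t, 0.0)
        for t in TISSUES
    }
    lo, hi = config.enrichment_range
    base_e = {t: np.where(methylated[t], rng.uniform(lo, hi, n), 0.0) for t in TISSUES}

    heat = np.zeros(n, dtype=bool)
    k = min(config.n_heat_genes, n)
    heat[rng.choice(n, size=k, replace=False)] = True

    shifted = np.zeros(n, dtype=bool)
    flower_idx = np.flatnonzero(methylated["flower"])
    n_shift = int(round(config.mutant_shift_fraction * flower_idx.size))
    if n_shift:
        shifted[rng.choice(flower_idx, size=n_shift, replace=False)] = True

    groups = config.groups()
    e_cols: dict[str, np.ndarray] = {}
    s_cols: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    sample_keys: list[SampleKey] = []
    for grp in groups:
        e = base_e[grp.tissue].copy()
        if grp.genotype == "mutant" and grp.tissue == "flower":
            e = e + np.where(shifted, config.mutant_shift, 0.0)
        sig = sigma0 * config.coupling ** (e / config.enrichment_scale)
        mu = median.copy()
        if grp.condition == "HS":
            att = config.attenuation.get(f"{grp.tissue}.{grp.genotype}", 1.0)
            mu = mu * np.where(heat, 2.0 ** (config.heat_log2fc * att), 1.0)
        e_cols[grp.label()] = e
        s_cols[grp.label()] = sig
        # biological levels per replicate; IP replicates are aliquots of the
        # same material, so they share the biological noise of the matching
        # input replicate and add only capture jitter on top of 2**E
        n_reps = max(config.n_input_reps, config.n_ip_reps)
        levels = [
            mu * np.exp(sig * rng.standard_normal(n)) for _ in range(n_reps)
        ]
        for rep in range(1, config.n_input_reps + 1):
            key = SampleKey(grp.tissue, grp.condition, grp.genotype, "input", rep)
            sample_keys.append(key)
            values[key.label()] = levels[rep - 1]
        for rep in range(1, config.n_ip_reps + 1):
            key = SampleKey(grp.tissue, grp.condition, grp.genotype, "IP", rep)
            sample_keys.append(key)
            values[key.label()] = (
                levels[rep - 1]
                * 2.0 ** e
                * 2.0 ** rng.normal(0.0, config.ip_jitter_sd, n)
            )

    df = pd.DataFrame(values, index=genes)
    expr = ExpressionMatrix(df, sample_keys)

    table = pd.DataFrame(
        {
            "methylated_leaf": methylated["leaf"],
            "methylated_flower": methylated["flower"],
            "mutant_shifted": shifted,
            "heat_induced": heat,
            "base_median": median,
            "base_sigma": sigma0,
            "E_leaf": base_e["leaf"],
            "E_flower": base_e["flower"],
        },
        index=genes,
    )
    truth = GroundTruth(
        table=table,
        enrichment=pd.DataFrame(e_cols, index=genes),
        sigma=pd.DataFrame(s_cols, index=genes),
        peak_centers={},
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Stage 3: peaks + motif planting
# ---------------------------------------------------------------------------

def generate_peaks(
    config: SimulationConfig,
    models: dict[str, TranscriptModel],
    truth: GroundTruth,
    seqs: dict[str, np.ndarray] | None = None,
) -> dict[tuple[GroupKey, int], PeakSet]:
    """Plant one peak per methylated gene per IP replicate near the stop codon.

    The m6A site is one fixed locus per gene: its centre is drawn once
    (Gaussian around the CDS/3'UTR junction, sd ``peak_center_sd``, clipped
    into the transcript) and shared across groups and replicates, so the
    replicate-reproducibility filter is defeated only by the configured
    replicate-specific fraction. The RRACH motif instance is written into
    the genome at each methylated gene's centre (strand-aware) when ``seqs``
    is supplied.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    half = config.peak_width // 2
    motif_dna = config.motif.replace("U", "T").upper()
    # one site per gene, fixed across groups (a methylation site is a
    # property of the transcript, not of the sample)
    site: dict[str, int] = {}
    for gene in truth.enrichment.index:
        model = models[gene]
        span = model.span
        boundary = cds_utr3_boundary(model)
        center = int(round(rng.normal(boundary, config.peak_center_sd)))
        site[gene] = int(np.clip(center, span.start + 3, span.end - 3))
    ever_methylated = truth.enrichment.gt(0).any(axis=1)
    if seqs is not None:
        for gene in truth.enrichment.index[ever_methylated]:
            model = models[gene]
            _plant_motif(seqs[model.chrom], site[gene], motif_dna, model.strand)
    out: dict[tuple[GroupKey, int], PeakSet] = {}
    truth.peak_centers = {}
    for grp in config.groups():
        label = grp.label()
        e = truth.enrichment[label]
        sets: dict[int, list[Peak]] = {r: [] for r in range(1, config.n_ip_reps + 1)}
        for gi, gene in enumerate(truth.enrichment.index):
            if e.iloc[gi] <= 0:
                continue
            model = models[gene]
            span = model.span
            center = site[gene]
            truth.peak_centers[(label, gene)] = center
            start = max(0, center - half)
            iv = GenomicInterval(span.chrom, start, start + config.peak_width, model.strand)
            replicate_specific = rng.random() < config.replicate_specific_fraction
            keep_rep = rng.integers(1, config.n_ip_reps + 1) if replicate_specific else None
            for rep in range(1, config.n_ip_reps + 1):
                if keep_rep is not None and rep != keep_rep:
                    continue
                score = max(0.0, e.iloc[gi] + rng.normal(0.0, config.score_jitter_sd))
                sets[rep].append(Peak(iv, float(score)))
        for rep, peaks in sets.items():
            out[(grp, rep)] = PeakSet(peaks, grp, rep).sorted()
    return out


def _plant_motif(seq: np.ndarray, center: int, motif_dna: str, strand: str) -> None:
    if strand == "-":
        motif_dna = reverse_complement(motif_dna)
    start = center - 2
    seq[start:start + 5] = np.frombuffer(motif_dna.encode(), dtype="S1")


# ---------------------------------------------------------------------------
# Stage 4: auxiliary per-gene scores
# ---------------------------------------------------------------------------

def generate_aux_scores(config: SimulationConfig, truth: GroundTruth) -> pd.Series:
    """Per-gene scores shifted upward by ``aux_effect`` for flower-methylated genes."""
    config.validate()
    rng = np.random.default_rng([config.seed, 4])
    genes = truth.table.index
    scores = rng.standard_normal(len(genes))
    scores = scores + np.where(truth.table["methylated_flower"], config.aux_effect, 0.0)
    return pd.Series(scores, index=genes, name="score")


# ---------------------------------------------------------------------------
# Driver: write the whole fixture directory
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, np.ndarray], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, arr in seqs.items():
            fh.write(f">{chrom}\n")
            s = arr.tobytes().decode()
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def peak_bed_name(group: GroupKey, replicate: int) -> str:
    return f"peaks.{group.tissue}.{group.condition}.{group.genotype}.ip{replicate}.bed"


def simulate(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full fixture directory; returns a name -> path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models, seqs = generate_genome(config)
    expr, truth = generate_expression(config, models)
    peaksets = generate_peaks(config, models, truth, seqs=seqs)
    aux = generate_aux_scores(config, truth)

    paths: dict[str, Path] = {}
    paths["gtf"] = outdir / "genes.gtf"
    write_gene_models(models.values(), paths["gtf"])
    paths["fasta"] = outdir / "genome.fa"
    write_fasta(seqs, paths["fasta"])
    paths["expression"] = outdir / "expression.tsv"
    expr.write_tsv(paths["expression"])
    for (grp, rep), ps in peaksets.items():
        name = peak_bed_name(grp, rep)
        paths[name] = outdir / name
        ps.write_bed(paths[name])
    paths["aux_scores"] = outdir / "aux_scores.tsv"
    aux_df = aux.to_frame()
    aux_df.index.name = "gene_id"
    aux_df.to_csv(paths["aux_scores"], sep="\t", float_format="%.8g")
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    truth.write_tsv(paths["ground_truth"])
    pc = pd.DataFrame(
        [(g, gene, c) for (g, gene), c in sorted(truth.peak_centers.items())],
        columns=["group", "gene_id", "center"],
    )
    paths["planted_peaks"] = outdir / "planted_peaks.tsv"
    pc.to_csv(paths["planted_peaks"], sep="\t", index=False)
    return paths
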