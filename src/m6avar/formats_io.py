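"""Readers/writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere. GTF (1-based,
inclusive) is converted on read and write; BED is passed through unchanged.
Sample metadata travels inside expression-table column headers as
``tissue.condition.genotype.fraction.repN`` tokens so a fixture is a single
file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("m6avar")

TISSUES = ("leaf", "flower")
CONDITIONS = ("CS", "HS")
GENOTYPES = ("wt", "mutant")
FRACTIONS = ("input", "IP")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class Peak(NamedTuple):
    interval: GenomicInterval
    score: float


class GroupKey(NamedTuple):
    """One sample group: a (tissue, condition, genotype) cell of the design."""

    tissue: str
    condition: str
    genotype: str

    def label(self) -> str:
        return ".".join(self)


class SampleKey(NamedTuple):
    tissue: str
    condition: str
    genotype: str
    fraction: str
    replicate: int

    @property
    def group(self) -> GroupKey:
        return GroupKey(self.tissue, self.condition, self.genotype)

    def label(self) -> str:
        return (
            f"{self.tissue}.{self.condition}.{self.genotype}."
            f"{self.fraction}.rep{self.replicate}"
        )

    @classmethod
    def parse(cls, token: str) -> "SampleKey":
        parts = token.split(".")
        if len(parts) != 5 or not parts[4].startswith("rep"):
            raise ValueError(f"malformed sample header token {token!r}")
        tissue, condition, genotype, fraction = parts[:4]
        if tissue not in TISSUES:
            raise ValueError(f"malformed sample header token {token!r}: unknown tissue {tissue!r}")
        if condition not in CONDITIONS:
            raise ValueError(f"malformed sample header token {token!r}: unknown condition {condition!r}")
        if genotype not in GENOTYPES:
            raise ValueError(f"malformed sample header token {token!r}: unknown genotype {genotype!r}")
        if fraction not in FRACTIONS:
            raise ValueError(f"malformed sample header token {token!r}: unknown fraction {fraction!r}")
        try:
            replicate = int(parts[4][3:])
        except ValueError:
            raise ValueError(f"malformed sample header token {token!r}: bad replicate") from None
        if replicate < 1:
            raise ValueError(f"malformed sample header token {token!r}: replicate must be >= 1")
        return cls(tissue, condition, genotype, fraction, replicate)


@dataclass
class TranscriptModel:
    """One gene's 5'UTR/CDS/3'UTR exon intervals in transcript order.

    All intervals share one chromosome and strand; regions are pairwise
    non-overlapping and the CDS is non-empty. For a minus-strand gene the
    transcript-order lists run from high to low genomic coordinate.
    """

    gene_id: str
    utr5: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = self.utr5 + self.cds + self.utr3
        if not self.cds:
            raise ValueError(f"gene {self.gene_id}: CDS must be non-empty")
        chroms = {iv.chrom for iv in ivs}
        strands = {iv.strand for iv in ivs}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"gene {self.gene_id}: intervals mix chrom/strand")
        by_start = sorted(ivs, key=lambda iv: iv.start)
        for a, b in zip(by_start, by_start[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping intervals")

    @property
    def chrom(self) -> str:
        return self.cds[0].chrom

    @property
    def strand(self) -> str:
        return self.cds[0].strand

    @property
    def span(self) -> GenomicInterval:
        ivs = self.utr5 + self.cds + self.utr3
        return GenomicInterval(
            self.chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs), self.strand
        )

    def region_intervals(self, region: str) -> list[GenomicInterval]:
        return {"utr5": self.utr5, "cds": self.cds, "utr3": self.utr3}[region]

    @property
    def lengths(self) -> dict[str, int]:
        return {
            region: sum(len(iv) for iv in self.region_intervals(region))
            for region in ("utr5", "cds", "utr3")
        }


@dataclass
class ExpressionMatrix:
    """Genes x samples of nonnegative abundance (FPKM) with sample metadata."""

    values: pd.DataFrame  # index: gene ids; columns: sample labels
    samples: list[SampleKey]

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.samples):
            raise ValueError("column count does not match sample metadata")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample metadata tuples must be unique")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def columns_for(
        self, group: GroupKey, fraction: str
    ) -> list[str]:
        return [
            s.label()
            for s in self.samples
            if s.group == group and s.fraction == fraction
        ]

    def group_values(self, group: GroupKey, fraction: str) -> pd.DataFrame:
        cols = self.columns_for(group, fraction)
        if not cols:
            raise KeyError(f"no {fraction} samples for group {group.label()}")
        return self.values[cols]

    def groups(self, fraction: str | None = None) -> list[GroupKey]:
        seen: dict[GroupKey, None] = {}
        for s in self.samples:
            if fraction is None or s.fraction == fraction:
                seen.setdefault(s.group)
        return list(seen)

    def write_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class PeakSet:
    """Scored peak intervals for one (group, replicate) sample."""

    peaks: list[Peak]
    group: GroupKey | None = None
    replicate: int | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def sorted(self) -> "PeakSet":
        return PeakSet(
            sorted(self.peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)),
            self.group,
            self.replicate,
        )

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (iv, score) in enumerate(self.peaks):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i + 1}\t{score:.6g}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> dict[str, TranscriptModel]:
    """Parse a GTF into TranscriptModels keyed by gene id.

    GTF 1-based inclusive coordinates become 0-based half-open. Rows with
    feature ``five_prime_utr``/``5UTR``, ``CDS`` and
    ``three_prime_utr``/``3UTR`` are used; genes without any CDS row are
    skipped (the composite metagene axis needs a CDS) and the skip count is
    logged.
    """
    path = Path(path)
    feature_map = {
        "five_prime_utr": "utr5", "5UTR": "utr5",
        "CDS": "cds",
        "three_prime_utr": "utr3", "3UTR": "utr3",
    }
    regions: dict[str, dict[str, list[GenomicInterval]]] = {}
    order: list[str] = []
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in feature_map:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            gene_id = _gtf_attribute(attrs, "gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            if start1 > end1:
                raise ValueError(f"{path}:{lineno}: start > end")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if gene_id not in regions:
                regions[gene_id] = {"utr5": [], "cds": [], "utr3": []}
                order.append(gene_id)
            regions[gene_id][feature_map[feature]].append(iv)
            n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: no usable feature rows")
    models: dict[str, TranscriptModel] = {}
    skipped = 0
    for gene_id in order:
        parts = regions[gene_id]
        if not parts["cds"]:
            skipped += 1
            continue
        strand = parts["cds"][0].strand
        rev = strand == "-"
        models[gene_id] = TranscriptModel(
            gene_id,
            utr5=sorted(parts["utr5"], key=lambda iv: iv.start, reverse=rev),
            cds=sorted(parts["cds"], key=lambda iv: iv.start, reverse=rev),
            utr3=sorted(parts["utr3"], key=lambda iv: iv.start, reverse=rev),
        )
    if skipped:
        logger.info("read_gene_models: skipped %d gene(s) without CDS", skipped)
    read_gene_models.last_skipped = skipped  # type: ignore[attr-defined]
    return models


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + " "):
            return item[len(key):].strip().strip('"')
    return None


def write_gene_models(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Emit GTF (1-based inclusive) for the given models."""
    rev_map = {"utr5": "five_prime_utr", "cds": "CDS", "utr3": "three_prime_utr"}
    with open(path, "w") as fh:
        for model in models:
            for region in ("utr5", "cds", "utr3"):
                for iv in sorted(model.region_intervals(region), key=lambda iv: iv.start):
                    fh.write(
                        f"{iv.chrom}\tm6avar\t{rev_map[region]}\t{iv.start + 1}\t{iv.end}"
                        f"\t.\t{iv.strand}\t.\tgene_id \"{model.gene_id}\";\n"
                    )


def read_peaks(
    path: str | Path,
    group: GroupKey | None = None,
    replicate: int | None = None,
) -> PeakSet:
    """Parse a BED5/BED6 file of scored peaks (coordinates kept as-is)."""
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 BED columns")
            chrom, start_s, end_s, _name, score_s = fields[:5]
            strand = fields[5] if len(fields) > 5 else "+"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            try:
                score = float(score_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric score {score_s!r}") from None
            if not np.isfinite(score):
                raise ValueError(f"{path}:{lineno}: non-finite score")
            peaks.append(Peak(GenomicInterval(chrom, start, end, strand), score))
    return PeakSet(peaks, group, replicate)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample FPKM TSV whose header encodes sample metadata."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = [SampleKey.parse(col) for col in df.columns]
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        gene = df.index[np.where(arr < 0)[0][0]]
        raise ValueError(f"{path}: negative value for gene {gene!r}")
    return ExpressionMatrix(df.astype(float), samples)


def compute_fpkm(
    counts: np.ndarray,
    lengths: Sequence[float],
    library_sizes: Sequence[float],
    genes: Sequence[str] | None = None,
    samples: list[SampleKey] | None = None,
) -> ExpressionMatrix | np.ndarray:
    """FPKM = count * 1e9 / (length * library_size).

    Returns an ExpressionMatrix when gene ids and sample metadata are given,
    otherwise the bare matrix.
    """
    counts = np.asarray(counts, dtype=float)
    lengths_a = np.asarray(lengths, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if (lengths_a <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (libs <= 0).any():
        raise ValueError("library sizes must be > 0")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    fpkm = counts * 1e9 / (lengths_a[:, None] * libs[None, :])
    if genes is None or samples is None:
        return fpkm
    df = pd.DataFrame(fpkm, index=list(genes), columns=[s.label() for s in samples])
    return ExpressionMatrix(df, samples)
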