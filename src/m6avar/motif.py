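"""RRACH consensus scanning and position frequency matrix over top peak regions.

The m6A consensus 5-mer RRACH (R = A/G, H = A/C/U) is scanned, overlapping
matches allowed, in the top-N highest-scoring peak regions; matched 5-mers
are pooled with equal weight into a 5 x 4 position frequency matrix reported
in the RNA alphabet (A, C, G, U).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

from .formats_io import PeakSet, TranscriptModel, logger
from .methylation import assign_peaks
from .synthetic_data import reverse_complement

RNA_ALPHABET = ("A", "C", "G", "U")
_R = frozenset("AG")
_H = frozenset("ACU")
_VALID = frozenset("ACGTUN")


@dataclass
class PositionFrequencyMatrix:
    frequencies: np.ndarray  # 5 x 4 over RNA_ALPHABET
    support: int  # number of matched 5-mers

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(RNA_ALPHABET) + "\n")
            for i, row in enumerate(self.frequencies, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    def to_transfac(self) -> str:
        """Count matrix block in transfac style for external logo renderers."""
        lines = ["ID RRACH_m6A", "BF synthetic", "P0\t" + "\t".join(RNA_ALPHABET)]
        counts = np.round(self.frequencies * self.support).astype(int)
        for i, row in enumerate(counts, start=1):
            lines.append(f"{i:02d}\t" + "\t".join(str(v) for v in row))
        lines.append("XX")
        lines.append("//")
        return "\n".join(lines) + "\n"


def top_regions(peaks: PeakSet, n: int = 1000) -> PeakSet:
    """The n highest-score peaks; ties break by (chrom, start)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(peaks) < n:
        logger.warning("top_regions: only %d peaks available (requested %d)", len(peaks), n)
    ordered = sorted(
        peaks.peaks,
        key=lambda p: (-p.score, p.interval.chrom, p.interval.start),
    )
    return PeakSet(ordered[:n], peaks.group, peaks.replicate)


def scan_rrach(sequence: str) -> list[tuple[int, str]]:
    """All offsets whose 5-mer matches RRACH (overlaps allowed; T == U; N never)."""
    seq = sequence.upper().replace("T", "U")
    for i, ch in enumerate(seq):
        if ch not in _VALID and ch != "U":
            raise ValueError(f"invalid nucleotide {ch!r} at offset {i}")
    hits: list[tuple[int, str]] = []
    for i in range(len(seq) - 4):
        w = seq[i:i + 5]
        if (
            w[0] in _R and w[1] in _R and w[2] == "A" and w[3] == "C" and w[4] in _H
        ):
            hits.append((i, w))
    return hits


def build_pfm(
    regions: PeakSet,
    genome: str | Path | Fasta,
    models: dict[str, TranscriptModel],
) -> PositionFrequencyMatrix:
    """Pool RRACH matches over the regions into a position frequency matrix.

    Each region is scanned on the strand of its assigned gene
    (reverse-complemented for minus-strand genes); regions assignable to no
    gene are scanned on the plus strand, with a logged count.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    assignment = assign_peaks(regions, models)
    strand_of = {id(p): models[g].strand for p, g in assignment.assigned}
    if assignment.unassigned:
        logger.info(
            "build_pfm: %d unassigned region(s) scanned on + strand",
            len(assignment.unassigned),
        )
    counts = np.zeros((5, 4), dtype=float)
    support = 0
    index = {b: i for i, b in enumerate(RNA_ALPHABET)}
    for peak in regions.peaks:
        iv = peak.interval
        chrom_len = len(fa[iv.chrom])
        if iv.end > chrom_len:
            raise ValueError(
                f"region {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end ({chrom_len})"
            )
        seq = str(fa[iv.chrom][iv.start:iv.end]).upper()
        if strand_of.get(id(peak), "+") == "-":
            seq = reverse_complement(seq)
        for _, word in scan_rrach(seq):
            for pos, base in enumerate(word):
                counts[pos, index[base]] += 1.0
            support += 1
    if support == 0:
        logger.warning("build_pfm: no RRACH matches in any region")
        return PositionFrequencyMatrix(np.zeros((5, 4)), 0)
    return PositionFrequencyMatrix(counts / support, support)
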