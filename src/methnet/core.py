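"""Shared domain containers.

All genomic coordinates throughout the package are 0-based, half-open.
CpG sites are strand-collapsed: a site is identified by the position of
the C of the plus-strand ``CG`` dinucleotide, and bottom-strand read
evidence (the complementary G) is folded into the same site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene with exon structure.

    ``start``/``end`` span the gene body; ``exons`` are sorted,
    non-overlapping, half-open intervals within the body.  The TSS is
    the 5' end in gene orientation, the TTS the 3' end.  Introns are
    the gaps between exons, numbered 1..n from the TSS side.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for (s, e) in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> list[tuple[int, int]]:
        """Half-open intron intervals, ordered 1..n from the TSS side."""
        gaps = [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]
        return gaps if self.strand == "+" else gaps[::-1]

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GroupDesign:
    """Two-group sample design (group1 = infant, group2 = adult)."""

    group1: tuple[str, ...]
    group2: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.group1) < 2 or len(self.group2) < 2:
            raise ValueError("each group needs >=2 samples")
        if set(self.group1) & set(self.group2):
            raise ValueError("samples cannot belong to both groups")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.group1 + self.group2


@dataclass
class CpGCountMatrix:
    """Per-CpG, per-sample methylated/unmethylated read counts.

    ``chrom``/``pos`` index sites sorted by (chrom, position); ``meth``
    and ``unmeth`` are (n_sites, n_samples) integer arrays aligned to
    ``samples``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    meth: np.ndarray
    unmeth: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pos)
        if len(self.chrom) != n:
            raise ValueError("chrom/pos length mismatch")
        for a in (self.meth, self.unmeth):
            if a.shape != (n, len(self.samples)):
                raise ValueError("count array shape mismatch")
        if np.any(self.meth < 0) or np.any(self.unmeth < 0):
            raise ValueError("negative counts")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("sites must be sorted by (chrom, position)")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def fractions(self) -> np.ndarray:
        """Per-site, per-sample methylation fraction; NaN where uncovered."""
        cov = self.coverage().astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(cov > 0, self.meth / cov, np.nan)

    def sample_index(self, names) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([idx[s] for s in names], dtype=int)

    def subset(self, mask: np.ndarray) -> "CpGCountMatrix":
        return CpGCountMatrix(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            samples=list(self.samples),
            meth=self.meth[mask],
            unmeth=self.unmeth[mask],
        )


@dataclass(frozen=True)
class DMR:
    """A maximal run of consecutive differentially methylated CpGs.

    ``start``/``end`` span the first to last member CpG, half-open and
    inclusive of the final CG dinucleotide (end = last C position + 2).
    ``mean_diff`` is the mean of member diffs (group2 - group1);
    direction 'hypo' means loss of methylation in group2 (adult),
    'hyper' a gain.
    """

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_diff: float
    direction: str
    site_index: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.end <= self.start:
            raise ValueError("empty DMR interval")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2
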