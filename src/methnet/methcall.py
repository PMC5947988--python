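"""Cytosine methylation calling from aligned bisulfite read pairs.

Bisulfite treatment converts unmethylated cytosine to uracil (read as
thymine) while methylated cytosine is protected.  After alignment to
in-silico converted references, a read base that maintains the cytosine
status is a methylated observation and a converted base an unmethylated
one.  This module implements the calling side of that protocol for
tagmentation-based libraries:

* reference conversion utilities (top strand C->T, bottom strand G->A)
* tagmentation end-masking (the transposase fills 9 bp at fragment
  ends, so the first 9 bp of read 2 and the last 9 bp before the
  adapter in read 1 are excluded from calling)
* Phred >= 20 base filtering, duplicate and antisense-read removal,
  once-per-pair counting of overlapping mate bases
* CpG counting strand-collapsed onto the plus-strand C coordinate
* bisulfite conversion-rate estimation from CH (non-CpG) cytosines,
  which are essentially unmethylated in somatic tissue.

Reads are stored the way SAM stores them: sequence and qualities in
reference orientation, with ``is_reverse`` recording the sequencing
direction.  Masks are defined in read orientation (as sequenced) and
mapped onto reference offsets internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from methnet.core import CpGCountMatrix

_VALID_DNA = set("ACGTN")


@dataclass(frozen=True)
class ReferenceSequence:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_DNA
        if bad:
            raise ValueError(f"invalid characters in reference {self.name!r}: {sorted(bad)}")


def convert_reference(ref: ReferenceSequence, mode: str) -> ReferenceSequence:
    """In-silico bisulfite conversion of a reference strand.

    ``top`` replaces every C with T (the fully converted plus strand);
    ``bottom`` replaces every G with A (the converted minus strand as
    seen in plus-strand coordinates).
    """
    if mode == "top":
        return ReferenceSequence(ref.name, ref.sequence.replace("C", "T"))
    if mode == "bottom":
        return ReferenceSequence(ref.name, ref.sequence.replace("G", "A"))
    raise ValueError(f"mode must be 'top' or 'bottom', got {mode!r}")


@dataclass
class AlignedRead:
    """One aligned mate; ``seq``/``quals`` in reference orientation."""

    chrom: str
    ref_start: int
    seq: str
    quals: np.ndarray
    is_reverse: bool

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.quals) != len(self.seq):
            raise ValueError("qualities and sequence must have equal length")

    def __len__(self) -> int:
        return len(self.seq)

    def read_index(self, ref_offset: int) -> int:
        """Read-orientation position of the base at ``ref_offset``."""
        return ref_offset if not self.is_reverse else len(self.seq) - 1 - ref_offset


@dataclass
class AlignedReadPair:
    read1: AlignedRead
    read2: Optional[AlignedRead]
    bs_strand: str  # 'top' | 'bottom': original bisulfite strand of the fragment
    adapter_offset: Optional[int] = None  # read-orientation index in read1 where adapter begins
    is_duplicate: bool = False
    is_antisense: bool = False
    alignment_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.bs_strand not in ("top", "bottom"):
            raise ValueError(f"bs_strand must be top|bottom, got {self.bs_strand!r}")
        if self.adapter_offset is not None and self.adapter_offset > len(self.read1):
            raise ValueError("adapter_offset beyond read1 length")


@dataclass(frozen=True)
class MethylCallConfig:
    min_base_quality: int = 20
    mask_read2_head: int = 9
    mask_read1_tail: int = 9
    drop_antisense: bool = True
    drop_duplicates: bool = True
    min_alignment_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be >= 0")


def mask_tagmentation_ends(
    pair: AlignedReadPair, cfg: MethylCallConfig
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Per-base call masks (read orientation; True = excluded).

    Read 2 loses its first ``mask_read2_head`` bases; read 1 loses the
    ``mask_read1_tail`` bases immediately before the adapter when the
    fragment was read through.  Reads shorter than the mask are fully
    masked.
    """
    mask1 = np.zeros(len(pair.read1), dtype=bool)
    if pair.adapter_offset is not None:
        lo = max(0, pair.adapter_offset - cfg.mask_read1_tail)
        mask1[lo : pair.adapter_offset] = True
    mask2 = None
    if pair.read2 is not None:
        mask2 = np.zeros(len(pair.read2), dtype=bool)
        mask2[: cfg.mask_read2_head] = True
    return mask1, mask2


def _dedup_key(pair: AlignedReadPair) -> tuple:
    starts = [pair.read1.ref_start]
    lens = [len(pair.read1)]
    if pair.read2 is not None:
        starts.append(pair.read2.ref_start)
        lens.append(len(pair.read2))
    return (pair.read1.chrom, min(starts), pair.bs_strand, tuple(sorted(lens)))


def _iter_pair_calls(
    pairs: Iterable[AlignedReadPair],
    reference: dict[str, str],
    cfg: MethylCallConfig,
) -> Iterator[tuple[str, int, str, str]]:
    """Yield (chrom, site_pos, context 'cpg'|'ch', state 'M'|'U') calls.

    Applies, in order: duplicate removal (flag or simplified positional
    rule), antisense removal, alignment-score floor, tagmentation
    masks, base-quality floor, and once-per-pair resolution of
    overlapping mate bases (higher quality wins).
    """
    seen: set[tuple] = set()
    for pair in pairs:
        if cfg.drop_antisense and pair.is_antisense:
            continue
        if cfg.drop_duplicates:
            if pair.is_duplicate:
                continue
            key = _dedup_key(pair)
            if key in seen:
                continue
            seen.add(key)
        if (
            cfg.min_alignment_score is not None
            and pair.alignment_score is not None
            and pair.alignment_score < cfg.min_alignment_score
        ):
            continue

        mask1, mask2 = mask_tagmentation_ends(pair, cfg)
        best: dict[int, tuple[int, str]] = {}  # ref pos -> (qual, base)
        for read, mask in ((pair.read1, mask1), (pair.read2, mask2)):
            if read is None:
                continue
            seq = reference.get(read.chrom)
            if seq is None:
                raise ValueError(f"read aligned to unknown reference {read.chrom!r}")
            if read.ref_start + len(read) > len(seq):
                raise ValueError(
                    f"read extends past end of reference {read.chrom!r} "
                    f"({read.ref_start}+{len(read)} > {len(seq)})"
                )
            for j in range(len(read)):
                if mask[read.read_index(j)]:
                    continue
                q = int(read.quals[j])
                if q < cfg.min_base_quality:
                    continue
                pos = read.ref_start + j
                prev = best.get(pos)
                if prev is None or q > prev[0]:
                    best[pos] = (q, read.seq[j])

        chrom = pair.read1.chrom
        seq = reference[chrom]
        if pair.bs_strand == "top":
            for pos, (_, base) in best.items():
                if seq[pos] != "C":
                    continue
                is_cpg = pos + 1 < len(seq) and seq[pos + 1] == "G"
                if base == "C":
                    yield chrom, pos, ("cpg" if is_cpg else "ch"), "M"
                elif base == "T":
                    yield chrom, pos, ("cpg" if is_cpg else "ch"), "U"
        else:
            for pos, (_, base) in best.items():
                if seq[pos] != "G":
                    continue
                is_cpg = pos > 0 and seq[pos - 1] == "C"
                site = pos - 1 if is_cpg else pos
                if base == "G":
                    yield chrom, site, ("cpg" if is_cpg else "ch"), "M"
                elif base == "A":
                    yield chrom, site, ("cpg" if is_cpg else "ch"), "U"


def reference_cpg_sites(reference: dict[str, str]) -> list[tuple[str, int]]:
    """All plus-strand CpG C positions, sorted by (chrom, position)."""
    sites = []
    for chrom in sorted(reference):
        seq = reference[chrom]
        sites.extend(
            (chrom, i) for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
        )
    return sites


def extract_cpg_calls(
    pairs: Sequence[AlignedReadPair],
    reference: dict[str, str] | ReferenceSequence,
    cfg: MethylCallConfig = MethylCallConfig(),
    sample: str = "sample1",
) -> CpGCountMatrix:
    """Count methylated/unmethylated CpG observations for one sample.

    Top-strand reads report the C of the plus-strand CG (C = methylated,
    T = unmethylated); bottom-strand reads report the complementary G
    (G = methylated, A = unmethylated) and are folded into the same
    plus-strand site.  Every CpG in the reference appears in the output,
    uncovered sites with zero counts.
    """
    if isinstance(reference, ReferenceSequence):
        reference = {reference.name: reference.sequence}
    sites = reference_cpg_sites(reference)
    index = {key: i for i, key in enumerate(sites)}
    meth = np.zeros((len(sites), 1), dtype=np.int64)
    unmeth = np.zeros((len(sites), 1), dtype=np.int64)
    for chrom, pos, context, state in _iter_pair_calls(pairs, reference, cfg):
        if context != "cpg":
            continue
        i = index[(chrom, pos)]
        if state == "M":
            meth[i, 0] += 1
        else:
            unmeth[i, 0] += 1
    return CpGCountMatrix(
        chrom=np.array([c for c, _ in sites], dtype=object),
        pos=np.array([p for _, p in sites], dtype=np.int64),
        samples=[sample],
        meth=meth,
        unmeth=unmeth,
    )


@dataclass(frozen=True)
class ConversionRate:
    rate: float
    converted: int
    unconverted: int

    @property
    def total(self) -> int:
        return self.converted + self.unconverted


def estimate_conversion_rate(
    pairs: Sequence[AlignedReadPair],
    reference: dict[str, str] | ReferenceSequence,
    cfg: MethylCallConfig = MethylCallConfig(),
) -> ConversionRate:
    """Bisulfite conversion rate from CH (non-CpG cytosine) calls.

    CH cytosines are assumed unmethylated, so any retained C there is a
    conversion failure: rate = 1 - unconverted / total CH calls.
    """
    if isinstance(reference, ReferenceSequence):
        reference = {reference.name: reference.sequence}
    converted = unconverted = 0
    for _, _, context, state in _iter_pair_calls(pairs, reference, cfg):
        if context != "ch":
            continue
        if state == "M":
            unconverted += 1
        else:
            converted += 1
    total = converted + unconverted
    if total == 0:
        raise ValueError("conversion rate undefined: no quality-passing CH observations")
    return ConversionRate(rate=1.0 - unconverted / total, converted=converted, unconverted=unconverted)


# ----------------------------------------------------------------- SAM I/O

_STRAND_TAG_VALUES = {"top": "CT", "bottom": "GA"}
_STRAND_FROM_TAG = {v: k for k, v in _STRAND_TAG_VALUES.items()}


def write_sam(path, pairs: Sequence[AlignedReadPair], reference: dict[str, str]) -> None:
    """Write pairs as plain-text SAM.

    The original bisulfite strand goes into the ``XG`` tag (``CT`` for
    top, ``GA`` for bottom, the Bismark convention); the read-1 adapter
    start into ``XO:i``; antisense alignments into ``ZS:i:1``.
    """
    import pysam

    chroms = sorted(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, pair in enumerate(pairs):
            qname = f"pair{i:07d}"
            mates = [(pair.read1, True)]
            if pair.read2 is not None:
                mates.append((pair.read2, False))
            for read, is_first in mates:
                a = pysam.AlignedSegment(out.header)
                a.query_name = qname
                a.query_sequence = read.seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.quals)
                )
                a.reference_id = tid[read.chrom]
                a.reference_start = read.ref_start
                a.cigarstring = f"{len(read)}M"
                a.mapping_quality = 60
                flag = 0x1
                flag |= 0x40 if is_first else 0x80
                if read.is_reverse:
                    flag |= 0x10
                mate = pair.read2 if is_first else pair.read1
                if mate is not None and mate.is_reverse:
                    flag |= 0x20
                if pair.is_duplicate:
                    flag |= 0x400
                a.flag = flag
                if mate is not None:
                    a.next_reference_id = tid[mate.chrom]
                    a.next_reference_start = mate.ref_start
                tags = [("XG", _STRAND_TAG_VALUES[pair.bs_strand])]
                if is_first and pair.adapter_offset is not None:
                    tags.append(("XO", pair.adapter_offset))
                if pair.is_antisense:
                    tags.append(("ZS", 1))
                if pair.alignment_score is not None:
                    tags.append(("AS", int(pair.alignment_score)))
                a.set_tags(tags)
                out.write(a)


def read_sam(path, strand_tag: str = "XG") -> list[AlignedReadPair]:
    """Read SAM alignments back into pairs, grouped by query name."""
    import pysam

    by_name: dict[str, dict] = {}
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            read = AlignedRead(
                chrom=a.reference_name,
                ref_start=a.reference_start,
                seq=a.query_sequence,
                quals=np.array(a.query_qualities, dtype=np.int64),
                is_reverse=a.is_reverse,
            )
            rec = by_name.setdefault(
                a.query_name,
                {
                    "read1": None,
                    "read2": None,
                    "bs_strand": _STRAND_FROM_TAG.get(
                        a.get_tag(strand_tag) if a.has_tag(strand_tag) else "CT", "top"
                    ),
                    "adapter_offset": None,
                    "is_duplicate": False,
                    "is_antisense": False,
                    "alignment_score": None,
                },
            )
            slot = "read1" if a.is_read1 or not a.is_paired else "read2"
            rec[slot] = read
            if a.is_duplicate:
                rec["is_duplicate"] = True
            if a.has_tag("ZS") and a.get_tag("ZS") == 1:
                rec["is_antisense"] = True
            if (a.is_read1 or not a.is_paired) and a.has_tag("XO"):
                rec["adapter_offset"] = int(a.get_tag("XO"))
            if a.has_tag("AS"):
                rec["alignment_score"] = float(a.get_tag("AS"))
    pairs = []
    for name in sorted(by_name):
        rec = by_name[name]
        if rec["read1"] is None:  # orphan second mate: promote
            rec["read1"], rec["read2"] = rec["read2"], None
        pairs.append(AlignedReadPair(**rec))
    return pairs
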