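"""Genomic and regulatory annotation of DMRs.

A DMR is positioned by its midpoint.  Feature classification follows a
fixed precedence (promoter/TSS > exon > intron > TTS > intergenic);
TSS distances are signed in gene orientation (positive = downstream of
the TSS); regulatory-domain assignment follows the GREAT
basal-plus-extension rule with up to three genes per region; track
enrichment is measured empirically against length-matched shuffled
intervals, and 2x2 enrichments with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from methnet.core import DMR, GeneModel


@dataclass(frozen=True)
class FeatureClass:
    kind: str  # promoter_tss | exon | intron | tts | intergenic
    intron_index: Optional[int] = None  # 1-based from the TSS side, intron only

    def __str__(self) -> str:
        return f"intron{self.intron_index}" if self.kind == "intron" else self.kind


@dataclass(frozen=True)
class OverlapEnrichment:
    """2x2 overlap table with odds ratio and two-sided Fisher exact p.

    Cells: a = query in feature, b = query out, c = background in,
    d = background out.  A zero row or column makes the odds ratio
    undefined; it is then reported with the Haldane-Anscombe +0.5
    correction and flagged degenerate.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    degenerate: bool = False


def classify_genomic_feature(
    dmr: DMR, genes: Sequence[GeneModel], promoter_window: int = 1000
) -> FeatureClass:
    """Classify the DMR midpoint against gene anatomy.

    Precedence: within ±promoter_window of a TSS > exon > intron(k) >
    within ±promoter_window of a TTS > intergenic.  When several genes
    compete within one precedence level the nearest TSS wins.
    """
    mid = dmr.midpoint
    same = [g for g in genes if g.chrom == dmr.chrom]
    by_tss = sorted(same, key=lambda g: (abs(mid - g.tss), g.gene_id))
    for g in by_tss:
        if abs(mid - g.tss) < promoter_window:  # exclusive: 1 kb away is not promoter
            return FeatureClass("promoter_tss")
    for g in by_tss:
        if g.contains(mid):
            for s, e in g.exons:
                if s <= mid < e:
                    return FeatureClass("exon")
            for k, (s, e) in enumerate(g.introns(), start=1):
                if s <= mid < e:
                    return FeatureClass("intron", intron_index=k)
    for g in by_tss:
        if abs(mid - g.tts) < promoter_window:
            return FeatureClass("tts")
    return FeatureClass("intergenic")


def distance_to_nearest_tss(
    dmr: DMR, genes: Sequence[GeneModel]
) -> tuple[Optional[int], Optional[str]]:
    """Signed distance (bp) from the DMR midpoint to the nearest TSS.

    Positive = downstream of that TSS in the gene's orientation;
    equidistant ties go to the smaller gene id.  Returns (None, None)
    when no gene shares the chromosome.
    """
    mid = dmr.midpoint
    best: Optional[tuple[int, str, int]] = None
    for g in genes:
        if g.chrom != dmr.chrom:
            continue
        d = abs(mid - g.tss)
        if best is None or (d, g.gene_id) < (best[0], best[1]):
            signed = mid - g.tss if g.strand == "+" else g.tss - mid
            best = (d, g.gene_id, signed)
    if best is None:
        return None, None
    return best[2], best[1]


def regulatory_domains(
    genes: Sequence[GeneModel],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
) -> dict[str, tuple[int, int]]:
    """GREAT-style basal-plus-extension regulatory domain per gene.

    The basal domain spans ``basal_up`` upstream to ``basal_down``
    downstream of the TSS in gene orientation; it is extended in both
    directions to the nearer of ``max_extension`` or the neighbouring
    gene's basal domain (basal domains themselves are never truncated).
    """
    basal: dict[str, tuple[int, int]] = {}
    for g in genes:
        if g.strand == "+":
            basal[g.gene_id] = (max(0, g.tss - basal_up), g.tss + basal_down)
        else:
            basal[g.gene_id] = (max(0, g.tss - basal_down), g.tss + basal_up)
    domains: dict[str, tuple[int, int]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (basal[g.gene_id][0], g.gene_id))
        for i, g in enumerate(gs):
            bs, be = basal[g.gene_id]
            left = max(bs - max_extension, 0)
            if i > 0:
                left = max(left, min(bs, basal[gs[i - 1].gene_id][1]))
            right = be + max_extension
            if i < len(gs) - 1:
                right = min(right, max(be, basal[gs[i + 1].gene_id][0]))
            domains[g.gene_id] = (left, right)
    return domains


def assign_regulatory_domains(
    dmr: DMR,
    genes: Sequence[GeneModel],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
    max_genes: int = 3,
) -> list[str]:
    """Genes whose regulatory domain contains the DMR midpoint.

    When more than ``max_genes`` domains hit, the ``max_genes`` genes
    with the nearest TSS are kept ("up to three nearby genes").
    """
    mid = dmr.midpoint
    domains = regulatory_domains(genes, basal_up, basal_down, max_extension)
    hits = [
        g for g in genes
        if g.chrom == dmr.chrom and domains[g.gene_id][0] <= mid < domains[g.gene_id][1]
    ]
    hits.sort(key=lambda g: (abs(mid - g.tss), g.gene_id))
    return [g.gene_id for g in hits[:max_genes]]


@dataclass
class AnnotatedDMR:
    dmr: DMR
    feature: FeatureClass
    tss_distance: Optional[int]
    nearest_gene: Optional[str]
    assigned_genes: tuple[str, ...]


def annotate_dmrs(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneModel],
    promoter_window: int = 1000,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
    max_genes: int = 3,
) -> list[AnnotatedDMR]:
    """Full per-DMR annotation: feature class, nearest TSS, GREAT genes."""
    out = []
    for d in dmrs:
        dist, gene = distance_to_nearest_tss(d, genes)
        out.append(AnnotatedDMR(
            dmr=d,
            feature=classify_genomic_feature(d, genes, promoter_window),
            tss_distance=dist,
            nearest_gene=gene,
            assigned_genes=tuple(assign_regulatory_domains(
                d, genes, basal_up, basal_down, max_extension, max_genes)),
        ))
    return out


def annotation_frame(annotated: Sequence[AnnotatedDMR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.dmr.chrom for a in annotated],
            "start": [a.dmr.start for a in annotated],
            "end": [a.dmr.end for a in annotated],
            "direction": [a.dmr.direction for a in annotated],
            "mean_diff": [a.dmr.mean_diff for a in annotated],
            "n_cpgs": [a.dmr.n_cpgs for a in annotated],
            "feature": [str(a.feature) for a in annotated],
            "tss_distance": [a.tss_distance for a in annotated],
            "nearest_gene": [a.nearest_gene for a in annotated],
            "assigned_genes": [",".join(a.assigned_genes) for a in annotated],
        }
    )


# ------------------------------------------------------- track intersection

def _overlaps_any(start: int, end: int, starts: np.ndarray, ends: np.ndarray) -> bool:
    # half-open overlap: [start,end) and [s,e) intersect iff s < end and start < e
    i = np.searchsorted(starts, end)  # intervals with s < end
    return bool(np.any(ends[:i] > start))


def intersect_tracks(
    dmrs: Sequence[DMR],
    tracks: dict[str, Sequence[tuple[str, int, int]]],
    chrom_sizes: dict[str, int],
    n_shuffles: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Overlap fraction per track with shuffle-based empirical enrichment.

    A DMR overlaps a track when any base intersects (half-open).  The
    null distribution places length-matched intervals uniformly on the
    same chromosome ``n_shuffles`` times; enrichment is observed/mean
    expected and the empirical p the add-one-smoothed fraction of
    shuffles with at least the observed overlap count.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, ivs in tracks.items():
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, s, e in ivs:
            if chrom not in chrom_sizes:
                raise ValueError(f"track {name!r} interval on unknown chromosome {chrom!r}")
            by_chrom.setdefault(chrom, ([], []))[0].append(s)
            by_chrom[chrom][1].append(e)
        packed = {}
        for chrom, (ss, ee) in by_chrom.items():
            order = np.argsort(ss)
            packed[chrom] = (np.asarray(ss)[order], np.asarray(ee)[order])

        def count(intervals: Sequence[tuple[str, int, int]]) -> int:
            c = 0
            for chrom, s, e in intervals:
                if chrom in packed and _overlaps_any(s, e, *packed[chrom]):
                    c += 1
            return c

        observed = count([(d.chrom, d.start, d.end) for d in dmrs])
        null = np.empty(n_shuffles, dtype=int)
        lengths = [(d.chrom, d.end - d.start) for d in dmrs]
        for k in range(n_shuffles):
            placed = []
            for chrom, ln in lengths:
                hi = max(1, chrom_sizes[chrom] - ln)
                s = int(rng.integers(0, hi))
                placed.append((chrom, s, s + ln))
            null[k] = count(placed)
        expected = float(null.mean()) if n_shuffles else np.nan
        p = float((1 + np.sum(null >= observed)) / (n_shuffles + 1))
        rows.append({
            "track": name,
            "n_overlap": observed,
            "overlap_fraction": observed / len(dmrs) if dmrs else np.nan,
            "expected_overlap": expected,
            "enrichment": observed / expected if expected else np.inf,
            "empirical_p": p,
        })
    return pd.DataFrame(rows)


def enrichment_2x2(
    query_in: int, query_out: int, bg_in: int, bg_out: int
) -> OverlapEnrichment:
    """Odds ratio (ad/bc) and two-sided Fisher exact p for a 2x2 table."""
    for v in (query_in, query_out, bg_in, bg_out):
        if v < 0:
            raise ValueError("counts must be non-negative")
    table = np.array([[query_in, query_out], [bg_in, bg_out]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    degenerate = bool(np.any(table == 0))
    if degenerate:  # Haldane-Anscombe correction keeps the estimate finite
        odds = ((query_in + 0.5) * (bg_out + 0.5)) / ((query_out + 0.5) * (bg_in + 0.5))
    else:
        odds = (query_in * bg_out) / (query_out * bg_in)
    return OverlapEnrichment(query_in, query_out, bg_in, bg_out,
                             float(odds), float(p), degenerate)


def intron_enrichment(
    annotated: Sequence[AnnotatedDMR],
    background_features: Sequence[str],
) -> OverlapEnrichment:
    """DMR-in-intron enrichment against a background feature census.

    ``background_features`` are feature-class strings for length-matched
    shuffled intervals (or any reference interval set) classified the
    same way.
    """
    q_in = sum(1 for a in annotated if a.feature.kind == "intron")
    q_out = len(annotated) - q_in
    b_in = sum(1 for f in background_features if f.startswith("intron"))
    b_out = len(background_features) - b_in
    return enrichment_2x2(q_in, q_out, b_in, b_out)


def shuffle_intervals(
    dmrs: Sequence[DMR], chrom_sizes: dict[str, int], seed: int = 0
) -> list[DMR]:
    """Length-matched random placement of DMR intervals (same chromosome)."""
    rng = np.random.default_rng(seed)
    out = []
    for d in dmrs:
        ln = d.end - d.start
        s = int(rng.integers(0, max(1, chrom_sizes[d.chrom] - ln)))
        out.append(DMR(chrom=d.chrom, start=s, end=s + ln, n_cpgs=d.n_cpgs,
                       mean_diff=d.mean_diff, direction=d.direction))
    return out
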