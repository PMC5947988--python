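"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a two-group
(infant vs adult endothelium, 3 vs 3 replicates) T-WGBS + RNA-seq
study so that the whole analysis can be exercised offline:

* a small multi-chromosome genome with non-overlapping, strand-assigned
  multi-exon gene models
* a CpG methylome with bimodal baseline methylation (Beta-mixture),
  negative-binomial coverage, and planted contiguous differentially
  methylated runs — hypomethylation preferentially intronic, a subset
  of genes carrying dense intragenic DMR clusters
* a replicate-level expression table in which hypomethylated-cluster
  genes are preferentially induced (the methylome-transcriptome
  coupling the integration stage is meant to detect)
* a scale-free interactome with a planted dense module from which most
  seeds are drawn
* paired bisulfite reads over a small reference with binary per-CpG
  truth states, conversion failures, low-quality bases and 9-bp
  tagmentation end artifacts.

Everything is driven by one :class:`SimConfig`; identical configs give
byte-identical outputs because each output type draws from its own
named substream of the global seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from methnet._rng import substream
from methnet.core import CpGCountMatrix, GeneModel, GroupDesign
from methnet.methcall import AlignedRead, AlignedReadPair, reference_cpg_sites


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with study-condition defaults."""

    rng_seed: int = 0

    # genome / gene models
    n_chromosomes: int = 2
    chrom_length_bp: int = 3_000_000
    n_genes: int = 150
    exons_per_gene: tuple[int, int] = (3, 8)
    gene_span_bp: tuple[int, int] = (12_000, 24_000)
    exon_length_bp: tuple[int, int] = (150, 300)
    min_intron_bp: int = 500

    # methylome
    n_cpgs: int = 40_000
    group_sizes: tuple[int, int] = (3, 3)
    coverage_mean: float = 20.0
    coverage_dispersion: float = 20.0  # NB size: mean 20 => sd ~6.3, i.e. ~8-30x coverage
    # (alpha, beta) of the low and high mixture components + weight of the high one
    baseline_beta_params: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 9.0), (9.0, 1.0))
    baseline_high_weight: float = 0.75
    n_planted_dmrs: int = 60
    planted_effect: float = 0.3
    planted_run_length: tuple[int, int] = (6, 10)
    hypo_fraction: float = 0.8
    intronic_placement_prob: float = 0.9
    n_cluster_genes: int = 10
    dmrs_per_cluster_gene: int = 8
    group2_high_shift: float = 0.0  # optional global shift of unplanted high-mode sites

    # expression
    expression_coupling: float = 0.8
    de_baseline_prob: float = 0.1  # per-direction background DE probability
    expression_log2_mean: float = 4.0
    expression_log2_sd: float = 1.5
    expression_noise_sd: float = 0.15
    de_fold_range: tuple[float, float] = (2.0, 4.0)
    low_expression_fraction: float = 0.1

    # interactome
    interactome_nodes: int = 2000
    interactome_attach: int = 3
    planted_module_size: int = 60
    module_internal_p: float = 0.15
    n_seeds: int = 40
    seed_module_fraction: float = 0.75

    # bisulfite read simulation (small-reference fixture path)
    conversion_failure_rate: float = 0.01
    read_length: int = 100
    n_read_pairs: int = 400
    fragment_length_range: tuple[int, int] = (80, 220)
    read_sim_meth_prob: float = 0.75
    low_quality_fraction: float = 0.05
    high_base_quality: int = 37
    low_base_quality: int = 11
    antisense_fraction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.group_sizes) < 2:
            raise ValueError("group_sizes components must be >= 2")
        for name in ("hypo_fraction", "intronic_placement_prob", "expression_coupling",
                     "de_baseline_prob", "conversion_failure_rate", "low_quality_fraction",
                     "seed_module_fraction", "module_internal_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.planted_effect <= 1.0:
            raise ValueError("planted_effect must be in [0, 1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        if self.planted_run_length[0] < 1 or self.planted_run_length[0] > self.planted_run_length[1]:
            raise ValueError("invalid planted_run_length range")

    def design(self) -> GroupDesign:
        n1, n2 = self.group_sizes
        return GroupDesign(
            group1=tuple(f"infant_{i + 1}" for i in range(n1)),
            group2=tuple(f"adult_{i + 1}" for i in range(n2)),
        )

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TruthRecord:
    """One planted ground-truth item (region, gene, or node)."""

    kind: str  # dmr | cluster_gene | de_gene | module_node
    chrom: str = "."
    start: int = 0
    end: int = 0
    name: str = ""
    direction: str = "n/a"  # hypo | hyper | up | down | n/a
    effect: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("dmr", "cluster_gene", "de_gene", "module_node"):
            raise ValueError(f"bad truth kind {self.kind!r}")


def _chrom_name(i: int, n: int) -> str:
    return f"chr{i + 1:02d}" if n > 9 else f"chr{i + 1}"


def simulate_gene_models(config: SimConfig) -> list[GeneModel]:
    """Place non-overlapping strand-assigned multi-exon genes.

    Gene spans and inter-gene gaps are drawn randomly per chromosome;
    each gene receives ``exons_per_gene`` exons (inclusive range),
    hence at least one intron.  Raises a configuration error when the
    requested genes cannot be packed into the chromosomes.
    """
    rng = substream(config.rng_seed, "genes")
    if config.n_genes == 0:
        return []
    lo_k, hi_k = config.exons_per_gene
    if lo_k < 2:
        raise ValueError("configuration error: exons_per_gene minimum must be >= 2")
    worst = hi_k * config.exon_length_bp[1] + (hi_k - 1) * config.min_intron_bp
    if config.gene_span_bp[0] < worst:
        raise ValueError("configuration error: gene span too small for requested exon count")

    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    gid = 0
    for ci in range(config.n_chromosomes):
        n = per_chrom[ci]
        if n == 0:
            continue
        chrom = _chrom_name(ci, config.n_chromosomes)
        spans = rng.integers(config.gene_span_bp[0], config.gene_span_bp[1] + 1, size=n)
        slack = config.chrom_length_bp - int(spans.sum())
        if slack < (n + 1) * 100:
            raise ValueError(
                f"configuration error: {n} genes (total {int(spans.sum())} bp) do not fit "
                f"chromosome of {config.chrom_length_bp} bp"
            )
        w = rng.random(n + 1)
        gaps = np.floor(slack * w / w.sum()).astype(int)
        cursor = 0
        for j in range(n):
            cursor += int(gaps[j])
            start = cursor
            end = start + int(spans[j])
            cursor = end
            k = int(rng.integers(lo_k, hi_k + 1))
            # short exons separated by long introns, as in real gene anatomy
            exon_len = rng.integers(config.exon_length_bp[0],
                                    config.exon_length_bp[1] + 1, size=k)
            intron_total = (end - start) - int(exon_len.sum())
            extra = intron_total - (k - 1) * config.min_intron_bp
            wseg = rng.random(k - 1)
            intron_len = config.min_intron_bp + np.floor(extra * wseg / wseg.sum()).astype(int)
            intron_len[-1] += intron_total - int(intron_len.sum())
            seg = np.empty(2 * k - 1, dtype=int)
            seg[0::2] = exon_len
            seg[1::2] = intron_len
            bounds = start + np.concatenate(([0], np.cumsum(seg)))
            exons = tuple(
                (int(bounds[m]), int(bounds[m + 1])) for m in range(0, 2 * k - 1, 2)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{gid:04d}", chrom, strand, start, end, exons))
            gid += 1
    return genes


def _intron_index(genes: Sequence[GeneModel], chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Gene index whose intron contains each CpG, or -1."""
    out = np.full(len(pos), -1, dtype=int)
    for gi, g in enumerate(genes):
        on = chrom == g.chrom
        if not on.any():
            continue
        p = pos[on]
        hit = np.zeros(len(p), dtype=bool)
        for s, e in g.introns():
            hit |= (p >= s) & (p < e)
        idx = np.flatnonzero(on)[hit]
        out[idx] = gi
    return out


def _carve_runs(
    stretches: list[np.ndarray],
    n_runs: int,
    run_lengths: np.ndarray,
    occupied: np.ndarray,
    rng: np.random.Generator,
    gap: int = 3,
) -> list[np.ndarray]:
    """Carve non-overlapping index runs out of candidate stretches.

    ``occupied`` marks CpG indices already used (plus buffer); carved
    runs update it in place.  Stretches are contiguous CpG index arrays.
    """
    runs: list[np.ndarray] = []
    order = rng.permutation(len(stretches)) if stretches else []
    si = 0
    attempts = 0
    while len(runs) < n_runs:
        if not stretches or attempts > 50 * n_runs:
            raise ValueError(
                "configuration error: requested planted runs exceed available CpGs"
            )
        stretch = stretches[order[si % len(stretches)]]
        si += 1
        attempts += 1
        length = int(run_lengths[len(runs)])
        free = ~occupied[stretch]
        # positions where a full run fits in free, contiguous territory
        ok = [
            i
            for i in range(len(stretch) - length + 1)
            if free[i : i + length].all()
        ]
        if not ok:
            continue
        i0 = int(rng.choice(ok))
        run = stretch[i0 : i0 + length]
        runs.append(run)
        lo = max(0, run[0] - gap)
        hi = min(len(occupied), run[-1] + 1 + gap)
        occupied[lo:hi] = True
    return runs


def simulate_methylome(
    config: SimConfig, genes: Sequence[GeneModel]
) -> tuple[CpGCountMatrix, list[TruthRecord]]:
    """Simulate CpG count tables with planted differential runs.

    Baseline per-site methylation comes from the bimodal Beta mixture;
    per-sample coverage is negative-binomial and counts binomial.
    Planted runs shift the group-2 (adult) mean by ±``planted_effect``
    over contiguous CpGs; the baseline at planted sites is clipped so
    the shifted level stays in [0, 1] — biologically, methylation loss
    starts from methylated territory and gain from unmethylated.
    """
    rng = substream(config.rng_seed, "methylome")

    # CpG positions: even coordinates guarantee non-overlapping CG units
    per_chrom = [config.n_cpgs // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_cpgs % config.n_chromosomes):
        per_chrom[i] += 1
    chroms, positions = [], []
    for ci in range(config.n_chromosomes):
        m = per_chrom[ci]
        half = config.chrom_length_bp // 2 - 1
        if m > half:
            raise ValueError("configuration error: n_cpgs exceeds chromosome capacity")
        p = np.sort(rng.choice(half, size=m, replace=False)) * 2
        chroms.append(np.repeat(_chrom_name(ci, config.n_chromosomes), m))
        positions.append(p)
    chrom = np.concatenate(chroms).astype(object)
    pos = np.concatenate(positions)
    n = len(pos)

    (a_lo, b_lo), (a_hi, b_hi) = config.baseline_beta_params
    is_high = rng.random(n) < config.baseline_high_weight
    p0 = np.where(is_high, rng.beta(a_hi, b_hi, size=n), rng.beta(a_lo, b_lo, size=n))

    # ---- plant differential runs
    truth: list[TruthRecord] = []
    occupied = np.zeros(n, dtype=bool)
    runs: list[tuple[np.ndarray, str, str]] = []  # (indices, direction, gene_id)

    intron_gene = _intron_index(genes, chrom, pos)
    lo_r, hi_r = config.planted_run_length
    eff = config.planted_effect

    def stretches_for(gene_indices: set[int]) -> list[np.ndarray]:
        """Maximal consecutive CpG-index stretches lying in introns of the given genes."""
        mask = np.isin(intron_gene, list(gene_indices)) if gene_indices else np.zeros(n, bool)
        out = []
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            return out
        breaks = np.flatnonzero(np.diff(idx) != 1)
        for seg in np.split(idx, breaks + 1):
            if len(seg) >= lo_r:
                out.append(seg)
        return out

    cluster_gene_ids: list[str] = []
    if config.n_cluster_genes > 0 and eff > 0:
        counts = pd.Series(intron_gene[intron_gene >= 0]).value_counts()
        ranked = sorted(
            counts.index, key=lambda gi: (-counts[gi], genes[gi].gene_id)
        )
        if len(ranked) < config.n_cluster_genes:
            raise ValueError("configuration error: not enough genes with intronic CpGs")
        cluster_idx = ranked[: config.n_cluster_genes]
        for gi in cluster_idx:
            g = genes[gi]
            lens = rng.integers(lo_r, hi_r + 1, size=config.dmrs_per_cluster_gene)
            carved = _carve_runs(stretches_for({gi}), config.dmrs_per_cluster_gene,
                                 lens, occupied, rng)
            for run in carved:
                runs.append((run, "hypo", g.gene_id))
            cluster_gene_ids.append(g.gene_id)
            truth.append(TruthRecord(kind="cluster_gene", chrom=g.chrom, start=g.start,
                                     end=g.end, name=g.gene_id, direction="hypo", effect=-eff))
        cluster_set = set(cluster_idx)
    else:
        cluster_set = set()

    if config.n_planted_dmrs > 0 and eff > 0:
        other_genes = {gi for gi in range(len(genes))} - cluster_set
        intronic_stretches = stretches_for(other_genes)
        all_idx = np.arange(n)
        breaks = np.flatnonzero(chrom[:-1] != chrom[1:])
        anywhere = [seg for seg in np.split(all_idx, breaks + 1) if len(seg) >= lo_r]
        for _ in range(config.n_planted_dmrs):
            hypo = rng.random() < config.hypo_fraction
            intronic = hypo and rng.random() < config.intronic_placement_prob
            pool = intronic_stretches if intronic and intronic_stretches else anywhere
            length = rng.integers(lo_r, hi_r + 1, size=1)
            run = _carve_runs(pool, 1, length, occupied, rng)[0]
            gi = intron_gene[run[0]]
            host = genes[gi].gene_id if gi >= 0 else ""
            runs.append((run, "hypo" if hypo else "hyper", host))

    # planted baselines come from the matching mixture component: loss of
    # methylation starts from methylated territory (high mode), gain from
    # unmethylated (low mode); clipping keeps the shifted level in [0, 1]
    level2 = p0.copy()
    for run, direction, host in runs:
        if direction == "hypo":
            p0[run] = np.clip(rng.beta(a_hi, b_hi, size=len(run)), eff + 0.05, 0.95)
            level2[run] = p0[run] - eff
            signed = -eff
        else:
            p0[run] = np.clip(rng.beta(a_lo, b_lo, size=len(run)), 0.05, 1.0 - eff - 0.05)
            level2[run] = p0[run] + eff
            signed = eff
        truth.append(TruthRecord(
            kind="dmr", chrom=str(chrom[run[0]]), start=int(pos[run[0]]),
            end=int(pos[run[-1]]) + 2, name=host, direction=direction, effect=signed,
        ))

    if config.group2_high_shift:
        untouched = is_high & ~occupied
        level2[untouched] = np.clip(level2[untouched] + config.group2_high_shift, 0.0, 1.0)

    # ---- counts
    design = config.design()
    samples = list(design.samples)
    n1 = len(design.group1)
    levels = np.column_stack(
        [p0] * n1 + [level2] * len(design.group2)
    )
    disp = config.coverage_dispersion
    p_nb = disp / (disp + config.coverage_mean)
    coverage = rng.negative_binomial(disp, p_nb, size=levels.shape)
    meth = rng.binomial(coverage, levels)
    matrix = CpGCountMatrix(chrom=chrom, pos=pos, samples=samples,
                            meth=meth, unmeth=coverage - meth)
    return matrix, truth


def simulate_expression(
    config: SimConfig, genes: Sequence[GeneModel], truth: Sequence[TruthRecord]
) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Replicate-level expression coupled to planted methylation clusters.

    Hypomethylated-cluster genes are induced (linear fold drawn from
    ``de_fold_range``, all > 1.75) with probability
    ``expression_coupling``; background genes are induced or repressed
    each with probability ``de_baseline_prob``.  The returned table
    carries per-group mean expression (RPKM-like), log2 fold change and
    a two-sided Welch p from the replicate comparison.
    """
    rng = substream(config.rng_seed, "expression")
    cluster = {t.name for t in truth if t.kind == "cluster_gene"}
    n1, n2 = config.group_sizes
    rows = []
    de_truth: list[TruthRecord] = []
    for g in genes:
        if rng.random() < config.low_expression_fraction:
            base = rng.normal(-2.0, 1.0)
        else:
            base = rng.normal(config.expression_log2_mean, config.expression_log2_sd)
        lfc = 0.0
        direction = None
        if g.gene_id in cluster:
            if rng.random() < config.expression_coupling:
                direction = "up"
        else:
            u = rng.random()
            if u < config.de_baseline_prob:
                direction = "up"
            elif u < 2 * config.de_baseline_prob:
                direction = "down"
        if direction is not None:
            fold = rng.uniform(*config.de_fold_range)
            lfc = np.log2(fold) if direction == "up" else -np.log2(fold)
            de_truth.append(TruthRecord(kind="de_gene", chrom=g.chrom, start=g.start,
                                        end=g.end, name=g.gene_id, direction=direction,
                                        effect=float(lfc)))
        rep1 = base + rng.normal(0.0, config.expression_noise_sd, size=n1)
        rep2 = base + lfc + rng.normal(0.0, config.expression_noise_sd, size=n2)
        m1 = float(np.mean(2.0 ** rep1))
        m2 = float(np.mean(2.0 ** rep2))
        if config.expression_noise_sd > 0:
            p = float(stats.ttest_ind(rep2, rep1, equal_var=False).pvalue)
        else:
            p = 1.0 if np.isclose(lfc, 0.0) else 0.0
        rows.append((g.gene_id, m1, m2, float(np.log2(m2 / m1)), p))
    table = pd.DataFrame(rows, columns=["gene_id", "mean_group1", "mean_group2",
                                        "log2fc", "pvalue"])
    return table, de_truth


def simulate_interactome(
    config: SimConfig,
) -> tuple[nx.Graph, list[str], list[TruthRecord]]:
    """Scale-free interactome with a planted dense module and seed set.

    A preferential-attachment (Barabási–Albert) graph mimics the
    degree structure of protein-interaction networks; the planted
    module receives extra internal edges so its density exceeds the
    global density, and most seeds are drawn from it.
    """
    rng = substream(config.rng_seed, "interactome")
    ba_seed = int(rng.integers(0, 2**31 - 1))
    g0 = nx.barabasi_albert_graph(config.interactome_nodes, config.interactome_attach,
                                  seed=ba_seed)
    width = len(str(config.interactome_nodes - 1))
    mapping = {i: f"n{i:0{width}d}" for i in g0.nodes}
    graph = nx.relabel_nodes(g0, mapping)

    truth: list[TruthRecord] = []
    nodes = sorted(graph.nodes)
    if config.planted_module_size > 0:
        module = sorted(rng.choice(nodes, size=config.planted_module_size, replace=False))
        for i, a in enumerate(module):
            for b in module[i + 1:]:
                if not graph.has_edge(a, b) and rng.random() < config.module_internal_p:
                    graph.add_edge(a, b)
        truth.extend(TruthRecord(kind="module_node", name=m) for m in module)
    else:
        module = []

    n_from_module = min(len(module), round(config.n_seeds * config.seed_module_fraction))
    seeds = list(rng.choice(module, size=n_from_module, replace=False)) if n_from_module else []
    outside = sorted(set(nodes) - set(module))
    n_out = config.n_seeds - n_from_module
    if n_out > 0:
        seeds += list(rng.choice(outside, size=n_out, replace=False))
    return graph, sorted(seeds), truth


def simulate_reference(config: SimConfig, length: int = 3000, n_chrom: int = 1) -> dict[str, str]:
    """Small random reference for the bisulfite read-simulation path."""
    rng = substream(config.rng_seed, "reference")
    ref = {}
    for i in range(n_chrom):
        ref[f"ref{i + 1}"] = "".join(rng.choice(list("ACGT"), size=length))
    return ref


def simulate_bisulfite_reads(
    config: SimConfig, reference: dict[str, str]
) -> tuple[list[AlignedReadPair], dict[tuple[str, int], int]]:
    """Paired bisulfite reads with binary per-CpG truth states.

    Each CpG gets a true state (1 methylated / 0 unmethylated).  On the
    sequenced strand, methylated cytosines are retained and
    unmethylated ones converted, with conversion failures at
    ``conversion_failure_rate`` on both CH and CpG cytosines.  A
    configurable fraction of bases gets Phred < 20; tagmentation
    artifact bases (raw unconverted genomic sequence) are written into
    the first 9 bp of read 2 and the last 9 bp before the adapter in
    read 1, so those bases carry spurious methylation signal unless
    masked.
    """
    rng = substream(config.rng_seed, "reads")
    truth = {
        (chrom, p): int(rng.random() < config.read_sim_meth_prob)
        for chrom, p in reference_cpg_sites(reference)
    }
    chroms = sorted(reference)
    weights = np.array([len(reference[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    R = config.read_length
    fail = config.conversion_failure_rate
    pairs: list[AlignedReadPair] = []

    def convert(chrom: str, s: int, e: int, strand: str) -> list[str]:
        seq = reference[chrom]
        frag = list(seq[s:e])
        for i, base in enumerate(frag):
            p = s + i
            if strand == "top" and base == "C":
                is_cpg = p + 1 < len(seq) and seq[p + 1] == "G"
                if is_cpg and truth[(chrom, p)]:
                    continue  # methylated C retained
                frag[i] = "C" if rng.random() < fail else "T"
            elif strand == "bottom" and base == "G":
                is_cpg = p > 0 and seq[p - 1] == "C"
                if is_cpg and truth[(chrom, p - 1)]:
                    continue  # methylated (minus-strand C) -> G retained
                frag[i] = "G" if rng.random() < fail else "A"
        return frag

    for _ in range(config.n_read_pairs):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        seq = reference[chrom]
        f_lo, f_hi = config.fragment_length_range
        F = int(rng.integers(f_lo, f_hi + 1))
        F = min(F, len(seq))
        s = int(rng.integers(0, len(seq) - F + 1))
        strand = "top" if rng.random() < 0.5 else "bottom"
        frag = convert(chrom, s, s + F, strand)
        L = min(R, F)
        adapter_offset = F if F < R else None

        if strand == "top":
            r1_start, r1_rev = s, False
            r2_start, r2_rev = s + F - L, True
        else:
            r1_start, r1_rev = s + F - L, True
            r2_start, r2_rev = s, False

        def slice_frag(start: int) -> list[str]:
            return frag[start - s : start - s + L]

        seq1 = slice_frag(r1_start)
        seq2 = slice_frag(r2_start)

        # tagmentation artifacts: raw genomic bases at fragment ends
        for i in range(min(9, L)):  # first 9 bp of read 2 (read orientation)
            j = i if not r2_rev else L - 1 - i
            seq2[j] = seq[r2_start + j]
        if adapter_offset is not None:  # last 9 bp before the adapter in read 1
            for i in range(max(0, adapter_offset - 9), adapter_offset):
                if i < L:
                    j = i if not r1_rev else L - 1 - i
                    seq1[j] = seq[r1_start + j]

        def quals() -> np.ndarray:
            low = rng.random(L) < config.low_quality_fraction
            return np.where(low, config.low_base_quality, config.high_base_quality)

        pair = AlignedReadPair(
            read1=AlignedRead(chrom, r1_start, "".join(seq1), quals(), r1_rev),
            read2=AlignedRead(chrom, r2_start, "".join(seq2), quals(), r2_rev),
            bs_strand=strand,
            adapter_offset=adapter_offset,
            is_antisense=bool(rng.random() < config.antisense_fraction),
        )
        pairs.append(pair)
    return pairs, truth


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in truth],
                        columns=["kind", "chrom", "start", "end", "name",
                                 "direction", "effect"])
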