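"""Methylome-transcriptome integration.

Differential expression is consumed as a summary table (gene, per-group
mean expression, log2 fold change, p); genes are partitioned into
induced / repressed / unchanged / filtered by the >1.75-fold, p<0.05,
RPKM>=1 rule.  On the methylation side each gene gets an intragenic
DMR profile; genes with more than five intragenic DMRs form "DMR
clusters".  The two sides meet in a GSEA-style running-sum enrichment
on DMR-count-ranked gene lists and in a tiered overlap of methylated
vs differentially expressed genes (any assigned DMR, intragenic DMR,
DMR cluster).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from methnet.annotate import AnnotatedDMR, OverlapEnrichment, enrichment_2x2
from methnet.core import GeneModel


@dataclass(frozen=True)
class DeConfig:
    fold_threshold: float = 1.75
    alpha: float = 0.05
    expression_floor: float = 1.0  # RPKM-like floor; gene kept if any group mean reaches it

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")


def define_de_genes(table: pd.DataFrame, cfg: DeConfig = DeConfig()) -> pd.DataFrame:
    """Partition expression records into induced/repressed/unchanged/filtered.

    A gene is filtered when both group means fall below the expression
    floor; induced when linear fold > fold_threshold with p < alpha;
    repressed when fold < 1/fold_threshold with p < alpha ("more than
    1.75-fold" is read strictly, so fold == 1.75 is unchanged).
    """
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    out = table.copy()
    fold = 2.0 ** out["log2fc"].to_numpy(dtype=float)
    p = out["pvalue"].to_numpy(dtype=float)
    filtered = (out["mean_group1"] < cfg.expression_floor) & (
        out["mean_group2"] < cfg.expression_floor
    )
    status = np.full(len(out), "unchanged", dtype=object)
    status[(fold > cfg.fold_threshold) & (p < cfg.alpha)] = "induced"
    status[(fold < 1.0 / cfg.fold_threshold) & (p < cfg.alpha)] = "repressed"
    status[filtered.to_numpy()] = "filtered"
    out["status"] = status
    return out


def de_gene_sets(records: pd.DataFrame) -> dict[str, set[str]]:
    sets = {}
    for s in ("induced", "repressed", "unchanged", "filtered"):
        sets[s] = set(records.loc[records["status"] == s, "gene_id"])
    sets["de"] = sets["induced"] | sets["repressed"]
    sets["expressed"] = sets["de"] | sets["unchanged"]
    return sets


# ------------------------------------------------------------ DMR profiles

def profile_gene_dmrs(
    annotated: Sequence[AnnotatedDMR],
    genes: Sequence[GeneModel],
    cluster_threshold: int = 5,
) -> pd.DataFrame:
    """Per-gene intragenic DMR counts split by direction.

    A DMR is intragenic for a gene when its midpoint lies inside the
    gene body [start, end); ``is_cluster`` marks genes with strictly
    more than ``cluster_threshold`` intragenic DMRs.
    """
    counts = {g.gene_id: [0, 0] for g in genes}  # [hypo, hyper]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for a in annotated:
        mid = a.dmr.midpoint
        for g in by_chrom.get(a.dmr.chrom, ()):
            if g.contains(mid):
                counts[g.gene_id][0 if a.dmr.direction == "hypo" else 1] += 1
    rows = [
        {
            "gene_id": gid,
            "n_intragenic_dmrs": h + y,
            "n_hypo": h,
            "n_hyper": y,
            "is_cluster": (h + y) > cluster_threshold,
        }
        for gid, (h, y) in counts.items()
    ]
    return pd.DataFrame(rows).sort_values("gene_id", ignore_index=True)


def detect_dmr_clusters(profiles: pd.DataFrame, threshold: int = 5) -> dict:
    """Cluster genes (> threshold intragenic DMRs) and composition stats."""
    is_cluster = profiles["n_intragenic_dmrs"] > threshold
    cluster = profiles.loc[is_cluster]
    total_dmrs = int(profiles["n_intragenic_dmrs"].sum())
    captured = int(cluster["n_intragenic_dmrs"].sum())
    hypo_in_clusters = int(cluster["n_hypo"].sum())
    return {
        "cluster_genes": set(cluster["gene_id"]),
        "n_cluster_genes": int(is_cluster.sum()),
        "n_dmrs_captured": captured,
        "fraction_dmrs_captured": captured / total_dmrs if total_dmrs else np.nan,
        "hypo_fraction_in_clusters": hypo_in_clusters / captured if captured else np.nan,
    }


def rank_genes_by_dmr_count(profiles: pd.DataFrame) -> pd.DataFrame:
    """Descending by intragenic DMR count; ties broken by gene id."""
    ranked = profiles.sort_values(
        ["n_intragenic_dmrs", "gene_id"], ascending=[False, True], ignore_index=True
    )
    return ranked[["gene_id", "n_intragenic_dmrs"]].rename(
        columns={"n_intragenic_dmrs": "statistic"}
    )


# ------------------------------------------------------------------- GSEA

@dataclass(frozen=True)
class GseaResult:
    es: float
    p: float
    n_permutations: int
    seed: int
    n_hits: int


def running_sum(
    ranked_ids: Sequence[str],
    gene_set: set[str],
    statistic: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Classic GSEA running sum along a ranked list.

    Hits increment 1/|S∩L| (unweighted) or |stat|/Σ|stat over hits|
    (weighted); misses decrement 1/(N - |S∩L|).
    """
    n = len(ranked_ids)
    hits = np.array([g in gene_set for g in ranked_ids])
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked list; miss increment undefined")
    steps = np.empty(n)
    if statistic is None:
        steps[hits] = 1.0 / n_hit
    else:
        w = np.abs(np.asarray(statistic, dtype=float))
        total = w[hits].sum()
        steps[hits] = (w[hits] / total) if total > 0 else 1.0 / n_hit
    steps[~hits] = -1.0 / (n - n_hit)
    return np.cumsum(steps)


def enrichment_score(
    ranked_ids: Sequence[str],
    gene_set: set[str],
    statistic: Optional[np.ndarray] = None,
) -> float:
    """Signed maximum deviation of the running sum."""
    rs = running_sum(ranked_ids, gene_set, statistic)
    return float(rs[np.argmax(np.abs(rs))])


def gsea_enrichment(
    ranked: pd.DataFrame,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weighted: bool = False,
) -> GseaResult:
    """Running-sum enrichment with gene-label permutation p-value.

    The p-value is the add-one-smoothed fraction of ``n_perm`` random
    same-size gene sets whose |ES| reaches the observed |ES|.
    """
    ids = list(ranked["gene_id"])
    stat = ranked["statistic"].to_numpy(dtype=float) if weighted else None
    present = gene_set & set(ids)
    if not present:
        raise ValueError("gene set does not intersect the ranked list")
    es = enrichment_score(ids, present, stat)
    rng = np.random.default_rng(seed)
    ids_arr = np.array(ids, dtype=object)
    count = 0
    for _ in range(n_perm):
        perm = set(rng.choice(ids_arr, size=len(present), replace=False))
        if abs(enrichment_score(ids, perm, stat)) >= abs(es):
            count += 1
    return GseaResult(
        es=es, p=(count + 1) / (n_perm + 1), n_permutations=n_perm,
        seed=seed, n_hits=len(present),
    )


# ------------------------------------------------- tiered expression overlap

@dataclass(frozen=True)
class OverlapResult:
    tier: str  # any_dmr | intragenic_dmr | clustered_dmr
    n_methylated: int
    n_de: int
    n_overlap: int
    overlap_fraction: float  # fraction of methylated genes that are DE
    enrichment: OverlapEnrichment
    concordant_hypo_induced: int
    concordant_hyper_repressed: int


def expression_methylation_overlap(
    de_records: pd.DataFrame,
    profiles: pd.DataFrame,
    annotated: Sequence[AnnotatedDMR],
    universe: Optional[set[str]] = None,
    cluster_threshold: int = 5,
) -> list[OverlapResult]:
    """Overlap of methylated and differentially expressed genes at three
    thresholds on the number of DMRs per gene.

    Tiers: ``any_dmr`` = genes with at least one regulatory-domain
    assigned DMR (distal DMRs count); ``intragenic_dmr`` = at least one
    intragenic DMR; ``clustered_dmr`` = more than ``cluster_threshold``
    intragenic DMRs.  Fisher enrichment is computed against the
    expressed universe.
    """
    sets = de_gene_sets(de_records)
    de = sets["de"]
    if universe is None:
        universe = sets["expressed"]
    missing = de - universe
    if missing:
        raise ValueError(f"universe missing DE genes: {sorted(missing)[:5]}")

    assigned: set[str] = set()
    hypo_assigned: set[str] = set()
    hyper_assigned: set[str] = set()
    for a in annotated:
        assigned.update(a.assigned_genes)
        (hypo_assigned if a.dmr.direction == "hypo" else hyper_assigned).update(
            a.assigned_genes
        )
    intragenic = set(profiles.loc[profiles["n_intragenic_dmrs"] >= 1, "gene_id"])
    clustered = set(
        profiles.loc[profiles["n_intragenic_dmrs"] > cluster_threshold, "gene_id"]
    )
    hypo_intra = set(profiles.loc[profiles["n_hypo"] >= 1, "gene_id"])
    hyper_intra = set(profiles.loc[profiles["n_hyper"] >= 1, "gene_id"])

    tiers = [
        ("any_dmr", assigned & universe, hypo_assigned, hyper_assigned),
        ("intragenic_dmr", intragenic & universe, hypo_intra, hyper_intra),
        ("clustered_dmr", clustered & universe, hypo_intra, hyper_intra),
    ]
    results = []
    for name, meth_set, hypo_set, hyper_set in tiers:
        overlap = meth_set & de
        enr = enrichment_2x2(
            len(overlap),
            len(meth_set - de),
            len(de - meth_set),
            len(universe - de - meth_set),
        )
        results.append(OverlapResult(
            tier=name,
            n_methylated=len(meth_set),
            n_de=len(de),
            n_overlap=len(overlap),
            overlap_fraction=len(overlap) / len(meth_set) if meth_set else np.nan,
            enrichment=enr,
            concordant_hypo_induced=len(meth_set & hypo_set & sets["induced"]),
            concordant_hyper_repressed=len(meth_set & hyper_set & sets["repressed"]),
        ))
    return results
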