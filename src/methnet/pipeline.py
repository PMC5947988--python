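"""Stage orchestration: configs, file layout, manifests.

Each stage is a plain function from input files to output files so the
CLI stays a thin shell; ``run_all`` chains them on a synthetic dataset.
Every default equals the study parameter where one exists (8x coverage
in 2 of 3 samples, p<0.05, 10% difference, 3 consecutive CpGs,
1.75-fold, RPKM 1, cluster >5 DMRs, Phred 20, 9-bp tagmentation masks).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from methnet import io
from methnet.core import GroupDesign
from methnet import annotate as ann
from methnet import dmr as dmrmod
from methnet import integrate as integ
from methnet import network as net
from methnet.methcall import MethylCallConfig, estimate_conversion_rate, extract_cpg_calls, read_sam, write_sam
from methnet.sim import SimConfig, TruthRecord, simulate_bisulfite_reads, simulate_expression, simulate_gene_models, simulate_interactome, simulate_methylome, simulate_reference, truth_to_frame
from methnet._rng import substream

log = logging.getLogger("methnet")


class ConfigError(ValueError):
    """Invalid or unknown configuration field."""


@dataclass(frozen=True)
class AnnotationConfig:
    promoter_window: int = 1000
    basal_up: int = 5000
    basal_down: int = 1000
    max_extension: int = 1_000_000
    max_genes: int = 3
    n_shuffles: int = 200


@dataclass(frozen=True)
class NetworkConfig:
    max_iter: int = 200
    window: int = 10
    theta: float = 0.001
    big_theta: float = 0.01


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    methcall: MethylCallConfig = field(default_factory=MethylCallConfig)
    dmr: dmrmod.DmrCallConfig = field(default_factory=dmrmod.DmrCallConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    de: integ.DeConfig = field(default_factory=integ.DeConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, sim=self.sim.replace(rng_seed=seed)
        )


_SECTIONS = {
    "sim": SimConfig,
    "methcall": MethylCallConfig,
    "dmr": dmrmod.DmrCallConfig,
    "annotation": AnnotationConfig,
    "de": integ.DeConfig,
    "network": NetworkConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown field {sorted(unknown)[0]!r} in section {section!r}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section {section!r}: {exc}") from exc


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for key, value in overrides.items():
            section, _, name = key.partition(".")
            if name:
                data.setdefault(section, {})[name] = value
            else:
                data[key] = value
    top_known = {"seed", "log_level", *_SECTIONS}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level field {sorted(unknown)[0]!r}")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    cfg = PipelineConfig(
        seed=int(data.get("seed", 0)), log_level=str(data.get("log_level", "INFO")),
        **kwargs,
    )
    if "seed" in data and "rng_seed" not in data.get("sim", {}):
        cfg = cfg.with_seed(int(data["seed"]))
    return cfg


# ----------------------------------------------------------------- manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig) -> None:
        self.outdir = outdir
        self.data = {
            "tool": "methnet",
            "version": __import__("methnet").__version__,
            "config": _config_dict(config),
            "stages": {},
        }

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.data["stages"][stage] = {
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
            "seconds": round(seconds, 3),
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        tmp = path.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        tmp.replace(path)  # atomic on POSIX
        return path


def _config_dict(cfg: PipelineConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(cfg)))


# ------------------------------------------------------------------- stages

def stage_simulate(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    """Generate every pipeline input, with truth, into ``outdir``."""
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    log.info("simulate: seed=%d n_cpgs=%d n_genes=%d", sim.rng_seed, sim.n_cpgs, sim.n_genes)
    genes = simulate_gene_models(sim)
    matrix, truth = simulate_methylome(sim, genes)
    expression, de_truth = simulate_expression(sim, genes, truth)
    graph, seeds, module_truth = simulate_interactome(sim)
    reference = simulate_reference(sim)
    pairs, read_truth = simulate_bisulfite_reads(sim, reference)
    truth = list(truth) + list(de_truth) + list(module_truth)

    paths: dict[str, Path] = {}

    def save(key: str, name: str, writer) -> None:
        p = outdir / name
        writer(p)
        paths[key] = p

    save("genes", "genes.bed12", lambda p: io.write_genes_bed12(p, genes))
    for sample in matrix.samples:
        save(f"cpg_{sample}", f"cpg_{sample}.tsv",
             lambda p, s=sample: io.write_cpg_report(p, matrix, s))
    save("expression", "expression.tsv", lambda p: io.write_expression_table(p, expression))
    save("edges", "interactome_edges.tsv",
         lambda p: io.write_edge_list(p, sorted(tuple(sorted(e)) for e in graph.edges)))
    save("seeds", "seeds.txt", lambda p: io.write_gene_list(p, seeds))
    save("reference", "reference.fa", lambda p: io.write_fasta(p, reference))
    save("reads", "reads.sam", lambda p: write_sam(p, pairs, reference))
    save("truth", "truth.tsv",
         lambda p: truth_to_frame(truth).to_csv(p, sep="\t", index=False))
    save("read_truth", "read_truth.tsv", lambda p: pd.DataFrame(
        [(c, pos, state) for (c, pos), state in sorted(read_truth.items())],
        columns=["chrom", "pos", "methylated"]).to_csv(p, sep="\t", index=False))

    # synthetic regulatory tracks: an enhancer-like track concentrated on
    # planted hypomethylated territory plus background, and a promoter track
    rng = substream(sim.rng_seed, "tracks")
    enhancers = []
    for t in truth:
        if t.kind == "dmr" and t.direction == "hypo" and rng.random() < 0.7:
            pad = int(rng.integers(200, 600))
            enhancers.append((t.chrom, max(0, t.start - pad), t.end + pad, "enhancer"))
    for _ in range(200):
        ci = int(rng.integers(0, sim.n_chromosomes))
        chrom = f"chr{ci + 1:02d}" if sim.n_chromosomes > 9 else f"chr{ci + 1}"
        s = int(rng.integers(0, sim.chrom_length_bp - 1500))
        enhancers.append((chrom, s, s + int(rng.integers(500, 1500)), "enhancer"))
    promoters = [
        (g.chrom, max(0, g.tss - 500), g.tss + 500, "promoter") for g in genes
    ]
    save("track_enhancer", "track_enhancer_like.bed",
         lambda p: io.write_bed6(p, sorted(enhancers)))
    save("track_promoter", "track_promoter_like.bed",
         lambda p: io.write_bed6(p, sorted(promoters)))

    # annotation gene sets for over-representation: planted module + random
    module = sorted(t.name for t in truth if t.kind == "module_node")
    nodes = sorted(graph.nodes)
    sets = {"planted_module": module} if module else {}
    for i in range(3):
        sets[f"random_set_{i + 1}"] = sorted(
            rng.choice(nodes, size=min(50, len(nodes)), replace=False)
        )
    save("genesets", "genesets.gmt", lambda p: io.write_gmt(p, sets))
    return paths


def stage_callmeth(config: PipelineConfig, sam: Path, fasta: Path, outdir: Path) -> dict[str, Path]:
    """Methylation calling on aligned bisulfite reads."""
    outdir.mkdir(parents=True, exist_ok=True)
    reference = io.read_fasta(fasta)
    pairs = read_sam(sam)
    log.info("callmeth: %d pairs, %d reference sequences", len(pairs), len(reference))
    matrix = extract_cpg_calls(pairs, reference, config.methcall, sample="readsim")
    rate = estimate_conversion_rate(pairs, reference, config.methcall)
    report = outdir / "cpg_readsim.tsv"
    io.write_cpg_report(report, matrix, "readsim")
    conv = outdir / "conversion_rate.json"
    conv.write_text(json.dumps({
        "rate": rate.rate, "converted": rate.converted,
        "unconverted": rate.unconverted}, indent=2))
    return {"cpg_report": report, "conversion": conv}


def stage_dmr(config: PipelineConfig, cpg_reports: dict[str, Path], design: GroupDesign,
              outdir: Path) -> dict[str, Path]:
    """Coverage filtering, DMC testing, DMR calling, genome summaries."""
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = io.read_cpg_reports({s: cpg_reports[s] for s in design.samples})
    log.info("dmr: %d sites, %d samples", matrix.n_sites, len(matrix.samples))
    dmcs = dmrmod.call_dmcs(matrix, design, config.dmr)
    dmrs = dmrmod.call_dmrs(dmcs, config.dmr)
    summary = {
        "n_sites": int(matrix.n_sites),
        "n_filtered_sites": int(len(dmcs)),
        "n_dmcs": int(dmcs["is_dmc"].sum()),
        "n_dmrs": len(dmrs),
        "direction_split": dmrmod.summarize_dmrs(dmrs, [0.1, 0.3]).to_dict("records"),
        "global_distribution": dmrmod.global_cpg_distribution(matrix, design),
    }
    paths = {}
    p = outdir / "dmcs.tsv"; dmcs.to_csv(p, sep="\t", index=False); paths["dmcs"] = p
    p = outdir / "dmrs.bed"; io.write_dmrs_bed(p, dmrs); paths["dmrs_bed"] = p
    p = outdir / "dmrs.tsv"
    pd.DataFrame([{
        "chrom": d.chrom, "start": d.start, "end": d.end, "n_cpgs": d.n_cpgs,
        "mean_diff": d.mean_diff, "direction": d.direction} for d in dmrs]
    ).to_csv(p, sep="\t", index=False); paths["dmrs_tsv"] = p
    p = outdir / "summary.json"; p.write_text(json.dumps(summary, indent=2)); paths["summary"] = p
    return paths


def _dmrs_from_tsv(path: Path) -> list:
    from methnet.core import DMR

    df = pd.read_csv(path, sep="\t")
    return [DMR(chrom=r.chrom, start=int(r.start), end=int(r.end), n_cpgs=int(r.n_cpgs),
                mean_diff=float(r.mean_diff), direction=r.direction)
            for r in df.itertuples()]


def stage_annotate(config: PipelineConfig, dmrs_tsv: Path, genes_bed: Path,
                   tracks: dict[str, Path], chrom_sizes: dict[str, int],
                   outdir: Path) -> dict[str, Path]:
    """Feature classes, TSS distances, GREAT assignment, track enrichment."""
    outdir.mkdir(parents=True, exist_ok=True)
    genes = io.read_genes_bed12(genes_bed)
    dmrs = _dmrs_from_tsv(dmrs_tsv)
    a = config.annotation
    annotated = ann.annotate_dmrs(dmrs, genes, a.promoter_window, a.basal_up,
                                  a.basal_down, a.max_extension, a.max_genes)
    frame = ann.annotation_frame(annotated)
    shuffled = ann.shuffle_intervals(dmrs, chrom_sizes, seed=config.seed)
    bg = [str(ann.classify_genomic_feature(d, genes, a.promoter_window)) for d in shuffled]
    intron_or = ann.intron_enrichment(annotated, bg)
    track_sets = {
        name: [(c, s, e) for c, s, e, *_ in io.read_bed6(p)] for name, p in tracks.items()
    }
    track_enr = ann.intersect_tracks(dmrs, track_sets, chrom_sizes,
                                     n_shuffles=a.n_shuffles, seed=config.seed)
    paths = {}
    p = outdir / "annotated_dmrs.tsv"; frame.to_csv(p, sep="\t", index=False)
    paths["annotated"] = p
    p = outdir / "enrichment.json"
    p.write_text(json.dumps({
        "intron": dataclasses.asdict(intron_or),
        "tracks": track_enr.to_dict("records"),
        "feature_counts": frame["feature"].str.replace(r"\d+$", "", regex=True)
                               .value_counts().to_dict(),
    }, indent=2))
    paths["enrichment"] = p
    return paths


def stage_integrate(config: PipelineConfig, expression_tsv: Path, annotated_tsv: Path,
                    genes_bed: Path, outdir: Path) -> dict[str, Path]:
    """DE definition, DMR profiles/clusters, GSEA, tiered overlap."""
    outdir.mkdir(parents=True, exist_ok=True)
    genes = io.read_genes_bed12(genes_bed)
    table = io.read_expression_table(expression_tsv)
    records = integ.define_de_genes(table, config.de)
    frame = pd.read_csv(annotated_tsv, sep="\t")
    annotated = _annotated_from_frame(frame)
    profiles = integ.profile_gene_dmrs(annotated, genes)
    clusters = integ.detect_dmr_clusters(profiles)
    ranked = integ.rank_genes_by_dmr_count(profiles)
    sets = integ.de_gene_sets(records)
    gsea = None
    if sets["induced"] & set(ranked["gene_id"]):
        res = integ.gsea_enrichment(ranked, sets["induced"], n_perm=1000, seed=config.seed)
        gsea = dataclasses.asdict(res)
    overlaps = integ.expression_methylation_overlap(records, profiles, annotated)
    paths = {}
    p = outdir / "de_genes.tsv"; records.to_csv(p, sep="\t", index=False); paths["de"] = p
    p = outdir / "dmr_profiles.tsv"; profiles.to_csv(p, sep="\t", index=False)
    paths["profiles"] = p
    p = outdir / "ranked_genes.tsv"; ranked.to_csv(p, sep="\t", index=False)
    paths["ranked"] = p
    p = outdir / "integration.json"
    p.write_text(json.dumps({
        "clusters": {k: (sorted(v) if isinstance(v, set) else v)
                     for k, v in clusters.items()},
        "gsea_induced_vs_dmr_rank": gsea,
        "overlap_tiers": [
            {**dataclasses.asdict(o), "enrichment": dataclasses.asdict(o.enrichment)}
            for o in overlaps
        ],
    }, indent=2))
    paths["integration"] = p
    return paths


def _annotated_from_frame(frame: pd.DataFrame) -> list[ann.AnnotatedDMR]:
    from methnet.core import DMR

    out = []
    for r in frame.itertuples():
        feature = (ann.FeatureClass("intron", int(r.feature[6:]))
                   if str(r.feature).startswith("intron") else ann.FeatureClass(r.feature))
        assigned = tuple(str(r.assigned_genes).split(",")) if isinstance(r.assigned_genes, str) and r.assigned_genes else ()
        out.append(ann.AnnotatedDMR(
            dmr=DMR(chrom=r.chrom, start=int(r.start), end=int(r.end),
                    n_cpgs=int(r.n_cpgs), mean_diff=float(r.mean_diff),
                    direction=r.direction),
            feature=feature,
            tss_distance=None if pd.isna(r.tss_distance) else int(r.tss_distance),
            nearest_gene=None if pd.isna(r.nearest_gene) else str(r.nearest_gene),
            assigned_genes=assigned,
        ))
    return out


def stage_network(config: PipelineConfig, edges_tsv: Path, seeds_txt: Path,
                  genesets_gmt: Optional[Path], outdir: Path) -> dict[str, Path]:
    """DIAMOnD expansion, saturation cut, communities, over-representation."""
    import networkx as nx

    outdir.mkdir(parents=True, exist_ok=True)
    graph = nx.Graph()
    graph.add_edges_from(io.read_edge_list(edges_tsv))
    seeds = io.read_gene_list(seeds_txt)
    cfgn = config.network
    steps = net.diamond_expand(graph, seeds, max_iter=cfgn.max_iter)
    frame = net.steps_frame(steps)
    stop = net.saturation_stop(frame["seed_fraction"].tolist(), w=cfgn.window,
                               theta=cfgn.theta, big_theta=cfgn.big_theta)
    kept = [s.node for s in steps[: stop.stop]]
    module_nodes = sorted(set(seeds) & set(graph.nodes)) + kept
    module = graph.subgraph(module_nodes)
    comms = net.detect_communities(module)
    paths = {}
    p = outdir / "diamond_steps.tsv"; frame.to_csv(p, sep="\t", index=False)
    paths["steps"] = p
    p = outdir / "module_edges.tsv"
    io.write_edge_list(p, sorted(tuple(sorted(e)) for e in module.edges))
    paths["module_edges"] = p
    p = outdir / "communities.tsv"
    pd.DataFrame([(i + 1, n) for i, c in enumerate(comms) for n in sorted(c)],
                 columns=["community", "node"]).to_csv(p, sep="\t", index=False)
    paths["communities"] = p
    summary = {
        "n_module_nodes": module.number_of_nodes(),
        "n_module_edges": module.number_of_edges(),
        "stop_iteration": stop.stop,
        "had_steep_phase": stop.had_steep_phase,
        "final_seed_fraction": float(frame["seed_fraction"].iloc[-1]) if len(frame) else 0.0,
        "n_communities": len(comms),
    }
    if genesets_gmt is not None:
        sets = io.read_gmt(genesets_gmt)
        ora = net.geneset_overrepresentation(set(module_nodes), sets, set(graph.nodes))
        p = outdir / "overrepresentation.tsv"; ora.to_csv(p, sep="\t", index=False)
        paths["ora"] = p
    p = outdir / "network_summary.json"; p.write_text(json.dumps(summary, indent=2))
    paths["summary"] = p
    return paths


def run_all(config: PipelineConfig, outdir: Path) -> Path:
    """Run every stage on a synthetic dataset; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config)
    design = config.sim.design()

    t0 = time.perf_counter()
    sim_paths = stage_simulate(config, outdir / "simulate")
    manifest.record("simulate", sorted(sim_paths.values()), time.perf_counter() - t0)

    t0 = time.perf_counter()
    cm = stage_callmeth(config, sim_paths["reads"], sim_paths["reference"],
                        outdir / "callmeth")
    manifest.record("callmeth", sorted(cm.values()), time.perf_counter() - t0)

    t0 = time.perf_counter()
    reports = {s: sim_paths[f"cpg_{s}"] for s in design.samples}
    dm = stage_dmr(config, reports, design, outdir / "dmr")
    manifest.record("dmr", sorted(dm.values()), time.perf_counter() - t0)

    chrom_sizes = {
        (f"chr{i + 1:02d}" if config.sim.n_chromosomes > 9 else f"chr{i + 1}"):
            config.sim.chrom_length_bp
        for i in range(config.sim.n_chromosomes)
    }
    t0 = time.perf_counter()
    an = stage_annotate(
        config, dm["dmrs_tsv"], sim_paths["genes"],
        {"enhancer_like": sim_paths["track_enhancer"],
         "promoter_like": sim_paths["track_promoter"]},
        chrom_sizes, outdir / "annotate")
    manifest.record("annotate", sorted(an.values()), time.perf_counter() - t0)

    t0 = time.perf_counter()
    it = stage_integrate(config, sim_paths["expression"], an["annotated"],
                         sim_paths["genes"], outdir / "integrate")
    manifest.record("integrate", sorted(it.values()), time.perf_counter() - t0)

    t0 = time.perf_counter()
    nw = stage_network(config, sim_paths["edges"], sim_paths["seeds"],
                       sim_paths["genesets"], outdir / "network")
    manifest.record("network", sorted(nw.values()), time.perf_counter() - t0)

    return manifest.write()
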