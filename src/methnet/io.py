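"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: every interval format is 0-based half-open; integer counts
round-trip bit-exact; malformed lines raise :class:`ParseError` naming
the file and 1-based line number.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from methnet.core import CpGCountMatrix, DMR, GeneModel


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------- FASTA

def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------- CpG report TSV
# Columns: chrom, start, end, methylation_percent, count_M, count_U
# (bedGraph-style, one file per sample).

CPG_REPORT_COLUMNS = ["chrom", "start", "end", "meth_pct", "count_M", "count_U"]


def write_cpg_report(path, matrix: CpGCountMatrix, sample: str) -> None:
    j = matrix.samples.index(sample)
    m = matrix.meth[:, j]
    u = matrix.unmeth[:, j]
    cov = m + u
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(cov > 0, 100.0 * m / cov, 0.0)
    df = pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "start": matrix.pos,
            "end": matrix.pos + 2,
            "meth_pct": np.round(pct, 4),
            "count_M": m,
            "count_U": u,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_cpg_reports(paths: dict[str, os.PathLike | str]) -> CpGCountMatrix:
    """Read per-sample CpG reports and align them on the union of sites.

    Sites absent from one sample get zero counts there (uncovered).
    """
    per_sample = {}
    for sample, path in paths.items():
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 6:
                    raise ParseError(path, lineno, f"expected 6 columns, got {len(parts)}")
                try:
                    rows.append((parts[0], int(parts[1]), int(parts[4]), int(parts[5])))
                except ValueError as exc:
                    raise ParseError(path, lineno, str(exc)) from None
        per_sample[sample] = pd.DataFrame(rows, columns=["chrom", "pos", "count_M", "count_U"])

    samples = list(paths)
    keys = pd.concat(
        [df[["chrom", "pos"]] for df in per_sample.values()], ignore_index=True
    ).drop_duplicates().sort_values(["chrom", "pos"], kind="mergesort")
    keys = keys.reset_index(drop=True)
    n = len(keys)
    meth = np.zeros((n, len(samples)), dtype=np.int64)
    unmeth = np.zeros((n, len(samples)), dtype=np.int64)
    index = pd.MultiIndex.from_frame(keys)
    for j, sample in enumerate(samples):
        df = per_sample[sample]
        loc = index.get_indexer(pd.MultiIndex.from_frame(df[["chrom", "pos"]]))
        meth[loc, j] = df["count_M"].to_numpy()
        unmeth[loc, j] = df["count_U"].to_numpy()
    return CpGCountMatrix(
        chrom=keys["chrom"].to_numpy(dtype=object),
        pos=keys["pos"].to_numpy(dtype=np.int64),
        samples=samples,
        meth=meth,
        unmeth=unmeth,
    )


# ------------------------------------------------------------ BED6 / BED12

def write_bed6(path, intervals: Iterable[tuple], name_default: str = ".") -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED6."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else name_default
            score = iv[4] if len(iv) > 4 else 0
            strand = iv[5] if len(iv) > 5 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "BED needs >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            name = parts[3] if len(parts) > 3 else "."
            try:
                score = int(float(parts[4])) if len(parts) > 4 and parts[4] != "." else 0
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            strand = parts[5] if len(parts) > 5 else "."
            out.append((parts[0], start, end, name, score, strand))
    return out


def write_genes_bed12(path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, _ in g.exons) + ","
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def read_genes_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(path, lineno, "BED12 needs 12 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name, strand = parts[3], parts[5]
                n_exons = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            except (ValueError, IndexError) as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if len(sizes) != n_exons or len(offsets) != n_exons:
                raise ParseError(path, lineno, "exon count mismatch")
            exons = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def write_dmrs_bed(path, dmrs: Sequence[DMR]) -> None:
    """DMR BED6: name = direction, score = round(1000*|mean_diff|)."""
    write_bed6(
        path,
        [
            (d.chrom, d.start, d.end, d.direction, round(1000 * abs(d.mean_diff)), ".")
            for d in dmrs
        ],
    )


# -------------------------------------------------------- expression TSV

EXPRESSION_COLUMNS = ["gene_id", "mean_group1", "mean_group2", "log2fc", "pvalue"]


def write_expression_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, columns=EXPRESSION_COLUMNS)


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing expression columns: {missing}")
    return df


# -------------------------------------------------- graphs, gene sets, lists

def write_edge_list(path, edges: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(path, lineno, "edge list needs 2 columns")
            if lineno == 1 and parts[0] in ("node_a", "source", "from"):
                continue
            edges.append((parts[0], parts[1]))
    return edges


def write_gene_list(path, genes: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: set name, description, then member ids, tab-separated."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "GMT needs name, description, >=1 member")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(path, sets: dict[str, Iterable[str]], description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
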