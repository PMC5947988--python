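"""DIAMOnD-style disease-module expansion and interactome statistics.

Starting from seed proteins (mapped differentially expressed genes),
each iteration scores every node adjacent to the growing module by the
hypergeometric probability of having at least its observed number of
links into the module, adds the most significant node, and repeats.
The expansion is cut at the point where the first steep rise of the
incorporated-seed fraction starts to flatten; the resulting module is
partitioned into communities by greedy modularity maximisation and
characterised by gene-set over-representation against the full
interactome background.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def connectivity_significance(
    k: int, ks: int, n_nodes: int, s: int, exclude_candidate: bool = True
) -> float:
    """Hypergeometric upper-tail p for ks-of-k links into an s-node module.

    The population is every node except the candidate (N-1 by default),
    successes are the s current module members, draws the candidate's k
    neighbours: p = sum_{i>=ks} C(s,i) C(N-1-s, k-i) / C(N-1, k).
    """
    pop = n_nodes - 1 if exclude_candidate else n_nodes
    if k > pop:
        raise ValueError(f"degree {k} exceeds population {pop}")
    if not 0 <= ks <= min(k, s):
        raise ValueError(f"ks={ks} outside [0, min(k={k}, s={s})]")
    if s >= n_nodes:
        raise ValueError("module size must be smaller than the interactome")
    return float(stats.hypergeom.sf(ks - 1, pop, s, k))


@dataclass(frozen=True)
class DiamondStep:
    iteration: int  # 1-based
    node: str
    degree: int
    links_to_module: int
    p: float
    module_size_before: int
    seed_fraction: float  # incorporated-seed fraction after this addition


def incorporated_seed_fraction(
    graph: nx.Graph, seeds: Sequence[str], module_nodes: set[str]
) -> float:
    """Fraction of seeds with at least one edge into the module.

    The module includes the seeds themselves, so a seed adjacent to
    another seed counts as incorporated from iteration 0.
    """
    seeds = list(seeds)
    if not seeds:
        return 0.0
    linked = sum(
        1 for s in seeds if any(nb in module_nodes for nb in graph.neighbors(s))
    )
    return linked / len(seeds)


def diamond_expand(
    graph: nx.Graph,
    seeds: Sequence[str],
    max_iter: int = 200,
    exclude_candidate: bool = True,
    seeds_only_significance: bool = False,
) -> list[DiamondStep]:
    """Iterative connectivity-significance expansion from the seed set.

    Each iteration scores every non-module node with >= 1 module link
    and adds the minimum-p node (ties broken by node id).  Added nodes
    join the module for subsequent significance computations unless
    ``seeds_only_significance``.
    """
    seeds = sorted(set(seeds) & set(graph.nodes))
    if not seeds:
        raise ValueError("no seed maps into the interactome")
    if not any(graph.degree(s) > 0 for s in seeds):
        raise ValueError("no seed has any edge")
    n_nodes = graph.number_of_nodes()
    module = set(seeds)
    scoring_set = set(seeds)
    # candidate -> links into the scoring set, maintained incrementally
    links = {}
    for m in scoring_set:
        for nb in graph.neighbors(m):
            if nb not in module:
                links[nb] = links.get(nb, 0) + 1

    @lru_cache(maxsize=200_000)
    def pval(k: int, ks: int, s: int) -> float:
        return connectivity_significance(k, ks, n_nodes, s, exclude_candidate)

    steps: list[DiamondStep] = []
    for it in range(1, max_iter + 1):
        if not links:
            break
        s = len(scoring_set)
        best = min(
            ((pval(graph.degree(c), ks, s), c) for c, ks in links.items()),
            key=lambda x: (x[0], x[1]),
        )
        p, node = best
        ks = links.pop(node)
        module.add(node)
        if not seeds_only_significance:
            scoring_set.add(node)
            for nb in graph.neighbors(node):
                if nb not in module:
                    links[nb] = links.get(nb, 0) + 1
        steps.append(DiamondStep(
            iteration=it, node=node, degree=graph.degree(node),
            links_to_module=ks, p=p, module_size_before=len(module) - 1,
            seed_fraction=incorporated_seed_fraction(graph, seeds, module),
        ))
    return steps


def steps_frame(steps: Sequence[DiamondStep]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "iteration": [s.iteration for s in steps],
            "node": [s.node for s in steps],
            "degree": [s.degree for s in steps],
            "links_to_module": [s.links_to_module for s in steps],
            "p": [s.p for s in steps],
            "module_size_before": [s.module_size_before for s in steps],
            "seed_fraction": [s.seed_fraction for s in steps],
        }
    )


@dataclass(frozen=True)
class SaturationStop:
    stop: int  # 1-based iteration index to cut at
    had_steep_phase: bool
    flagged: bool = False  # True when the rule could not be evaluated


def saturation_stop(
    fractions: Sequence[float], w: int = 10, theta: float = 0.001, big_theta: float = 0.01
) -> SaturationStop:
    """First flattening after the first steep rise of the seed curve.

    Windowed slope slope_i = (f_i - f_{i-w}) / w for i > w (1-based);
    the stop is the smallest i whose slope drops below ``theta`` after
    some earlier slope reached ``big_theta``.  If the curve never
    flattens (or never steepens) all iterations are kept.
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    f = np.asarray(fractions, dtype=float)
    T = len(f)
    if T < w + 1:
        return SaturationStop(stop=T, had_steep_phase=False, flagged=True)
    slopes = (f[w:] - f[:-w]) / w  # slope at 1-based iterations w+1 .. T
    steep_seen = False
    for j, slope in enumerate(slopes):
        if slope >= big_theta:
            steep_seen = True
        elif steep_seen and slope < theta:
            return SaturationStop(stop=j + w + 1, had_steep_phase=True)
    return SaturationStop(stop=T, had_steep_phase=steep_seen)


def detect_communities(graph: nx.Graph) -> list[set[str]]:
    """Greedy modularity communities, canonically ordered.

    The input is rebuilt with sorted nodes and edges so the partition
    is independent of insertion order; communities come back largest
    first, ties by smallest member id.  Isolated nodes form singletons.
    """
    canon = nx.Graph()
    canon.add_nodes_from(sorted(graph.nodes))
    canon.add_edges_from(sorted(tuple(sorted(e)) for e in graph.edges))
    if canon.number_of_edges() == 0:
        return [{n} for n in sorted(canon.nodes)]
    comms = nx.algorithms.community.greedy_modularity_communities(canon)
    return sorted((set(c) for c in comms), key=lambda c: (-len(c), min(c)))


def geneset_overrepresentation(
    query: set[str],
    annotation_sets: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query in annotation sets.

    p = upper tail of drawing >= overlap members of each set when
    |query| nodes are drawn from the background; Benjamini-Hochberg
    q-values adjust across sets.
    """
    if not query <= background:
        raise ValueError(f"query not contained in background: "
                         f"{sorted(query - background)[:5]}")
    rows = []
    for name in sorted(annotation_sets):
        members = annotation_sets[name] & background
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, len(background), len(members), len(query)))
        rows.append({"set": name, "n_set": len(members), "n_overlap": overlap, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df
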