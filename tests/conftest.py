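import numpy as np
import pytest

from methnet.core import GroupDesign
from methnet.sim import (
    SimConfig,
    simulate_gene_models,
    simulate_methylome,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(rng_seed=0)


@pytest.fixture(scope="session")
def design(default_config) -> GroupDesign:
    return default_config.design()


@pytest.fixture(scope="session")
def genes(default_config):
    return simulate_gene_models(default_config)


@pytest.fixture(scope="session")
def methylome(default_config, genes):
    """Default planted methylome: (CpGCountMatrix, truth records)."""
    return simulate_methylome(default_config, genes)


@pytest.fixture(scope="session")
def null_methylome():
    """No planted effect: pure baseline noise, empty truth."""
    cfg = SimConfig(rng_seed=0, n_planted_dmrs=0, n_cluster_genes=0, planted_effect=0.0)
    return simulate_methylome(cfg, simulate_gene_models(cfg))


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


@pytest.fixture(scope="session")
def jaccard():
    return interval_jaccard


def brute_force_dmrs(chrom, diff, is_dmc, min_consecutive=3, min_diff=0.10,
                     require_same_direction=True):
    """Independent maximal-window enumeration of the DMR definition.

    Enumerates every window of the site list, checks membership
    conditions for all members, maximality at both ends, and the
    length/mean-difference thresholds.  Deliberately quadratic.
    """
    n = len(diff)
    chrom = list(chrom)
    diff = list(diff)
    is_dmc = list(is_dmc)

    def chain(a, b):
        """Adjacent sites a, b=a+1 can belong to one run."""
        if not (is_dmc[a] and is_dmc[b]) or chrom[a] != chrom[b]:
            return False
        if require_same_direction and np.sign(diff[a]) != np.sign(diff[b]):
            return False
        return True

    out = []
    for i in range(n):
        if not is_dmc[i]:
            continue
        for j in range(i, n):
            if not is_dmc[j] or (j > i and not chain(j - 1, j)):
                break
            left_maximal = i == 0 or not chain(i - 1, i)
            right_maximal = j == n - 1 or not chain(j, j + 1)
            if not (left_maximal and right_maximal):
                continue
            if j - i + 1 < min_consecutive:
                continue
            mean = float(np.mean(diff[i : j + 1]))
            if abs(mean) >= min_diff:
                out.append((i, j, mean))
    return out
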