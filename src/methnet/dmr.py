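"""Consecutive-CpG differential methylation calling, without smoothing.

The model: keep CpGs with coverage >= 8x in at least two of the three
samples of each group; test each site with a two-sample t-test on the
per-sample methylation fractions; a differentially methylated cytosine
(DMC) has p < 0.05 and an absolute group difference >= 10%; a DMR is a
maximal run of >= 3 DMCs that are consecutive in the coverage-filtered
site list, share a direction, and keep an absolute mean difference
>= 10%.  No multiple-testing correction is applied to the per-CpG
p-values — the region-level run requirement is the specificity device.

Direction is group2 (adult) relative to group1 (infant): ``hypo``
means loss of methylation in group2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from methnet.core import CpGCountMatrix, DMR, GroupDesign


@dataclass(frozen=True)
class DmrCallConfig:
    min_coverage: int = 8
    min_samples_per_group: int = 2
    alpha: float = 0.05
    min_diff: float = 0.10
    min_consecutive: int = 3
    require_same_direction: bool = True
    max_gap_bp: Optional[int] = None  # cap on genomic gap between consecutive members
    test_variant: str = "student"  # 'student' (pooled variance) or 'welch'

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.min_diff <= 1:
            raise ValueError("min_diff must be in (0, 1]")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")
        if self.test_variant not in ("welch", "student"):
            raise ValueError("test_variant must be 'welch' or 'student'")


def filter_coverage(
    matrix: CpGCountMatrix, design: GroupDesign, cfg: DmrCallConfig = DmrCallConfig()
) -> CpGCountMatrix:
    """Keep sites where each group has enough adequately covered samples.

    A site survives when >= ``min_samples_per_group`` samples of *each*
    group reach ``min_coverage``; site order is preserved.
    """
    cov = matrix.coverage()
    keep = np.ones(matrix.n_sites, dtype=bool)
    for group in (design.group1, design.group2):
        cols = matrix.sample_index(group)
        keep &= (cov[:, cols] >= cfg.min_coverage).sum(axis=1) >= cfg.min_samples_per_group
    return matrix.subset(keep)


def _group_stats(frac: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """nan-aware per-site mean, variance (ddof=1) and count for one group."""
    n = np.sum(~np.isnan(frac), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(frac, axis=1)
        var = np.where(n > 1, np.nanvar(frac, axis=1, ddof=1), np.nan)
    return mean, var, n


def _t_test(
    f1: np.ndarray, f2: np.ndarray, variant: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided two-sample t-test on fraction matrices.

    Returns (t, p, m1, m2).  Samples with zero coverage (NaN fraction)
    are excluded site-wise.  Degenerate sites where both groups have
    zero variance get the documented convention: equal means -> p = 1,
    unequal means -> p = 0.
    """
    m1, v1, n1 = _group_stats(f1)
    m2, v2, n2 = _group_stats(f2)
    if variant == "welch":
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = (n1 + n2 - 2).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # exact-tie groups produce variance at float-noise level (~1e-34);
    # any real fraction difference yields se^2 orders of magnitude larger
    zero_se = se2 < 1e-20
    equal = np.isclose(m1, m2)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se, np.where(equal, 0.0, np.sign(m1 - m2) * np.inf), t)
    p = np.where(zero_se, np.where(equal, 1.0, 0.0), p)
    return t, p, m1, m2


def call_dmcs(
    matrix: CpGCountMatrix,
    design: GroupDesign,
    cfg: DmrCallConfig = DmrCallConfig(),
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Coverage-filter, test every site and flag DMCs.

    Returns the filtered sites in order with columns chrom, pos, m1,
    m2, diff (= m2 - m1), t, p, significant (p < alpha), is_dmc
    (significant and |diff| >= min_diff).
    """
    filtered = matrix if prefiltered else filter_coverage(matrix, design, cfg)
    frac = filtered.fractions()
    f1 = frac[:, filtered.sample_index(design.group1)]
    f2 = frac[:, filtered.sample_index(design.group2)]
    t, p, m1, m2 = _t_test(f1, f2, cfg.test_variant)
    diff = m2 - m1
    significant = p < cfg.alpha
    return pd.DataFrame(
        {
            "chrom": filtered.chrom,
            "pos": filtered.pos,
            "m1": m1,
            "m2": m2,
            "diff": diff,
            "t": t,
            "p": p,
            "significant": significant,
            "is_dmc": significant & (np.abs(diff) >= cfg.min_diff),
        }
    )


def test_site(
    meth: Sequence[int],
    unmeth: Sequence[int],
    design: GroupDesign,
    cfg: DmrCallConfig = DmrCallConfig(),
) -> pd.Series:
    """Single-site convenience wrapper; counts ordered as design.samples."""
    m = np.asarray(meth, dtype=np.int64).reshape(1, -1)
    u = np.asarray(unmeth, dtype=np.int64).reshape(1, -1)
    matrix = CpGCountMatrix(
        chrom=np.array(["chr1"], dtype=object), pos=np.array([0]),
        samples=list(design.samples), meth=m, unmeth=u,
    )
    return call_dmcs(matrix, design, cfg, prefiltered=True).iloc[0]


def call_dmrs(dmcs: pd.DataFrame, cfg: DmrCallConfig = DmrCallConfig()) -> list[DMR]:
    """Maximal runs of consecutive DMCs in the filtered site list.

    "Consecutive" means adjacent rows of the filtered table on the same
    chromosome (optionally within ``max_gap_bp``); when
    ``require_same_direction`` the run breaks on a sign change.  A run
    is kept when it has >= ``min_consecutive`` members and the absolute
    mean of member diffs reaches ``min_diff``.
    """
    chrom = dmcs["chrom"].to_numpy()
    pos = dmcs["pos"].to_numpy()
    if len(dmcs):
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (pos[1:] <= pos[:-1])):
            raise ValueError("dmcs must be sorted by (chrom, position)")
        blocks = pd.unique(chrom)
        if len(blocks) != len(set(blocks)) or np.sum(~same) != len(blocks) - 1:
            raise ValueError("dmcs must group each chromosome contiguously")
    diff = dmcs["diff"].to_numpy()
    is_dmc = dmcs["is_dmc"].to_numpy()

    out: list[DMR] = []
    run: list[int] = []

    def close() -> None:
        if len(run) >= cfg.min_consecutive:
            d = float(np.mean(diff[run]))
            if abs(d) >= cfg.min_diff:
                out.append(DMR(
                    chrom=str(chrom[run[0]]), start=int(pos[run[0]]),
                    end=int(pos[run[-1]]) + 2, n_cpgs=len(run), mean_diff=d,
                    direction="hypo" if d < 0 else "hyper",
                    site_index=tuple(run),
                ))
        run.clear()

    for i in range(len(dmcs)):
        if not is_dmc[i]:
            close()
            continue
        if run:
            breaks = chrom[i] != chrom[run[-1]]
            if cfg.max_gap_bp is not None and not breaks:
                breaks = pos[i] - pos[run[-1]] > cfg.max_gap_bp
            if cfg.require_same_direction and not breaks:
                breaks = np.sign(diff[i]) != np.sign(diff[run[-1]])
            if breaks:
                close()
        run.append(i)
    close()
    return out


def summarize_dmrs(dmrs: Sequence[DMR], thresholds: Sequence[float]) -> pd.DataFrame:
    """Gain/loss counts and fractions at each |mean_diff| threshold.

    Fractions are relative to the DMRs counted at that threshold, the
    way direction splits are usually quoted (e.g. "54% gain / 46% loss
    at a 10% threshold").
    """
    rows = []
    diffs = np.array([d.mean_diff for d in dmrs])
    for t in thresholds:
        gain = int(np.sum(diffs >= t))
        loss = int(np.sum(diffs <= -t))
        total = gain + loss
        rows.append({
            "threshold": t, "n_gain": gain, "n_loss": loss, "n_total": total,
            "gain_fraction": gain / total if total else np.nan,
            "loss_fraction": loss / total if total else np.nan,
        })
    return pd.DataFrame(rows)


def global_cpg_distribution(
    matrix: CpGCountMatrix,
    design: GroupDesign,
    bins: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    high_bin: float = 0.8,
) -> dict:
    """Per-group histogram of per-CpG mean methylation, plus a
    two-proportion z-test on the fraction of CpGs above ``high_bin``
    (the ">80% methylated" compartment whose expansion marks global
    methylation gain)."""
    from statsmodels.stats.proportion import proportions_ztest

    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    frac = matrix.fractions()
    result: dict = {"bins": list(bins)}
    high_counts = []
    n_sites = []
    for label, group in (("group1", design.group1), ("group2", design.group2)):
        with np.errstate(invalid="ignore"):
            means = np.nanmean(frac[:, matrix.sample_index(group)], axis=1)
        means = means[~np.isnan(means)]
        hist, _ = np.histogram(means, bins=bins)
        result[label] = {
            "histogram": (hist / len(means)).tolist(),
            "fraction_high": float(np.mean(means > high_bin)),
            "n": int(len(means)),
        }
        high_counts.append(int(np.sum(means > high_bin)))
        n_sites.append(len(means))
    if high_counts[0] in (0, n_sites[0]) and high_counts[1] in (0, n_sites[1]) and (
        high_counts[0] / n_sites[0] == high_counts[1] / n_sites[1]
    ):
        stat, p = 0.0, 1.0
    else:
        stat, p = proportions_ztest(high_counts, n_sites)
    result["high_bin_test"] = {
        "statistic": float(stat), "p": float(p),
        "difference": high_counts[1] / n_sites[1] - high_counts[0] / n_sites[0],
    }
    return result
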