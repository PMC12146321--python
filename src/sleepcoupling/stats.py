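"""Stage-wise statistical treatment of the coupling records.

MIC values are pooled per (pair, band_x, band_y) cell and compared across the
four grouped sleep stages non-parametrically: Kolmogorov-Smirnov normality
screening (Lilliefors-corrected by default), a Kruskal-Wallis omnibus test
with tie correction, and Dunn's pairwise z-tests with Bonferroni adjustment
over the six stage pairs.  Summaries are median (IQR), the appropriate
convention for skewed MIC distributions; the heart-gut vs brain-gut contrast
pools all HGC and BGC records within each stage and applies a Mann-Whitney
rank test, Bonferroni-corrected over the four stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ks_normality",
    "kruskal_wallis",
    "pairwise_dunn_bonferroni",
    "significance_glyph",
    "summarize",
    "contrast_hgc_bgc",
    "StageComparison",
]

STAGE_ORDER = ("Awake", "LS", "DS", "REM")


@dataclass
class StageComparison:
    """Per-cell stage comparison: medians, IQRs, omnibus and pairwise tests."""

    pair: str
    band_x: str
    band_y: str
    medians: Dict[str, float]
    iqrs: Dict[str, float]
    kw_h: float
    kw_p: float
    pairwise_p: Dict[Tuple[str, str], float]
    glyphs: Dict[Tuple[str, str], str] = field(default_factory=dict)


def ks_normality(sample, alpha: float = 0.05, corrected: bool = True) -> Tuple[float, str]:
    """One-sample normality screen; returns (p, 'normal'|'non-normal').

    Uses the Lilliefors-corrected Kolmogorov-Smirnov test against a normal
    with sample-estimated mean and SD (the uncorrected K-S is available via
    ``corrected=False``).  A constant sample is reported non-normal
    (degenerate); fewer than 5 observations raise.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0:
        return 0.0, "non-normal"
    if corrected:
        _, p = lilliefors(x, dist="norm")
    else:
        _, p = sstats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(p), ("normal" if p >= alpha else "non-normal")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p over k groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one observation")
    if sum(a.size for a in arrays) < 5:
        raise ValueError("need at least 5 observations in total")
    if np.ptp(np.concatenate(arrays)) == 0:  # all observations identical
        return 0.0, 1.0
    h, p = sstats.kruskal(*arrays)
    return float(h), float(p)


def _pooled_rank_stats(arrays: List[np.ndarray]) -> Tuple[List[float], float, int]:
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sstats.rankdata(pooled)
    mean_ranks = []
    i = 0
    for a in arrays:
        mean_ranks.append(float(ranks[i : i + a.size].mean()))
        i += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    return mean_ranks, tie_term, n


def pairwise_dunn_bonferroni(
    groups: Sequence[Sequence[float]]
) -> Dict[Tuple[int, int], float]:
    """Dunn's z-tests on pooled ranks, Bonferroni-adjusted over all pairs.

    Adjusted p values are ``min(1, raw * n_pairs)``; identical groups give 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    mean_ranks, tie_term, n = _pooled_rank_stats(arrays)
    var_base = n * (n + 1) / 12.0 - tie_term
    pairs = list(combinations(range(len(arrays)), 2))
    out: Dict[Tuple[int, int], float] = {}
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        if se == 0:
            out[(i, j)] = 1.0
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw = 2.0 * sstats.norm.sf(abs(z))
        out[(i, j)] = float(min(1.0, raw * len(pairs)))
    return out


def significance_glyph(p: float) -> str:
    """The figure-legend convention: ns / * / ** / *** at 0.05/0.01/0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Stage comparison per (pair, band_x, band_y) cell.

    Returns a tidy frame with per-stage median/IQR, the Kruskal-Wallis H and
    p, and Bonferroni-adjusted Dunn p + glyph for each of the six stage
    pairs.  Cells with records in fewer than two stages are omitted.
    """
    rows = []
    for (pair, bx, by), cell in records.groupby(["pair", "band_x", "band_y"], sort=False):
        groups = {
            s: cell.loc[cell["stage"] == s, "mic"].to_numpy()
            for s in STAGE_ORDER
            if (cell["stage"] == s).any()
        }
        if len(groups) < 2:
            continue
        row = {"pair": pair, "band_x": bx, "band_y": by}
        for s in STAGE_ORDER:
            g = groups.get(s, np.array([]))
            row[f"median_{s}"] = float(np.median(g)) if g.size else np.nan
            row[f"iqr_{s}"] = (
                float(np.percentile(g, 75) - np.percentile(g, 25)) if g.size else np.nan
            )
        names = list(groups)
        try:
            h, p = kruskal_wallis([groups[s] for s in names])
        except ValueError:  # cell too small for the omnibus test
            h, p = np.nan, np.nan
        row["kw_h"], row["kw_p"] = h, p
        adj = pairwise_dunn_bonferroni([groups[s] for s in names])
        for (i, j), pv in adj.items():
            key = f"p_{names[i]}_vs_{names[j]}"
            row[key] = pv
            row[f"sig_{names[i]}_vs_{names[j]}"] = significance_glyph(pv)
        rows.append(row)
    return pd.DataFrame(rows)


def contrast_hgc_bgc(records: pd.DataFrame) -> pd.DataFrame:
    """Per-stage heart-gut vs brain-gut contrast (Mann-Whitney, Bonferroni x4).

    Pools every HGC and every BGC MIC within each stage; reports medians, the
    one-sided direction (HGC > BGC when the HGC median is larger) with a
    two-sided rank-test p adjusted over the four stages.
    """
    rows = []
    stages = [s for s in STAGE_ORDER if (records["stage"] == s).any()]
    for s in stages:
        hgc = records.loc[(records["pair"] == "HGC") & (records["stage"] == s), "mic"].to_numpy()
        bgc = records.loc[(records["pair"] == "BGC") & (records["stage"] == s), "mic"].to_numpy()
        if hgc.size == 0 or bgc.size == 0:
            continue
        u, p = sstats.mannwhitneyu(hgc, bgc, alternative="two-sided")
        adj = float(min(1.0, p * len(stages)))
        rows.append(
            {
                "stage": s,
                "median_hgc": float(np.median(hgc)),
                "median_bgc": float(np.median(bgc)),
                "hgc_greater": bool(np.median(hgc) > np.median(bgc)),
                "u": float(u),
                "p_adj": adj,
                "sig": significance_glyph(adj),
            }
        )
    return pd.DataFrame(rows)
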