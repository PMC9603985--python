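"""Cohort comparisons of taxon abundances with FDR control.

Two-group tests are two-sided Wilcoxon rank-sum (exact null distribution
for small tie-free samples, normal approximation with continuity
correction otherwise); three-group tests are tie-corrected
Kruskal-Wallis.  p-values are adjusted per screen family with
Benjamini-Hochberg and flagged at adjusted p < 0.05.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceMatrix, filter_high_abundance
from .io_core import Manifest, logger

ALPHA = 0.05


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (U statistic for x, p).

    Exact p when both groups have <= 25 tie-free values, else the normal
    approximation with continuity correction.  Identical pooled values
    give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square (k-1 df) p-value."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(p: Sequence[float], method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    if method != "BH":
        raise ValueError(f"unsupported method {method!r}")
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def screen_features(abund: AbundanceMatrix | pd.DataFrame, manifest: Manifest,
                    habitat: str, level: str = "votu",
                    mean_threshold: float = 1e-4) -> pd.DataFrame:
    """Differential screen of one habitat's features across cohorts.

    Features passing the mean-abundance filter are tested with
    Kruskal-Wallis across all cohorts present and pairwise Wilcoxon for
    each cohort pair; each test family (the KW screen, and each pairwise
    screen) is BH-adjusted separately.  The overall ``significant`` flag
    is the KW adjusted p < 0.05.

    Returns a tidy frame: feature, level, test, comparison, statistic, p,
    p_adj, per-cohort means, direction, significant.
    """
    values = abund.values if isinstance(abund, AbundanceMatrix) else abund
    sub = manifest.subset(habitat=habitat)
    ids = [s for s in sub.sample_ids if s in values.index]
    cohort = sub.cohorts(ids)
    # canonical cohort order so pairwise comparison names are predictable
    from .io_core import COHORTS

    present = sorted(cohort.unique(),
                     key=lambda c: (COHORTS.index(c) if c in COHORTS else 99, c))
    if len(present) < 2:
        raise ValueError(f"habitat {habitat!r} has fewer than 2 cohorts")
    data = values.loc[ids]
    kept = filter_high_abundance(data, mean_threshold)
    if not len(kept):
        logger.warning("no features pass the %.2g mean-abundance filter", mean_threshold)
        return pd.DataFrame(columns=["feature", "level", "test", "comparison",
                                     "statistic", "p", "p_adj", "direction",
                                     "significant"])
    data = data[kept]
    by_cohort = {c: data.loc[cohort[cohort == c].index] for c in present}
    means = pd.DataFrame({c: by_cohort[c].mean(axis=0) for c in present})
    direction = means.idxmax(axis=1)

    blocks = []
    stats_p = [kruskal_wallis([by_cohort[c][f] for c in present]) for f in kept]
    blocks.append(pd.DataFrame({
        "feature": kept, "test": "kruskal_wallis", "comparison": "all",
        "statistic": [s for s, _ in stats_p], "p": [p for _, p in stats_p]}))
    for a, b in combinations(present, 2):
        stats_p = [wilcoxon_rank_sum(by_cohort[a][f], by_cohort[b][f]) for f in kept]
        blocks.append(pd.DataFrame({
            "feature": kept, "test": "wilcoxon", "comparison": f"{a}_vs_{b}",
            "statistic": [s for s, _ in stats_p], "p": [p for _, p in stats_p]}))
    out = []
    for block in blocks:
        block = block.copy()
        block["p_adj"] = adjust_pvalues(block["p"].to_numpy())
        out.append(block)
    result = pd.concat(out, ignore_index=True)
    result.insert(1, "level", level)
    for c in present:
        result[f"mean_{c}"] = result["feature"].map(means[c])
    result["direction"] = result["feature"].map(direction)
    result["significant"] = result["p_adj"] < ALPHA
    return result
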