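"""FDR-controlled Spearman co-abundance and clinical-index networks.

Virus-bacterium networks are built within a (cohort, habitat) stratum over
all feature pairs passing a mean-abundance filter; the taxon-clinical
network pools cohorts within a habitat.  Each network's p-values form one
Benjamini-Hochberg family; edges are retained at adjusted p < 0.05 and
signed by the correlation.  Covariate effect sizes are single-term
PERMANOVAs (adonis-style: numeric covariates enter as regression terms on
the distance matrix), BH-adjusted across the covariates of a panel.
"""

from __future__ import annotations

from itertools import permutations as _iperm
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceMatrix, filter_high_abundance
from .differential import adjust_pvalues
from .diversity import bray_curtis, permanova
from .io_core import Manifest, logger

ALPHA = 0.05

EDGE_COLUMNS = ["source", "target", "rho", "p", "p_adj", "sign", "cohort", "habitat"]


def spearman(x: Sequence[float], y: Sequence[float],
             exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Pairs with a missing value are dropped.  ``exact=True`` (n <= 8)
    computes the permutation-exact two-sided p instead.  Constant input
    raises, since rho is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman rho undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    if exact:
        if x.size > 8:
            raise ValueError("exact permutation p limited to n <= 8")
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        obs = abs(rho)
        count = total = 0
        for perm in _iperm(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        return rho, count / total
    return rho, float(stats.spearmanr(x, y).pvalue)


def _pairwise_spearman(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """All cross pairs (left col, right col): rho and t-approx p."""
    n = left.shape[0]
    rl = left.rank(axis=0).to_numpy()
    rr = right.rank(axis=0).to_numpy()
    rl = (rl - rl.mean(axis=0)) / rl.std(axis=0, ddof=0)
    rr = (rr - rr.mean(axis=0)) / rr.std(axis=0, ddof=0)
    rho = rl.T @ rr / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    rows = []
    for i, a in enumerate(left.columns):
        for j, b in enumerate(right.columns):
            rows.append((a, b, float(rho[i, j]), float(p[i, j])))
    return pd.DataFrame(rows, columns=["source", "target", "rho", "p"])


def build_network(abund_v: AbundanceMatrix | pd.DataFrame,
                  abund_b: AbundanceMatrix | pd.DataFrame,
                  manifest: Manifest, cohort: str, habitat: str,
                  mean_threshold: float = 5e-4,
                  min_samples: int = 5) -> pd.DataFrame:
    """Virus-bacterium co-abundance network for one (cohort, habitat) stratum.

    Feature filters use the mean abundance over ALL samples of the matrix
    (the habitat-wide high-abundance sets); correlations use the stratum's
    samples only.  One BH family across all tested pairs; edges kept at
    adjusted p < 0.05.  Constant features within the stratum are excluded
    with a warning.
    """
    values_v = abund_v.values if isinstance(abund_v, AbundanceMatrix) else abund_v
    values_b = abund_b.values if isinstance(abund_b, AbundanceMatrix) else abund_b
    stratum = manifest.subset(habitat=habitat, cohort=cohort)
    ids = [s for s in stratum.sample_ids
           if s in values_v.index and s in values_b.index]
    if len(ids) < min_samples:
        raise ValueError(
            f"stratum (cohort={cohort}, habitat={habitat}) has only "
            f"{len(ids)} samples (< {min_samples})")
    keep_v = filter_high_abundance(values_v, mean_threshold)
    keep_b = filter_high_abundance(values_b, mean_threshold)
    sub_v = values_v.loc[ids, keep_v]
    sub_b = values_b.loc[ids, keep_b]
    const_v = sub_v.columns[sub_v.nunique() <= 1]
    const_b = sub_b.columns[sub_b.nunique() <= 1]
    if len(const_v) or len(const_b):
        logger.warning("excluding constant features in stratum (%s, %s): %d virus, "
                       "%d bacteria", cohort, habitat, len(const_v), len(const_b))
        sub_v = sub_v.drop(columns=const_v)
        sub_b = sub_b.drop(columns=const_b)
    if sub_v.shape[1] == 0 or sub_b.shape[1] == 0:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    edges = _pairwise_spearman(sub_v, sub_b)
    edges["p_adj"] = adjust_pvalues(edges["p"].to_numpy())
    edges = edges[edges["p_adj"] < ALPHA].copy()
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    edges["cohort"] = cohort
    edges["habitat"] = habitat
    return edges.reset_index(drop=True)[EDGE_COLUMNS]


def compare_edge_sets(networks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Shared/unique edge counts across cohorts (edges keyed by unordered pair).

    Returns one row per non-empty cohort combination with the count of
    edges present in exactly that set of cohorts.
    """
    keys = {name: {frozenset((r.source, r.target)) for r in net.itertuples()}
            for name, net in networks.items()}
    names = sorted(keys)
    all_edges = set().union(*keys.values()) if keys else set()
    combos: dict[tuple[str, ...], int] = {}
    for edge in all_edges:
        member = tuple(n for n in names if edge in keys[n])
        combos[member] = combos.get(member, 0) + 1
    rows = [{"cohorts": "&".join(member), "n_edges": count}
            for member, count in sorted(combos.items())]
    return pd.DataFrame(rows, columns=["cohorts", "n_edges"])


def clinical_index_network(abund: AbundanceMatrix | pd.DataFrame,
                           indices: pd.DataFrame, manifest: Manifest,
                           habitat: Optional[str] = None,
                           mean_threshold: float = 5e-4) -> pd.DataFrame:
    """Taxon x clinical-index Spearman network (cohorts pooled).

    Missing index values are dropped pairwise; indices with fewer than 3
    non-missing values are skipped with a warning.  One BH family over all
    tested (taxon, index) pairs; edges kept at adjusted p < 0.05.
    """
    values = abund.values if isinstance(abund, AbundanceMatrix) else abund
    sub = manifest if habitat is None else manifest.subset(habitat=habitat)
    ids = [s for s in sub.sample_ids if s in values.index and s in indices.index]
    keep = filter_high_abundance(values, mean_threshold)
    data = values.loc[ids, keep]
    rows = []
    for index_name in indices.columns:
        vec = indices.loc[ids, index_name].astype(float)
        if vec.notna().sum() < 3:
            logger.warning("index %s has < 3 non-missing values; skipped", index_name)
            continue
        for taxon in data.columns:
            x = data[taxon].to_numpy(dtype=float)
            y = vec.to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3 or np.all(x[mask] == x[mask][0]) \
                    or np.all(y[mask] == y[mask][0]):
                continue
            rho, p = spearman(x[mask], y[mask])
            rows.append((taxon, index_name, rho, p))
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p"])
    if not len(edges):
        return pd.DataFrame(columns=EDGE_COLUMNS)
    edges["p_adj"] = adjust_pvalues(edges["p"].to_numpy())
    edges = edges[edges["p_adj"] < ALPHA].copy()
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    edges["cohort"] = "all"
    edges["habitat"] = habitat or "all"
    return edges.reset_index(drop=True)[EDGE_COLUMNS]


def covariate_effect_sizes(abund: AbundanceMatrix | pd.DataFrame,
                           manifest: Manifest, covariates: Sequence[str],
                           habitat: str, level: str = "votu",
                           n_perm: int = 999, rng=0) -> pd.DataFrame:
    """Adonis-style effect size of each covariate on community composition.

    Per covariate: samples of the habitat with a non-missing value enter a
    single-term PERMANOVA on Bray-Curtis distances (categorical covariates
    as indicators, numeric ones as regression terms).  Adjusted R-squared
    is the effect size; p-values are BH-adjusted across the panel's
    covariates.  Constant covariates are skipped with a warning.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values = abund.values if isinstance(abund, AbundanceMatrix) else abund
    sub = manifest.subset(habitat=habitat)
    rows = []
    for name in covariates:
        if name == "cohort":
            vec = sub.cohorts(sub.sample_ids)
        else:
            vec = sub.covariate(name)
        vec = vec[vec.index.isin(values.index)]
        if vec.dtype.kind in "ifu":
            vec = vec.dropna()
        if vec.nunique() < 2:
            logger.warning("covariate %s constant in habitat %s; skipped", name, habitat)
            continue
        ids = list(vec.index)
        dist = bray_curtis(values.loc[ids])
        res = permanova(dist, vec.to_numpy(), n_perm=n_perm, rng=rng)
        rows.append({"covariate": name, "habitat": habitat, "feature_level": level,
                     "r2": res.r2, "r2_adjusted": res.r2_adjusted,
                     "pseudo_f": res.pseudo_f, "p": res.p, "n": len(ids)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = adjust_pvalues(out["p"].to_numpy())
    return out
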