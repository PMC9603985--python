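"""Rarefaction, alpha/beta diversity, ordination, and PERMANOVA.

Alpha diversity (observed features, Shannon in nats) is estimated on reads
rarefied without replacement to a common depth.  Beta diversity is
Bray-Curtis on relative abundances.  Ordination covers PCA on standardized
abundances and distance-based redundancy analysis (PCoA of the distance
matrix followed by redundancy analysis on group indicators, negative
eigenvalue axes dropped).  PERMANOVA partitions the Gower-centered squared
distance matrix by an arbitrary design (categorical groups or numeric
covariates) with permutation p-values using the +1 convention; effect
sizes are reported as R-squared with the Ezekiel adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_core import logger


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------- rarefaction

def rarefy_counts(row: np.ndarray | pd.Series, depth: int, rng=0) -> np.ndarray:
    """Subsample exactly ``depth`` reads without replacement.

    A multivariate-hypergeometric draw from the read pool; requires
    depth <= row total.
    """
    rng = _rng(rng)
    counts = np.asarray(row, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds row total {total}")
    if depth == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)


def rarefaction_curve(counts: pd.DataFrame, depths: Sequence[int],
                      n_replicates: int = 10, rng=0) -> pd.DataFrame:
    """Observed-feature and Shannon trajectories over a depth grid.

    Samples shallower than a depth are marked absent (NaN) at that depth.
    Returns a tidy frame: sample, depth, replicate, observed, shannon.
    """
    rng = _rng(rng)
    rows = []
    totals = counts.sum(axis=1)
    for sample in counts.index:
        vec = counts.loc[sample].to_numpy()
        for depth in depths:
            for rep in range(n_replicates):
                if depth > totals.loc[sample]:
                    rows.append((sample, depth, rep, np.nan, np.nan))
                    continue
                sub = rarefy_counts(vec, int(depth), rng)
                rows.append((sample, depth, rep, observed_features(sub),
                             shannon(sub)))
    return pd.DataFrame(rows, columns=["sample", "depth", "replicate",
                                       "observed", "shannon"])


def alpha_diversity(counts: pd.DataFrame, depth: Optional[int] = None,
                    n_replicates: int = 10, rng=0) -> pd.DataFrame:
    """Per-sample observed features and Shannon index at a common depth.

    ``depth`` defaults to the shallowest sample's total so every sample is
    comparable; metrics are averaged over rarefaction replicates.
    """
    rng = _rng(rng)
    totals = counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    rows = []
    for sample in counts.index:
        if totals.loc[sample] < depth:
            rows.append((sample, np.nan, np.nan))
            continue
        vec = counts.loc[sample].to_numpy()
        obs, sha = [], []
        for _ in range(n_replicates):
            sub = rarefy_counts(vec, depth, rng)
            obs.append(observed_features(sub))
            sha.append(shannon(sub))
        rows.append((sample, float(np.mean(obs)), float(np.mean(sha))))
    return pd.DataFrame(rows, columns=["sample", "observed", "shannon"]
                        ).set_index("sample")


# ---------------------------------------------------------------- alpha

def shannon(x) -> float:
    """Shannon index H = -sum p ln p over nonzero proportions (nats)."""
    arr = np.asarray(x, dtype=float)
    if arr.sum() <= 0:
        raise ValueError("Shannon index undefined for an all-zero profile")
    p = arr[arr > 0] / arr.sum()
    return float(-(p * np.log(p)).sum())


def observed_features(x) -> int:
    """Number of features with strictly positive count/abundance."""
    return int((np.asarray(x) > 0).sum())


# ---------------------------------------------------------------- beta

def bray_curtis(abund: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y).

    Pairs of all-zero rows get distance 0 (with a warning).
    """
    values = abund.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    with np.errstate(invalid="ignore"):
        dist = squareform(pdist(values, metric="braycurtis"))
    if np.isnan(dist).any():
        logger.warning("all-zero row pair(s): Bray-Curtis set to 0")
        dist = np.nan_to_num(dist, nan=0.0)
    return pd.DataFrame(dist, index=abund.index, columns=abund.index)


# ---------------------------------------------------------------- ordination

@dataclass
class OrdinationResult:
    """Sample scores, eigenvalues and explained fractions of an ordination."""

    axis_scores: pd.DataFrame
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    constrained_axes: list[str]


def pca(abund: pd.DataFrame, scale: bool = True) -> OrdinationResult:
    """Principal-component analysis of (optionally standardized) abundances.

    Columns are centered and, with ``scale``, divided by their standard
    deviation; constant columns are dropped.  Explained fractions over all
    retained axes sum to 1.
    """
    X = abund.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        X = X[:, keep] / sd[keep]
    else:
        keep = X.std(axis=0) >= 0
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 non-constant features")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    nz = s > 1e-12
    scores = U[:, nz] * s[nz]
    axes = [f"PC{i + 1}" for i in range(int(nz.sum()))]
    return OrdinationResult(
        axis_scores=pd.DataFrame(scores, index=abund.index, columns=axes),
        eigenvalues=eigvals[nz],
        explained_fraction=eigvals[nz] / eigvals.sum(),
        constrained_axes=[],
    )


def _gower_center(dist: np.ndarray) -> np.ndarray:
    A = -0.5 * dist**2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _pcoa_embedding(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding; negative-eigenvalue axes dropped."""
    G = _gower_center(dist)
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(eigvals.max(), 0) * 1e-10
    return eigvecs[:, pos] * np.sqrt(eigvals[pos]), eigvals[pos]


def _design_matrix(groups) -> np.ndarray:
    """Centered design: one-hot for categorical labels, column(s) for numeric."""
    arr = np.asarray(groups)
    if arr.ndim == 1 and arr.dtype.kind in "ifu":
        X = arr[:, None].astype(float)
    elif arr.ndim == 2:
        X = arr.astype(float)
    else:
        levels = sorted(set(arr.tolist()))
        if len(levels) < 2:
            raise ValueError("grouping is constant")
        X = np.array([[1.0 if g == lv else 0.0 for lv in levels] for g in arr])
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("design is constant")
    return Xc


def dbrda(dist: pd.DataFrame, groups: Sequence) -> OrdinationResult:
    """Distance-based redundancy analysis: PCoA then RDA on group indicators.

    Constrained axes are labelled CAP1, CAP2, ...; explained fractions are
    relative to the total inertia (sum of positive PCoA eigenvalues).
    """
    labels = pd.Series(list(groups), index=dist.index)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("dbRDA needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError(f"group(s) of size 1: {list(counts[counts < 2].index)}")
    D = dist.to_numpy(dtype=float)
    Y, eigvals = _pcoa_embedding(D)
    total_inertia = eigvals.sum()
    Xc = _design_matrix(labels.to_numpy())
    # hat-matrix projection of the embedding onto the design space
    Q, R = np.linalg.qr(Xc)
    rank = int((np.abs(np.diag(R)) > 1e-10).sum())
    Q = Q[:, :rank]
    fitted = Q @ (Q.T @ Y)
    # constrained axes: eigenvectors of the fitted cross-product
    C = fitted.T @ fitted
    lam, W = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam, W = lam[order], W[:, order]
    keep = lam > max(lam.max(), 0) * 1e-10
    lam, W = lam[keep], W[:, keep]
    scores = fitted @ W
    axes = [f"CAP{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        axis_scores=pd.DataFrame(scores, index=dist.index, columns=axes),
        eigenvalues=lam,
        explained_fraction=lam / total_inertia,
        constrained_axes=axes,
    )


# ---------------------------------------------------------------- tests

def _onehot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, inv = np.unique(labels, return_inverse=True)
    P = np.zeros((labels.size, levels.size))
    P[np.arange(labels.size), inv] = 1.0
    return P, levels


def envfit_factor(ordination: OrdinationResult, labels: Sequence,
                  n_perm: int = 1000, rng=0) -> tuple[float, float]:
    """Factor fit on the first two ordination axes.

    r2 = 1 - SS_within / SS_total of the axis scores around group
    centroids; significance by label permutation with the +1 convention.
    A single group returns (0.0, 1.0).
    """
    rng = _rng(rng)
    scores = ordination.axis_scores.to_numpy(dtype=float)[:, :2]
    labels = np.asarray(list(labels))
    if len(np.unique(labels)) < 2:
        return 0.0, 1.0
    centered = scores - scores.mean(axis=0)
    ss_total = (centered**2).sum()
    if ss_total <= 0:
        return 0.0, 1.0

    def _r2(lab_matrix: np.ndarray) -> np.ndarray:
        # lab_matrix: (m, n) integer group codes
        out = np.empty(lab_matrix.shape[0])
        for i, codes in enumerate(lab_matrix):
            P, _ = _onehot(codes)
            sizes = P.sum(axis=0)
            centroids = (P.T @ centered) / sizes[:, None]
            resid = centered - P @ centroids
            out[i] = 1.0 - (resid**2).sum() / ss_total
        return out

    codes = np.unique(labels, return_inverse=True)[1]
    r2_obs = float(_r2(codes[None, :])[0])
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    r2_perm = _r2(perms)
    p = (1 + int((r2_perm >= r2_obs).sum())) / (n_perm + 1)
    return r2_obs, p


@dataclass
class PermanovaResult:
    r2: float
    r2_adjusted: float
    pseudo_f: float
    p: float
    n_permutations: int
    df_model: int
    df_residual: int


def permanova(dist: pd.DataFrame | np.ndarray, groups: Sequence,
              n_perm: int = 999, rng=0) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the Gower-centered -D^2/2 matrix by the design (categorical
    labels become centered one-hot indicators; numeric covariates enter as
    regression terms).  pseudo-F = (SS_model/df_m) / (SS_res/df_r);
    R2 = SS_model / SS_total; adjusted R2 by the Ezekiel formula
    1 - (1 - R2)(n - 1)/(n - df_m - 1).  The permutation p-value uses the
    +1 convention, so p >= 1/(n_perm + 1).
    """
    rng = _rng(rng)
    D = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    n = D.shape[0]
    G = _gower_center(D)
    Xc = _design_matrix(np.asarray(list(groups)))
    Q, R = np.linalg.qr(Xc)
    rank = int((np.abs(np.diag(R)) > 1e-10).sum())
    Q = Q[:, :rank]
    H = Q @ Q.T
    ss_total = float(np.trace(G))
    ss_model = float(np.sum(G * H))  # trace(G H), H symmetric idempotent
    df_m = rank
    df_r = n - rank - 1
    if df_r <= 0:
        raise ValueError("not enough residual degrees of freedom")

    def _f(ss_m: float) -> float:
        ss_r = max(ss_total - ss_m, 0.0)
        if ss_r <= 1e-12 * max(ss_total, 1.0):  # perfect fit
            return np.inf
        return (ss_m / df_m) / (ss_r / df_r)

    f_obs = _f(ss_model)

    # permute sample identities: trace(G_perm H) via fancy indexing
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        if _f(float(np.sum(Gp * H))) >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    r2 = min(ss_model / ss_total, 1.0)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_r
    return PermanovaResult(r2=r2, r2_adjusted=r2_adj, pseudo_f=f_obs, p=p,
                           n_permutations=n_perm, df_model=df_m, df_residual=df_r)
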