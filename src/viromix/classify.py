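"""Random-forest discrimination of cohort pairs with LOOCV ROC/AUC.

Feature panels are the habitat's high-abundance, significantly different
taxa (selected once on the full data, mirroring common practice in
microbiome marker studies; a nested per-fold selection mode is available
for leakage-free evaluation).  Each sample's positive-class probability
comes from a forest trained on all remaining samples; the ROC curve and
its trapezoidal AUC are computed over the pooled out-of-fold
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .abundance import AbundanceMatrix, filter_high_abundance
from .differential import ALPHA
from .io_core import COHORTS, Manifest, logger


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class RocResult:
    """LOOCV ROC: pooled out-of-fold scores, curve points and AUC."""

    auc: float
    points: pd.DataFrame  # columns fpr, tpr, monotone from (0,0) to (1,1)
    per_sample_scores: pd.Series
    positive_label: str


def select_model_features(diff_results: pd.DataFrame, comparison: str,
                          mean_threshold: float = 5e-4,
                          abund: Optional[AbundanceMatrix | pd.DataFrame] = None
                          ) -> list[str]:
    """Features significant in the pairwise screen and above the abundance bar.

    ``diff_results`` is a :func:`viromix.differential.screen_features`
    frame; ``comparison`` names the pairwise Wilcoxon screen (e.g.
    ``"HC_vs_RA_untreated"``).  When ``abund`` is given the mean-abundance
    filter is recomputed from it, otherwise the screen's own filter is
    trusted.
    """
    sub = diff_results[(diff_results["test"] == "wilcoxon")
                       & (diff_results["comparison"] == comparison)]
    selected = sub.loc[sub["p_adj"] < ALPHA, "feature"].tolist()
    if abund is not None:
        values = abund.values if isinstance(abund, AbundanceMatrix) else abund
        high = set(filter_high_abundance(values, mean_threshold))
        selected = [f for f in selected if f in high]
    if not selected:
        raise ValueError(
            f"no features selected for {comparison!r}; relax mean_threshold "
            "or the significance cutoff")
    return selected


def loocv_rf(features: pd.DataFrame, labels: Sequence[str],
             n_trees: int = 500, rng=0, positive_label: Optional[str] = None,
             max_features: str | float = "sqrt",
             selector=None) -> RocResult:
    """Leave-one-out cross-validated random forest ROC.

    Each sample is scored by a fresh ``n_trees``-tree forest trained on all
    other samples; deterministic given ``rng``.

    ``selector`` enables nested (leakage-free) feature selection: a callable
    ``(X_train, y_train) -> column subset`` applied inside every fold, so
    the held-out sample never influences which features the fold's forest
    sees.  By default all supplied columns are used (the select-once
    convention, where selection happens upstream on the full data).
    """
    rng = _rng(rng)
    y = pd.Series(list(labels), index=features.index)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if (y.value_counts() < 2).any():
        raise ValueError("both classes need at least 2 samples")
    if positive_label is None:
        positive_label = classes[1]
    X = features.to_numpy(dtype=float)
    y_arr = (y == positive_label).to_numpy()
    scores = np.empty(len(y_arr))
    for i in range(len(y_arr)):
        mask = np.ones(len(y_arr), dtype=bool)
        mask[i] = False
        cols = np.arange(X.shape[1])
        if selector is not None:
            chosen = selector(features.iloc[mask], y.iloc[mask])
            cols = np.array([features.columns.get_loc(c) for c in chosen])
            if cols.size == 0:
                raise ValueError("selector returned no features for a fold")
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features=max_features,
            random_state=int(rng.integers(2**31 - 1)))
        forest.fit(X[np.ix_(mask, cols)], y_arr[mask])
        if forest.classes_.size == 1:  # degenerate training fold
            scores[i] = float(forest.classes_[0])
        else:
            scores[i] = forest.predict_proba(
                X[i:i + 1, cols])[0, list(forest.classes_).index(True)]
    fpr, tpr, _ = roc_curve(y_arr, scores, drop_intermediate=False)
    return RocResult(
        auc=float(_trapezoid_auc(fpr, tpr)),
        points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        per_sample_scores=pd.Series(scores, index=features.index),
        positive_label=positive_label,
    )


#: cohort pairings reported per habitat, (positive, negative)
PAIRINGS = (("RA_untreated", "HC"), ("RA_treated", "HC"),
            ("RA_untreated", "RA_treated"))


def pairwise_panels(abund_v: AbundanceMatrix | pd.DataFrame,
                    abund_b: AbundanceMatrix | pd.DataFrame,
                    manifest: Manifest, habitat: str,
                    diff_v: pd.DataFrame, diff_b: pd.DataFrame,
                    mean_threshold: float = 5e-4, n_trees: int = 500,
                    rng=0) -> pd.DataFrame:
    """AUC table: {bacteriome, virome, combined} x cohort pairings.

    Feature sets come from :func:`select_model_features` on the habitat's
    differential screens; the combined set is the union.  Pairings with a
    missing cohort or an empty feature set are reported as NaN with a
    warning.
    """
    rng = _rng(rng)
    values_v = abund_v.values if isinstance(abund_v, AbundanceMatrix) else abund_v
    values_b = abund_b.values if isinstance(abund_b, AbundanceMatrix) else abund_b
    sub = manifest.subset(habitat=habitat)
    cohort = sub.cohorts([s for s in sub.sample_ids if s in values_v.index])
    rows = []
    for pos, neg in PAIRINGS:
        ids = cohort.index[cohort.isin([pos, neg])].tolist()
        comparison = "_vs_".join(sorted([pos, neg], key=COHORTS.index))
        for feature_set, (diff, frames) in {
            "bacteriome": (diff_b, [values_b]),
            "virome": (diff_v, [values_v]),
            "combined": (None, [values_v, values_b]),
        }.items():
            row = {"habitat": habitat, "feature_set": feature_set,
                   "comparison": f"{pos}_vs_{neg}",
                   "n_pos": int((cohort == pos).sum()),
                   "n_neg": int((cohort == neg).sum()), "auc": np.nan}
            try:
                if feature_set == "combined":
                    feats_v = select_model_features(diff_v, comparison,
                                                    mean_threshold, values_v)
                    feats_b = select_model_features(diff_b, comparison,
                                                    mean_threshold, values_b)
                    X = pd.concat([values_v.loc[ids, feats_v],
                                   values_b.loc[ids, feats_b]], axis=1)
                else:
                    feats = select_model_features(diff, comparison,
                                                  mean_threshold, frames[0])
                    X = frames[0].loc[ids, feats]
                if len(set(cohort.loc[ids])) < 2:
                    raise ValueError(f"cohort {pos} or {neg} missing in {habitat}")
                roc = loocv_rf(X, cohort.loc[ids], n_trees=n_trees, rng=rng,
                               positive_label=pos)
                row["auc"] = roc.auc
                row["n_features"] = X.shape[1]
            except ValueError as exc:
                logger.warning("panel %s/%s/%s skipped: %s", habitat,
                               feature_set, f"{pos}_vs_{neg}", exc)
            rows.append(row)
    return pd.DataFrame(rows)
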