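"""Family-level taxonomy by majority-fraction protein voting.

Each vOTU's predicted proteins are matched against a protein -> viral-family
reference (alignment bit score >= 50); the vOTU is assigned the family that
recruits strictly more than one-third of ALL its predicted proteins.  A
protein with several reference hits votes once, through its best hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

UNCLASSIFIED = "Unclassified"
MIN_SCORE = 50.0
VOTE_FRACTION = 1.0 / 3.0


@dataclass
class FamilyCall:
    votu_id: str
    family: str
    vote_fraction: float


def assign_family(assignments: pd.DataFrame,
                  n_proteins: Mapping[str, int]) -> pd.DataFrame:
    """Vote a family per vOTU.

    ``assignments`` columns: votu_id, protein_id, family, score.  Hits with
    score < 50 are discarded; each protein votes via its best-scoring hit.
    The winning family needs count / n_proteins > 1/3 (strict); count ties
    break by larger summed score, then fall back to Unclassified.  vOTUs
    with zero proteins are Unclassified with vote fraction 0.

    Returns a frame with columns votu_id, family, vote_fraction covering
    every key of ``n_proteins``.
    """
    n_proteins = pd.Series(n_proteins)
    df = assignments[assignments["score"] >= MIN_SCORE].copy()
    # best hit per protein: highest score, ties by family name for determinism
    df = df.sort_values(["votu_id", "protein_id", "score", "family"],
                        ascending=[True, True, False, True])
    df = df.drop_duplicates(subset=["votu_id", "protein_id"], keep="first")

    n_assigned = df.groupby("votu_id")["protein_id"].count()
    bad = n_assigned[n_assigned > n_proteins.reindex(n_assigned.index)]
    if len(bad):
        raise ValueError(f"more assigned proteins than n_proteins for {list(bad.index)}")

    rows = []
    grouped = dict(tuple(df.groupby("votu_id")))
    for votu in n_proteins.index:
        total = int(n_proteins.loc[votu])
        sub = grouped.get(votu)
        if total == 0 or sub is None or not len(sub):
            rows.append((votu, UNCLASSIFIED, 0.0))
            continue
        tally = sub.groupby("family").agg(count=("protein_id", "count"),
                                          score=("score", "sum"))
        tally = tally.sort_values(["count", "score"], ascending=False)
        top_count = int(tally["count"].iloc[0])
        top = tally[tally["count"] == top_count]
        if top_count / total <= VOTE_FRACTION:
            rows.append((votu, UNCLASSIFIED, top_count / total))
            continue
        if len(top) > 1 and top["score"].iloc[0] == top["score"].iloc[1]:
            # unresolved tie on count and summed score
            rows.append((votu, UNCLASSIFIED, top_count / total))
            continue
        rows.append((votu, top.index[0], top_count / total))
    return pd.DataFrame(rows, columns=["votu_id", "family", "vote_fraction"])


def aggregate_family_abundance(abund: pd.DataFrame,
                               calls: pd.DataFrame) -> pd.DataFrame:
    """Sum member-vOTU abundances per family (incl. the Unclassified bucket).

    ``abund`` is samples x vOTUs; every column must have a family call.
    Per-sample totals are conserved exactly up to float addition order.
    """
    family_of = calls.set_index("votu_id")["family"]
    missing = [v for v in abund.columns if v not in family_of.index]
    if missing:
        raise ValueError(f"missing family call for {missing}")
    out = abund.T.groupby(family_of.reindex(abund.columns)).sum().T
    return out
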