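"""Three-criterion viral-contig decision rule and BUSCO contamination filter.

A contig is called viral when it satisfies at least one of:

* **homology** — >=50% of its proteins hit the viral protein reference
  (or >=3 hits when it carries fewer than 6 proteins);
* **sorter** — a homology-based sorter placed it in category 1, 2, 4 or 5;
* **kmer** — a k-mer classifier score > 0.9 with p < 0.05 (both strict).

Viral calls are then screened for bacterial contamination: contigs whose
BUSCO ratio (bacterial universal single-copy orthologs / total genes) is
>= 5% are discarded.  Thresholds follow a literal reading: the two "at
least" bounds are inclusive, the score/p bounds strict, and the 5% removal
bound inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional


import pandas as pd

SORTER_VIRAL_CATEGORIES = frozenset({1, 2, 4, 5})

#: evidence-table columns, in canonical order
EVIDENCE_COLUMNS = (
    "contig_id", "length", "n_proteins", "n_viral_hits", "sorter_category",
    "kmer_score", "kmer_p", "n_busco_hits", "n_genes",
)


@dataclass
class ContigEvidence:
    """Per-contig evidence bundle driving the viral decision rule."""

    contig_id: str
    length: int
    n_proteins: int
    n_viral_hits: int
    sorter_category: Optional[int] = None
    kmer_score: Optional[float] = None
    kmer_p: Optional[float] = None
    n_busco_hits: int = 0
    n_genes: int = 0

    def __post_init__(self) -> None:
        if self.n_viral_hits > self.n_proteins:
            raise ValueError(
                f"{self.contig_id}: n_viral_hits ({self.n_viral_hits}) exceeds "
                f"n_proteins ({self.n_proteins})"
            )
        if self.n_busco_hits > self.n_genes:
            raise ValueError(
                f"{self.contig_id}: n_busco_hits ({self.n_busco_hits}) exceeds "
                f"n_genes ({self.n_genes})"
            )


@dataclass
class ViralCall:
    """Decision for one contig: criteria passed, contamination, retention."""

    contig_id: str
    passed: frozenset
    busco_ratio: float
    is_viral: bool
    retained: bool


def apply_homology_criterion(ev: ContigEvidence) -> bool:
    """True when enough of the contig's proteins hit the viral reference.

    Contigs with six or more proteins need at least half of them hitting;
    smaller contigs need at least three hits.  Zero proteins can never pass.
    """
    if ev.n_proteins == 0:
        return False
    if ev.n_proteins >= 6:
        return ev.n_viral_hits / ev.n_proteins >= 0.5
    return ev.n_viral_hits >= 3


def apply_sorter_criterion(ev: ContigEvidence) -> bool:
    """True when the sorter placed the contig in a confident viral category."""
    return ev.sorter_category is not None and ev.sorter_category in SORTER_VIRAL_CATEGORIES


def apply_kmer_criterion(ev: ContigEvidence) -> bool:
    """True when score > 0.9 and p < 0.05, both present and both strict."""
    if ev.kmer_score is None or ev.kmer_p is None:
        return False
    return ev.kmer_score > 0.9 and ev.kmer_p < 0.05


def busco_ratio(ev: ContigEvidence) -> float:
    """Fraction of genes matching bacterial single-copy orthologs.

    With no predicted genes there is no contamination evidence: ratio 0.
    """
    if ev.n_genes == 0:
        return 0.0
    return ev.n_busco_hits / ev.n_genes


def call_viral_contigs(evidence: Iterable[ContigEvidence],
                       busco_max: float = 0.05) -> list[ViralCall]:
    """Apply the union of the three criteria plus the contamination filter.

    ``retained`` requires a viral call AND a BUSCO ratio strictly below
    ``busco_max`` (the removal bound is inclusive: ratio == busco_max drops).
    """
    calls: list[ViralCall] = []
    seen: set[str] = set()
    for ev in evidence:
        if ev.contig_id in seen:
            raise ValueError(f"duplicate contig_id {ev.contig_id!r}")
        seen.add(ev.contig_id)
        passed = set()
        if apply_homology_criterion(ev):
            passed.add("homology")
        if apply_sorter_criterion(ev):
            passed.add("sorter")
        if apply_kmer_criterion(ev):
            passed.add("kmer")
        ratio = busco_ratio(ev)
        is_viral = bool(passed)
        calls.append(
            ViralCall(ev.contig_id, frozenset(passed), ratio, is_viral,
                      is_viral and ratio < busco_max)
        )
    return calls


def evidence_from_frame(df: pd.DataFrame, min_length: int = 5000) -> list[ContigEvidence]:
    """Build evidence records from an evidence TSV frame.

    Contigs below ``min_length`` are excluded at ingest.  Absent sorter
    category / k-mer columns are encoded as NA.
    """
    out: list[ContigEvidence] = []
    for _, row in df.iterrows():
        if int(row["length"]) < min_length:
            continue
        cat = row.get("sorter_category")
        score = row.get("kmer_score")
        pval = row.get("kmer_p")
        out.append(ContigEvidence(
            contig_id=str(row["contig_id"]),
            length=int(row["length"]),
            n_proteins=int(row["n_proteins"]),
            n_viral_hits=int(row["n_viral_hits"]),
            sorter_category=None if pd.isna(cat) else int(cat),
            kmer_score=None if pd.isna(score) else float(score),
            kmer_p=None if pd.isna(pval) else float(pval),
            n_busco_hits=int(row["n_busco_hits"]),
            n_genes=int(row["n_genes"]),
        ))
    return out


def calls_to_frame(calls: Iterable[ViralCall]) -> pd.DataFrame:
    rows = [
        {
            "contig_id": c.contig_id,
            "passed": ",".join(sorted(c.passed)),
            "busco_ratio": c.busco_ratio,
            "is_viral": c.is_viral,
            "retained": c.retained,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["contig_id", "passed", "busco_ratio",
                                       "is_viral", "retained"])


def call_viral_frame(df: pd.DataFrame, min_length: int = 5000,
                     busco_max: float = 0.05) -> pd.DataFrame:
    """Frame-level wrapper: evidence TSV in, per-contig decision table out."""
    calls = call_viral_contigs(evidence_from_frame(df, min_length=min_length),
                               busco_max=busco_max)
    return calls_to_frame(calls)
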