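"""Length-normalized relative abundances and habitat presence summaries.

The per-sample abundance of a vOTU is its read count divided by its genome
length (a read density), renormalized so each sample row sums to one.  The
renormalized proportion differs from a total-mapped-reads denominator only
by a per-sample constant; the mapped-read fraction (mapped / high-quality
reads) is kept as a separate per-sample quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_core import Manifest, logger


@dataclass
class AbundanceMatrix:
    """Samples x features relative abundances with per-sample read bookkeeping."""

    values: pd.DataFrame
    feature_lengths: pd.Series
    sample_totals: pd.Series
    mapped_reads: pd.Series

    def mapped_fraction(self) -> pd.Series:
        totals = self.sample_totals.reindex(self.values.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = self.mapped_reads / totals
        return frac.fillna(0.0)


def relative_abundance(counts: pd.DataFrame, lengths: Mapping[str, float],
                       totals: pd.Series | Mapping[str, int]) -> AbundanceMatrix:
    """Length-normalize counts and renormalize rows to proportions.

    For sample s and vOTU v with reads r and length L: density d = r/L,
    abundance a = d / sum_v d (all-zero rows stay all-zero).
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = [f for f in counts.columns if f not in lengths.index or
               not np.isfinite(lengths.get(f, np.nan))]
    if missing:
        raise ValueError(f"missing genome length for {missing}")
    lengths = lengths.reindex(counts.columns)
    if (lengths <= 0).any():
        raise ValueError("genome lengths must be positive")
    density = counts.astype(float) / lengths
    row_sum = density.sum(axis=1)
    values = density.div(row_sum.where(row_sum > 0, 1.0), axis=0)
    return AbundanceMatrix(
        values=values,
        feature_lengths=lengths,
        sample_totals=pd.Series(totals).reindex(counts.index),
        mapped_reads=counts.sum(axis=1),
    )


def mapped_fraction(counts: pd.DataFrame,
                    totals: pd.Series | Mapping[str, int]) -> pd.Series:
    """Per-sample fraction of high-quality reads assigned to any feature."""
    totals = pd.Series(totals).reindex(counts.index).astype(float)
    mapped = counts.sum(axis=1).astype(float)
    if (mapped > totals).any():
        raise ValueError("mapped reads exceed total high-quality reads")
    out = pd.Series(0.0, index=counts.index)
    zero = totals == 0
    if zero.any():
        logger.warning("samples with zero total reads: %s", list(counts.index[zero]))
    nz = ~zero
    out[nz] = mapped[nz] / totals[nz]
    return out


def habitat_presence_overlap(abund: AbundanceMatrix, manifest: Manifest
                             ) -> tuple[dict[str, set], pd.DataFrame]:
    """Per-habitat vOTU presence sets and ordered pairwise shared fractions.

    A vOTU is present in a habitat iff it is nonzero in at least one sample
    of that habitat.  For an ordered pair (A, B) the shared fraction is
    |A intersect B| / |A|.
    """
    habitats = manifest.habitats()
    present: dict[str, set] = {}
    for habitat in sorted(habitats.unique()):
        ids = [s for s in abund.values.index if habitats.get(s) == habitat]
        if not ids:
            logger.warning("habitat %s has no samples; excluded", habitat)
            continue
        nonzero = (abund.values.loc[ids] > 0).any(axis=0)
        present[habitat] = set(abund.values.columns[nonzero])
    rows = []
    for a in present:
        for b in present:
            if a == b:
                continue
            n_a = len(present[a])
            shared = len(present[a] & present[b])
            rows.append({"habitat_a": a, "habitat_b": b, "n_a": n_a,
                         "n_shared": shared,
                         "fraction": shared / n_a if n_a else 0.0})
    return present, pd.DataFrame(rows, columns=["habitat_a", "habitat_b",
                                                "n_a", "n_shared", "fraction"])


def filter_high_abundance(abund: AbundanceMatrix | pd.DataFrame,
                          threshold: float) -> pd.Index:
    """Features whose mean relative abundance across all samples strictly
    exceeds ``threshold`` (zeros included in the mean)."""
    values = abund.values if isinstance(abund, AbundanceMatrix) else abund
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = values.mean(axis=0)
    return values.columns[means > threshold]
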