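"""Readers/writers for on-disk artifacts and the sample-manifest model.

All tabular artifacts are tab-separated UTF-8 with a single header row.
Missing covariate values are encoded as the literal ``NA``; samples with
missing values are dropped per-analysis, never globally.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HABITATS = ("dental_plaque", "saliva", "feces")
COHORTS = ("HC", "RA_untreated", "RA_treated")

#: manifest columns that are not covariates
_MANIFEST_CORE = ("sample_id", "subject_id", "habitat", "cohort", "total_hq_reads")

logger = logging.getLogger("viromix")


def configure_logging(level: int = logging.INFO) -> None:
    """Log to stderr with ISO timestamps (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s",
                              datefmt="%Y-%m-%dT%H:%M:%S")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


@dataclass
class SampleRecord:
    """One sequenced sample: identity, stratum, sequencing depth, covariates.

    ``total_hq_reads`` is the number of high-quality non-host metagenomic
    reads for the sample — the denominator of the mapped-read fraction.
    Covariates hold clinical/demographic variables (age, BMI, DAS28, ...);
    missing values are ``None``/NaN.
    """

    sample_id: str
    subject_id: str
    habitat: str
    cohort: str
    total_hq_reads: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r} for sample {self.sample_id!r}")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r} for sample {self.sample_id!r}")
        if self.total_hq_reads < 0:
            raise ValueError(f"total_hq_reads < 0 for sample {self.sample_id!r}")


class Manifest:
    """Ordered collection of :class:`SampleRecord` with uniqueness checks."""

    def __init__(self, samples: Iterable[SampleRecord]):
        self.samples = list(samples)
        seen_ids: set[str] = set()
        seen_pairs: set[tuple[str, str]] = set()
        for rec in self.samples:
            if rec.sample_id in seen_ids:
                raise ValueError(f"duplicate sample_id {rec.sample_id!r} in manifest")
            seen_ids.add(rec.sample_id)
            pair = (rec.subject_id, rec.habitat)
            if pair in seen_pairs:
                raise ValueError(f"duplicate (subject_id, habitat) pair {pair!r} in manifest")
            seen_pairs.add(pair)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [rec.sample_id for rec in self.samples]

    def subset(self, habitat: str | None = None, cohort: str | None = None) -> "Manifest":
        kept = [
            rec for rec in self.samples
            if (habitat is None or rec.habitat == habitat)
            and (cohort is None or rec.cohort == cohort)
        ]
        return Manifest(kept)

    def cohorts(self, sample_ids: Iterable[str] | None = None) -> pd.Series:
        """Cohort label per sample, optionally restricted/ordered by ``sample_ids``."""
        ser = pd.Series({rec.sample_id: rec.cohort for rec in self.samples})
        return ser if sample_ids is None else ser.loc[list(sample_ids)]

    def habitats(self) -> pd.Series:
        return pd.Series({rec.sample_id: rec.habitat for rec in self.samples})

    def total_reads(self) -> pd.Series:
        return pd.Series({rec.sample_id: rec.total_hq_reads for rec in self.samples})

    def covariate(self, name: str) -> pd.Series:
        """Covariate values per sample (NaN where missing)."""
        return pd.Series({rec.sample_id: rec.covariates.get(name, np.nan)
                          for rec in self.samples})

    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for rec in self.samples:
            for key in rec.covariates:
                if key not in names:
                    names.append(key)
        return names

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.samples:
            row = {
                "sample_id": rec.sample_id,
                "subject_id": rec.subject_id,
                "habitat": rec.habitat,
                "cohort": rec.cohort,
                "total_hq_reads": rec.total_hq_reads,
            }
            row.update(rec.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


def read_manifest(path: str | Path) -> Manifest:
    """Read a sample manifest TSV.

    Requires columns sample_id, subject_id, habitat, cohort, total_hq_reads;
    any additional column becomes a covariate.  ``NA`` cells are missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [col for col in _MANIFEST_CORE if col not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required column(s) {missing}")
    covar_cols = [c for c in df.columns if c not in _MANIFEST_CORE]
    records = []
    for i, row in df.iterrows():
        covars = {}
        for col in covar_cols:
            raw = row[col]
            if raw == "NA" or raw == "":
                covars[col] = np.nan
            else:
                try:
                    covars[col] = float(raw)
                except ValueError:
                    covars[col] = raw
        try:
            total = int(row["total_hq_reads"])
        except ValueError as exc:
            raise ValueError(
                f"non-integer total_hq_reads {row['total_hq_reads']!r} at row {i}"
            ) from exc
        try:
            records.append(
                SampleRecord(row["sample_id"], row["subject_id"], row["habitat"],
                             row["cohort"], total, covars)
            )
        except ValueError as exc:
            raise ValueError(f"{exc} (manifest row {i})") from exc
    return Manifest(records)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    df = manifest.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples x features matrix of non-negative integer counts.

    First column holds sample ids; an empty feature set (header-only columns)
    is accepted and yields a 0-column table.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        values = df[col]
        numeric = pd.to_numeric(values, errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric != numeric.round())
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"count matrix {path}: invalid cell {values.loc[row]!r} at "
                f"(row {row!r}, col {col!r}); counts must be non-negative integers"
            )
    return df.astype(np.int64)


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic TSV result reader (inverse of :func:`write_result_table`)."""
    return pd.read_csv(path, sep="\t")


def write_result_table(result: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as TSV.

    Floats are written with full shortest-round-trip precision, so a
    write/read cycle reproduces values exactly for integers and to full
    double precision for floats.
    """
    if not isinstance(result, pd.DataFrame):
        result = pd.DataFrame(result)
    index = result.index.name is not None
    result.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read contig sequences, keyed by record id, as uppercase strings."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
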