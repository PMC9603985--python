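"""Synthetic study generator with recorded ground truth.

Emulates every input the pipeline consumes — contig FASTA, per-contig
evidence tables, per-sample vOTU read counts, a bacterial species matrix,
and a sample manifest with clinical covariates — for a three-habitat,
three-cohort design, so every downstream stage is testable with planted
truth.

Model choices (all exposed in :class:`SimulationConfig`):

* vOTU structure: seed genomes mutated at a within-clique substitution rate
  (default 2%) well below the 5% clustering radius, while independent seeds
  are effectively unrelated (>20% divergent), so clique truth is
  unambiguous.
* Counts: negative-binomial with log-normal mean heterogeneity across
  features, per-habitat baseline profiles, and log-normal per-sample depth
  factors — the over-dispersion real virome counts show.
* Planted cohort effects multiply a feature's mean by a configured fold in
  one cohort.
* Planted virus-bacterium correlations and taxon-clinical links are induced
  through shared Gaussian latent factors mapped through negative-binomial
  quantiles (a Gaussian copula), which controls rank correlation directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import COHORTS, HABITATS, Manifest, SampleRecord
from .viral_id import EVIDENCE_COLUMNS

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: viral families used for synthetic protein-vote tables
FAMILIES = ("Siphoviridae", "Myoviridae", "Herelleviridae", "Autographiviridae",
            "Phycodnaviridae", "Microviridae", "Podoviridae", "Drexlerviridae")

CLINICAL_INDICES = ("DAS28", "CDAI", "CRP", "GH", "disease_activity", "RA_duration")

#: per-habitat mean fraction of reads mapping to the virome
_MAPPED_FRACTION = {"dental_plaque": 0.063, "saliva": 0.095, "feces": 0.14}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the synthetic generator."""

    n_subjects_per_cohort: int = 30
    habitats: Sequence[str] = HABITATS
    n_seed_genomes: int = 40
    genome_length_range: tuple[int, int] = (5000, 20000)
    max_copies_per_seed: int = 3
    divergence_within_votu: float = 0.02
    divergence_between_votu: float = 0.20
    identity_threshold: float = 0.95
    truncation_prob: float = 0.3
    min_copy_fraction: float = 0.8
    n_non_viral_contigs: int = 20
    n_bacteria: int = 60
    nb_dispersion: float = 1.0          # NB size k; var = mu + mu^2/k
    mean_log_mu: float = 4.0            # ln-scale location of feature means
    mean_log_sigma: float = 1.5         # ln-scale spread of feature means
    depth_log_sigma: float = 0.3        # per-sample depth factor spread
    effect_fold: float = 8.0
    n_planted_diff: int = 20            # differential vOTUs
    n_planted_diff_bacteria: int = 12
    n_planted_edges: int = 10
    edge_strength: float = 0.8
    clinical_indices: Sequence[str] = CLINICAL_INDICES
    clinical_link_strength: float = 0.7
    evidence_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence_within_votu", "divergence_between_votu",
                     "identity_threshold", "truncation_prob", "min_copy_fraction",
                     "evidence_noise"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} = {value} outside [0, 1]")
        radius = 1.0 - self.identity_threshold
        if not (self.divergence_within_votu < radius < self.divergence_between_votu):
            raise ValueError(
                "divergence ordering violated: need divergence_within_votu < "
                f"{radius:.3f} < divergence_between_votu, got "
                f"{self.divergence_within_votu} / {self.divergence_between_votu}"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generator."""

    contig_labels: dict[str, str] = field(default_factory=dict)
    clique_map: dict[str, str] = field(default_factory=dict)
    below_coverage: set[str] = field(default_factory=set)
    #: feature id -> (enriched cohort, fold)
    planted_diff_features: dict[str, tuple[str, float]] = field(default_factory=dict)
    #: (virus id, bacterium id, sign, latent correlation strength)
    planted_edges: list[tuple[str, str, str, float]] = field(default_factory=list)
    #: (taxon id, index name, sign)
    planted_clinical_links: list[tuple[str, str, str]] = field(default_factory=list)

    def cliques(self) -> list[frozenset]:
        groups: dict[str, set[str]] = {}
        for contig, clique in self.clique_map.items():
            groups.setdefault(clique, set()).add(contig)
        return [frozenset(v) for v in groups.values()]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # substitute with a uniformly chosen *different* base
        offsets = rng.integers(1, 4, size=n_hit)
        base_idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(base_idx + offsets) % 4]
    return arr.tobytes().decode()


def simulate_contigs(cfg: SimulationConfig,
                     rng: Optional[np.random.Generator] = None
                     ) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate redundant viral contigs plus unrelated non-viral contigs.

    Each seed genome yields 1..max_copies_per_seed mutated copies (point
    substitutions at the within-clique rate, optional end truncation down to
    ``min_copy_fraction`` of the seed length) sharing the seed's clique id.
    All contigs are >= 5,000 bp.  Deterministic given config seed.
    """
    rng = _rng(cfg.seed if rng is None else rng)
    lo, hi = cfg.genome_length_range
    if lo < 5000:
        raise ValueError("genome_length_range must start at >= 5000 bp")
    truth = SyntheticTruth()
    contigs: dict[str, str] = {}
    for g in range(cfg.n_seed_genomes):
        clique = f"seed{g:03d}"
        length = int(rng.integers(lo, hi + 1))
        genome = _random_sequence(rng, length)
        n_copies = int(rng.integers(1, cfg.max_copies_per_seed + 1))
        for c in range(n_copies):
            seq = _mutate(rng, genome, cfg.divergence_within_votu) if c else genome
            if c and rng.random() < cfg.truncation_prob:
                frac = rng.uniform(cfg.min_copy_fraction, 1.0)
                keep = max(5000, int(len(seq) * frac))
                if rng.random() < 0.5:
                    seq = seq[:keep]
                else:
                    seq = seq[len(seq) - keep:]
            cid = f"{clique}_c{c}"
            contigs[cid] = seq
            truth.contig_labels[cid] = "viral"
            truth.clique_map[cid] = clique
            if len(seq) < cfg.min_copy_fraction * length:
                truth.below_coverage.add(cid)
    for j in range(cfg.n_non_viral_contigs):
        cid = f"nonviral{j:03d}"
        contigs[cid] = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        truth.contig_labels[cid] = "non_viral"
    return contigs, truth


def simulate_evidence(truth: SyntheticTruth, noise: float = 0.0,
                      rng: Optional[np.random.Generator] = None,
                      lengths: Optional[Mapping[str, int]] = None,
                      seed: int = 0) -> pd.DataFrame:
    """Generate a per-contig evidence table consistent with planted labels.

    Viral contigs receive evidence passing at least one of the three
    criteria and a BUSCO ratio < 5%; non-viral contigs either fail all
    three or look viral but carry a >= 5% BUSCO ratio (contamination).
    With probability ``noise`` a contig's evidence is generated from the
    flipped label.
    """
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must be in [0, 1)")
    rng = _rng(seed if rng is None else rng)
    rows = []
    for cid, label in truth.contig_labels.items():
        length = int(lengths[cid]) if lengths else 10000
        effective = label
        if noise and rng.random() < noise:
            effective = "non_viral" if label == "viral" else "viral"
        n_proteins = max(3, int(rng.poisson(length / 1000)))
        n_genes = n_proteins + int(rng.poisson(1))
        row = {
            "contig_id": cid, "length": length, "n_proteins": n_proteins,
            "sorter_category": np.nan, "kmer_score": np.nan, "kmer_p": np.nan,
            "n_genes": n_genes,
        }
        if effective == "viral":
            which = rng.random(3) < 0.7
            if not which.any():
                which[rng.integers(3)] = True
            if which[0]:
                need = max(3, -(-n_proteins // 2))  # ceil(n/2), >= 3
                row["n_viral_hits"] = int(rng.integers(min(need, n_proteins),
                                                       n_proteins + 1))
            else:
                cap = 2 if n_proteins < 6 else max(0, (n_proteins - 1) // 2)
                row["n_viral_hits"] = int(rng.integers(0, min(cap, n_proteins) + 1))
            if which[1]:
                row["sorter_category"] = int(rng.choice([1, 2, 4, 5]))
            elif rng.random() < 0.5:
                row["sorter_category"] = int(rng.choice([3, 6]))
            if which[2]:
                row["kmer_score"] = float(rng.uniform(0.905, 1.0))
                row["kmer_p"] = float(rng.uniform(0.0, 0.049))
            else:
                row["kmer_score"] = float(rng.uniform(0.0, 0.9))
                row["kmer_p"] = float(rng.uniform(0.0, 1.0))
            # clean viral contig: BUSCO ratio strictly below 5%
            row["n_busco_hits"] = int(min(n_genes, rng.integers(0, max(1, int(0.05 * n_genes)))))
        else:
            contaminated = rng.random() < 0.3
            if contaminated:
                # passes a criterion but is flagged by the BUSCO filter
                row["n_viral_hits"] = n_proteins
                row["n_busco_hits"] = int(rng.integers(
                    -(-n_genes * 5 // 100), n_genes + 1))  # >= ceil(0.05*n_genes)
            else:
                cap = 2 if n_proteins < 6 else max(0, (n_proteins - 1) // 2)
                row["n_viral_hits"] = int(rng.integers(0, min(cap, n_proteins) + 1))
                if rng.random() < 0.5:
                    row["sorter_category"] = int(rng.choice([3, 6]))
                if rng.random() < 0.5:
                    row["kmer_score"] = float(rng.uniform(0.0, 0.9))
                    row["kmer_p"] = float(rng.uniform(0.0, 1.0))
                else:
                    row["kmer_score"] = float(rng.uniform(0.905, 1.0))
                    row["kmer_p"] = float(rng.uniform(0.06, 1.0))
                row["n_busco_hits"] = int(rng.integers(
                    -(-n_genes * 5 // 100), n_genes + 1))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS))


def simulate_manifest(cfg: SimulationConfig,
                      rng: Optional[np.random.Generator] = None) -> Manifest:
    """Subjects per cohort sampled in every configured habitat.

    Subject ids are shared across habitats (one subject contributes up to
    three samples); demographics (age, gender, BMI) are drawn once per
    subject.  Clinical indices are attached later, after counts exist.
    """
    rng = _rng(cfg.seed + 1 if rng is None else rng)
    abbrev = {"dental_plaque": "dp", "saliva": "sa", "feces": "fe"}
    records = []
    subject_no = 0
    for cohort in COHORTS:
        for _ in range(cfg.n_subjects_per_cohort):
            subject = f"subj{subject_no:03d}"
            subject_no += 1
            age = float(np.round(rng.normal(55, 10), 1))
            gender = str(rng.choice(["F", "M"]))
            bmi = float(np.round(rng.normal(23, 3), 1))
            for habitat in cfg.habitats:
                records.append(SampleRecord(
                    sample_id=f"{subject}_{abbrev[habitat]}",
                    subject_id=subject, habitat=habitat, cohort=cohort,
                    total_hq_reads=0,  # filled in by simulate_cohort_counts
                    covariates={"age": age, "gender": gender, "BMI": bmi},
                ))
    return Manifest(records)


def _nb_quantile_counts(u: np.ndarray, mu: np.ndarray, k: float) -> np.ndarray:
    """Map copula uniforms through NB(mu, size=k) quantiles."""
    mu = np.maximum(mu, 1e-9)
    p = k / (k + mu)
    return stats.nbinom.ppf(u, k, p).astype(np.int64)


def simulate_cohort_counts(cfg: SimulationConfig, manifest: Manifest,
                           features: Sequence[str],
                           rng: Optional[np.random.Generator] = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth,
                                      pd.DataFrame]:
    """Draw virus and bacterium count matrices plus clinical indices.

    Returns ``(virus_counts, bacteria_counts, truth_update, indices)`` where
    ``indices`` is a samples x clinical-index frame aligned to the manifest.
    Feature-wise negative-binomial counts; planted differential features get
    their mean multiplied by ``effect_fold`` in their designated cohort;
    planted virus-bacterium edges and taxon-index links act through shared
    Gaussian latent factors.  Deterministic given config seed.
    """
    rng = _rng(cfg.seed + 2 if rng is None else rng)
    features = list(features)
    bacteria = [f"bact{b:03d}" for b in range(cfg.n_bacteria)]
    cohorts_present = sorted({rec.cohort for rec in manifest})
    if len(cohorts_present) < 2:
        raise ValueError("manifest must cover at least 2 cohorts")
    if cfg.n_planted_diff > len(features) or cfg.n_planted_edges > min(
            len(features), len(bacteria)):
        raise ValueError("fewer features than planted sets")

    truth = SyntheticTruth()

    # per-(habitat, feature) log-normal baseline means
    habitats = [h for h in cfg.habitats
                if any(rec.habitat == h for rec in manifest)]
    base_mu = {
        (h, f): float(np.exp(rng.normal(cfg.mean_log_mu, cfg.mean_log_sigma)))
        for h in habitats for f in features + bacteria
    }

    # rank features by mean so planted sets sit in the higher-mean region and
    # survive mean-abundance filters; shuffle within that region, then carve
    # disjoint slices for differential features and edge endpoints
    def _eligible(pool: list[str], n_needed: int) -> list[str]:
        ranked = sorted(pool, key=lambda f: -np.mean([base_mu[(h, f)] for h in habitats]))
        eligible = ranked[:max(n_needed, int(0.8 * len(ranked)))]
        idx = rng.permutation(len(eligible))
        return [eligible[i] for i in idx]

    enrich_cycle = [c for c in COHORTS if c in cohorts_present]
    pool_v = _eligible(features, cfg.n_planted_diff + cfg.n_planted_edges)
    pool_b = _eligible(bacteria, cfg.n_planted_diff_bacteria + cfg.n_planted_edges)
    for i, feat in enumerate(pool_v[:cfg.n_planted_diff]):
        truth.planted_diff_features[feat] = (enrich_cycle[i % len(enrich_cycle)],
                                             cfg.effect_fold)
    for i, feat in enumerate(pool_b[:cfg.n_planted_diff_bacteria]):
        truth.planted_diff_features[feat] = (enrich_cycle[i % len(enrich_cycle)],
                                             cfg.effect_fold)

    # planted virus-bacterium edges among the remaining (non-differential) slice
    free_v = pool_v[cfg.n_planted_diff:]
    free_b = pool_b[cfg.n_planted_diff_bacteria:]
    n_edges = min(cfg.n_planted_edges, len(free_v), len(free_b))
    edge_latents: dict[str, tuple[int, float]] = {}  # feature -> (latent idx, signed root-weight)
    for e in range(n_edges):
        sign = "positive" if e % 2 == 0 else "negative"
        truth.planted_edges.append((free_v[e], free_b[e], sign, cfg.edge_strength))
        w = np.sqrt(cfg.edge_strength)
        edge_latents[free_v[e]] = (e, w)
        edge_latents[free_b[e]] = (e, w if sign == "positive" else -w)

    sample_ids = manifest.sample_ids
    n = len(sample_ids)
    habitat_of = manifest.habitats().loc[sample_ids].to_numpy()
    cohort_of = manifest.cohorts(sample_ids).to_numpy()
    depth = np.exp(rng.normal(0.0, cfg.depth_log_sigma, size=n))
    latents = rng.normal(size=(n, max(n_edges, 1)))

    def _draw(ids: list[str]) -> pd.DataFrame:
        cols = {}
        for feat in ids:
            mu = np.array([base_mu[(h, feat)] for h in habitat_of]) * depth
            if feat in truth.planted_diff_features:
                cohort, fold = truth.planted_diff_features[feat]
                mu = np.where(cohort_of == cohort, mu * fold, mu)
            eps = rng.normal(size=n)
            if feat in edge_latents:
                idx, w = edge_latents[feat]
                a = w * latents[:, idx] + np.sqrt(1 - w * w) * eps
            else:
                a = eps
            u = stats.norm.cdf(a)
            cols[feat] = _nb_quantile_counts(u, mu, cfg.nb_dispersion)
        return pd.DataFrame(cols, index=sample_ids)

    virus_counts = _draw(features)
    bacteria_counts = _draw(bacteria)

    # clinical indices: cohort shift + planted taxon link + noise
    index_base = {"DAS28": (2.0, 2.5), "CDAI": (5.0, 15.0), "CRP": (3.0, 10.0),
                  "GH": (20.0, 30.0), "disease_activity": (1.0, 1.5),
                  "RA_duration": (0.0, 5.0)}
    link_pool = [f for f in free_v + free_b if f not in edge_latents] or free_v + free_b
    indices = {}
    all_counts = pd.concat([virus_counts, bacteria_counts], axis=1)
    for i, name in enumerate(cfg.clinical_indices):
        base, ra_shift = index_base.get(name, (0.0, 1.0))
        taxon = link_pool[i % len(link_pool)] if link_pool else None
        sign = "positive" if i % 2 == 0 else "negative"
        value = base + np.where(cohort_of == "HC", 0.0, ra_shift)
        value = value + rng.normal(0.0, 1.0, size=n) * max(ra_shift / 3.0, 0.5)
        if taxon is not None:
            z = np.log1p(all_counts[taxon].to_numpy(dtype=float) / depth)
            z = (z - z.mean()) / max(z.std(), 1e-9)
            scale = max(ra_shift, 1.0) * cfg.clinical_link_strength
            value = value + (scale if sign == "positive" else -scale) * z
            truth.planted_clinical_links.append((taxon, name, sign))
        indices[name] = np.round(value, 3)
    indices_df = pd.DataFrame(indices, index=sample_ids)
    return virus_counts, bacteria_counts, truth, indices_df


def attach_study_metadata(manifest: Manifest, virus_counts: pd.DataFrame,
                          indices: pd.DataFrame,
                          rng: Optional[np.random.Generator] = None,
                          seed: int = 0) -> Manifest:
    """Return a manifest with clinical indices and realistic read totals.

    ``total_hq_reads`` is set so that the virome captures roughly the
    habitat-typical fraction of each sample's high-quality reads.
    """
    rng = _rng(seed if rng is None else rng)
    mapped = virus_counts.sum(axis=1)
    records = []
    for rec in manifest:
        frac = _MAPPED_FRACTION.get(rec.habitat, 0.1)
        frac = float(np.clip(rng.normal(frac, frac / 4), 0.01, 0.9))
        covars = dict(rec.covariates)
        for name in indices.columns:
            covars[name] = float(indices.loc[rec.sample_id, name])
        records.append(replace(
            rec, total_hq_reads=int(mapped.loc[rec.sample_id] / frac),
            covariates=covars))
    return Manifest(records)


def simulate_protein_assignments(votu_ids: Sequence[str],
                                 rng: Optional[np.random.Generator] = None,
                                 classified_fraction: float = 0.55,
                                 seed: int = 0
                                 ) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Synthetic protein-to-family hit table for the taxonomy vote.

    A ``classified_fraction`` of vOTUs get a dominant planted family voted
    by more than one-third of their proteins; the rest receive scattered
    sub-threshold hits.  Returns (assignments frame, per-vOTU protein
    counts, planted family truth with "Unclassified" for the rest).
    """
    rng = _rng(seed if rng is None else rng)
    rows = []
    n_proteins = {}
    planted: dict[str, str] = {}
    for votu in votu_ids:
        n = int(rng.integers(6, 30))
        n_proteins[votu] = n
        if rng.random() < classified_fraction:
            fam = str(rng.choice(FAMILIES))
            planted[votu] = fam
            n_fam = int(rng.integers(n // 3 + 1, n + 1))  # strictly > 1/3
            for p in range(n_fam):
                rows.append((votu, f"{votu}_p{p}", fam, float(rng.uniform(60, 300))))
        else:
            planted[votu] = "Unclassified"
            n_hit = int(rng.integers(0, max(1, n // 3)))  # at most floor(n/3) - never > 1/3
            fams = rng.choice(FAMILIES, size=n_hit) if n_hit else []
            for p, fam in enumerate(fams):
                rows.append((votu, f"{votu}_p{p}", str(fam), float(rng.uniform(50, 120))))
    frame = pd.DataFrame(rows, columns=["votu_id", "protein_id", "family", "score"])
    return frame, pd.Series(n_proteins, name="n_proteins"), planted


@dataclass
class SyntheticStudy:
    """Bundle of all generated inputs plus recorded truth."""

    config: SimulationConfig
    contigs: dict[str, str]
    evidence: pd.DataFrame
    manifest: Manifest
    virus_counts: pd.DataFrame
    bacteria_counts: pd.DataFrame
    clinical_indices: pd.DataFrame
    feature_lengths: pd.Series
    truth: SyntheticTruth


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study, deterministic given cfg.seed.

    Count features are the true vOTU cliques; feature lengths are the seed
    genome (longest member) lengths, as a clustering run would report.
    """
    contigs, truth = simulate_contigs(cfg)
    lengths = {cid: len(seq) for cid, seq in contigs.items()}
    evidence = simulate_evidence(truth, noise=cfg.evidence_noise,
                                 rng=_rng(cfg.seed + 10), lengths=lengths)
    manifest = simulate_manifest(cfg)
    cliques = sorted({truth.clique_map[c] for c in truth.clique_map})
    virus_counts, bacteria_counts, truth2, indices = simulate_cohort_counts(
        cfg, manifest, cliques)
    truth.planted_diff_features = truth2.planted_diff_features
    truth.planted_edges = truth2.planted_edges
    truth.planted_clinical_links = truth2.planted_clinical_links
    manifest = attach_study_metadata(manifest, virus_counts, indices,
                                     rng=_rng(cfg.seed + 3))
    clique_len = pd.Series({
        clique: max(lengths[c] for c, q in truth.clique_map.items() if q == clique)
        for clique in cliques
    })
    return SyntheticStudy(cfg, contigs, evidence, manifest, virus_counts,
                          bacteria_counts, indices, clique_len, truth)


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Emit the exact on-disk formats the io layer reads."""
    from pathlib import Path

    from . import io_core

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_core.write_fasta(study.contigs, out / "contigs.fasta")
    study.evidence.to_csv(out / "evidence.tsv", sep="\t", index=False, na_rep="NA")
    io_core.write_manifest(study.manifest, out / "manifest.tsv")
    io_core.write_count_matrix(study.virus_counts, out / "virus_counts.tsv")
    io_core.write_count_matrix(study.bacteria_counts, out / "bacteria_counts.tsv")
    study.feature_lengths.rename("length").to_frame().to_csv(
        out / "feature_lengths.tsv", sep="\t", index_label="feature")
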