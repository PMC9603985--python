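# viromix

Whole-virome analysis of multi-habitat case/control metagenome cohorts.

Shotgun metagenomes of dental plaque, saliva and feces contain a large,
mostly unnamed viral fraction. `viromix` implements the full analysis
chain that turns assembled contigs plus per-contig evidence tables into
cohort-level virome biology for a three-cohort design (healthy controls,
untreated and drug-treated rheumatoid-arthritis patients):

1. **Viral identification** — a contig is viral when it satisfies any of
   three criteria: ≥50% of its proteins hit a viral protein reference
   (≥3 hits when it has <6 proteins), a sorter category in {1, 2, 4, 5},
   or a k-mer score >0.9 with *p* <0.05; contigs with a BUSCO ratio
   (bacterial single-copy orthologs / genes) ≥5% are removed as
   contaminated.
2. **vOTU construction** — greedy centroid clustering at ≥95% nucleotide
   identity and ≥80% coverage of the shorter sequence; the longest contig
   represents each viral operational taxonomic unit (vOTU).
3. **Taxonomy** — a vOTU gets the family that recruits >1/3 of its
   proteins (best BLASTP hit per protein, score ≥50).
4. **Abundance** — for vOTU *v* in sample *s* with assigned reads
   *r*<sub>vs</sub> and genome size *L*<sub>v</sub>, the relative
   abundance is (*r*<sub>vs</sub>/*L*<sub>v</sub>) / Σ<sub>v</sub>
   (*r*<sub>vs</sub>/*L*<sub>v</sub>); the mapped fraction is
   Σ<sub>v</sub> *r*<sub>vs</sub> / (high-quality reads in *s*).
5. **Diversity & ordination** — rarefied richness and Shannon index,
   Bray–Curtis dissimilarity, PCA, distance-based redundancy analysis
   (CAP axes), envfit, and PERMANOVA with Ezekiel-adjusted *R*².
6. **Differential screens** — Kruskal–Wallis across cohorts and pairwise
   Wilcoxon rank-sum on high-abundance taxa, Benjamini–Hochberg FDR.
7. **Networks** — FDR-controlled Spearman co-abundance edges between
   viruses and bacteria per cohort/habitat stratum, taxon–clinical-index
   networks, and adonis-style covariate effect sizes.
8. **Classification** — random-forest discrimination of cohort pairs from
   significant taxa, evaluated by leave-one-out cross-validated ROC/AUC.

A first-class synthetic-data generator (`viromix.synthetic`) emulates all
pipeline inputs — redundant contigs mutated from seed genomes, evidence
tables, negative-binomial count matrices with planted cohort effects,
virus–bacterium correlations and clinical links — with recorded ground
truth, so the whole pipeline is testable end-to-end without any external
sequencing data.

## Worked example

```bash
viromix --seed 5 simulate --out-dir sim/
viromix identify --evidence sim/evidence.tsv --out sim/calls.tsv
viromix cluster --contigs sim/contigs.fasta --keep sim/calls.tsv --out sim/votus.tsv
```

which prints, for the default synthetic study:

```
wrote synthetic study (96 contigs, 270 samples) to sim/
76 of 96 contigs retained
40 vOTUs from 76 contigs
```

96 contigs were generated from 40 seed genomes plus unrelated decoys; the
decision rule retains exactly the 76 planted viral contigs, and greedy
clustering collapses them back to the 40 seed genomes (one vOTU each).
The same stages are available as library calls; see
`viromix.diversity.permanova`, `viromix.networks.build_network`,
`viromix.classify.loocv_rf`, etc.

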