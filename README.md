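# triomic

Integrative analysis of gene expression along the cell cycle across three
layers of measurement: steady-state mRNA (microarray), translation
(nascent-chain proteomics, quantified per translating ribosome) and
steady-state protein (shotgun MS, quantified per unit protein mass).
`triomic` is for researchers who have synchronized-population measurements
of two or three of these layers and want to know *which* step of gene
expression — transcription, translation or protein turnover — drives the
periodicity of each gene.

## What it computes

**Protein-centric merge.** Translatome and proteome protein groups are
unioned; transcripts are attached through a probeset-to-accession map,
keeping per protein group the single probeset with the highest mean
expression ("maximum value" rule).

**Absolute quantification.** From a peptide table, iBAQ
(`sum of peptide intensities / number of theoretically observable tryptic
peptides`, fully tryptic 7–30 residues) and TOP3 (sum of the three most
intense peptides), both log2.

**Fold-change statistics.** For the cyclic transitions G2/M→G1, G1→S and
S→G2/M (labelled `G1_FC`, `S_FC`, `G2M_FC`):

    fc(g, r) = log2 x(g, entered phase, rep r) − mean_r log2 x(g, preceding phase)

with a minimum of 2 replicates behind every mean. Columns are Z-transformed
to unify dynamic range across platforms; a one-sample Student t-test per
gene and column with Benjamini–Hochberg control (FDR < 0.05) flags
significantly changing genes, and a 1.5-fold / 2-of-3-layers filter gives
the effect-size-based alternative.

**Correlation structure.** Spearman correlations computed per replicate
pairing and averaged; intra-platform replicate correlations r_xx give
disattenuated between-layer correlations `r / sqrt(r_xx · r_yy)`;
dynamic range, explained variance (R²) and average-linkage clustering of
the correlation matrix (distance 1 − r).

**Patterns and modes.** K-means (k = 10, k-means++, seeded) on the
9-dimensional mean-Z profile (3 layers × 3 transitions); hierarchical
clustering with correlation distance on untransformed fold-changes; and a
transparent rule cascade assigning each gene one regulatory mode —
concordant mitotic (A), mRNA-buffered (B), S-phase translational (C),
lagged protein accumulation (D), protein-stability-driven (E) — with
"active" meaning |mean Z| ≥ τ (default 1).

**Enrichment.** Protein stability score (mean log2 protein − mean log2
translation, the abundance-to-synthesis ratio); rank-based 1D enrichment
(Mann–Whitney, s = 2·AUC − 1 ∈ [−1, 1]) and Fisher's exact test, both at
FDR < 0.02.

**Synthetic ground truth.** A synthesis–degradation–dilution kinetic
simulator generates complete three-layer datasets: each gene has a periodic
transcription profile m(t), translation-efficiency profile TE(t) and
half-life t½; protein copies follow `dP/dt = share(t)·dM/dt − (ln2/t½)·P`
on a 14 h cycle whose total protein mass M(t) doubles with growth
concentrated in S-phase. Measurements emulate platform effects
(microarray gain compression, per-ribosome and per-mass normalization,
replicate noise, detection limits) and a peptide-level intensity table.
See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from triomic.synthetic_data import SimulationConfig, simulate, as_multiomic
from triomic.ingest import summarize_dataset
from triomic.correlate import correlation_matrix, dynamic_range
from triomic.cycle_stats import (fold_changes, zscore_columns,
                                 one_sample_test, significant_union_filter)
from triomic.patterns import classify_modes

sd, truth = simulate(SimulationConfig(n_genes=600, seed=1))
ds = as_multiomic(sd)
print(summarize_dataset(ds))
print({name: round(dynamic_range(lm), 2) for name, lm in ds.layers.items()})

fcm = zscore_columns(fold_changes(ds))
sig = significant_union_filter(one_sample_test(fcm, alpha=0.05))
print(f"{len(sig)} of {ds.n_genes} genes change significantly (FDR<0.05)")
print(classify_modes(fcm.profiles(use_z=True)).value_counts().to_dict())

cm = correlation_matrix(ds)
print(cm.r.loc["translation|G1", "protein|G1"], cm.r.loc["mRNA|G1", "protein|G1"])
```

prints

```
{'genes_total': 589, 'in_transcriptome': 589, 'in_translatome': 589,
 'in_proteome': 579, 'proteome_only': 0, 'combined': 589}
{'mRNA': 3.17, 'translation': 4.63, 'protein': 4.83}
237 of 589 genes change significantly (FDR<0.05)
{'unclassified': 381, 'lagged_protein': 52, 'protein_stability': 52,
 'translation_S': 46, 'mRNA_buffered': 31, 'concordant_mitotic': 27}
0.81  0.69
```

Reading the output: 589 of the 600 simulated genes survive the detection
limits and form the merged dataset. The measured dynamic range is smallest
for mRNA (gain-compressed microarray), larger for translation and largest
for protein, whose spread adds half-life variation on top of synthesis.
About 40% of genes change significantly somewhere in the cycle, and the
mode classifier splits the changers among the five regulatory modes
(the simulation's truth table says which calls are right — here 86% of the
A/C/D/E genes, with most misses caused by detection-limit censoring of
trough-phase protein). Translation predicts protein abundance better than mRNA
does (r_s 0.81 vs 0.69) because protein integrates synthesis, not
transcript level.

The same analysis runs from the shell:

```
triomic simulate --n-genes 600 --seed 1 --out data/
triomic run-all --synthetic --n-genes 600 --seed 1 --out results/
triomic merge --data data/      # layer-detection summary
triomic stats --data data/ --out stats.tsv
```

`run-all` writes fold-change, test, correlation, cluster/mode and
enrichment tables plus a `manifest.json` with a checksum per output;
rerunning with the same seed reproduces every file byte for byte.

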