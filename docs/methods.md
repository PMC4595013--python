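# Methods

## The analysis model

`triomic` treats a synchronized-population experiment as three matrices of
log2 abundances over a shared design (3 cell-cycle phases × replicates),
one per expression layer. The layers are deliberately *not* placed on a
common absolute scale for the core statistics: each platform measures a
different physical quantity (transcript hybridization signal, nascent
chains per translating ribosome, protein per unit extracted protein mass),
so cross-layer comparisons are made on within-platform fold-changes,
Z-transformed per sample column to unify dynamic range. This
normalization assumes the true biological ranges of the layers are
comparable; it can over-correct, which is why the 1.5-fold filter on
untransformed fold-changes is provided as the scale-free cross-check.

Fold-changes are defined on the cyclic transitions G2/M→G1 (`G1_FC`),
G1→S (`S_FC`) and S→G2/M (`G2M_FC`), per replicate, as the replicate's
log2 value in the entered phase minus the replicate-mean log2 value of the
preceding phase (means require ≥ 2 replicates). A consequence used as a
correctness oracle throughout: for a gene with complete data the three
mean fold-changes telescope to exactly zero.

The per-gene significance call is a one-sample Student t-test of the
replicate Z-values against zero, df = n − 1, two-sided, BH-adjusted within
each (layer, transition) column. The column-wise family matches how
matrix-analysis tools apply per-column FDR; a pooled single-family option
exists (`family="global"`). Because the preceding-phase mean is shared by
the replicates of a transition, replicate fold-changes are weakly
positively correlated and the test is mildly anti-conservative; the null
simulations below measure the realized union-filter rate directly
(≈ 0.2–0.5% of genes at α = 0.05, well under α) rather than assuming the
nominal level.

Disattenuation corrects an observed between-layer Spearman correlation for
platform unreliability: r' = r_xy / √(r_xx·r_yy) with r_xx the mean
pairwise Spearman among a platform's replicates, clipped to [−1, 1].
Between-layer correlations are computed separately per matched replicate
pair and averaged (replicate i against replicate i — replicates are
matched experimental batches; all-pairs averaging is available).

The regulatory-mode classifier is a transparent rule cascade on the
9-dimensional mean-Z profile, first match wins, with "up"/"down" = signed
crossing of ±τ (default τ = 1 Z-unit) and "inactive" = |Z| < τ at every
transition of a layer:

| mode | rule |
|---|---|
| concordant mitotic (A) | all 3 layers up at `G2M_FC` and down at `G1_FC` |
| mRNA-buffered (B) | mRNA up at `G2M_FC`, protein inactive everywhere |
| S-phase translational (C) | translation up at `S_FC` and down at `G2M_FC`, protein inactive |
| lagged protein (D) | mRNA and translation up at `G1_FC`, protein up at `S_FC` |
| protein stability (E) | protein up at `G2M_FC` or down at `S_FC`, mRNA and translation inactive |

A cascade was chosen over nearest-centroid matching because the published
pattern classes are described qualitatively, not parameterized; the
cascade makes every call auditable. Missing profile entries count as
inactive (no evidence of change); k-means clustering likewise imputes
missing entries to 0 by default (an exclusion mode exists), so cluster
sizes shift if that choice is changed.

## The kinetic simulator

The generator is a first-class package component: it produces the datasets
on which every pipeline stage is validated, with full ground truth.

**State model.** Each gene g has a periodic transcription profile m_g(t)
(baseline abundance μ_g times piecewise burst windows), a
translation-efficiency profile TE_g(t) (a constitutive per-gene level
times burst windows) and a half-life t½_g(t), possibly phase-dependent.
The cell's total protein mass is M(t) = 2^F(t), F piecewise-linear over
the phases with fractions 0.15/0.70/0.15 of the doubling placed in
G1/S/G2M — growth rises exponentially within each phase and fastest in S.
Global ribosome output is taken to track instantaneous mass production,
so gene-level synthesis flux is the gene's share of translational weight
times dM/dt:

    share_g(t) = m_g(t)·TE_g(t) / Σ_h m_h(t)·TE_h(t)
    dP_g/dt    = share_g(t)·dM/dt − (ln2 / t½_g(t))·P_g

with P_g halved at division. Writing the flux this way (rather than with a
free global synthesis constant) makes the dilution identity exact by
construction: a gene with constant share and no degradation has
P_g(t) = share_g·M(t) at the periodic steady state, so its per-mass signal
is flat while its copy number doubles — the growth-dilution buffering
effect the proteome normalization induces, for any shape of M(t).

**Integration.** Fixed-step classical Runge–Kutta (4th order) at
dt = 0.1 h on a 14 h cycle (G1 0–5 h, S 5–10 h, G2/M 10–14 h), iterated
over cycles with division halving until the phase-sampled protein vector
changes by < 1e−4 relative between consecutive cycles (error after at most
50 cycles). Stiff solvers are unnecessary at these rates and a fixed-step
scheme keeps runs bit-reproducible. Burst windows are step functions; the
integrator's accuracy loss at the discontinuities is far below measurement
noise.

**Measurement model.** Samples are taken mid-phase (2.5 / 7.5 / 12 h;
configurable) for each of 3 replicates:

* mRNA = γ·log2 m_g + ε, with gain γ = 0.6 emulating microarray
  dynamic-range compression (a simple log-scale gain; saturation curves
  are out of scope);
* translation = log2 share_g + ε (per-ribosome normalization; linear
  shares sum to 1 per sample before noise);
* protein = log2 (P_g / M) + ε (per-mass normalization — the dilution
  effect);
* ε ~ N(0, 0.25²) log2 units per value, independent across genes, samples
  and layers; per-layer detection limits censor the lowest 5% of MS values
  (0% for microarray).

Baseline abundances μ_g are log-normal with 2.6 log2-unit spread, chosen
so the translatome spans ≈ 5 orders of magnitude; constitutive TE_g is
log-normal with 1.5 log2-unit spread — without between-gene TE variation,
mRNA would predict protein as well as translation does, contrary to what
ribosome-density data show. Noise 0.25, γ = 0.6 and the 5% detection
quantile are engineering defaults representing a well-executed experiment.

**Archetypes.** Seven templates define the population: A (mRNA burst ×6 in
G2/M, t½ 1–1.5 h), B (same mRNA burst exactly compensated by a TE drop,
t½ 25–40 h), C (TE ×6 in S on flat mRNA, t½ 30–50 h), D (mRNA ×6 and TE
×2.5 in late G1 [2–6 h], t½ 8–12 h), E (flat synthesis, t½ 40–60 h outside
S destabilized to 0.8–1.2 h within S), histone (mRNA ×8 spanning the G1/S
boundary with translation gated to S-phase, t½ 80–120 h) and flat
(constitutive, t½ 5–50 h). Effect sizes were set by a class-separability
analysis at the fixed noise level and τ = 1: each archetype's defining
contrasts clear the threshold with margin while its "inactive" layers stay
inside it, and no single archetype dominates the Z-column spread. Early
template drafts failed to express their own definitions — an all-G1
induction makes protein peak *before* the mid-G1 sample rather than lag
into S, and a 20 h baseline half-life is already degradation-limited so an
S-phase destabilization barely moves it — which is why D's window is late
G1 and E's baseline half-life is long.

**Peptide emulation.** Protein sequences are synthetic chains of fully
cleavable tryptic blocks (interior residues exclude K/R/P), so observable
peptide counts are controlled by construction. Each peptide gets a fixed
log-normal ionization efficiency (σ = 1 natural-log unit); intensity =
copies × efficiency × per-sample depth factor, with a global 1% detection
floor. iBAQ on these tables recovers true copy ranking at Spearman ≥ 0.95
per sample.

## What the simulations do and do not show

The generator emulates platform dynamic-range differences, replicate
noise, abundance-dependent censoring, ribosome- and mass-normalization,
growth dilution and peptide-level quantification noise. It does **not**
emulate: partial synchrony and its phase-smearing, transcription bursting
or any single-cell stochasticity, between-replicate batch effects beyond
i.i.d. noise, shared-peptide protein-inference ambiguity, or
post-translational modification. Passing tests therefore demonstrate that
the pipeline's statistics and classifiers are correct and well calibrated
under a faithful bulk kinetic model — not that real data meet these
assumptions. Published headline gene counts from the original
experimental datasets are not reproduced here because that requires the
external microarray/proteome tables; the filters that would produce them
are implemented and validated on synthetic data.

Two measurement-design points matter when interpreting recovery numbers.
First, mode-recovery experiments disable the detection limit: with it on,
about a fifth of short-half-life archetype genes lose their entire
trough-phase protein measurements (their per-mass abundance falls below
the global cut), making their profiles incomplete — a censoring effect,
not a classification error; a dedicated test documents the censored
behavior separately. Second, class-level summaries (e.g. histone
buffering) are evaluated on across-gene means, matching how replicate
bar plots summarize a gene family.

## Numerical choices and degenerate inputs

* Missing values are NaN throughout; MS intensity 0 is converted to
  missing on read and never log-transformed.
* Spearman/Pearson need ≥ 3 complete pairs, else NaN with a warning;
  zero-variance vectors give NaN.
* Z-transformation raises on zero-spread columns; the t-test flags
  zero-spread replicate sets as degenerate (no p) instead of emitting
  infinities.
* BH q-values: NaN p-values pass through; out-of-range p is an error.
* Fisher odds ratios add 0.5 to all cells only when a zero cell occurs,
  and the row is flagged.
* The "maximum value" probeset rule breaks exact mean ties by smallest
  probeset id, making the merge invariant to id-map row order.
* K-means uses k-means++ with a fixed seed and 10 restarts; correlation
  dendrograms sort labels before linkage so leaf order is deterministic.
* Pipeline stage seeds are spawned from the single run seed via
  `numpy.random.SeedSequence`, so stages are individually reproducible.

## Problem sizes

Validation simulations use 300–1000 genes: large enough that Z-columns,
FDR families and rank statistics are in their asymptotic regime, small
enough that the full suite and the acceptance script each run in seconds.
Recovery and calibration results are stable across seeds at these sizes
(mode recovery 91–97% across seeds at the reference noise level).

## Known limitations

* Phase labels are metadata supplied by the user's sample sheet; the
  package never infers phase from harvest timepoints (published
  time-to-phase mappings for this design disagree between sources).
* The 1.5-fold filter's "2 of 3 layers" condition is evaluated within a
  single transition; a variant requiring layers across different
  transitions would be weaker and is not implemented (set
  `min_layers=1` for the any-layer reading).
* Whether R² should be squared Pearson or squared Spearman is
  platform-convention dependent; both are exposed, Pearson² on log values
  is the default.
* 1D enrichment uses the normal approximation of the Mann–Whitney U with
  tie correction; exact p-values for very small terms are not implemented
  (terms under the minimum size are skipped instead).
* The stability score is a relative, within-dataset quantity; it orders
  proteins by turnover but does not estimate absolute half-lives.
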