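"""Synthetic three-layer cell-cycle datasets with known kinetic ground truth.

Genes are simulated from a synthesis-degradation-dilution model on a
repeating cell cycle.  Each gene g carries a periodic transcription profile
m_g(t), a periodic translation-efficiency profile TE_g(t) and a (possibly
phase-dependent) protein half-life t1/2_g.  The cell's total protein mass
M(t) doubles once per cycle, rising fastest during S-phase, and halves at
division.  Global ribosome output tracks mass growth, so the synthesis flux
of gene g is its share of translational weight times the instantaneous mass
production rate:

    share_g(t) = m_g(t) TE_g(t) / sum_h m_h(t) TE_h(t)
    dP_g/dt    = share_g(t) dM/dt - (ln 2 / t1/2_g(t)) P_g,   P_g -> P_g/2 at division

integrated to a periodic steady state.  Measurements mimic the three
platforms: microarray mRNA is gain-compressed log2 m_g; the translatome is
the log2 synthesis share (per-ribosome normalization); the proteome is
log2 P_g / M(t) (per-mass normalization -- the dilution effect that hides
S-phase protein accumulation).  Replicate noise, platform detection limits
and a peptide-level intensity table complete the emulation.

This construction makes the buffering phenomena exact rather than tuned: a
gene with a constant share and no degradation has P_g(t) proportional to
M(t) at steady state, so its per-mass abundance is flat even though its
copy number doubles every cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import LayerMatrix, MultiOmicDataset, SampleDescriptor, make_samples
from .ingest import write_expression_table
from .quantify import DigestParams, digest

__all__ = [
    "ArchetypeTemplate",
    "archetype_library",
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate",
    "as_multiomic",
    "make_protein_sequences",
    "make_peptide_table",
    "write_dataset",
]

LN2 = float(np.log(2.0))

#: residues used for synthetic protein interiors -- no K/R (cleavage sites
#: are appended explicitly) and no P (keeps every site cleavable)
_INTERIOR_ALPHABET = "ACDEFGHILMNQSTVWY"


@dataclass(frozen=True)
class ArchetypeTemplate:
    """Kinetic parameter template for one expression archetype.

    Bursts are ``(start_h, end_h, fold)`` windows multiplying the baseline
    profile inside ``[start, end)``; half-lives are drawn log-uniformly from
    ``half_life_h``.  ``s_half_life_h``, when set, overrides the half-life
    during S-phase (phase-dependent degradation).
    """

    name: str
    mrna_bursts: tuple[tuple[float, float, float], ...] = ()
    te_bursts: tuple[tuple[float, float, float], ...] = ()
    te_baseline: float = 1.0
    half_life_h: tuple[float, float] = (5.0, 50.0)
    s_half_life_h: tuple[float, float] | None = None
    notes: str = ""


def archetype_library() -> dict[str, ArchetypeTemplate]:
    """The seven named archetypes.

    A  concordant mitotic induction: mRNA burst in G2/M, flat TE, short
       half-life so the protein tracks synthesis into and out of mitosis.
    B  buffered mitotic mRNA: the G2/M mRNA burst is cancelled by a
       reciprocal TE drop; long half-life keeps the protein flat.
    C  S-phase translational burst on flat mRNA; long half-life means the
       extra synthesis is absorbed by cell growth (dilution buffering).
    D  late-G1 mRNA+TE induction with a moderate half-life: protein
       accumulation lags the synthesis burst and peaks in S-phase.
    E  constant synthesis, stable protein outside S but strongly
       destabilized during S: cycling happens purely at the level of
       protein stability.
    histone  mRNA rises at the G1/S boundary but translation is gated to
       S-phase (SLBP-dependent); near-infinite half-life plus dilution keeps
       measured protein flat.
    flat  constitutive control genes.
    """
    return {
        "A": ArchetypeTemplate(
            "A", mrna_bursts=((10.0, 14.0, 6.0),), half_life_h=(1.0, 1.5),
            notes="concordant mitotic",
        ),
        "B": ArchetypeTemplate(
            "B", mrna_bursts=((10.0, 14.0, 6.0),), te_bursts=((10.0, 14.0, 1.0 / 6.0),),
            half_life_h=(25.0, 40.0), notes="mRNA buffered",
        ),
        "C": ArchetypeTemplate(
            "C", te_bursts=((5.0, 10.0, 6.0),), half_life_h=(30.0, 50.0),
            notes="S-phase translation",
        ),
        "D": ArchetypeTemplate(
            "D", mrna_bursts=((2.0, 6.0, 6.0),), te_bursts=((2.0, 6.0, 2.5),),
            half_life_h=(8.0, 12.0), notes="lagged protein accumulation",
        ),
        "E": ArchetypeTemplate(
            "E", half_life_h=(40.0, 60.0), s_half_life_h=(0.8, 1.2),
            notes="protein stability",
        ),
        "histone": ArchetypeTemplate(
            "histone", mrna_bursts=((4.0, 10.0, 8.0),), te_baseline=0.25,
            te_bursts=((5.0, 10.0, 4.0),), half_life_h=(80.0, 120.0),
            notes="replication-coupled histone",
        ),
        "flat": ArchetypeTemplate("flat", notes="constitutive"),
    }


def _default_mix() -> dict[str, float]:
    return {"A": 0.05, "B": 0.05, "C": 0.05, "D": 0.10, "E": 0.10, "histone": 0.05, "flat": 0.60}


def _default_detection() -> dict[str, float]:
    return {"mRNA": 0.0, "translation": 0.05, "protein": 0.05}


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults emulate the triplicate three-phase design: a 14 h cycle split
    G1 5 h / S 5 h / G2M 4 h sampled mid-phase, 0.25 log2 units of replicate
    noise per layer, a 0.6 microarray gain (dynamic-range compression), a 5%
    detection limit on the MS layers, and 70% of cell mass gain placed in
    S-phase.  Baseline abundances are log-normal with a 2.6 log2-unit spread
    so the translatome spans roughly five orders of magnitude.
    """

    n_genes: int = 600
    archetype_mix: dict[str, float] = field(default_factory=_default_mix)
    n_replicates: int = 3
    noise_sd: float = 0.25
    microarray_gain: float = 0.6
    detection_quantile: dict[str, float] = field(default_factory=_default_detection)
    cycle_h: float = 14.0
    phase_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"G1": (0.0, 5.0), "S": (5.0, 10.0), "G2M": (10.0, 14.0)}
    )
    sample_times: dict[str, float] | None = None  # default: mid-phase
    growth_fractions: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.15, "S": 0.70, "G2M": 0.15}
    )
    abundance_log2_sd: float = 2.6
    te_log2_sd: float = 1.5
    half_life_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    dt: float = 0.1
    steady_state_tol: float = 1e-4
    max_cycles: int = 50
    mrna_intercept: float = 7.0
    ms_intercept: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions must sum to 1, got {total}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.microarray_gain <= 1):
            raise ValueError("microarray_gain must lie in (0, 1]")
        if abs(sum(self.growth_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("growth fractions must sum to 1 (mass doubles once per cycle)")
        if self.sample_times is None:
            self.sample_times = {
                p: (a + b) / 2.0 for p, (a, b) in self.phase_bounds.items()
            }


@dataclass
class SyntheticTruth:
    """Per-gene generative parameters and noise-free sampled quantities."""

    params: pd.DataFrame  # gene x {archetype, mu, half_life_h, s_half_life_h}
    protein_copies: pd.DataFrame  # gene x phase, periodic-steady-state copies
    synthesis_share: pd.DataFrame  # gene x phase, fraction of ribosome output
    mrna_level: pd.DataFrame  # gene x phase, linear relative mRNA
    mass: pd.Series  # phase -> total protein mass M(t_sample)
    cycles_to_converge: int


@dataclass
class SyntheticDataset:
    layers: dict[str, LayerMatrix]
    annotations: pd.DataFrame  # tidy (gene, term) table of archetype pseudo-terms
    config: SimulationConfig


# --------------------------------------------------------------------------
# profile construction


def _burst_profile(t: np.ndarray, bursts, baseline: float = 1.0) -> np.ndarray:
    prof = np.full_like(t, baseline, dtype=float)
    for start, end, fold in bursts:
        prof[(t >= start) & (t < end)] = baseline * fold
    return prof


def _assign_archetypes(config: SimulationConfig) -> list[str]:
    """Deterministic block assignment honoring the mix fractions exactly."""
    names = sorted(config.archetype_mix)
    raw = {a: config.archetype_mix[a] * config.n_genes for a in names}
    counts = {a: int(np.floor(raw[a])) for a in names}
    short = config.n_genes - sum(counts.values())
    for a in sorted(names, key=lambda a: raw[a] - counts[a], reverse=True)[:short]:
        counts[a] += 1
    out: list[str] = []
    for a in names:
        out.extend([a] * counts[a])
    return out


def _growth_curve(config: SimulationConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """M(t) = 2**F(t) with F piecewise linear per phase; returns (M, dM/dt)."""
    frac_rate = np.zeros_like(t)
    F = np.zeros_like(t)
    acc = 0.0
    for phase in ("G1", "S", "G2M"):
        a, b = config.phase_bounds[phase]
        rate = config.growth_fractions[phase] / (b - a)
        sel = (t >= a) & (t < b)
        frac_rate[sel] = rate
        F[sel] = acc + (t[sel] - a) * rate
        acc += config.growth_fractions[phase]
    F[t >= config.phase_bounds["G2M"][1]] = 1.0
    frac_rate[t >= config.phase_bounds["G2M"][1]] = (
        config.growth_fractions["G2M"]
        / (config.phase_bounds["G2M"][1] - config.phase_bounds["G2M"][0])
    )
    M = np.exp2(F)
    dM = LN2 * frac_rate * M
    return M, dM


def simulate(config: SimulationConfig) -> tuple[SyntheticDataset, SyntheticTruth]:
    """Run the kinetic model and emit a measured three-layer dataset.

    All randomness derives from ``config.seed``.  Raises ``RuntimeError``
    when the protein profiles fail to reach a periodic steady state within
    ``max_cycles`` cycles.
    """
    rng = np.random.default_rng(config.seed)
    lib = archetype_library()
    archetypes = _assign_archetypes(config)
    n = config.n_genes
    genes = pd.Index([f"SYN{i + 1:05d}" for i in range(n)], name="gene")

    mu = np.exp2(rng.normal(0.0, config.abundance_log2_sd, size=n))
    # constitutive per-gene translation efficiency: decouples mRNA abundance
    # from synthesis (and hence protein), as ribosome-density data show
    te_gene = np.exp2(rng.normal(0.0, config.te_log2_sd, size=n))
    half_life = np.empty(n)
    s_half_life = np.full(n, np.nan)
    for i, a in enumerate(archetypes):
        lo, hi = config.half_life_overrides.get(a, lib[a].half_life_h)
        half_life[i] = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        if lib[a].s_half_life_h is not None:
            slo, shi = lib[a].s_half_life_h
            s_half_life[i] = np.exp(rng.uniform(np.log(slo), np.log(shi)))

    # half-step time grid for the fixed-step RK4 integrator
    dt = config.dt
    n_steps = int(round(config.cycle_h / dt))
    t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)
    t_full = t_half[::2]

    m_prof = np.empty((n, t_half.size))
    te_prof = np.empty((n, t_half.size))
    delta = np.empty((n, t_half.size))
    s_a, s_b = config.phase_bounds["S"]
    in_s = (t_half >= s_a) & (t_half < s_b)
    for i, a in enumerate(archetypes):
        tpl = lib[a]
        m_prof[i] = mu[i] * _burst_profile(t_half, tpl.mrna_bursts)
        te_prof[i] = te_gene[i] * _burst_profile(t_half, tpl.te_bursts, baseline=tpl.te_baseline)
        hl = np.full(t_half.size, half_life[i])
        if np.isfinite(s_half_life[i]):
            hl[in_s] = s_half_life[i]
        delta[i] = LN2 / hl

    w = m_prof * te_prof
    share = w / w.sum(axis=0, keepdims=True)
    M, dM = _growth_curve(config, t_half)
    flux = share * dM[None, :]

    # integrate to the periodic steady state (division halves P at cycle end)
    P = flux.mean(axis=1) * config.cycle_h  # rough scale of one cycle's synthesis
    sample_idx_full = {
        p: int(round(t / dt)) for p, t in config.sample_times.items()
    }
    prev_sample = None
    cycles = 0
    traj = np.empty((n, n_steps + 1))
    for cycles in range(1, config.max_cycles + 1):
        traj[:, 0] = P
        for s in range(n_steps):
            i0, i1, i2 = 2 * s, 2 * s + 1, 2 * s + 2
            k1 = flux[:, i0] - delta[:, i0] * P
            k2 = flux[:, i1] - delta[:, i1] * (P + 0.5 * dt * k1)
            k3 = flux[:, i1] - delta[:, i1] * (P + 0.5 * dt * k2)
            k4 = flux[:, i2] - delta[:, i2] * (P + dt * k3)
            P = np.maximum(P + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
            traj[:, s + 1] = P
        sampled = traj[:, sorted(sample_idx_full.values())]
        if prev_sample is not None:
            rel = np.max(np.abs(sampled - prev_sample) / (np.abs(prev_sample) + 1e-300))
            if rel < config.steady_state_tol:
                break
        prev_sample = sampled
        P = P / 2.0  # division
    else:
        raise RuntimeError(
            f"no periodic steady state after {config.max_cycles} cycles "
            f"(last relative change {rel:.3g}); check half-lives vs cycle length"
        )

    phases = list(config.phase_bounds)
    copies = pd.DataFrame(
        {p: traj[:, sample_idx_full[p]] for p in phases}, index=genes
    )
    share_s = pd.DataFrame(
        {p: share[:, 2 * sample_idx_full[p]] for p in phases}, index=genes
    )
    mrna_s = pd.DataFrame(
        {p: m_prof[:, 2 * sample_idx_full[p]] for p in phases}, index=genes
    )
    mass = pd.Series({p: M[2 * sample_idx_full[p]] for p in phases})

    # noise-free log2 signals per layer
    signal = {
        "mRNA": config.mrna_intercept + config.microarray_gain * np.log2(mrna_s),
        "translation": config.ms_intercept + np.log2(share_s),
        "protein": config.ms_intercept + np.log2(copies.div(mass, axis=1)),
    }

    layers: dict[str, LayerMatrix] = {}
    for layer, clean in signal.items():
        samples = make_samples(
            layer, phases, range(1, config.n_replicates + 1), timepoints=config.sample_times
        )
        cols = {}
        for s in samples:
            noise = rng.normal(0.0, config.noise_sd, size=n)
            cols[s.label] = clean[s.phase].to_numpy() + noise
        values = pd.DataFrame(cols, index=genes)
        q = config.detection_quantile.get(layer, 0.0)
        if q > 0:
            cut = np.nanquantile(values.to_numpy(), q)
            values = values.where(values >= cut)
        layers[layer] = LayerMatrix(
            values=values,
            samples=samples,
            scale="log2",
            quant_scheme={"mRNA": "RMA", "translation": "iBAQ", "protein": "iBAQ"}[layer],
        )

    params = pd.DataFrame(
        {
            "archetype": archetypes,
            "mu": mu,
            "te": te_gene,
            "half_life_h": half_life,
            "s_half_life_h": s_half_life,
        },
        index=genes,
    )
    annotations = pd.DataFrame(
        {"gene": genes, "term": [f"archetype_{a}" for a in archetypes]}
    )
    truth = SyntheticTruth(
        params=params,
        protein_copies=copies,
        synthesis_share=share_s,
        mrna_level=mrna_s,
        mass=mass,
        cycles_to_converge=cycles,
    )
    return SyntheticDataset(layers=layers, annotations=annotations, config=config), truth


def as_multiomic(sd: SyntheticDataset) -> MultiOmicDataset:
    """View a synthetic dataset as a merged protein-centric dataset.

    Synthetic layers already share one gene index; genes undetected in both
    MS layers are dropped (the union rule).
    """
    trans_det = sd.layers["translation"].values.notna().any(axis=1)
    prot_det = sd.layers["protein"].values.notna().any(axis=1)
    keep = sd.layers["translation"].gene_ids[trans_det | prot_det]
    provenance = pd.DataFrame(
        {
            "in_transcriptome": sd.layers["mRNA"].values.reindex(keep).notna().any(axis=1),
            "in_translatome": trans_det.reindex(keep),
            "in_proteome": prot_det.reindex(keep),
        },
        index=keep,
    )
    return MultiOmicDataset(
        gene_index=keep,
        layers={name: lm.reindexed(keep) for name, lm in sd.layers.items()},
        provenance=provenance,
    )


# --------------------------------------------------------------------------
# peptide-level emulation


def make_protein_sequences(
    gene_ids,
    seed: int = 0,
    n_peptides: tuple[int, int] = (12, 30),
    peptide_len: tuple[int, int] = (7, 25),
) -> dict[str, str]:
    """Random tryptic-friendly protein sequences with controlled peptide counts.

    Synthetic stand-ins for a sequence database: each protein is a chain of
    fully-cleavable tryptic blocks (interior residues exclude K/R/P), so the
    theoretically observable peptide count is known by construction.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(_INTERIOR_ALPHABET))
    seqs: dict[str, str] = {}
    for gid in gene_ids:
        k = int(rng.integers(n_peptides[0], n_peptides[1] + 1))
        blocks = []
        for _ in range(k):
            ln = int(rng.integers(peptide_len[0], peptide_len[1] + 1))
            body = "".join(rng.choice(letters, size=ln - 1))
            blocks.append(body + ("K" if rng.random() < 0.5 else "R"))
        seqs[str(gid)] = "".join(blocks)
    return seqs


def make_peptide_table(
    truth: SyntheticTruth,
    sequences: dict[str, str],
    config: SimulationConfig,
    seed: int | None = None,
    ionization_log_sd: float = 1.0,
    depth_log2_sd: float = 0.2,
    copy_noise_sd: float = 0.1,
    detection_quantile: float = 0.01,
    params: DigestParams = DigestParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide intensity table derived from true protein copy numbers.

    Each observable tryptic peptide receives a fixed log-normal ionization
    efficiency; intensity = copies x efficiency x per-sample depth factor.
    Peptides below the global detection quantile are dropped.  Returns
    ``(peptide_table, realized_copies)`` where the second frame holds the
    per-sample copy numbers (including replicate noise) the intensities were
    generated from -- the oracle for quantification tests.
    """
    rng = np.random.default_rng(config.seed + 101 if seed is None else seed)
    genes = [g for g in truth.protein_copies.index if g in sequences]
    phases = list(truth.protein_copies.columns)
    sample_cols = [
        f"{p}_{r}" for p in phases for r in range(1, config.n_replicates + 1)
    ]

    copies = {}
    for col in sample_cols:
        phase = col.rsplit("_", 1)[0]
        noise = np.exp2(rng.normal(0.0, copy_noise_sd, size=len(genes)))
        copies[col] = truth.protein_copies.loc[genes, phase].to_numpy() * noise
    realized = pd.DataFrame(copies, index=pd.Index(genes, name="gene"))

    depth = np.exp2(rng.normal(0.0, depth_log2_sd, size=len(sample_cols)))
    rows = []
    for gi, g in enumerate(genes):
        peps = [
            p
            for p in digest(sequences[g], params)
            if params.min_len <= len(p) <= params.max_len
        ]
        eff = np.exp(rng.normal(0.0, ionization_log_sd, size=len(peps)))
        gene_copies = realized.iloc[gi].to_numpy()
        if (gene_copies <= 0).all():
            continue
        inten = np.outer(eff, gene_copies * depth)
        for pi, pep in enumerate(peps):
            rows.append((pep, g, *inten[pi]))
    table = pd.DataFrame(rows, columns=["peptide", "protein", *sample_cols])

    vals = table[sample_cols].to_numpy()
    if detection_quantile > 0 and vals.size:
        cut = np.quantile(vals[vals > 0], detection_quantile)
        table[sample_cols] = np.where(vals >= cut, vals, 0.0)
    return table, realized


def write_dataset(
    sd: SyntheticDataset,
    outdir: str | Path,
    peptides: pd.DataFrame | None = None,
    sequences: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write a synthetic dataset in the exact formats the ingest module reads.

    Emits per-layer TSV expression tables, a YAML sample sheet, an identity
    probeset-to-accession map, a GMT file of archetype pseudo-terms, and
    optionally a MaxQuant-style peptide table and FASTA.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sheet = []
    for name, lm in sd.layers.items():
        p = outdir / f"{name}.tsv"
        write_expression_table(lm, p)
        paths[name] = p
        for s in lm.samples:
            sheet.append(
                {
                    "column": s.label,
                    "layer": s.layer,
                    "phase": s.phase,
                    "replicate": s.replicate,
                    "timepoint_h": s.timepoint_h,
                }
            )
    paths["sample_sheet"] = outdir / "sample_sheet.yaml"
    paths["sample_sheet"].write_text(yaml.safe_dump(sheet, sort_keys=False))

    genes = sd.layers["mRNA"].gene_ids
    idmap = pd.DataFrame({"probeset_id": genes, "protein_group_id": genes})
    paths["idmap"] = outdir / "idmap.tsv"
    idmap.to_csv(paths["idmap"], sep="\t", index=False)

    term_sets: dict[str, set] = {
        term: set(grp["gene"]) for term, grp in sd.annotations.groupby("term")
    }
    from .enrich import write_gmt

    paths["annotations"] = outdir / "archetypes.gmt"
    write_gmt(term_sets, paths["annotations"], description="synthetic archetype")

    if peptides is not None:
        paths["peptides"] = outdir / "peptides.txt"
        mq = peptides.rename(columns={"peptide": "Sequence", "protein": "Leading razor protein"})
        mq.columns = [
            c if c in ("Sequence", "Leading razor protein") else f"Intensity {c}"
            for c in mq.columns
        ]
        mq.to_csv(paths["peptides"], sep="\t", index=False, float_format="%.6g")
    if sequences is not None:
        paths["fasta"] = outdir / "proteins.fasta"
        lines = [f">{acc}\n{seq}" for acc, seq in sorted(sequences.items())]
        paths["fasta"].write_text("\n".join(lines) + "\n")
    return paths
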