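"""Core data containers shared across the pipeline.

The pipeline is protein-centric: every layer (mRNA, translation, protein) is
ultimately re-indexed onto protein-group accessions so that the three kinds of
measurement can be compared gene by gene.  Values are kept as log2 abundances
in pandas DataFrames (genes x samples); NaN marks a missing measurement and is
never conflated with zero intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The three expression layers, in pipeline order.
LAYERS = ("mRNA", "translation", "protein")

#: Cell-cycle phases in cyclic order G1 -> S -> G2M -> G1.
PHASES = ("G1", "S", "G2M")

#: Phase-to-phase transitions.  Each label names the phase being *entered*:
#: G1_FC is the G2/M-to-G1 transition, S_FC is G1-to-S, G2M_FC is S-to-G2/M.
TRANSITIONS = ("G1_FC", "S_FC", "G2M_FC")

#: transition label -> (preceding phase, entered phase)
TRANSITION_PHASES = {
    "G1_FC": ("G2M", "G1"),
    "S_FC": ("G1", "S"),
    "G2M_FC": ("S", "G2M"),
}


@dataclass(frozen=True)
class SampleDescriptor:
    """Identity of one measured sample within a layer.

    ``(layer, phase, replicate)`` must be unique within a dataset; the
    timepoint is carried as optional metadata only and is never used to infer
    the phase (published time-to-phase mappings for this design are
    inconsistent, so phase labels always come from the user's sample sheet).
    """

    layer: str
    phase: str
    replicate: int
    timepoint_h: float | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if int(self.replicate) < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.layer, self.phase, self.replicate)

    @property
    def label(self) -> str:
        """Column label used in tables: ``layer|phase|rep<k>``."""
        return f"{self.layer}|{self.phase}|rep{self.replicate}"


@dataclass
class LayerMatrix:
    """One expression layer as a genes x samples matrix of abundances.

    values
        DataFrame indexed by gene/protein-group id, one column per sample
        (columns are the ``SampleDescriptor.label`` strings, in the order of
        ``samples``).  NaN = missing.
    scale
        "log2" or "linear".
    quant_scheme
        Provenance of the numbers: RMA, LFQ, iBAQ, TOP3 or raw.
    group_ids
        Optional full protein-group strings (e.g. semicolon-joined accession
        lists) keyed by the primary accession used in ``values.index``.
    flags
        Optional boolean gene x sample DataFrame of quality flags (used by
        TOP3 to mark low-evidence quantifications).
    """

    values: pd.DataFrame
    samples: list[SampleDescriptor]
    scale: str = "log2"
    quant_scheme: str = "raw"
    group_ids: pd.Series | None = None
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        if self.values.shape[1] != len(self.samples):
            raise ValueError(
                f"{self.values.shape[1]} value columns but {len(self.samples)} sample descriptors"
            )
        dup = self.values.index[self.values.index.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicated gene ids: {', '.join(map(str, dup[:10]))}")
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicated (layer, phase, replicate) sample descriptors")
        self.values.columns = [s.label for s in self.samples]

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def layer(self) -> str:
        return self.samples[0].layer if self.samples else ""

    def columns_for(self, phase: str | None = None, replicate: int | None = None) -> list[str]:
        """Labels of samples matching the given phase and/or replicate."""
        out = []
        for s in self.samples:
            if phase is not None and s.phase != phase:
                continue
            if replicate is not None and s.replicate != replicate:
                continue
            out.append(s.label)
        return out

    def replicates(self) -> list[int]:
        return sorted({s.replicate for s in self.samples})

    def to_linear(self) -> "LayerMatrix":
        if self.scale == "linear":
            return self
        return replace(self, values=np.exp2(self.values), scale="linear")

    def to_log2(self) -> "LayerMatrix":
        if self.scale == "log2":
            return self
        vals = self.values.where(self.values > 0)
        return replace(self, values=np.log2(vals), scale="log2")

    def reindexed(self, gene_index: pd.Index) -> "LayerMatrix":
        """Return a copy aligned onto ``gene_index`` (absent genes -> NaN rows)."""
        return replace(self, values=self.values.reindex(gene_index))


@dataclass
class MultiOmicDataset:
    """Protein-centric alignment of the three layers on a shared gene index.

    Invariant (union rule): every gene in ``gene_index`` was detected in the
    translatome or the proteome; the transcriptome is mapped on top and may be
    missing per gene.
    """

    gene_index: pd.Index
    layers: dict[str, LayerMatrix]
    provenance: pd.DataFrame  # boolean columns in_transcriptome/in_translatome/in_proteome

    def __post_init__(self) -> None:
        for name, lm in self.layers.items():
            if not lm.values.index.equals(self.gene_index):
                raise ValueError(f"layer {name!r} is not aligned to gene_index")
        need = {"in_transcriptome", "in_translatome", "in_proteome"}
        if not need.issubset(self.provenance.columns):
            raise ValueError(f"provenance must have columns {sorted(need)}")
        union_ok = (self.provenance["in_translatome"] | self.provenance["in_proteome"]).all()
        if len(self.gene_index) and not union_ok:
            raise ValueError("union rule violated: gene in neither translatome nor proteome")

    def layer(self, name: str) -> LayerMatrix:
        return self.layers[name]

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)


@dataclass
class FoldChangeMatrix:
    """Per-gene log2 fold-changes for the three cyclic phase transitions.

    fc
        genes x (layer, transition, replicate) per-replicate log2 fold-changes
        (value in the entered phase minus the mean of the preceding phase).
    z
        the same table after per-column Z-transformation (None until
        ``zscore_columns`` has run).
    mean_fc / mean_z
        genes x (layer, transition) replicate means, NaN when fewer than
        ``min_reps`` replicate values were available.
    n
        genes x (layer, transition) count of replicate fold-changes present.
    """

    fc: pd.DataFrame
    mean_fc: pd.DataFrame
    n: pd.DataFrame
    z: pd.DataFrame | None = None
    mean_z: pd.DataFrame | None = None
    min_reps: int = 2

    @property
    def gene_index(self) -> pd.Index:
        return self.mean_fc.index

    def profiles(self, use_z: bool = True) -> pd.DataFrame:
        """Per-gene 9-dimensional (layer x transition) mean profile matrix."""
        mat = self.mean_z if use_z else self.mean_fc
        if mat is None:
            raise ValueError("Z-transformed values requested but zscore_columns has not run")
        cols = [(l, t) for l in LAYERS for t in TRANSITIONS if (l, t) in mat.columns]
        return mat.loc[:, cols]


def make_samples(
    layer: str,
    phases: Sequence[str] = PHASES,
    replicates: Iterable[int] = (1, 2, 3),
    timepoints: dict[str, float] | None = None,
) -> list[SampleDescriptor]:
    """Build the standard phase x replicate sample grid for one layer."""
    return [
        SampleDescriptor(
            layer, p, r, timepoint_h=None if timepoints is None else timepoints.get(p)
        )
        for p in phases
        for r in replicates
    ]
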