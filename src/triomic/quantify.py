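"""Peptide-to-protein absolute quantification: digestion, iBAQ, TOP3.

iBAQ divides a protein's summed peptide intensity by its number of
theoretically observable tryptic peptides, giving a quantity proportional to
copy number; TOP3 sums the three most intense peptides.  Both operate on a
MaxQuant-dialect peptide table and return log2 :class:`LayerMatrix` objects.
A simple total-intensity column normalization is provided for datasets
without LFQ columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import LayerMatrix, SampleDescriptor

__all__ = [
    "DigestParams",
    "digest",
    "observable_count",
    "read_peptide_table",
    "read_fasta",
    "ibaq",
    "top3",
    "total_intensity_normalize",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

# trypsin: cleave C-terminal to K or R, except when the next residue is P
_TRYPSIN_SITE = re.compile(r"(?<=[KR])(?!P)")


@dataclass(frozen=True)
class DigestParams:
    """In-silico digestion settings.

    ``min_len``/``max_len`` bound the peptides counted as MS-observable in
    the iBAQ denominator (default 7-30 residues, fully tryptic).
    """

    enzyme: str = "trypsin"
    missed_cleavages: int = 0
    min_len: int = 7
    max_len: int = 30

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


def _validate_sequence(sequence: str) -> None:
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue characters: {sorted(bad)}")


def digest(sequence: str, params: DigestParams = DigestParams()) -> list[str]:
    """Tryptic digest of ``sequence``.

    Cleaves C-terminal to K/R unless followed by P.  With ``missed_cleavages
    = m``, concatenations of up to ``m + 1`` adjacent fully-cleaved fragments
    are also emitted.  Peptides are returned grouped by span length and in
    N-to-C order within each span; duplicates are allowed.
    """
    _validate_sequence(sequence)
    if not sequence:
        return []
    frags = [f for f in _TRYPSIN_SITE.split(sequence) if f]
    out: list[str] = []
    for span in range(1, params.missed_cleavages + 2):
        for start in range(0, len(frags) - span + 1):
            out.append("".join(frags[start : start + span]))
    return out


def observable_count(sequence: str, params: DigestParams = DigestParams()) -> int:
    """Number of distinct fully-cleaved peptides within the observable window."""
    fully = digest(sequence, replace(params, missed_cleavages=0))
    return len({p for p in fully if params.min_len <= len(p) <= params.max_len})


def read_peptide_table(
    path: str | Path,
    sample_spec: dict[str, SampleDescriptor] | None = None,
    intensity_prefix: str = "Intensity ",
    protein_column: str = "Leading razor protein",
) -> pd.DataFrame:
    """Read a MaxQuant-dialect ``peptides.txt`` into a tidy peptide table.

    Returns a DataFrame with columns ``peptide``, ``protein`` and one linear
    intensity column per sample (0 kept as 0 here; quantification treats
    zero-sum proteins per sample as missing).  Reverse/contaminant rows are
    dropped.
    """
    df = pd.read_csv(path, sep="\t", low_memory=False)
    for marker in ("Reverse", "Potential contaminant"):
        if marker in df.columns:
            df = df[df[marker].fillna("") != "+"]
    if protein_column not in df.columns:
        protein_column = "Proteins"
    int_cols = [c for c in df.columns if c.startswith(intensity_prefix) and c != "Intensity"]
    if not int_cols:
        raise ValueError(f"no columns with prefix {intensity_prefix!r} in {path}")
    out = pd.DataFrame(
        {
            "peptide": df["Sequence"].astype(str),
            "protein": df[protein_column].astype(str).str.split(";").str[0],
        }
    )
    for c in int_cols:
        out[c[len(intensity_prefix):]] = pd.to_numeric(df[c], errors="coerce").fillna(0.0)
    return out.reset_index(drop=True)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning ``{accession: sequence}``.

    The accession is the first ``|``-delimited field of the header after any
    database tag (``>sp|P12345|NAME`` -> ``P12345``; ``>P12345`` -> ``P12345``).
    """
    seqs: dict[str, str] = {}
    acc = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if acc is not None:
                seqs[acc] = "".join(chunks)
            fields = line[1:].split()[0].split("|")
            acc = fields[1] if len(fields) >= 2 else fields[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if acc is not None:
        seqs[acc] = "".join(chunks)
    return seqs


def _intensity_columns(peptides: pd.DataFrame) -> list[str]:
    return [c for c in peptides.columns if c not in ("peptide", "protein")]


def _sample_descriptors(
    cols: list[str], layer: str, sample_spec: dict[str, SampleDescriptor] | None
) -> list[SampleDescriptor]:
    if sample_spec is not None:
        return [sample_spec[c] for c in cols]
    out = []
    for c in cols:
        phase, _, rep = c.rpartition("_")
        out.append(SampleDescriptor(layer=layer, phase=phase, replicate=int(rep)))
    return out


def ibaq(
    peptides: pd.DataFrame,
    sequences: dict[str, str],
    params: DigestParams = DigestParams(),
    layer: str = "protein",
    sample_spec: dict[str, SampleDescriptor] | None = None,
) -> LayerMatrix:
    """Intensity-based absolute quantification.

    Per protein and sample: summed peptide intensity divided by the count of
    theoretically observable tryptic peptides, log2-transformed.  Samples
    with no detected peptide and proteins with zero observable peptides are
    missing.  Proteins quantified without a sequence are an error (the
    denominator cannot be computed).
    """
    cols = _intensity_columns(peptides)
    prots = peptides["protein"].unique()
    missing = sorted(p for p in prots if p not in sequences)
    if missing:
        raise KeyError(f"no sequence for quantified proteins: {', '.join(missing[:10])}")

    sums = peptides.groupby("protein")[cols].sum()
    counts = pd.Series({p: observable_count(sequences[p], params) for p in sums.index})
    linear = sums.div(counts.where(counts > 0), axis=0)
    values = np.log2(linear.where(linear > 0))
    values.index.name = "accession"
    return LayerMatrix(
        values=values,
        samples=_sample_descriptors(cols, layer, sample_spec),
        scale="log2",
        quant_scheme="iBAQ",
    )


def top3(
    peptides: pd.DataFrame,
    layer: str = "protein",
    sample_spec: dict[str, SampleDescriptor] | None = None,
) -> LayerMatrix:
    """TOP3 quantification: per protein/sample sum of the 3 largest intensities.

    Proteins with fewer than 3 detected peptides in a sample are still
    quantified from what is available but flagged low-evidence in ``flags``
    (dropping them would silently shrink the proteome).
    """
    cols = _intensity_columns(peptides)

    def _top3_sum(v: pd.Series) -> float:
        det = v[v > 0]
        return float(det.nlargest(3).sum())

    def _n_det(v: pd.Series) -> int:
        return int((v > 0).sum())

    grouped = peptides.groupby("protein")[cols]
    sums = grouped.agg(_top3_sum)
    ndet = grouped.agg(_n_det)
    values = np.log2(sums.where(sums > 0))
    values.index.name = "accession"
    flags = (ndet < 3) & (ndet > 0)
    return LayerMatrix(
        values=values,
        samples=_sample_descriptors(cols, layer, sample_spec),
        scale="log2",
        quant_scheme="TOP3",
        flags=flags,
    )


def total_intensity_normalize(lm: LayerMatrix) -> LayerMatrix:
    """Equalize linear column sums to their across-sample mean.

    A deliberately simple column normalization for tables without LFQ
    intensities; it preserves within-sample ratios exactly.
    """
    linear = lm.to_linear()
    sums = linear.values.sum(axis=0, skipna=True)
    if (sums == 0).any() or sums.isna().any():
        bad = list(sums.index[(sums == 0) | sums.isna()])
        raise ValueError(f"all-missing or zero-sum sample columns: {bad}")
    scaled = linear.values.mul(sums.mean() / sums, axis=1)
    out = replace(linear, values=scaled)
    return out.to_log2() if lm.scale == "log2" else out
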