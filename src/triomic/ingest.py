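"""Reading expression layers and merging them into a protein-centric dataset.

Supported inputs are plain tab-separated tables: generic expression tables
(one identifier column + one numeric column per sample), MaxQuant-dialect
``proteinGroups.txt``, a two-column probeset-to-accession id map, and a
YAML/JSON sample sheet declaring ``(column, layer, phase, replicate)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import LAYERS, LayerMatrix, MultiOmicDataset, SampleDescriptor

__all__ = [
    "read_sample_sheet",
    "read_expression_table",
    "write_expression_table",
    "read_maxquant_protein_groups",
    "read_id_map",
    "merge_multiomic",
    "summarize_dataset",
]


def read_sample_sheet(path: str | Path) -> dict[str, SampleDescriptor]:
    """Read a YAML/JSON sample sheet into ``{column name: SampleDescriptor}``.

    The sheet is a list of records with keys ``column``, ``layer``, ``phase``,
    ``replicate`` and optional ``timepoint_h``.
    """
    text = Path(path).read_text()
    records = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    out: dict[str, SampleDescriptor] = {}
    for rec in records:
        col = rec["column"]
        if col in out:
            raise ValueError(f"sample sheet declares column {col!r} twice")
        out[col] = SampleDescriptor(
            layer=rec["layer"],
            phase=rec["phase"],
            replicate=int(rec["replicate"]),
            timepoint_h=rec.get("timepoint_h"),
        )
    return out


def read_expression_table(
    path: str | Path,
    layer: str,
    sample_spec: dict[str, SampleDescriptor],
    id_column: str | None = None,
    scale: str = "log2",
    quant_scheme: str = "raw",
) -> LayerMatrix:
    """Read a TSV expression table into a :class:`LayerMatrix`.

    ``sample_spec`` maps column names to descriptors; every declared column
    must exist in the table and belong to ``layer``.  Empty cells and NaN are
    missing values -- never silently treated as zero.  Duplicate identifiers
    are an error (the merge step requires a unique gene index).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str} if id_column is None else None)
    id_column = id_column or df.columns[0]
    if id_column not in df.columns:
        raise ValueError(f"identifier column {id_column!r} not found in {path}")
    df = df.set_index(df[id_column].astype(str))

    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicated identifiers in {path}: {', '.join(dup[:10])}")

    missing_cols = [c for c in sample_spec if c not in df.columns]
    if missing_cols:
        raise ValueError(f"sample sheet columns not present in {path}: {missing_cols}")
    bad_layer = [c for c, s in sample_spec.items() if s.layer != layer]
    if bad_layer:
        raise ValueError(f"columns {bad_layer} are not declared as layer {layer!r}")

    cols = list(sample_spec)
    values = df[cols].apply(pd.to_numeric, errors="coerce")
    samples = [sample_spec[c] for c in cols]
    return LayerMatrix(values=values, samples=samples, scale=scale, quant_scheme=quant_scheme)


def write_expression_table(lm: LayerMatrix, path: str | Path, id_column: str | None = None) -> None:
    """Write a LayerMatrix as TSV (inverse of :func:`read_expression_table`)."""
    out = lm.values.copy()
    out.insert(0, id_column or lm.values.index.name or "id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_maxquant_protein_groups(
    path: str | Path,
    intensity_prefix: str = "LFQ intensity ",
    sample_spec: dict[str, SampleDescriptor] | None = None,
    layer: str = "protein",
    quant_scheme: str = "LFQ",
) -> LayerMatrix:
    """Read a MaxQuant-dialect ``proteinGroups.txt`` table.

    Rows flagged ``Reverse`` or ``Potential contaminant`` (marker ``+``) are
    removed.  Intensities are log2-transformed with 0 treated as missing (an
    MS zero means "not detected", not "absent at log2(0)").  The row key is
    the first accession of "Majority protein IDs"; the full semicolon-joined
    group string is retained in ``group_ids`` for reporting.

    ``sample_spec`` maps the column *suffixes* after ``intensity_prefix``
    (e.g. ``"G1_1"``) to descriptors; without it, descriptors are built from
    suffixes of the form ``<phase>_<replicate>``.
    """
    df = pd.read_csv(path, sep="\t", low_memory=False)
    if "Majority protein IDs" not in df.columns:
        raise ValueError(f"{path} has no 'Majority protein IDs' column")

    for marker in ("Reverse", "Potential contaminant"):
        if marker in df.columns:
            df = df[df[marker].fillna("") != "+"]

    int_cols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not int_cols:
        raise ValueError(f"no columns with prefix {intensity_prefix!r} in {path}")

    groups = df["Majority protein IDs"].astype(str)
    primary = groups.str.split(";").str[0]
    dup = primary[primary.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicated primary accessions in {path}: {', '.join(dup[:10])}")

    values = df[int_cols].apply(pd.to_numeric, errors="coerce")
    values = np.log2(values.where(values > 0))
    values.index = pd.Index(primary, name="accession")

    samples = []
    for col in int_cols:
        suffix = col[len(intensity_prefix):]
        if sample_spec is not None:
            if suffix not in sample_spec:
                raise ValueError(f"intensity column suffix {suffix!r} not in sample spec")
            samples.append(sample_spec[suffix])
        else:
            phase, _, rep = suffix.rpartition("_")
            samples.append(SampleDescriptor(layer=layer, phase=phase, replicate=int(rep)))

    return LayerMatrix(
        values=values,
        samples=samples,
        scale="log2",
        quant_scheme=quant_scheme,
        group_ids=pd.Series(groups.values, index=values.index),
    )


def read_id_map(path: str | Path) -> pd.DataFrame:
    """Read a 2-column TSV probeset-to-accession map (many-to-many allowed)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["probeset_id", "protein_group_id"]
    bad = df["probeset_id"].fillna("").eq("") | df["protein_group_id"].fillna("").eq("")
    if bad.any():
        raise ValueError(f"{int(bad.sum())} id-map records with an empty identifier")
    return df.drop_duplicates()


def merge_multiomic(
    mrna: LayerMatrix,
    translation: LayerMatrix,
    protein: LayerMatrix,
    idmap: pd.DataFrame,
) -> MultiOmicDataset:
    """Merge the three layers into a protein-centric :class:`MultiOmicDataset`.

    The gene index is the union of translatome and proteome accessions: a gene
    only needs to be detected in one of the two MS layers to be kept.  mRNA is
    attached through the probeset-to-accession map using the maximum-value
    rule: when several probesets map to one protein group, the whole row of
    the single probeset with the highest mean expression across all mRNA
    samples is used, so the within-transcript phase profile is preserved.
    Ties are broken by probeset id, making the merge invariant to the order of
    id-map records.  Accessions with no mapped probeset get an all-missing
    mRNA row and ``in_transcriptome=False``.
    """
    gene_index = translation.gene_ids.union(protein.gene_ids, sort=True)

    probe_means = mrna.values.mean(axis=1, skipna=True)
    valid = idmap[idmap["probeset_id"].isin(mrna.gene_ids)]
    chosen: dict[str, str] = {}
    for acc, grp in valid.groupby("protein_group_id"):
        probes = grp["probeset_id"].unique()
        means = probe_means.reindex(probes)
        if means.notna().any():
            # highest mean wins; ties resolved by lexicographically smallest id
            best = means.loc[means == means.max()].index.min()
            chosen[acc] = best

    mrna_rows = pd.DataFrame(
        np.nan, index=gene_index, columns=mrna.values.columns, dtype=float
    )
    for acc in gene_index:
        if acc in chosen:
            mrna_rows.loc[acc] = mrna.values.loc[chosen[acc]].values

    layers = {
        "mRNA": LayerMatrix(
            values=mrna_rows, samples=mrna.samples, scale=mrna.scale, quant_scheme=mrna.quant_scheme
        ),
        "translation": translation.reindexed(gene_index),
        "protein": protein.reindexed(gene_index),
    }
    provenance = pd.DataFrame(
        {
            "in_transcriptome": gene_index.isin(list(chosen)),
            "in_translatome": gene_index.isin(translation.gene_ids),
            "in_proteome": gene_index.isin(protein.gene_ids),
        },
        index=gene_index,
    )
    return MultiOmicDataset(gene_index=gene_index, layers=layers, provenance=provenance)


def summarize_dataset(ds: MultiOmicDataset) -> dict[str, int]:
    """Headline counts for a merged dataset.

    ``combined`` counts genes detected in the transcriptome AND in the
    translatome or proteome -- the definition behind the merged-dataset size
    reported for this experimental design.
    """
    p = ds.provenance
    return {
        "genes_total": int(len(ds.gene_index)),
        "in_transcriptome": int(p["in_transcriptome"].sum()),
        "in_translatome": int(p["in_translatome"].sum()),
        "in_proteome": int(p["in_proteome"].sum()),
        "proteome_only": int((p["in_proteome"] & ~p["in_translatome"] & ~p["in_transcriptome"]).sum()),
        "combined": int((p["in_transcriptome"] & (p["in_translatome"] | p["in_proteome"])).sum()),
    }
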