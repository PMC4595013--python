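"""Phase-to-phase fold-change statistics and the two published cycling filters.

Fold-changes are computed per replicate as the log2 value in the entered
phase minus the mean log2 value of the preceding phase, for the cyclic
transitions G2/M->G1 (G1_FC), G1->S (S_FC) and S->G2/M (G2M_FC).  Columns
are Z-transformed to unify dynamic range across platforms before one-sample
t-testing with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    LAYERS,
    TRANSITION_PHASES,
    TRANSITIONS,
    FoldChangeMatrix,
    MultiOmicDataset,
)

__all__ = [
    "fold_changes",
    "zscore_columns",
    "bh_adjust",
    "one_sample_test",
    "significant_union_filter",
    "fc_threshold_filter",
    "GOBP_CELL_CYCLE_TERMS",
    "gobp_subset",
    "select_highest_fold_change",
]

#: The GO Biological Process categories used for the cell-cycle gene filter.
GOBP_CELL_CYCLE_TERMS = (
    "Cell cycle",
    "Cell cycle arrest",
    "Cell cycle checkpoint",
    "Cell cycle cytokinesis",
    "Cell cycle phase",
    "Cell cycle process",
    "Cell division",
)


def fold_changes(ds: MultiOmicDataset, min_reps: int = 2) -> FoldChangeMatrix:
    """Per-replicate and mean log2 fold-changes for the three transitions.

    For transition (prev -> cur) and replicate r:
    ``fc = value(cur, r) - mean over replicates of value(prev)``, where the
    preceding-phase mean requires at least ``min_reps`` non-missing
    replicates (else the fold-change is missing).  Per-gene mean fold-changes
    likewise require ``min_reps`` replicate fold-changes.

    For genes with complete data, the three mean fold-changes telescope to
    exactly zero around the cycle.
    """
    fc_cols: dict[tuple[str, str, int], pd.Series] = {}
    for layer in LAYERS:
        lm = ds.layers.get(layer)
        if lm is None:
            continue
        phases_present = {s.phase for s in lm.samples}
        for trans in TRANSITIONS:
            prev, cur = TRANSITION_PHASES[trans]
            if prev not in phases_present or cur not in phases_present:
                raise ValueError(
                    f"layer {layer!r} lacks phase data for transition {trans} ({prev}->{cur})"
                )
            prev_cols = lm.columns_for(phase=prev)
            prev_vals = lm.values[prev_cols]
            prev_mean = prev_vals.mean(axis=1).where(prev_vals.notna().sum(axis=1) >= min_reps)
            for s in lm.samples:
                if s.phase == cur:
                    fc_cols[(layer, trans, s.replicate)] = lm.values[s.label] - prev_mean

    fc = pd.DataFrame(fc_cols)
    fc.columns = pd.MultiIndex.from_tuples(fc.columns, names=["layer", "transition", "replicate"])

    mean_fc, n = _replicate_means(fc, min_reps)
    return FoldChangeMatrix(fc=fc, mean_fc=mean_fc, n=n, min_reps=min_reps)


def _replicate_means(mat: pd.DataFrame, min_reps: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    grouped = mat.T.groupby(level=["layer", "transition"], sort=False)
    n = grouped.count().T
    means = grouped.mean().T.where(n >= min_reps)
    return means, n


def zscore_columns(fcm: FoldChangeMatrix) -> FoldChangeMatrix:
    """Z-transform each (layer, transition, replicate) column across genes.

    Uses the mean and (ddof=1) standard deviation over non-missing genes;
    missing entries stay missing.  Zero column spread is an error.
    """
    mu = fcm.fc.mean(axis=0)
    sd = fcm.fc.std(axis=0, ddof=1)
    bad = sd[(sd == 0) | sd.isna()]
    if len(bad):
        raise ValueError(f"zero or undefined spread in columns: {list(bad.index)}")
    z = (fcm.fc - mu) / sd
    mean_z, _ = _replicate_means(z, fcm.min_reps)
    fcm.z = z
    fcm.mean_z = mean_z
    return fcm


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaNs are passed through; input outside [0, 1] is an error.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def one_sample_test(
    fcm: FoldChangeMatrix,
    alpha: float = 0.05,
    use_z: bool = True,
    family: str = "per_column",
) -> pd.DataFrame:
    """One-sample Student t-test of replicate (Z-transformed) fold-changes.

    Per (gene, layer, transition): t = mean * sqrt(n) / sd over the replicate
    values, df = n - 1, two-sided p.  Genes with zero replicate spread are
    flagged degenerate with no p.  BH adjustment is applied within each
    (layer, transition) family by default (``family='global'`` pools all
    tests into one family); ``significant`` marks q < alpha.

    Returns a tidy DataFrame: gene, layer, transition, n, t, p, q,
    significant, degenerate.
    """
    mat = fcm.z if use_z else fcm.fc
    if mat is None:
        raise ValueError("Z-transformed fold-changes requested but zscore_columns has not run")
    if family not in ("per_column", "global"):
        raise ValueError("family must be 'per_column' or 'global'")

    records = []
    for layer, trans in {(l, t) for (l, t, _r) in mat.columns}:
        sub = mat[layer][trans]
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        valid = n >= 2
        degen = valid & (sd == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean * np.sqrt(n) / sd
        p = pd.Series(np.nan, index=sub.index)
        testable = valid & ~degen
        p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), df=n[testable] - 1)
        frame = pd.DataFrame(
            {
                "gene": sub.index,
                "layer": layer,
                "transition": trans,
                "n": n.values,
                "t": t.where(testable).values,
                "p": p.values,
                "degenerate": degen.values,
            }
        )
        records.append(frame[valid.values])

    results = pd.concat(records, ignore_index=True)
    results = results.sort_values(["layer", "transition", "gene"], ignore_index=True)
    results["q"] = np.nan
    if family == "global":
        results["q"] = bh_adjust(results["p"])
    else:
        for _, idx in results.groupby(["layer", "transition"]).groups.items():
            results.loc[idx, "q"] = bh_adjust(results.loc[idx, "p"])
    results["significant"] = results["q"] < alpha
    return results


def significant_union_filter(results: pd.DataFrame, alpha: float = 0.05) -> pd.Index:
    """Genes significant in >= 1 (layer, transition) test at FDR < alpha."""
    sig = results[results["q"] < alpha]
    return pd.Index(sorted(sig["gene"].unique()))


def fc_threshold_filter(
    fcm: FoldChangeMatrix, fold: float = 1.5, min_layers: int = 2
) -> pd.Index:
    """Genes with a >= ``fold`` change in >= ``min_layers`` layers.

    A gene passes when, at some single transition, its absolute mean log2
    fold-change reaches log2(fold) in at least ``min_layers`` of the three
    layers (set ``min_layers=1`` for the weaker any-layer variant).
    Untransformed fold-changes are used, to emphasize effect size over
    statistical significance.
    """
    cut = np.log2(fold)
    hits = (fcm.mean_fc.abs() >= cut)
    keep = pd.Series(False, index=fcm.gene_index)
    for trans in TRANSITIONS:
        cols = [(l, trans) for l in LAYERS if (l, trans) in hits.columns]
        keep |= hits.loc[:, cols].sum(axis=1) >= min_layers
    return fcm.gene_index[keep]


def gobp_subset(
    annotations: pd.DataFrame,
    gene_index: pd.Index,
    categories: tuple[str, ...] = GOBP_CELL_CYCLE_TERMS,
) -> pd.Series:
    """Boolean mask over ``gene_index``: annotated with >= 1 listed category.

    ``annotations`` is a tidy (gene, term) table.
    """
    hits = annotations[annotations["term"].isin(categories)]["gene"].unique()
    return pd.Series(gene_index.isin(hits), index=gene_index)


def select_highest_fold_change(
    fcm: FoldChangeMatrix, paralog_groups: pd.Series
) -> pd.Index:
    """Resolve indistinguishable paralogs (e.g. histone genes) to one member.

    ``paralog_groups`` maps gene id -> group label for genes encoding
    indistinguishable protein products.  Within each group only the gene with
    the highest absolute mean fold-change (any layer/transition) is kept;
    genes absent from the mapping are kept unconditionally.
    """
    max_abs = fcm.mean_fc.abs().max(axis=1)
    keep = list(fcm.gene_index[~fcm.gene_index.isin(paralog_groups.index)])
    groups = paralog_groups.reindex(fcm.gene_index).dropna()
    for _, members in groups.groupby(groups):
        scores = max_abs.reindex(members.index)
        if scores.notna().any():
            best = scores.loc[scores == scores.max()].index.min()
        else:
            best = members.index.min()
        keep.append(best)
    return pd.Index(sorted(keep))
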