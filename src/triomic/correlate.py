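"""Cross-layer / cross-phase correlation structure.

Correlations between layers are Spearman rank correlations computed
separately for each replicate pairing and averaged, which keeps replicate
noise from being averaged away before ranking.  Observed between-layer
correlations can be disattenuated (corrected for platform unreliability) by
dividing by the geometric mean of the intra-platform replicate correlations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import cluster as scipy_cluster
from scipy import stats
from scipy.spatial.distance import squareform

from .containers import (
    LAYERS,
    PHASES,
    TRANSITIONS,
    FoldChangeMatrix,
    LayerMatrix,
    MultiOmicDataset,
)

__all__ = [
    "spearman",
    "CorrelationMatrix",
    "correlation_matrix",
    "ReliabilityEstimate",
    "reliability",
    "disattenuate",
    "explained_variance",
    "dynamic_range",
    "cluster_correlations",
]

MIN_PAIRS = 3


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(x, y) -> float:
    """Spearman rank correlation on complete pairs (ties -> average ranks).

    Returns NaN (with a warning) when fewer than 3 complete pairs remain or
    either vector has zero rank variance.
    """
    xs, ys = _complete_pairs(x, y)
    if len(xs) < MIN_PAIRS:
        warnings.warn(f"only {len(xs)} complete pairs; Spearman undefined", stacklevel=2)
        return float("nan")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    return float(stats.spearmanr(xs, ys).statistic)


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of replicate-averaged Spearman correlations.

    ``labels`` are (layer, phase) or (layer, transition) pairs; ``r`` and
    ``n_pairs`` are DataFrames indexed by the flattened label strings.
    """

    labels: list[tuple[str, str]]
    r: pd.DataFrame
    n_pairs: pd.DataFrame


def _replicate_columns(ds_or_fcm, use_z: bool):
    """Yield ((layer, condition), {replicate: vector}) for every condition."""
    if isinstance(ds_or_fcm, MultiOmicDataset):
        for layer in LAYERS:
            lm = ds_or_fcm.layers[layer]
            for phase in PHASES:
                reps = {}
                for s in lm.samples:
                    if s.phase == phase:
                        reps[s.replicate] = lm.values[s.label]
                if reps:
                    yield (layer, phase), reps
    elif isinstance(ds_or_fcm, FoldChangeMatrix):
        mat = ds_or_fcm.z if use_z else ds_or_fcm.fc
        if mat is None:
            raise ValueError("Z-transformed fold-changes requested but not computed")
        for layer, trans in itertools.product(LAYERS, TRANSITIONS):
            reps = {
                r: mat[(layer, trans, r)]
                for (l2, t2, r) in mat.columns
                if l2 == layer and t2 == trans
            }
            if reps:
                yield (layer, trans), reps
    else:
        raise TypeError(f"unsupported input type {type(ds_or_fcm)}")


def correlation_matrix(
    ds_or_fcm: MultiOmicDataset | FoldChangeMatrix,
    gene_mask: pd.Series | None = None,
    use_z: bool = True,
    pairing: str = "matched",
) -> CorrelationMatrix:
    """Replicate-averaged Spearman correlations between all conditions.

    Each cell is the mean over replicate pairings of the Spearman correlation
    between two (layer, phase) columns of a merged dataset -- or two (layer,
    transition) columns of a fold-change matrix (Z-scored values by default).

    pairing
        "matched" pairs replicate i with replicate i (matched experimental
        batches); "all" averages over the full cross product.
    gene_mask
        optional boolean Series restricting the computation to a gene subset
        (e.g. cell-cycle-annotated genes).
    """
    if pairing not in ("matched", "all"):
        raise ValueError("pairing must be 'matched' or 'all'")

    conditions = list(_replicate_columns(ds_or_fcm, use_z))
    labels = [lab for lab, _ in conditions]
    names = [f"{l}|{c}" for l, c in labels]
    k = len(labels)
    r = np.eye(k)
    n = np.zeros((k, k))

    def _apply_mask(v: pd.Series) -> pd.Series:
        return v[gene_mask.reindex(v.index, fill_value=False)] if gene_mask is not None else v

    for i in range(k):
        for j in range(i, k):
            reps_i, reps_j = conditions[i][1], conditions[j][1]
            if pairing == "matched":
                pairs = [(rr, rr) for rr in sorted(set(reps_i) & set(reps_j))]
                if i == j:  # reliability-style: all distinct pairs within condition
                    pairs = list(itertools.combinations(sorted(reps_i), 2))
            else:
                pairs = [
                    (a, b)
                    for a in sorted(reps_i)
                    for b in sorted(reps_j)
                    if not (i == j and a >= b)
                ]
            vals, ns = [], []
            for a, b in pairs:
                x, y = _apply_mask(reps_i[a]), _apply_mask(reps_j[b])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    vals.append(spearman(x, y))
                ns.append(int((np.isfinite(x) & np.isfinite(y.reindex(x.index))).sum()))
            rv = float(np.nanmean(vals)) if vals else float("nan")
            if i == j:
                rv = 1.0  # diagonal is the self-correlation by definition
            r[i, j] = r[j, i] = rv
            n[i, j] = n[j, i] = float(np.mean(ns)) if ns else 0.0

    return CorrelationMatrix(
        labels=labels,
        r=pd.DataFrame(r, index=names, columns=names),
        n_pairs=pd.DataFrame(n, index=names, columns=names),
    )


@dataclass(frozen=True)
class ReliabilityEstimate:
    """Intra-platform reliability: mean pairwise Spearman among replicates."""

    layer: str
    phase: str
    r_xx: float
    n_replicates: int


def reliability(lm: LayerMatrix, phase: str, gene_mask: pd.Series | None = None) -> ReliabilityEstimate:
    """Mean of all pairwise replicate Spearman correlations for one condition."""
    cols = lm.columns_for(phase=phase)
    if len(cols) < 2:
        raise ValueError(f"need >= 2 replicates for {lm.layer}/{phase}, found {len(cols)}")
    vals = []
    for a, b in itertools.combinations(cols, 2):
        x, y = lm.values[a], lm.values[b]
        if gene_mask is not None:
            keep = gene_mask.reindex(x.index, fill_value=False)
            x, y = x[keep], y[keep]
        vals.append(spearman(x, y))
    return ReliabilityEstimate(lm.layer, phase, float(np.nanmean(vals)), len(cols))


def disattenuate(r_xy: float, r_xx: float, r_yy: float) -> float:
    """Correct an observed correlation for measurement unreliability.

    corrected = r_xy / sqrt(r_xx * r_yy), clipped to [-1, 1].  The
    reliabilities are intra-platform replicate correlations; with perfect
    reliability the correction is the identity.
    """
    if r_xx <= 0 or r_yy <= 0:
        raise ValueError(f"reliabilities must be positive, got r_xx={r_xx}, r_yy={r_yy}")
    return float(np.clip(r_xy / np.sqrt(r_xx * r_yy), -1.0, 1.0))


def explained_variance(x, y, method: str = "pearson") -> float:
    """R-squared between two log-scale vectors on complete pairs.

    Default is squared Pearson (scatterplot-style R2 on log axes); squared
    Spearman is available via ``method='spearman'``.
    """
    xs, ys = _complete_pairs(x, y)
    if len(xs) < MIN_PAIRS:
        warnings.warn(f"only {len(xs)} complete pairs; R2 undefined", stacklevel=2)
        return float("nan")
    if method == "pearson":
        r = stats.pearsonr(xs, ys).statistic
    elif method == "spearman":
        r = stats.spearmanr(xs, ys).statistic
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r * r)


def dynamic_range(lm: LayerMatrix, lo_q: float = 0.0, hi_q: float = 1.0) -> float:
    """Orders of magnitude spanned by detected values, pooled across samples.

    log10 of the ratio between the ``hi_q`` and ``lo_q`` quantiles of the
    linear-scale detected values (defaults: min-max).  Quantile settings
    below the extremes give a detection-limit-robust range.
    """
    linear = lm.to_linear().values.to_numpy().ravel()
    linear = linear[np.isfinite(linear) & (linear > 0)]
    if linear.size == 0:
        raise ValueError("no detected values")
    lo = np.quantile(linear, lo_q)
    hi = np.quantile(linear, hi_q)
    return float(np.log10(hi / lo))


def cluster_correlations(cm: CorrelationMatrix):
    """Average-linkage agglomerative clustering of a correlation matrix.

    Distance is 1 - r.  Returns ``(linkage, leaf_labels)`` with a
    deterministic leaf order (scipy's ordering on the label-sorted input).
    """
    order = np.argsort(cm.r.index)
    r = cm.r.iloc[order, order].to_numpy()
    labels = list(cm.r.index[order])
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = scipy_cluster.hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = scipy_cluster.hierarchy.leaves_list(link)
    return link, [labels[i] for i in leaves]
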