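"""Expression-pattern clustering and regulatory-mode classification.

Genes that cycle are grouped by k-means on their Z-scored fold-change
profiles (the 9-dimensional layer x transition vector) and, independently,
by average-linkage hierarchical clustering with correlation distance on the
untransformed fold-changes.  Each gene is also assigned one of five
regulatory modes describing which expression level drives its periodicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .containers import LAYERS, TRANSITIONS

__all__ = [
    "ClusterResult",
    "kmeans_profiles",
    "hcluster_profiles",
    "ModeThresholds",
    "REGULATORY_MODES",
    "classify_mode",
    "classify_modes",
    "cluster_summary",
]


@dataclass
class ClusterResult:
    assignments: pd.Series  # gene -> cluster id (0..k-1)
    centroids: pd.DataFrame  # cluster x profile-dimension mean Z values
    k: int
    seed: int | None
    inertia: float


def kmeans_profiles(
    profiles: pd.DataFrame,
    k: int = 10,
    seed: int | None = 0,
    restarts: int = 10,
    missing: str = "impute_zero",
) -> ClusterResult:
    """K-means clustering of per-gene mean-Z fold-change profiles.

    Squared-Euclidean objective with k-means++ initialization, best of
    ``restarts`` runs by inertia; deterministic for a given seed.  Missing
    profile entries are imputed to 0 (no evidence of change) by default, or
    the gene is excluded with ``missing='drop'``.
    """
    if missing == "impute_zero":
        x = profiles.fillna(0.0)
    elif missing == "drop":
        x = profiles.dropna()
    else:
        raise ValueError("missing must be 'impute_zero' or 'drop'")
    if k > len(x):
        raise ValueError(f"k={k} exceeds the {len(x)} clusterable genes")

    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    labels = km.fit_predict(x.to_numpy())
    return ClusterResult(
        assignments=pd.Series(labels, index=x.index, name="cluster"),
        centroids=pd.DataFrame(km.cluster_centers_, columns=x.columns),
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


def hcluster_profiles(profiles: pd.DataFrame, cut_height: float | None = None):
    """Hierarchical clustering of untransformed fold-change profiles.

    Distance = 1 - Pearson correlation between gene profiles, average
    linkage.  The column (condition) order of ``profiles`` is used as given
    and never reordered.  Constant (zero-variance) profiles cannot be
    correlated and are excluded with a warning.

    Returns ``(linkage, gene_ids, flat_clusters)``; ``flat_clusters`` is None
    unless ``cut_height`` is given.
    """
    x = profiles.dropna()
    const = x.std(axis=1, ddof=0) == 0
    if const.any():
        warnings.warn(
            f"excluding {int(const.sum())} constant profiles from correlation clustering",
            stacklevel=2,
        )
        x = x[~const]
    if len(x) < 2:
        raise ValueError("need >= 2 non-constant complete profiles")
    dist = np.clip(pdist(x.to_numpy(), metric="correlation"), 0.0, None)
    link = hierarchy.linkage(dist, method="average")
    flat = None
    if cut_height is not None:
        flat = pd.Series(
            hierarchy.fcluster(link, t=cut_height, criterion="distance"),
            index=x.index,
            name="cluster",
        )
    return link, x.index, flat


#: Regulatory-mode labels, in cascade order.  Letters follow the published
#: cluster naming for the five strongest expression patterns.
REGULATORY_MODES = (
    "concordant_mitotic",  # A: mRNA+translation+protein up into G2/M, down into G1
    "mRNA_buffered",       # B: mitotic mRNA rise buffered at the protein level
    "translation_S",       # C: S-phase translation burst, protein flat
    "lagged_protein",      # D: G1 mRNA/translation rise, protein peaks in S
    "protein_stability",   # E: protein-only cycling (stability-driven)
    "unclassified",
)


@dataclass(frozen=True)
class ModeThresholds:
    """Activity threshold for mode calls: |mean Z| >= tau counts as a change."""

    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def classify_mode(profile: pd.Series, th: ModeThresholds = ModeThresholds()) -> str:
    """Assign one regulatory mode to a 9-dimensional mean-Z profile.

    ``profile`` is indexed by (layer, transition).  The rule cascade is
    evaluated in order A..E with first match winning; "up"/"down" mean the
    signed Z-value crosses +-tau, "inactive" means |Z| < tau at every
    transition of that layer.  Missing entries count as inactive.
    """
    z = {
        (l, t): float(profile.get((l, t), np.nan))
        for l in LAYERS
        for t in TRANSITIONS
    }

    def up(layer, trans):
        v = z[(layer, trans)]
        return np.isfinite(v) and v >= th.tau

    def down(layer, trans):
        v = z[(layer, trans)]
        return np.isfinite(v) and v <= -th.tau

    def inactive(layer):
        return all(
            not np.isfinite(z[(layer, t)]) or abs(z[(layer, t)]) < th.tau
            for t in TRANSITIONS
        )

    if all(up(l, "G2M_FC") for l in LAYERS) and all(down(l, "G1_FC") for l in LAYERS):
        return "concordant_mitotic"
    if up("mRNA", "G2M_FC") and inactive("protein"):
        return "mRNA_buffered"
    if up("translation", "S_FC") and down("translation", "G2M_FC") and inactive("protein"):
        return "translation_S"
    if up("mRNA", "G1_FC") and up("translation", "G1_FC") and up("protein", "S_FC"):
        return "lagged_protein"
    if (up("protein", "G2M_FC") or down("protein", "S_FC")) and inactive("mRNA") and inactive(
        "translation"
    ):
        return "protein_stability"
    return "unclassified"


def classify_modes(profiles: pd.DataFrame, th: ModeThresholds = ModeThresholds()) -> pd.Series:
    """Vector version of :func:`classify_mode` over a gene x profile matrix."""
    return pd.Series(
        [classify_mode(profiles.loc[g], th) for g in profiles.index],
        index=profiles.index,
        name="mode",
    )


def cluster_summary(
    cr: ClusterResult,
    annotations: pd.DataFrame | None = None,
    background: pd.Index | None = None,
    fdr: float = 0.02,
    top_terms: int = 5,
) -> pd.DataFrame:
    """Per-cluster size, centroid and top Fisher-enriched annotation terms."""
    from .enrich import fisher_enrichment  # local import avoids a cycle

    rows = []
    bg = background if background is not None else cr.assignments.index
    term_sets = None
    if annotations is not None and len(annotations):
        term_sets = {
            term: set(grp["gene"]) for term, grp in annotations.groupby("term")
        }
    for cid in range(cr.k):
        members = cr.assignments.index[cr.assignments == cid]
        rec = {"cluster": cid, "size": int(len(members))}
        for col in cr.centroids.columns:
            rec[f"centroid:{col[0]}|{col[1]}" if isinstance(col, tuple) else f"centroid:{col}"] = (
                float(cr.centroids.loc[cid, col])
            )
        if term_sets and len(members):
            res = fisher_enrichment(pd.Index(members), pd.Index(bg), term_sets, fdr=fdr)
            enriched = res[res["q"] < fdr].nsmallest(top_terms, "p")
            rec["enriched_terms"] = ";".join(enriched["term"])
        rows.append(rec)
    return pd.DataFrame(rows)
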