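"""Protein stability scoring and annotation enrichment.

The stability score is the log2 difference between steady-state protein
abundance and translation level: a protein synthesized slowly yet abundant
must be stable, one synthesized fast yet scarce must be labile.  Two
enrichment flavors are provided: rank-based 1D enrichment of a numeric score
(Mann-Whitney with an s-score in [-1, 1]) and Fisher's exact test for
categorical subsets, both BH-controlled.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MultiOmicDataset
from .cycle_stats import bh_adjust

__all__ = [
    "stability_score",
    "enrichment_1d",
    "fisher_enrichment",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)


def stability_score(ds: MultiOmicDataset, phase: str | None = None) -> pd.Series:
    """Relative protein stability per gene.

    score = mean log2 protein - mean log2 translation over the selected
    samples (one phase, or pooled across the cycle when ``phase`` is None).
    This is the abundance-to-synthesis ratio on the log scale; high scores
    mark stable, slowly-degraded proteins.  Missing when either layer is
    undetected.  Both layers should carry comparable absolute quantification
    (e.g. iBAQ).
    """
    prot = ds.layers["protein"]
    trans = ds.layers["translation"]
    pcols = prot.columns_for(phase=phase) if phase else [s.label for s in prot.samples]
    tcols = trans.columns_for(phase=phase) if phase else [s.label for s in trans.samples]
    score = prot.values[pcols].mean(axis=1) - trans.values[tcols].mean(axis=1)
    score.name = "stability_score"
    return score


def enrichment_1d(
    scores: pd.Series,
    term_sets: dict[str, set],
    fdr: float = 0.02,
    min_size: int = 10,
) -> pd.DataFrame:
    """Rank-based 1D annotation enrichment of a numeric per-gene score.

    Per term, a two-sided Mann-Whitney U test (normal approximation with tie
    correction) compares member against non-member scores.  The reported
    statistic is s = 2*U/(n1*n2) - 1 in [-1, 1]: positive means term members
    have systematically higher scores.  It depends only on ranks, so any
    monotone transform of the scores leaves it unchanged.  Terms with fewer
    than ``min_size`` scored members are skipped.  BH adjustment runs across
    the tested terms; ``enriched`` marks q < fdr.
    """
    scores = scores.dropna()
    rows = []
    for term, members in sorted(term_sets.items()):
        member_scores = scores[scores.index.isin(members)]
        other_scores = scores[~scores.index.isin(members)]
        n1, n2 = len(member_scores), len(other_scores)
        if n1 < min_size or n2 < 1:
            logger.info("skipping term %r: %d scored members < %d", term, n1, min_size)
            continue
        res = stats.mannwhitneyu(
            member_scores, other_scores, alternative="two-sided", method="asymptotic"
        )
        s = 2.0 * float(res.statistic) / (n1 * n2) - 1.0
        rows.append(
            {
                "term": term,
                "n_term": n1,
                "n_background": n1 + n2,
                "s": s,
                "p": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows, columns=["term", "n_term", "n_background", "s", "p"])
    out["q"] = bh_adjust(out["p"]) if len(out) else pd.Series(dtype=float)
    out["enriched"] = out["q"] < fdr
    return out


def fisher_enrichment(
    subset: pd.Index,
    background: pd.Index,
    term_sets: dict[str, set],
    fdr: float = 0.02,
    min_size: int = 3,
) -> pd.DataFrame:
    """Fisher's exact test for term over-representation in a gene subset.

    Per term the 2x2 table (subset/rest x in-term/not-in-term) is tested
    two-sided via hypergeometric enumeration.  The odds ratio adds 0.5 to
    every cell only when a zero cell occurs (flagged in ``haldane``).  The
    subset must be contained in the background.
    """
    subset = pd.Index(subset)
    background = pd.Index(background)
    if not subset.isin(background).all():
        raise ValueError("subset contains genes absent from the background")

    in_sub = set(subset)
    bg = set(background)
    n_sub = len(in_sub)
    n_bg = len(bg)
    rows = []
    for term, members in sorted(term_sets.items()):
        term_bg = set(members) & bg
        if len(term_bg) < min_size:
            logger.info("skipping term %r: %d background members < %d", term, len(term_bg), min_size)
            continue
        a = len(term_bg & in_sub)
        b = n_sub - a
        c = len(term_bg) - a
        d = (n_bg - n_sub) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        haldane = 0 in (a, b, c, d)
        if haldane:
            odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            odds = a * d / (b * c)
        rows.append(
            {
                "term": term,
                "n_term": len(term_bg),
                "n_subset_term": a,
                "odds_ratio": float(odds),
                "haldane": haldane,
                "p": float(p),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "n_term", "n_subset_term", "odds_ratio", "haldane", "p"]
    )
    out["q"] = bh_adjust(out["p"]) if len(out) else pd.Series(dtype=float)
    out["enriched"] = out["q"] < fdr
    return out


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read GMT-format term sets (term <tab> description <tab> genes...)."""
    term_sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        term_sets[fields[0]] = set(fields[2:])
    return term_sets


def write_gmt(term_sets: dict[str, set], path: str | Path, description: str = "") -> None:
    lines = [
        "\t".join([term, description, *sorted(genes)])
        for term, genes in sorted(term_sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")
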