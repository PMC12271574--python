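"""Phylogenetic binning and per-bin niche / productivity statistics.

Tips are grouped into *phylogenetic bins*: maximal clades whose largest
within-clade tip-to-tip (cophenetic) distance does not exceed a fixed
threshold (0.1 tree distance units by default). Bins partition the tips;
tips in no qualifying multi-tip clade become singleton bins. Per bin, the
mean pairwise phylogenetic distance, Pearson correlations of the bin's
mean relative abundance with community productivity (BP, BA, sBP), and
mean pairwise niche overlap / niche difference are computed — the
bin-level view of how phylogenetic distance structures niche
differentiation and the productivity of clades.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
import skbio

from .diversity import cophenetic_distances
from .stats import pearson

logger = logging.getLogger(__name__)

DEFAULT_BIN_THRESHOLD = 0.1


def bin_phylogeny(tree: skbio.TreeNode, threshold: float = DEFAULT_BIN_THRESHOLD,
                  mode: str = "pairwise"):
    """Partition the tree's tips into phylogenetic bins.

    ``mode='pairwise'`` (default): a clade qualifies when its maximum
    within-clade cophenetic distance is <= ``threshold``; bins are the
    maximal qualifying clades found by root-to-tip traversal.
    ``mode='depth'``: a clade qualifies when every member tip lies within
    ``threshold`` branch-length units of the clade root (a tip-depth cut).

    Returns
    -------
    assignment : Series
        taxon_id -> bin_id (bin ids in traversal order).
    bins : DataFrame
        Per bin: ``n_taxa`` and ``mean_pd`` (mean pairwise cophenetic
        distance; NaN for singletons).
    """
    if threshold < 0:
        raise ValueError("bin threshold must be non-negative")
    if mode not in ("pairwise", "depth"):
        raise ValueError(f"unknown binning mode {mode!r}")
    dmat = cophenetic_distances(tree)
    ids = {name: k for k, name in enumerate(dmat.index)}
    d = dmat.to_numpy()

    def qualifies(node) -> bool:
        tip_names = [t.name for t in node.tips()]
        idx = [ids[n] for n in tip_names]
        if mode == "pairwise":
            return d[np.ix_(idx, idx)].max() <= threshold

        def tip_depth(tip):
            dep, cur = 0.0, tip
            while cur is not node:
                dep += cur.length
                cur = cur.parent
            return dep

        return max(tip_depth(t) for t in node.tips()) <= threshold

    assignment = {}
    bin_members: list[list[str]] = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_tip():
            bin_members.append([node.name])
        elif qualifies(node):
            bin_members.append([t.name for t in node.tips()])
        else:
            # reversed: preorder left-to-right with a LIFO stack
            stack.extend(reversed(node.children))

    records = []
    for k, members in enumerate(bin_members):
        bin_id = f"bin_{k:04d}"
        for name in members:
            assignment[name] = bin_id
        if len(members) > 1:
            idx = [ids[n] for n in members]
            sub = d[np.ix_(idx, idx)]
            mean_pd = sub[np.triu_indices(len(idx), k=1)].mean()
        else:
            mean_pd = np.nan
        records.append({"bin_id": bin_id, "n_taxa": len(members),
                        "mean_pd": mean_pd})
    series = pd.Series(assignment, name="bin_id")
    series.index.name = "taxon_id"
    bins = pd.DataFrame(records).set_index("bin_id")
    return series, bins


def bin_statistics(assignment: pd.Series, bins: pd.DataFrame,
                   abundances: pd.DataFrame, meta: pd.DataFrame,
                   niche_table: pd.DataFrame,
                   overlap: pd.DataFrame) -> pd.DataFrame:
    """Per-bin statistics linking phylogeny, niche structure and productivity.

    For every bin: Pearson r of the bin's per-sample mean member relative
    abundance against BP, BA and sBP (NaN when fewer than 3 complete
    samples or zero variance), and the mean pairwise niche overlap and
    AWM-salinity difference over unordered member pairs (NaN for
    singletons).
    """
    stats = bins.copy()
    awm_sal = niche_table["awm_salinity"]
    prod_cols = [c for c in ("bp", "ba", "sbp") if c in meta.columns]
    for bin_id in stats.index:
        members = assignment.index[assignment == bin_id]
        members = [m for m in members if m in abundances.columns]
        mean_abund = abundances[members].mean(axis=1)
        for col in prod_cols:
            y = meta[col].reindex(abundances.index)
            ok = mean_abund.notna() & y.notna()
            if ok.sum() < 3:
                logger.warning("bin %s: < 3 complete samples for %s correlation",
                               bin_id, col)
                r = np.nan
            else:
                r, _ = pearson(mean_abund[ok], y[ok])
            stats.loc[bin_id, f"r_{col}"] = r
        if len(members) > 1:
            pairs = list(combinations(members, 2))
            in_overlap = [p for p in pairs
                          if p[0] in overlap.index and p[1] in overlap.index]
            stats.loc[bin_id, "mean_overlap"] = (
                np.mean([overlap.loc[i, j] for i, j in in_overlap])
                if in_overlap else np.nan)
            sal_pairs = [(awm_sal.get(i), awm_sal.get(j)) for i, j in pairs]
            diffs = [abs(a - b) for a, b in sal_pairs
                     if pd.notna(a) and pd.notna(b)]
            stats.loc[bin_id, "mean_niche_difference"] = (
                np.mean(diffs) if diffs else np.nan)
        else:
            stats.loc[bin_id, "mean_overlap"] = np.nan
            stats.loc[bin_id, "mean_niche_difference"] = np.nan
    return stats
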