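"""Salinity-niche metrics for individual taxa.

Each taxon's realized environmental optimum is summarized by the
abundance-weighted mean (AWM) of a per-sample variable over the samples it
occupies:

    AWM = sum_i w_i v_i / sum_i w_i,

with ``w_i`` the taxon's abundance in sample ``i`` and ``v_i`` the
variable (salinity for the niche optimum, cell-specific production for a
per-taxon productivity score). AWM salinity is then thresholded with the
same water-mass cuts as the samples to classify plume / mixed / SCS
indicator taxa, and pairwise niche structure is quantified by Levins'
overlap of abundance profiles and by absolute AWM-salinity differences.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_io import classify_water_mass

logger = logging.getLogger(__name__)

OVERLAP_METHODS = ("levins", "pianka", "schoener")


def awm_strategy(abundances: pd.DataFrame, v: pd.Series) -> pd.Series:
    """Abundance-weighted mean of a per-sample variable, per taxon.

    ``abundances`` is samples x taxa (counts or relative abundances —
    the AWM is invariant to rescaling a taxon's profile); ``v`` is indexed
    by sample. Taxa with zero total abundance get NaN.
    """
    v = v.reindex(abundances.index).astype(float)
    w = abundances.to_numpy(dtype=float)
    totals = w.sum(axis=0)
    if np.isnan(v.to_numpy()[(w > 0).any(axis=1)]).any():
        raise ValueError("variable is missing in a sample with positive abundance")
    with np.errstate(invalid="ignore", divide="ignore"):
        awm = (w * v.to_numpy()[:, None]).sum(axis=0) / totals
    awm[totals == 0] = np.nan
    return pd.Series(awm, index=abundances.columns)


def classify_indicators(awm_salinity: pd.Series) -> pd.Series:
    """Label taxa as plume / mixed / scs indicators from their AWM salinity.

    Uses the same thresholds and boundary convention as the sample-level
    water-mass classification. Taxa with undefined niche are left
    unclassified (NaN) with a warning.
    """
    labels = pd.Series(pd.NA, index=awm_salinity.index, dtype="object")
    defined = awm_salinity.notna()
    if (~defined).any():
        logger.warning("%d taxa have undefined salinity niche; left unclassified",
                       int((~defined).sum()))
    labels[defined] = awm_salinity[defined].map(classify_water_mass)
    return labels.rename("indicator")


def _profiles(abundances: pd.DataFrame) -> np.ndarray:
    """Per-taxon occupancy profiles p_ih (columns normalized to sum 1)."""
    w = abundances.to_numpy(dtype=float)
    totals = w.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("niche overlap undefined for zero-abundance taxa")
    return w / totals


def niche_overlap(abundances: pd.DataFrame, method: str = "levins",
                  symmetrize: bool = True) -> pd.DataFrame:
    """Pairwise niche overlap of taxa from their sample-abundance profiles.

    Levins (default): O_ij = sum_h p_ih p_jh / sum_h p_ih^2 — asymmetric;
    the pairwise summary averages O_ij and O_ji when ``symmetrize``.
    Pianka: O_ij = sum_h p_ih p_jh / sqrt(sum p_ih^2 sum p_jh^2).
    Schoener: O_ij = 1 - 0.5 sum_h |p_ih - p_jh|.
    """
    if method not in OVERLAP_METHODS:
        raise ValueError(f"unknown overlap method {method!r}")
    p = _profiles(abundances)
    gram = p.T @ p
    diag = np.diag(gram)
    if method == "levins":
        overlap = gram / diag[:, None]
        if symmetrize:
            overlap = 0.5 * (overlap + overlap.T)
    elif method == "pianka":
        overlap = gram / np.sqrt(diag[:, None] * diag[None, :])
    else:  # schoener
        n = p.shape[1]
        overlap = np.empty((n, n))
        for i in range(n):
            overlap[i] = 1.0 - 0.5 * np.abs(p[:, [i]] - p).sum(axis=0)
    return pd.DataFrame(overlap, index=abundances.columns, columns=abundances.columns)


def niche_difference(awm_salinity: pd.Series) -> pd.DataFrame:
    """|AWM salinity_i - AWM salinity_j| for all taxon pairs (PSU).

    Taxa with undefined niche are excluded rather than imputed.
    """
    s = awm_salinity.dropna()
    vals = s.to_numpy(dtype=float)
    diff = np.abs(vals[:, None] - vals[None, :])
    return pd.DataFrame(diff, index=s.index, columns=s.index)


def build_niche_table(abundances: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon niche summary: AWM salinity, AWM sBP, indicator class,
    mean relative abundance."""
    if "salinity" not in meta.columns:
        raise ValueError("metadata lacks required column 'salinity'")
    awm_sal = awm_strategy(abundances, meta["salinity"])
    table = pd.DataFrame({"awm_salinity": awm_sal})
    if "sbp" in meta.columns:
        table["awm_sbp"] = awm_strategy(abundances, meta["sbp"])
    table["indicator"] = classify_indicators(awm_sal)
    rel = abundances.div(abundances.sum(axis=1), axis=0)
    table["mean_rel_abundance"] = rel.mean(axis=0)
    table.index.name = "taxon_id"
    return table


def pair_matrix_long(matrix: pd.DataFrame, value_name: str) -> pd.DataFrame:
    """Flatten a square pair matrix to long format (taxon_i, taxon_j, value),
    unordered pairs only."""
    ids = list(matrix.index)
    rows = []
    arr = matrix.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append((ids[i], ids[j], arr[i, j]))
    return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", value_name])
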