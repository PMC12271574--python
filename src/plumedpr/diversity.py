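"""Species and phylogenetic diversity.

Implements the diversity layer of the analysis: per-sample richness and
Shannon entropy, abundance-weighted mean pairwise phylogenetic distance
(MPD) from cophenetic tip-to-tip distances, and the standardized effect
size of MPD (SES_MPD) against an independent-swap null model.

The abundance-weighted MPD of a sample with relative abundances ``w`` and
cophenetic distances ``d`` is

    MPD = sum_{i != j} w_i w_j d_ij / sum_{i != j} w_i w_j,

restricted to taxa present in the sample and invariant to rescaling of
``w``. The null model randomizes the community matrix with 2x2
checkerboard swaps that carry abundances, preserving per-sample richness
and per-taxon occurrence frequency exactly, and

    SES_MPD = (MPD_obs - mean(MPD_null)) / sd(MPD_null).

Positive SES_MPD means co-occurring taxa are more phylogenetically
dispersed than expected under the null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import skbio
from numba import njit

logger = logging.getLogger(__name__)

DEFAULT_N_NULL = 999
DEFAULT_N_SWAPS = 1000


def cophenetic_distances(tree: skbio.TreeNode) -> pd.DataFrame:
    """Tip-to-tip path-length (cophenetic) distance matrix of a tree."""
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("tree has missing branch lengths")
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def richness_shannon(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness (taxa with count > 0) and Shannon entropy (nats)."""
    arr = counts.to_numpy(dtype=float)
    row_sums = arr.sum(axis=1)
    if (row_sums <= 0).any():
        raise ValueError("zero-sum samples have undefined diversity")
    richness = (arr > 0).sum(axis=1)
    p = arr / row_sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    return pd.DataFrame({"richness": richness, "shannon": shannon},
                        index=counts.index)


def weighted_mpd(weights, dists) -> float:
    """Abundance-weighted MPD of one community.

    ``weights`` is a per-taxon abundance vector aligned with ``dists``
    (any non-negative scale; MPD is scale-invariant); ``dists`` a square
    cophenetic matrix (ndarray or DataFrame). Returns NaN with a warning
    when fewer than two taxa are present.
    """
    w = np.asarray(weights, dtype=float)
    d = dists.to_numpy() if isinstance(dists, pd.DataFrame) else np.asarray(dists, float)
    if w.shape[0] != d.shape[0]:
        raise ValueError("weights and distance matrix are not aligned")
    present = w > 0
    if present.sum() < 2:
        logger.warning("MPD undefined for a community with < 2 taxa")
        return float("nan")
    w = w[present]
    d = d[np.ix_(present, present)]
    num = w @ d @ w  # diag(d) == 0, so the i == j terms vanish
    den = w.sum() ** 2 - (w ** 2).sum()
    return float(num / den)


def _mpd_rows(weight_matrix: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorized weighted MPD over the rows of a samples x taxa matrix."""
    w = weight_matrix / weight_matrix.sum(axis=1, keepdims=True)
    num = np.einsum("si,ij,sj->s", w, d, w)
    den = 1.0 - (w ** 2).sum(axis=1)
    present = (weight_matrix > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mpd = num / den
    mpd[present < 2] = np.nan
    return mpd


@njit(cache=True)
def _swap_kernel(mat, n_swaps, max_attempts, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n, m = mat.shape
    done = 0
    attempts = 0
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        r1 = np.random.randint(0, n)
        r2 = np.random.randint(0, n)
        c1 = np.random.randint(0, m)
        c2 = np.random.randint(0, m)
        if r1 == r2 or c1 == c2:
            continue
        a = mat[r1, c1]
        b = mat[r1, c2]
        c = mat[r2, c1]
        d = mat[r2, c2]
        if a > 0 and d > 0 and b == 0 and c == 0:
            mat[r1, c1] = 0
            mat[r2, c2] = 0
            mat[r1, c2] = a
            mat[r2, c1] = d
            done += 1
        elif b > 0 and c > 0 and a == 0 and d == 0:
            mat[r1, c2] = 0
            mat[r2, c1] = 0
            mat[r1, c1] = b
            mat[r2, c2] = c
            done += 1
    return done


def independent_swap(counts: pd.DataFrame, n_swaps: int = DEFAULT_N_SWAPS,
                     seed: int = 0, attempts_per_swap: int = 200) -> pd.DataFrame:
    """Randomize a community matrix with abundance-carrying checkerboard swaps.

    A swap picks a 2x2 submatrix with occupancy pattern [[+,0],[0,+]] (or
    its mirror) and moves the two non-zero entries to the opposite
    diagonal, carrying their abundances. Per-sample richness (row
    occupancy) and per-taxon occurrence frequency (column occupancy) are
    preserved exactly, as is total abundance. ``n_swaps`` successful swaps
    are performed; if the matrix admits no checkerboard the input is
    returned unchanged once the attempt budget is spent.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be non-negative")
    mat = counts.to_numpy().astype(np.int64).copy()
    sub_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    done = _swap_kernel(mat, n_swaps, max(1, n_swaps) * attempts_per_swap, sub_seed)
    if done < n_swaps:
        logger.debug("independent_swap: %d of %d swaps achieved", done, n_swaps)
    return pd.DataFrame(mat, index=counts.index, columns=counts.columns)


def ses_mpd(counts: pd.DataFrame, dists: pd.DataFrame,
            n_null: int = DEFAULT_N_NULL, n_swaps: int = DEFAULT_N_SWAPS,
            seed: int = 0):
    """Observed MPD and its standardized effect size under the swap null.

    Each of the ``n_null`` replicates applies ``n_swaps`` successful
    independent swaps to the *observed* matrix (replicate seeds spawned
    from ``seed``, so replicates are independent chains, not one long
    chain), then recomputes the abundance-weighted MPD of every sample.

    Returns
    -------
    table : DataFrame
        Per sample: ``mpd``, ``ses_mpd``, ``null_mean``, ``null_sd``.
        SES is NaN where the null sd is degenerate (< 1e-12) or the
        sample has < 2 taxa.
    null_mpds : ndarray, shape (n_null, n_samples)
        The null MPD replicates, for audit.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    dists = dists.loc[counts.columns, counts.columns]
    d = dists.to_numpy()
    obs = _mpd_rows(counts.to_numpy(dtype=float), d)

    children = np.random.SeedSequence(seed).spawn(n_null)
    null_mpds = np.empty((n_null, counts.shape[0]))
    mat0 = counts.to_numpy().astype(np.int64)
    for k, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        mat = mat0.copy()
        _swap_kernel(mat, n_swaps, max(1, n_swaps) * 200, sub_seed)
        null_mpds[k] = _mpd_rows(mat.astype(float), d)

    null_mean = np.nanmean(null_mpds, axis=0)
    null_sd = np.nanstd(null_mpds, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = (obs - null_mean) / null_sd
    degenerate = null_sd < 1e-12
    if degenerate.any():
        logger.warning("SES_MPD undefined for %d samples (degenerate null sd)",
                       int(degenerate.sum()))
    ses[degenerate] = np.nan
    table = pd.DataFrame(
        {"mpd": obs, "ses_mpd": ses, "null_mean": null_mean, "null_sd": null_sd},
        index=counts.index,
    )
    return table, null_mpds


def diversity_table(counts: pd.DataFrame, dists: pd.DataFrame,
                    n_null: int = DEFAULT_N_NULL, n_swaps: int = DEFAULT_N_SWAPS,
                    seed: int = 0) -> pd.DataFrame:
    """Full per-sample diversity table: richness, shannon, mpd, ses_mpd."""
    rs = richness_shannon(counts)
    ses, _ = ses_mpd(counts, dists, n_null=n_null, n_swaps=n_swaps, seed=seed)
    return pd.concat([rs, ses[["mpd", "ses_mpd"]]], axis=1)
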