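"""Compositionality-robust co-occurrence networks and derived sample metrics.

Relative-abundance (compositional) data induce spurious negative
correlations; the SparCC approach estimates correlations between the
latent *basis* abundances instead. For taxa i, j with fractions x_i, x_j
the log-ratio variation t_ij = var(log(x_i/x_j)) decomposes as

    t_ij = w_i^2 + w_j^2 - 2 r_ij w_i w_j,

with w_i^2 the basis log-variance of taxon i and r_ij the basis
correlation. Under sparsity (most r_ij ~ 0) the basis variances solve a
linear system in the row sums of t; strongly correlated pairs that
violate the sparsity assumption are excluded from the system iteratively.
Uncertainty from finite counts is integrated out by averaging over
Dirichlet posterior resamples of each sample's fractions, and
significance is assessed by a permutation bootstrap.

The significant-edge meta-network (p < .01, |r| >= 0.75 by default) is
then restricted to each sample's present taxa to form per-sample
subnetworks, summarized by topology (size, connectivity, mean degree,
clustering, modularity), cohesion (abundance-weighted mean correlation
with network partners), and a complementarity proxy: the total branch
length of the phylogenetic subtree spanned by the sample's co-occurring
taxa.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

DEFAULT_N_INNER = 20
DEFAULT_EXCLUSION_THRESHOLD = 0.1
DEFAULT_EXCLUSION_ITER = 10
DEFAULT_N_BOOT = 100
DEFAULT_R_CUT = 0.75
DEFAULT_P_CUT = 0.01


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def _variation_matrix(fracs: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i / x_j)) across samples, from log-fraction covariance."""
    logf = np.log(fracs)
    cov = np.cov(logf, rowvar=False, ddof=1)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(t: np.ndarray, exclusion_threshold: float,
                        max_iter: int) -> np.ndarray:
    """Solve the sparsity-approximated basis system and return correlations.

    One strongly correlated pair (the current max |r| above the threshold)
    is removed from the system per iteration, up to ``max_iter`` rounds.
    """
    d = t.shape[0]
    m = np.full((d, d), 1.0)
    np.fill_diagonal(m, d - 1.0)
    t_work = t.copy()
    excluded = np.zeros((d, d), dtype=bool)

    r = None
    for _ in range(max_iter + 1):
        row_sums = (t_work * ~excluded).sum(axis=1) - np.diag(t_work)
        try:
            omega_sq = np.linalg.solve(m, row_sums)
        except np.linalg.LinAlgError:
            omega_sq = np.linalg.lstsq(m, row_sums, rcond=None)[0]
        omega_sq = np.maximum(omega_sq, 1e-10)
        omega = np.sqrt(omega_sq)
        with np.errstate(invalid="ignore"):
            r = (omega_sq[:, None] + omega_sq[None, :] - t) / (2.0 * np.outer(omega, omega))
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)

        cand = np.abs(r).copy()
        np.fill_diagonal(cand, 0.0)
        cand[excluded] = 0.0
        # keep every taxon in at least two pairs so the system stays solvable
        weak = m.diagonal() <= 2.0
        cand[weak, :] = 0.0
        cand[:, weak] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            return r, False
        # drop pair (i, j) from the linear system
        excluded[i, j] = excluded[j, i] = True
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
    return r, True


def sparcc(counts: pd.DataFrame, n_inner: int = DEFAULT_N_INNER,
           exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
           seed: int = 0, max_exclusion_iter: int = DEFAULT_EXCLUSION_ITER) -> pd.DataFrame:
    """Estimate basis correlations between taxa from a count table.

    ``n_inner`` Dirichlet resamples (pseudocount 1 on each sample's
    counts) propagate count uncertainty; the returned matrix is the mean
    of the per-resample basis correlations, clipped to [-1, 1].
    """
    n_samples, n_taxa = counts.shape
    if n_taxa < 4:
        raise ValueError("SparCC needs >= 4 taxa (basis system underdetermined)")
    if n_samples < 4:
        raise ValueError("SparCC needs >= 4 samples")
    mat = counts.to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    acc = np.zeros((n_taxa, n_taxa))
    n_capped = 0
    for _ in range(n_inner):
        gam = rng.standard_gamma(mat + 1.0)
        fracs = gam / gam.sum(axis=1, keepdims=True)
        t = _variation_matrix(fracs)
        r_inner, capped = _basis_correlations(t, exclusion_threshold,
                                              max_exclusion_iter)
        acc += r_inner
        n_capped += capped
    if n_capped:
        logger.debug("SparCC exclusion loop hit the iteration cap in %d/%d "
                     "resamples (expected with many taxa)", n_capped, n_inner)
    r = np.clip(acc / n_inner, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=counts.columns, columns=counts.columns)


def bootstrap_pvalues(counts: pd.DataFrame, r_obs: pd.DataFrame,
                      n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
                      **sparcc_kwargs) -> pd.DataFrame:
    """Two-sided permutation pseudo-p-values for SparCC correlations.

    Each bootstrap permutes every taxon's counts across samples
    independently (destroying all between-taxon association while keeping
    marginals), recomputes SparCC, and

        p_ij = (1 + #{|r_boot,ij| >= |r_obs,ij|}) / (n_boot + 1),

    so p is never 0 and the smallest attainable value at 100 bootstraps
    is 1/101 ~ 0.0099.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    r0 = np.abs(r_obs.loc[counts.columns, counts.columns].to_numpy())
    ss = np.random.SeedSequence(seed)
    perm_rng = np.random.default_rng(ss.spawn(1)[0])
    sparcc_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n_boot)]
    mat = counts.to_numpy()
    exceed = np.zeros_like(r0)
    for b in range(n_boot):
        perm = np.column_stack([perm_rng.permutation(mat[:, k])
                                for k in range(mat.shape[1])])
        r_b = sparcc(pd.DataFrame(perm, columns=counts.columns),
                     seed=sparcc_seeds[b], **sparcc_kwargs).to_numpy()
        exceed += np.abs(r_b) >= r0
    p = (1.0 + exceed) / (n_boot + 1.0)
    p = 0.5 * (p + p.T)  # exact symmetry despite column-wise permutation noise
    return pd.DataFrame(p, index=counts.columns, columns=counts.columns)


# ---------------------------------------------------------------------------
# meta-network and per-sample subnetworks
# ---------------------------------------------------------------------------

def build_metanetwork(r: pd.DataFrame, p: pd.DataFrame,
                      r_cut: float = DEFAULT_R_CUT,
                      p_cut: float = DEFAULT_P_CUT) -> nx.Graph:
    """Threshold (r, p) into the signed co-occurrence meta-network.

    An edge joins taxa i, j iff p_ij < ``p_cut`` and |r_ij| >= ``r_cut``;
    its sign attribute follows the sign of r. Nodes are the taxa that
    participate in at least one significant edge.
    """
    if list(r.index) != list(r.columns) or list(p.index) != list(p.columns):
        raise ValueError("correlation / p matrices must be square with matching ids")
    if not np.allclose(r.to_numpy(), r.to_numpy().T, atol=1e-12):
        raise ValueError("correlation matrix is not symmetric")
    if not np.allclose(p.to_numpy(), p.to_numpy().T, atol=1e-12):
        raise ValueError("p-value matrix is not symmetric")
    p = p.loc[r.index, r.columns]
    g = nx.Graph()
    ids = list(r.index)
    r_arr, p_arr = r.to_numpy(), p.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if p_arr[i, j] < p_cut and abs(r_arr[i, j]) >= r_cut:
                g.add_edge(ids[i], ids[j], r=float(r_arr[i, j]),
                           p=float(p_arr[i, j]),
                           sign="+" if r_arr[i, j] > 0 else "-")
    return g


def sample_subnetwork(meta: nx.Graph, abundances: pd.Series) -> nx.Graph:
    """Meta-network restricted to the taxa present (> 0) in one sample."""
    present = set(abundances.index[abundances > 0])
    keep = [n for n in meta.nodes if n in present]
    return meta.subgraph(keep).copy()


def topology_metrics(g: nx.Graph) -> dict:
    """Size, connectivity, mean degree, average local clustering, modularity.

    Modularity is Q of the greedy agglomerative community partition on
    the unsigned graph; node order is fixed (sorted ids) so the partition
    is deterministic. Empty graphs yield all-zero metrics with a warning.
    """
    size = g.number_of_nodes()
    edges = g.number_of_edges()
    if size == 0:
        logger.warning("topology metrics of an empty graph are all zero")
        return {"size": 0, "connectivity": 0, "mean_degree": 0.0,
                "clustering": 0.0, "modularity": 0.0}
    # rebuild with deterministic node/edge order for reproducible agglomeration
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes))
    h.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in g.edges))
    mean_degree = 2.0 * edges / size
    clustering = nx.average_clustering(h) if size > 0 else 0.0
    if edges == 0:
        modularity = 0.0
    else:
        communities = nx.community.greedy_modularity_communities(h)
        modularity = nx.community.modularity(h, communities)
    return {"size": size, "connectivity": edges, "mean_degree": mean_degree,
            "clustering": clustering, "modularity": float(modularity)}


def cohesion(meta: nx.Graph, abundances: pd.Series):
    """Positive / negative cohesion of one sample against the meta-network.

    Each taxon's positive (negative) connectedness is the mean r over its
    positive (negative) significant edges, 0 if it has none; cohesion
    weights connectedness by the taxon's relative abundance in the sample
    and sums over taxa:

        C+ = sum_i a_i * mean(r+ of i),   C- = sum_i a_i * mean(r- of i).

    Returns (positive cohesion, negative cohesion, |negative|/positive
    ratio); the ratio is NaN with a warning when positive cohesion is 0.
    """
    pos = 0.0
    neg = 0.0
    for node in meta.nodes:
        a = float(abundances.get(node, 0.0))
        if a <= 0:
            continue
        rs = [d["r"] for _, _, d in meta.edges(node, data=True)]
        pos_rs = [x for x in rs if x > 0]
        neg_rs = [x for x in rs if x < 0]
        if pos_rs:
            pos += a * (sum(pos_rs) / len(pos_rs))
        if neg_rs:
            neg += a * (sum(neg_rs) / len(neg_rs))
    if pos == 0.0:
        if neg != 0.0:
            logger.warning("negative/positive cohesion ratio undefined "
                           "(positive cohesion is zero)")
            ratio = float("nan")
        else:
            ratio = 0.0
    else:
        ratio = abs(neg) / pos
    return pos, neg, ratio


def complementarity(tips, tree: skbio.TreeNode) -> float:
    """Total branch length of the minimal subtree connecting ``tips``.

    The stem above the tips' most recent common ancestor is excluded.
    Fewer than two tips span no subtree, so the value is 0.
    """
    tips = list(tips)
    if len(tips) < 2:
        return 0.0
    tip_map = {t.name: t for t in tree.tips()}
    missing = [t for t in tips if t not in tip_map]
    if missing:
        raise ValueError(f"tips absent from tree: {missing[:10]}")
    nodes = [tip_map[t] for t in tips]
    mrca = tree.lowest_common_ancestor(nodes)
    seen = set()
    total = 0.0
    for node in nodes:
        while node is not mrca and id(node) not in seen:
            seen.add(id(node))
            total += node.length
            node = node.parent
    return total


def subnetwork_metrics(meta: nx.Graph, abundances: pd.DataFrame,
                       tree: skbio.TreeNode) -> pd.DataFrame:
    """Per-sample subnetwork summary table.

    ``abundances`` is the samples x taxa *relative* abundance table of the
    whole community (cohesion weights come from it); complementarity uses
    the subgraph's co-occurring taxa — nodes with degree >= 1.
    """
    rows = {}
    for sample_id, row in abundances.iterrows():
        sub = sample_subnetwork(meta, row)
        topo = topology_metrics(sub) if sub.number_of_nodes() else {
            "size": 0, "connectivity": 0, "mean_degree": 0.0,
            "clustering": 0.0, "modularity": 0.0}
        pos, neg, ratio = cohesion(meta, row)
        cooccurring = [n for n, deg in sub.degree() if deg >= 1]
        comp = complementarity(cooccurring, tree)
        rows[sample_id] = {**topo, "positive_cohesion": pos,
                           "negative_cohesion": neg,
                           "neg_pos_cohesion_ratio": ratio,
                           "complementarity": comp}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return table


def edge_table(meta: nx.Graph) -> pd.DataFrame:
    """Edge list (taxon_i, taxon_j, r, p, sign) of the meta-network."""
    rows = [(u, v, d["r"], d["p"], d["sign"])
            for u, v, d in sorted(meta.edges(data=True))]
    return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "r", "p", "sign"])
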