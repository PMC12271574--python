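"""Group statistics: Kruskal-Wallis with BH correction and compact-letter
display, Pearson correlation, and hierarchical partitioning of R².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """Omnibus Kruskal-Wallis result with pairwise follow-up.

    ``letters`` is the compact letter display: groups that share a letter
    are not significantly different at the BH-adjusted 0.05 level.
    """

    variable: str
    h: float
    df: int
    p: float
    pairwise_p: dict = field(default_factory=dict)
    letters: dict = field(default_factory=dict)
    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)


def pearson(x, y):
    """Pearson r with its two-sided p-value; NaN for degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("Pearson correlation needs >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("Pearson r undefined: zero variance")
        return float("nan"), float("nan")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, never below the raw p)."""
    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


def _compact_letters(groups, nsd_pairs) -> dict:
    """Assign display letters so groups sharing a letter are linked by a
    not-significantly-different relation.

    Letters label the maximal cliques of the NSD graph; clique order (and
    so lettering) follows the given group order for determinism.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(nsd_pairs)
    cliques = list(nx.find_cliques(g))
    order = {name: k for k, name in enumerate(groups)}
    cliques.sort(key=lambda c: sorted(order[m] for m in c))
    letters = {name: "" for name in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, clique in zip(alphabet, cliques):
        for member in clique:
            letters[member] += letter
    return letters


def kruskal_wallis_bh(values: pd.Series, groups: pd.Series,
                      variable: str = "", alpha: float = 0.05) -> TestResult:
    """Kruskal-Wallis omnibus test with BH-corrected pairwise follow-up.

    Groups with fewer than two observations are excluded with a warning.
    Pairwise comparisons use two-sided rank-sum (Mann-Whitney) tests,
    BH-adjusted across the group pairs; the compact letter display is
    derived from the adjusted p-values at ``alpha``.
    """
    values = pd.Series(values).astype(float)
    groups = pd.Series(groups).reindex(values.index)
    ok = values.notna() & groups.notna()
    values, groups = values[ok], groups[ok]
    counts = groups.value_counts()
    small = counts.index[counts < 2]
    if len(small):
        logger.warning("excluding groups with < 2 observations: %s", list(small))
        keep = ~groups.isin(small)
        values, groups = values[keep], groups[keep]
    names = list(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups with >= 2 observations")
    samples = [values[groups == name].to_numpy() for name in names]

    if np.ptp(np.concatenate(samples)) == 0:
        h_stat, p_omni = 0.0, 1.0  # all values tied; scipy raises here
    else:
        h_stat, p_omni = scipy.stats.kruskal(*samples)

    pairs = list(combinations(range(len(names)), 2))
    raw = []
    for i, j in pairs:
        if np.ptp(np.concatenate([samples[i], samples[j]])) == 0:
            raw.append(1.0)
        else:
            raw.append(scipy.stats.mannwhitneyu(
                samples[i], samples[j], alternative="two-sided").pvalue)
    adj = benjamini_hochberg(raw) if raw else np.array([])
    pairwise = {(names[i], names[j]): float(a)
                for (i, j), a in zip(pairs, adj)}
    nsd = [(names[i], names[j]) for (i, j), a in zip(pairs, adj) if a >= alpha]
    # letter 'a' goes to the highest-valued group, as in summary tables
    order = sorted(names, key=lambda n: -float(np.median(values[groups == n])))
    letters = _compact_letters(order, nsd)

    return TestResult(
        variable=variable, h=float(h_stat), df=len(names) - 1, p=float(p_omni),
        pairwise_p=pairwise, letters=letters,
        group_means={n: float(np.mean(values[groups == n])) for n in names},
        group_sds={n: float(np.std(values[groups == n], ddof=1)) for n in names},
    )


def group_comparison_table(data: pd.DataFrame, groups: pd.Series,
                           variables=None, alpha: float = 0.05) -> pd.DataFrame:
    """Mean ± sd per group with significance letters, one row per variable."""
    if variables is None:
        variables = [c for c in data.columns if
                     pd.api.types.is_numeric_dtype(data[c])]
    group_names = list(pd.unique(groups.dropna()))
    rows = []
    for var in variables:
        res = kruskal_wallis_bh(data[var], groups, variable=var, alpha=alpha)
        row = {"variable": var, "H": res.h, "df": res.df, "p": res.p}
        for name in group_names:
            if name in res.group_means:
                row[name] = (f"{res.group_means[name]:.3g} ± "
                             f"{res.group_sds[name]:.3g}"
                             f" {res.letters.get(name, '')}".rstrip())
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# hierarchical partitioning
# ---------------------------------------------------------------------------

def _r_squared(y: np.ndarray, x: np.ndarray) -> float:
    """Least-squares R² of y on [1, x] (0 for the intercept-only model)."""
    n = y.shape[0]
    design = np.column_stack([np.ones(n)] + ([x] if x.size else []))
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    return float(1.0 - (resid ** 2).sum() / tss)


def hierarchical_partitioning(response, predictors: pd.DataFrame,
                              groups: dict | None = None) -> pd.DataFrame:
    """Chevan-Sutherland hierarchical partitioning of explained variance.

    Decomposes the full-model least-squares R² of ``response`` on the
    predictors into one *independent effect* per predictor group: the
    average, over all orderings of the groups, of the group's incremental
    R² when added to the groups before it. The independent effects sum to
    the full-model R² exactly.

    ``groups`` maps group names to lists of predictor columns; by default
    every column is its own group. At most 10 groups (2^k subset
    enumeration).
    """
    y = np.asarray(response, dtype=float)
    if groups is None:
        groups = {c: [c] for c in predictors.columns}
    names = list(groups)
    k = len(names)
    if k > 10:
        raise ValueError("at most 10 predictor groups (2^k subsets)")
    if y.shape[0] <= sum(len(v) for v in groups.values()):
        raise ValueError("need more observations than predictors")
    full = np.asarray(predictors[sum(groups.values(), [])], dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), full])) < full.shape[1] + 1:
        logger.warning("collinear predictors: least-squares uses the "
                       "minimum-norm solution; R² is unaffected")

    cache = {}

    def r2(subset: frozenset) -> float:
        if subset not in cache:
            cols = sum((groups[n] for n in names if n in subset), [])
            x = np.asarray(predictors[cols], dtype=float) if cols else np.empty((len(y), 0))
            cache[subset] = _r_squared(y, x)
        return cache[subset]

    effects = {}
    for g in names:
        others = [n for n in names if n != g]
        total = 0.0
        for size in range(k):
            weight = 1.0 / (k * comb(k - 1, size))
            for subset in combinations(others, size):
                s = frozenset(subset)
                total += weight * (r2(s | {g}) - r2(s))
        effects[g] = total

    out = pd.DataFrame({"independent_effect": pd.Series(effects)})
    out.index.name = "predictor_group"
    out.attrs["total_r2"] = r2(frozenset(names))
    return out
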