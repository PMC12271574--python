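"""Data model, file I/O and preprocessing.

The pipeline's in-memory containers are deliberately plain:

* count / abundance tables -- :class:`pandas.DataFrame`, samples as rows,
  taxa as columns;
* sample metadata -- :class:`pandas.DataFrame` indexed by sample id, with
  the column vocabulary of :data:`SAMPLE_COLUMNS`;
* phylogeny -- :class:`skbio.TreeNode` (rooted, branch lengths required);
* 16S copy numbers -- :class:`pandas.Series` indexed by taxon id.

Preprocessing mirrors the upstream amplicon workflow the tables come from:
16S rRNA operon copy-number correction, rarefaction to the minimum sample
depth, conversion to relative abundances, classification of samples into
the three salinity-defined water masses of the study region, and
derivation of bacterial production (BP) and cell-specific production (sBP)
from tritiated-leucine incorporation rates.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

#: Salinity (PSU) below which a sample belongs to the estuarine plume.
PLUME_SALINITY_MAX = 33.0
#: Salinity (PSU) above which a sample belongs to open South China Sea water.
SCS_SALINITY_MIN = 33.75

#: Leucine-to-carbon conversion: 0.35 kg C (mol leucine)^-1, 24 h d^-1,
#: 1 pmol l^-1 h^-1 -> 0.0084 mg C m^-3 d^-1 after unit algebra.
LEUCINE_TO_CARBON_KG_PER_MOL = 0.35
_BP_PER_LEU = LEUCINE_TO_CARBON_KG_PER_MOL * 24.0 * 1.0e-3  # mg C m-3 d-1 per pmol l-1 h-1

#: mg C m^-3 over cells ml^-1 -> fg C cell^-1 (10^12 fg mg^-1 / 10^6 ml m^-3).
_MG_M3_PER_CELL_ML_TO_FG = 1.0e6

SAMPLE_COLUMNS = (
    "salinity", "temperature", "chla", "depth_layer",
    "leu_rate", "bp", "ba", "sbp", "hna", "lna", "water_mass",
)

WATER_MASSES = ("plume", "mixed", "scs")


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check count-table invariants (non-negative, unique ids) and return it."""
    if counts.index.has_duplicates:
        raise ValueError("duplicate sample ids in count table")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate taxon ids in count table")
    arr = counts.to_numpy()
    if not np.isfinite(arr).all():
        raise ValueError("count table contains non-finite entries")
    if (arr < 0).any():
        raise ValueError("count table contains negative entries")
    return counts


def validate_tree(tree: skbio.TreeNode, taxon_ids: Iterable[str]) -> skbio.TreeNode:
    """Check that every taxon maps to exactly one tip with a branch length."""
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("tree has duplicate tip names")
    missing = sorted(set(taxon_ids) - set(tips))
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:10]}" +
                         (" ..." if len(missing) > 10 else ""))
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"missing branch length at node {node.name!r}")
        if node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return tree


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Read a count table from TSV (samples x taxa) or BIOM 2.1 (.biom).

    TSV layout: header row of taxon ids, first column of sample ids.
    BIOM tables (taxa as observations, samples as columns, the format's
    convention) are transposed into the samples-by-taxa orientation.
    """
    path = str(path)
    if path.endswith(".biom"):
        import biom  # noqa: deferred; only needed for BIOM input

        table = biom.load_table(path)
        counts = pd.DataFrame(
            table.matrix_data.toarray().T,
            index=table.ids("sample"),
            columns=table.ids("observation"),
        )
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    counts = counts.astype(np.int64, errors="ignore")
    return validate_counts(counts)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata CSV, indexed by ``sample_id``.

    Unknown columns are passed through untouched.
    """
    meta = pd.read_csv(path)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must contain a 'sample_id' column")
    meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    return meta


def read_tree(path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")


def read_copy_numbers(path) -> pd.Series:
    """Read a two-column TSV (taxon_id, copies) into a Series."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError("copy-number table needs two columns: taxon_id, copies")
    series = table.set_index(table.columns[0])[table.columns[1]].astype(float)
    if (series <= 0).any():
        raise ValueError("copy numbers must be positive")
    return series


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def correct_copy_number(counts: pd.DataFrame, copies: pd.Series,
                        default: float = 1.0) -> pd.DataFrame:
    """Divide each taxon's counts by its 16S rRNA operon copy number.

    Results are rounded half-up back to integers so the corrected table can
    be rarefied. Taxa absent from ``copies`` fall back to ``default`` (a
    no-op at the default of 1) with a logged warning.
    """
    validate_counts(counts)
    if (copies <= 0).any():
        raise ValueError("copy numbers must be positive")
    missing = counts.columns.difference(copies.index)
    if len(missing):
        logger.warning("%d taxa lack copy numbers; defaulting to %g",
                       len(missing), default)
    factors = copies.reindex(counts.columns).fillna(default).to_numpy()
    corrected = np.floor(counts.to_numpy() / factors + 0.5).astype(np.int64)
    return pd.DataFrame(corrected, index=counts.index, columns=counts.columns)


def rarefy(counts: pd.DataFrame, seed: int, depth: int | None = None) -> pd.DataFrame:
    """Subsample every sample without replacement to a common depth.

    ``depth`` defaults to the minimum row sum. One master ``seed`` governs
    all samples; per-sample streams are spawned from it deterministically,
    so the result is reproducible and independent of sample order effects
    within a single stream.
    """
    validate_counts(counts)
    if counts.shape[0] == 0:
        raise ValueError("empty count table")
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        bad = list(row_sums.index[row_sums == 0])
        raise ValueError(f"zero-sum samples cannot be rarefied: {bad}")
    if depth is None:
        depth = int(row_sums.min())
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    if (row_sums < depth).any():
        raise ValueError("rarefaction depth exceeds a sample's total count")

    children = np.random.SeedSequence(seed).spawn(counts.shape[0])
    out = np.empty(counts.shape, dtype=np.int64)
    mat = counts.to_numpy().astype(np.int64)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        out[i] = rng.multivariate_hypergeometric(mat[i], depth)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample (row) to sum to one."""
    row_sums = counts.sum(axis=1)
    if (row_sums <= 0).any():
        bad = list(row_sums.index[row_sums <= 0])
        raise ValueError(f"zero-sum samples have no relative abundances: {bad}")
    return counts.div(row_sums, axis=0)


# ---------------------------------------------------------------------------
# water masses and productivity
# ---------------------------------------------------------------------------

def classify_water_mass(salinity: float) -> str:
    """Map a salinity (PSU) to its water mass.

    ``plume`` below 33, ``scs`` above 33.75, ``mixed`` in between; both
    boundary values belong to ``mixed`` (the outer classes are defined by
    strict inequalities).
    """
    salinity = float(salinity)
    if np.isnan(salinity):
        raise ValueError("salinity is missing (NaN)")
    if salinity < 0:
        raise ValueError("salinity must be non-negative")
    if salinity < PLUME_SALINITY_MAX:
        return "plume"
    if salinity > SCS_SALINITY_MIN:
        return "scs"
    return "mixed"


def classify_water_masses(salinity: pd.Series) -> pd.Series:
    """Vectorized :func:`classify_water_mass` over a salinity Series."""
    return salinity.map(classify_water_mass).rename("water_mass")


def derive_productivity(leu_rate, ba=None):
    """Convert leucine incorporation into bacterial production.

    Parameters
    ----------
    leu_rate : float or array-like
        Leucine incorporation rate, pmol l^-1 h^-1.
    ba : float or array-like, optional
        Bacterial abundance, cells ml^-1. Required for cell-specific
        production.

    Returns
    -------
    bp : float or ndarray
        Bacterial production, mg C m^-3 d^-1 (0.35 kg C per mol leucine,
        24 h per day: 1 pmol l^-1 h^-1 -> 0.0084 mg C m^-3 d^-1).
    sbp : float or ndarray or None
        Cell-specific production, fg C cell^-1 d^-1 (= BP / BA after unit
        conversion); ``None`` when ``ba`` is not given.
    """
    leu = np.asarray(leu_rate, dtype=float)
    if (leu < 0).any():
        raise ValueError("leucine incorporation rate must be non-negative")
    bp = leu * _BP_PER_LEU
    if ba is None:
        sbp = None
    else:
        ba_arr = np.asarray(ba, dtype=float)
        if (ba_arr <= 0).any():
            raise ZeroDivisionError("bacterial abundance must be positive for sBP")
        sbp = bp / ba_arr * _MG_M3_PER_CELL_ML_TO_FG
        if np.isscalar(leu_rate) or leu.ndim == 0:
            sbp = float(sbp)
    if np.isscalar(leu_rate) or leu.ndim == 0:
        bp = float(bp)
    return bp, sbp


def prepare_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Fill in derived metadata columns: water_mass, bp, sbp.

    ``bp`` is derived from ``leu_rate`` where absent; ``sbp`` from
    ``bp``/``ba``. Existing values are kept and, when all three of bp, ba
    and sbp are present, checked for internal consistency.
    """
    meta = meta.copy()
    if "salinity" not in meta.columns:
        raise ValueError("metadata lacks required column 'salinity'")
    meta["water_mass"] = classify_water_masses(meta["salinity"].astype(float))
    if "bp" not in meta.columns and "leu_rate" in meta.columns:
        meta["bp"], _ = derive_productivity(meta["leu_rate"].to_numpy())
    if "sbp" not in meta.columns and {"bp", "ba"}.issubset(meta.columns):
        meta["sbp"] = (meta["bp"] / meta["ba"] * _MG_M3_PER_CELL_ML_TO_FG)
    if {"bp", "ba", "sbp"}.issubset(meta.columns):
        implied = meta["bp"] / meta["ba"] * _MG_M3_PER_CELL_ML_TO_FG
        rel = np.abs(implied - meta["sbp"]) / np.maximum(np.abs(meta["sbp"]), 1e-300)
        if (rel.dropna() > 1e-6).any():
            raise ValueError("sbp inconsistent with bp/ba beyond 1e-6 relative")
    return meta
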