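"""Configuration-driven orchestration of the full analysis.

Stages: preprocess (copy-number correction -> rarefaction -> relative
abundance, water-mass classification, productivity derivation) ->
diversity (richness, Shannon, MPD, SES_MPD) -> niche (AWM salinity/sBP,
indicator classes, overlap and difference matrices) -> network (SparCC,
bootstrap, meta-network, per-sample subnetwork metrics) -> bins
(phylogenetic binning and bin statistics) -> stats (Kruskal-Wallis tables
across water masses, hierarchical partitioning of diversity on indicator
groups). All outputs are TSV plus a YAML run manifest recording inputs,
seed, parameters and collected warnings; a rerun with the same config and
inputs is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, binning, conetwork, core_io, diversity, niche, stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline inputs and parameters (defaults = the analysis defaults)."""

    counts: str = ""
    tree: str = ""
    metadata: str = ""
    copy_numbers: str | None = None
    outdir: str = "results"
    seed: int = 0
    n_null: int = diversity.DEFAULT_N_NULL
    n_swaps: int = diversity.DEFAULT_N_SWAPS
    n_inner: int = conetwork.DEFAULT_N_INNER
    n_boot: int = conetwork.DEFAULT_N_BOOT
    exclusion_threshold: float = conetwork.DEFAULT_EXCLUSION_THRESHOLD
    p_cut: float = conetwork.DEFAULT_P_CUT
    r_cut: float = conetwork.DEFAULT_R_CUT
    bin_threshold: float = binning.DEFAULT_BIN_THRESHOLD
    overlap_method: str = "levins"
    threads: int = 1
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        extra = {k: v for k, v in raw.items() if k not in known}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs.setdefault("extra", {}).update(extra)
        return cls(**kwargs)


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.records: list[str] = []

    def emit(self, record):
        self.records.append(self.format(record))


def _load_inputs(config: RunConfig):
    counts = core_io.read_counts(config.counts)
    tree = core_io.read_tree(config.tree)
    meta = core_io.read_metadata(config.metadata)
    core_io.validate_tree(tree, counts.columns)
    missing = counts.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"samples absent from metadata: {list(missing)[:10]}")
    meta = meta.loc[counts.index]
    copies = (core_io.read_copy_numbers(config.copy_numbers)
              if config.copy_numbers else None)
    return counts, tree, meta, copies


def preprocess(counts, meta, copies, seed: int):
    """Copy-number correction -> rarefaction -> relative abundance; derived
    metadata columns (water_mass, bp, sbp)."""
    if copies is not None:
        counts = core_io.correct_copy_number(counts, copies)
    rarefied = core_io.rarefy(counts, seed=seed)
    rel = core_io.relative_abundance(rarefied)
    meta = core_io.prepare_metadata(meta)
    return rarefied, rel, meta


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle; returns output paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("plumedpr").addHandler(collector)
    try:
        seeds = np.random.SeedSequence(config.seed).spawn(4)
        seed_rarefy, seed_null, seed_sparcc, seed_boot = (
            int(s.generate_state(1)[0] % (2 ** 31)) for s in seeds)

        counts, tree, meta, copies = _load_inputs(config)
        logger.info("loaded %d samples x %d taxa", *counts.shape)

        rarefied, rel, meta = preprocess(counts, meta, copies, seed_rarefy)
        paths = {}

        def save(name, frame, index_label):
            path = outdir / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index_label=index_label,
                         float_format="%.10g")
            paths[name] = str(path)

        save("rarefied_counts", rarefied, "sample_id")
        save("metadata_prepared", meta, "sample_id")

        logger.info("diversity: MPD + SES_MPD, %d null replicates", config.n_null)
        dists = diversity.cophenetic_distances(tree).loc[
            rarefied.columns, rarefied.columns]
        div = diversity.diversity_table(
            rarefied, dists, n_null=config.n_null, n_swaps=config.n_swaps,
            seed=seed_null)
        save("diversity", div, "sample_id")

        logger.info("niche: AWM metrics and pair matrices (%s overlap)",
                    config.overlap_method)
        niche_table = niche.build_niche_table(rarefied, meta)
        save("niche", niche_table, "taxon_id")
        overlap = niche.niche_overlap(rarefied, method=config.overlap_method)
        save("niche_overlap", niche.pair_matrix_long(overlap, "overlap"),
             "pair_id")
        ndiff = niche.niche_difference(niche_table["awm_salinity"])
        save("niche_difference",
             niche.pair_matrix_long(ndiff, "salinity_difference"), "pair_id")

        logger.info("network: SparCC (%d resamples) + %d bootstraps",
                    config.n_inner, config.n_boot)
        r = conetwork.sparcc(rarefied, n_inner=config.n_inner,
                             exclusion_threshold=config.exclusion_threshold,
                             seed=seed_sparcc)
        p = conetwork.bootstrap_pvalues(
            rarefied, r, n_boot=config.n_boot, seed=seed_boot,
            n_inner=config.n_inner,
            exclusion_threshold=config.exclusion_threshold)
        meta_net = conetwork.build_metanetwork(r, p, r_cut=config.r_cut,
                                               p_cut=config.p_cut)
        save("metanetwork_edges", conetwork.edge_table(meta_net), "edge_id")
        try:
            import networkx as nx
            nx.write_graphml(meta_net, outdir / "metanetwork.graphml")
            paths["metanetwork_graphml"] = str(outdir / "metanetwork.graphml")
        except Exception as exc:  # pragma: no cover - optional output
            logger.warning("GraphML export failed: %s", exc)
        subnet = conetwork.subnetwork_metrics(meta_net, rel, tree)
        save("subnetwork_metrics", subnet, "sample_id")

        logger.info("bins: threshold %.3g", config.bin_threshold)
        assignment, bins = binning.bin_phylogeny(tree, config.bin_threshold)
        save("bin_assignment", assignment.to_frame(), "taxon_id")
        bin_stats = binning.bin_statistics(assignment, bins, rel, meta,
                                           niche_table, overlap)
        save("bin_stats", bin_stats, "bin_id")

        logger.info("stats: group comparisons + hierarchical partitioning")
        per_sample = pd.concat([meta[["bp", "ba", "sbp"]], div, subnet], axis=1)
        comparison = stats.group_comparison_table(per_sample, meta["water_mass"])
        save("water_mass_comparison", comparison, "variable")

        hp_frames = []
        indicator_abund = _indicator_abundances(rel, niche_table)
        if indicator_abund.shape[1] >= 2:
            for metric in ("richness", "shannon", "mpd", "ses_mpd"):
                y = div[metric]
                ok = y.notna()
                if ok.sum() <= indicator_abund.shape[1]:
                    continue
                hp = stats.hierarchical_partitioning(
                    y[ok], indicator_abund.loc[ok])
                hp = hp.rename(columns={
                    "independent_effect": f"ie_{metric}"})
                hp_frames.append(hp)
            if hp_frames:
                save("hierarchical_partitioning",
                     pd.concat(hp_frames, axis=1), "predictor_group")

        manifest = {
            "package": "plumedpr",
            "version": __version__,
            "config": asdict(config),
            "stage_seeds": {"rarefy": seed_rarefy, "null_model": seed_null,
                            "sparcc": seed_sparcc, "bootstrap": seed_boot},
            "inputs": {"counts": config.counts, "tree": config.tree,
                       "metadata": config.metadata,
                       "copy_numbers": config.copy_numbers},
            "n_samples": int(counts.shape[0]),
            "n_taxa": int(counts.shape[1]),
            "rarefaction_depth": int(rarefied.sum(axis=1).iloc[0]),
            "assumption_flags": [
                "n_null, swap count and abundance-carrying swaps are package "
                "choices (null model details unstated upstream)",
                "overlap index and symmetrization are config choices",
                "mean degree used as the degree summary",
                "modularity/clustering on the unsigned graph",
                "pairwise follow-up: rank-sum tests with BH across pairs",
            ],
            "warnings": collector.records,
        }
        manifest_path = outdir / "manifest.yaml"
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        paths["manifest"] = str(manifest_path)
        return paths
    finally:
        logging.getLogger("plumedpr").removeHandler(collector)


def _indicator_abundances(rel: pd.DataFrame, niche_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample summed relative abundance of each indicator class."""
    cols = {}
    for label in ("plume", "mixed", "scs"):
        taxa = niche_table.index[niche_table["indicator"] == label]
        if len(taxa):
            cols[f"{label}_indicators"] = rel[taxa].sum(axis=1)
    return pd.DataFrame(cols, index=rel.index)
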