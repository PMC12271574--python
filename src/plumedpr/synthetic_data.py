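"""Synthetic communities along an estuarine-plume salinity gradient.

The generator emulates the statistical structure the analysis pipeline
assumes in the field system: a rooted phylogeny; two trait guilds —
copiotrophs (fast-growing, high per-cell production, plume-adapted
salinity optima, concentrated in several deep and mutually distant
clades) and oligotrophs (slow-growing, high-salinity optima, spread over
the rest of the tree with phylogenetically clustered dominance); Gaussian
salinity niches; multinomial sequencing at log-normal depths; and
productivity coupled to who is abundant:

    BA_s ∝ Σ_t E_ts             (total expected cells)
    BP_s ∝ Σ_t E_ts · prod_t    (production trait weighted by abundance)
    sBP_s = BP_s / BA_s         (cell-specific production)

Because copiotroph clades are few, abundant in the plume, mutually
distant and highly productive, the generated data carry the designed
qualitative pattern of the study system: plume samples have higher
production but lower richness, and abundance-weighted phylogenetic
diversity couples positively to production while richness decouples.
Ground truth (per-taxon optima, guilds, production traits) is returned
for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .core_io import classify_water_mass, derive_productivity

#: fg C ml^-1 d^-1 -> mg C m^-3 d^-1
_FG_ML_TO_MG_M3 = 1.0e-6
_BP_PER_LEU = 0.0084  # mg C m-3 d-1 per pmol leucine l-1 h-1


@dataclass
class SimConfig:
    """Study conditions of the simulated survey (defaults = the emulated one)."""

    seed: int = 0
    n_taxa: int = 250
    n_samples: int = 66
    salinity_range: tuple = (28.0, 34.5)
    copiotroph_fraction: float = 0.3
    copiotroph_optimum: float = 30.5   # PSU, guild mean
    oligotroph_optimum: float = 34.1   # PSU, guild mean
    copiotroph_breadth: float = 1.2    # PSU, Gaussian niche sd
    oligotroph_breadth: float = 0.8    # PSU
    phylo_signal: float = 1.0          # trait-diffusion rate (var per unit branch)
    tree_depth: float = 0.5            # root-to-tip depth, tree distance units
    depth_log_mean: float = float(np.log(2.0e4))  # sequencing depth, log reads
    depth_log_sd: float = 0.3
    productivity_coupling: float = 1.0
    productivity_ratio: float = 3.0    # copiotroph / oligotroph mean production
    noise_sd: float = 0.5              # log-normal abundance noise (log scale)
    ba_scale: float = 2.0e3            # cells ml^-1 per unit expected abundance
    min_clades: int = 3                # deep copiotroph clades
    n_dominant_oligotroph_clades: int = 2  # related clades dominating high salinity

    def __post_init__(self):
        lo, hi = self.salinity_range
        if not (lo < 33.0 and hi > 33.75):
            raise ValueError("salinity range must span plume, mixed and SCS classes")
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")


def simulate_tree(n_taxa: int, seed: int, depth: float = 0.5) -> skbio.TreeNode:
    """Pure-birth (Yule) tree with ``n_taxa`` tips, rescaled to root-to-tip
    ``depth``; bit-reproducible for a fixed seed."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    root = skbio.TreeNode()
    first, second = skbio.TreeNode(length=0.0), skbio.TreeNode(length=0.0)
    root.append(first)
    root.append(second)
    active = [first, second]
    while len(active) < n_taxa:
        k = len(active)
        dt = rng.exponential(1.0 / k)
        for tip in active:
            tip.length += dt
        parent = active.pop(int(rng.integers(k)))
        kids = [skbio.TreeNode(length=0.0), skbio.TreeNode(length=0.0)]
        for kid in kids:
            parent.append(kid)
        active.extend(kids)
    dt = rng.exponential(1.0 / n_taxa)
    for tip in active:
        tip.length += dt
    # rescale to the requested depth (ultrametric by construction)
    current = active[0].length
    node = active[0].parent
    while node.parent is not None:
        current += node.length
        node = node.parent
    factor = depth / current
    for node in root.traverse(include_self=False):
        node.length *= factor
    for i, tip in enumerate(root.tips()):
        tip.name = f"t{i:04d}"
    return root


def _brownian_trait(tree: skbio.TreeNode, rate: float,
                    rng: np.random.Generator) -> dict:
    """Latent trait diffusing along branches; variance ∝ branch length."""
    trait = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(max(rate * node.length, 0.0)))
        trait[id(node)] = trait[id(node.parent)] + step
    return {tip.name: trait[id(tip)] for tip in tree.tips()}


def _pick_copiotroph_clades(tree: skbio.TreeNode, n_taxa: int,
                            target: int, min_clades: int,
                            rng: np.random.Generator) -> list:
    """Choose deep, mutually distant, disjoint clades for the copiotroph guild.

    Candidates hold 3%-15% of the tips; clades are added farthest-first
    (maximizing the minimum tip-to-tip distance to the already chosen)
    until the guild reaches ``target`` tips and ``min_clades`` clades.
    """
    lo = max(3, int(0.03 * n_taxa))
    hi = max(lo + 1, int(0.15 * n_taxa))
    candidates = [node for node in tree.non_tips(include_self=False)
                  if lo <= node.count(tips=True) <= hi]
    rng.shuffle(candidates)
    dmat = tree.tip_tip_distances()
    idx = {name: k for k, name in enumerate(dmat.ids)}

    def rep(node):
        return idx[next(node.tips()).name]

    chosen: list = []
    chosen_tips: set = set()
    n_guild = 0
    while candidates and (n_guild < target or len(chosen) < min_clades):
        disjoint = [c for c in candidates
                    if not ({t.name for t in c.tips()} & chosen_tips)]
        if not disjoint:
            break
        if not chosen:
            pick = disjoint[0]
        else:
            pick = max(disjoint, key=lambda c: min(
                dmat.data[rep(c), rep(o)] for o in chosen))
        chosen.append(pick)
        names = {t.name for t in pick.tips()}
        chosen_tips |= names
        n_guild += len(names)
        candidates = [c for c in candidates if c is not pick]
    return chosen


def _pick_dominant_oligotroph_clades(tree: skbio.TreeNode, n_taxa: int,
                                     taken: set, k: int,
                                     rng: np.random.Generator) -> list:
    """Choose ``k`` *compact* clades (disjoint from ``taken``) whose members
    will dominate high-salinity communities.

    Compactness (clade diameter well below the tree diameter) is what makes
    the high-salinity communities phylogenetically clustered; clades after
    the first are added nearest-first so the dominant region stays coherent.
    """
    lo = max(3, int(0.06 * n_taxa))
    hi = max(lo + 1, int(0.18 * n_taxa))
    dmat = tree.tip_tip_distances()
    idx = {name: j for j, name in enumerate(dmat.ids)}
    tree_diam = dmat.data.max()

    candidates = []
    for node in tree.non_tips(include_self=False):
        names = [t.name for t in node.tips()]
        if not (lo <= len(names) <= hi) or (set(names) & taken):
            continue
        ii = [idx[x] for x in names]
        diam = dmat.data[np.ix_(ii, ii)].max()
        candidates.append((node, set(names), diam, ii[0]))
    if not candidates:
        return []
    compact = [c for c in candidates if c[2] <= 0.5 * tree_diam] or \
        [min(candidates, key=lambda c: c[2])]
    # largest compact clade anchors the dominant region
    compact.sort(key=lambda c: (-len(c[1]), c[2]))
    chosen = [compact[0]]
    chosen_tips = set(compact[0][1])
    while len(chosen) < k:
        disjoint = [c for c in compact if not (c[1] & chosen_tips)]
        if not disjoint:
            break
        pick = min(disjoint, key=lambda c: min(
            dmat.data[c[3], o[3]] for o in chosen))
        if min(dmat.data[pick[3], o[3]] for o in chosen) > 0.5 * tree_diam:
            break  # nothing nearby: keep the region coherent
        chosen.append(pick)
        chosen_tips |= pick[1]
    return [c[0] for c in chosen]


def simulate_traits(tree: skbio.TreeNode, config: SimConfig,
                    seed: int | None = None) -> pd.DataFrame:
    """Assign guilds, salinity optima, niche breadths, production traits
    and abundance amplitudes to the tree's tips.

    Returns the ground-truth table (index: taxon_id) with columns
    ``guild``, ``clade``, ``optimum`` (PSU), ``breadth`` (PSU),
    ``productivity`` (fg C cell^-1 d^-1 scale), ``amplitude``, ``latent``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tips = [t.name for t in tree.tips()]
    n = len(tips)
    latent = _brownian_trait(tree, config.phylo_signal, rng)

    target = int(round(config.copiotroph_fraction * n))
    clades = _pick_copiotroph_clades(tree, n, target, config.min_clades, rng)
    clade_of = {}
    for k, clade in enumerate(clades):
        for t in clade.tips():
            clade_of[t.name] = f"clade_{k}"

    lat = np.array([latent[t] for t in tips])
    z = (lat - lat.mean()) / (lat.std() or 1.0)
    is_cop = np.array([t in clade_of for t in tips])

    # dominant oligotroph clades: few, *mutually close* clades concentrate
    # the high-salinity communities' abundance, so those communities are
    # phylogenetically clustered (negative SES_MPD side of the contrast)
    dominant = _pick_dominant_oligotroph_clades(
        tree, n, set(clade_of), config.n_dominant_oligotroph_clades, rng)
    dominant_tips = set()
    for k, clade in enumerate(dominant):
        for t in clade.tips():
            if t.name not in clade_of:
                clade_of[t.name] = f"olig_clade_{k}"
                dominant_tips.add(t.name)
    is_dom = np.array([t in dominant_tips for t in tips])

    optimum = np.where(
        is_cop,
        config.copiotroph_optimum + 0.3 * z + rng.normal(0, 0.5, n),
        config.oligotroph_optimum + 0.15 * z + rng.normal(0, 0.25, n),
    )
    breadth = np.where(is_cop, config.copiotroph_breadth, config.oligotroph_breadth)
    olig_prod = 1.5
    prod_mean = np.where(is_cop, olig_prod * config.productivity_ratio, olig_prod)
    productivity = prod_mean * rng.lognormal(0.0, 0.25, n)
    amplitude = np.select(
        [is_cop, is_dom],
        [5.0 * rng.lognormal(0.0, 0.3, n), 5.0 * rng.lognormal(0.0, 0.3, n)],
        default=0.4 * rng.lognormal(0.0, 0.4, n),
    )
    truth = pd.DataFrame(
        {
            "guild": np.where(is_cop, "copiotroph", "oligotroph"),
            "clade": [clade_of.get(t, "background") for t in tips],
            "optimum": optimum,
            "breadth": breadth,
            "productivity": productivity,
            "amplitude": amplitude,
            "latent": lat,
        },
        index=pd.Index(tips, name="taxon_id"),
    )
    return truth


def _sample_salinities(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Salinities stratified over the three water-mass classes."""
    lo, hi = config.salinity_range
    bands = [(lo, min(32.9, 33.0 - 1e-6)), (33.0, 33.75), (33.8, hi)]
    n = config.n_samples
    per = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    sal = np.concatenate([rng.uniform(a, b, size=k)
                          for (a, b), k in zip(bands, per)])
    rng.shuffle(sal)
    return sal


def simulate_community(truth: pd.DataFrame, config: SimConfig,
                       seed: int | None = None):
    """Draw the count table and sample metadata from the ground truth.

    Expected abundance of taxon t in sample s is a Gaussian response of
    the sample's salinity around the taxon's optimum, scaled by the
    taxon's amplitude and log-normal noise; counts are multinomial at a
    log-normal sequencing depth. BA, BP, sBP, HNA/LNA counts and a
    consistent leucine incorporation rate are derived per sample.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sal = _sample_salinities(config, rng)
    classes = np.array([classify_water_mass(s) for s in sal])
    if len(set(classes)) < 3:
        raise ValueError("configuration does not span all three water masses")

    taxa = truth.index.to_numpy()
    opt = truth["optimum"].to_numpy()
    br = truth["breadth"].to_numpy()
    amp = truth["amplitude"].to_numpy()
    prod = truth["productivity"].to_numpy()
    is_cop = (truth["guild"] == "copiotroph").to_numpy()

    response = np.exp(-((sal[:, None] - opt[None, :]) ** 2) / (2.0 * br[None, :] ** 2))
    noise = rng.lognormal(0.0, config.noise_sd, size=response.shape)
    expected = amp[None, :] * response * noise  # cells, arbitrary units

    totals = expected.sum(axis=1)
    depths = np.maximum(
        rng.lognormal(config.depth_log_mean, config.depth_log_sd,
                      config.n_samples).astype(np.int64), 100)
    counts = np.vstack([
        rng.multinomial(depths[s], expected[s] / totals[s])
        for s in range(config.n_samples)
    ])

    ba = config.ba_scale * totals  # cells ml^-1
    bp_noise = rng.lognormal(0.0, 0.2, config.n_samples)
    bp = (config.productivity_coupling * config.ba_scale *
          (expected * prod[None, :]).sum(axis=1) * _FG_ML_TO_MG_M3 * bp_noise)
    sbp = bp / ba * 1.0e6  # fg C cell^-1 d^-1
    hna = config.ba_scale * (expected[:, is_cop]).sum(axis=1)
    lna = ba - hna

    sample_ids = [f"S{s:03d}" for s in range(config.n_samples)]
    count_table = pd.DataFrame(counts, index=sample_ids, columns=taxa)
    count_table.index.name = "sample_id"
    lo, hi = config.salinity_range
    meta = pd.DataFrame(
        {
            "salinity": sal,
            "temperature": 30.0 - 1.1 * (sal - lo) + rng.normal(0, 0.4, config.n_samples),
            "chla": np.exp(1.2 - 0.6 * (sal - lo)) * rng.lognormal(0, 0.3, config.n_samples),
            "depth_layer": [
                {"plume": "surface", "mixed": "middle", "scs": "bottom"}[c]
                for c in classes
            ],
            "leu_rate": bp / _BP_PER_LEU,
            "bp": bp,
            "ba": ba,
            "sbp": sbp,
            "hna": hna,
            "lna": lna,
            "water_mass": classes,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    # leu_rate is stored pre-rounding, so the conversion chain is exact
    check_bp, _ = derive_productivity(meta["leu_rate"].to_numpy())
    assert np.allclose(check_bp, bp)
    return count_table, meta


def simulate_dataset(config: SimConfig | None = None, seed: int | None = None):
    """Tree + ground truth + counts + metadata from one master seed.

    Sub-seeds for the tree, traits and community are spawned from the
    master seed, so a dataset is reproduced bit-identically by its seed.
    """
    if config is None:
        config = SimConfig()
    if seed is None:
        seed = config.seed
    s_tree, s_traits, s_comm = [
        int(c.generate_state(1)[0] % (2 ** 31))
        for c in np.random.SeedSequence(seed).spawn(3)
    ]
    tree = simulate_tree(config.n_taxa, s_tree, depth=config.tree_depth)
    truth = simulate_traits(tree, config, seed=s_traits)
    counts, meta = simulate_community(truth, config, seed=s_comm)
    return {"tree": tree, "truth": truth, "counts": counts, "meta": meta,
            "config": config}


def write_dataset(data: dict, outdir) -> dict:
    """Write a dataset in the formats the pipeline reads (TSV / newick / CSV)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "tree": outdir / "tree.nwk",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.tsv",
    }
    data["counts"].to_csv(paths["counts"], sep="\t", index_label="sample_id")
    data["tree"].write(str(paths["tree"]), format="newick")
    data["meta"].to_csv(paths["metadata"], index_label="sample_id")
    data["truth"].to_csv(paths["truth"], sep="\t", index_label="taxon_id")
    return {k: str(v) for k, v in paths.items()}


def fixture_config(seed: int = 0) -> SimConfig:
    """Small test-set conditions: 30 samples x 60 taxa."""
    return SimConfig(seed=seed, n_taxa=60, n_samples=30,
                     depth_log_mean=float(np.log(5000.0)))
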