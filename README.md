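# plumedpr

Phylogenetic diversity–productivity analysis of marine bacterioplankton
communities along estuarine-plume salinity gradients.

## The scientific problem

In coastal seas influenced by river plumes, bacterial production (BP),
abundance (BA) and cell-specific production (sBP = BP/BA) vary strongly
along the salinity gradient from plume water (salinity < 33) through mixed
water (33–33.75) to open-sea water (> 33.75). A central question is which
facet of community diversity tracks this productivity: species diversity
(ASV richness, Shannon index) or *phylogenetic* diversity. The
abundance-weighted mean pairwise phylogenetic distance of a community is

```
MPD = Σᵢ Σ_{j≠i} wᵢ wⱼ dᵢⱼ / Σᵢ Σ_{j≠i} wᵢ wⱼ
```

with `wᵢ` taxon relative abundances and `dᵢⱼ` the cophenetic (tip-to-tip)
distance on the 16S phylogeny, and its standardized effect size against an
independent-swap null model (which preserves each sample's richness and
each taxon's occurrence frequency exactly) is

```
SES_MPD = (MPD_obs − mean MPD_null) / sd MPD_null .
```

Positive SES_MPD means co-occurring taxa are more phylogenetically
dispersed than chance. To separate *complementarity* from the *selection
effect*, the pipeline infers a compositionality-robust co-occurrence
network (SparCC, 100 permutation bootstraps; edges at p < .01 and
|r| ≥ 0.75), restricts it to each sample's present taxa, and summarizes
each subnetwork by topology (size, connectivity, mean degree, clustering,
modularity), cohesion (abundance-weighted mean correlation with network
partners, positive and negative) and a complementarity proxy — the total
branch length of the phylogenetic subtree spanned by the sample's
co-occurring taxa. Per-taxon salinity niches are abundance-weighted mean
(AWM) salinities, thresholded into plume / mixed / open-sea indicator
classes; phylogenetic bins (maximal clades with pairwise distance ≤ 0.1)
link phylogenetic distance to niche overlap (Levins), niche differences
and per-bin abundance–productivity correlations. Group contrasts use
Kruskal–Wallis with Benjamini–Hochberg correction, and the contribution of
indicator groups to diversity is decomposed by hierarchical partitioning.

The package is aimed at microbial ecologists who want this analysis chain
as tested, reusable components rather than a one-off script collection. A
ground-truthed synthetic-data generator (`plumedpr.synthetic_data`)
emulates the gradient's community structure — phylogenetically structured
copiotroph/oligotroph guilds with salinity optima and productivity coupled
to copiotroph abundance — so every stage is testable without field data.

## Worked example

```python
import numpy as np
from plumedpr import core_io, diversity, synthetic_data as sd
from plumedpr.stats import pearson

data = sd.simulate_dataset(sd.fixture_config(seed=0))   # 30 samples x 60 taxa
counts, meta, tree = data["counts"], data["meta"], data["tree"]

rarefied = core_io.rarefy(counts, seed=0)
dists = diversity.cophenetic_distances(tree)
div = diversity.diversity_table(
    rarefied, dists.loc[counts.columns, counts.columns], n_null=999, seed=0)

print(div.join(meta[["water_mass", "bp"]]).groupby("water_mass")[
    ["richness", "shannon", "mpd", "ses_mpd", "bp"]].mean().round(3))
r, p = pearson(div["mpd"], meta["bp"])
print(f"Pearson r(MPD, BP) = {r:.3f} (p = {p:.2e})")
```

prints

```
            richness  shannon    mpd  ses_mpd     bp
water_mass
mixed           58.0    3.235  0.606   -1.859  0.249
plume           28.1    2.772  0.707   -1.004  0.574
scs             51.2    2.999  0.530   -3.980  0.247
Pearson r(MPD, BP) = 0.580 (p = 7.90e-04)
```

The plume-class samples are the most productive (BP in mg C m⁻³ d⁻¹) and
the most phylogenetically dispersed (highest MPD, least-negative SES_MPD)
while carrying the *fewest* taxa — the signature decoupling of species
diversity from productivity, with phylogenetic diversity carrying the
positive diversity–productivity relationship (r = 0.58).

The same analysis runs from the shell:

```bash
plumedpr simulate --outdir data --seed 1
plumedpr all --counts data/counts.tsv --tree data/tree.nwk \
             --metadata data/metadata.csv --outdir results --seed 1
```

which writes the full TSV bundle (diversity, niche, network edge list,
per-sample subnetwork metrics, bin assignment and statistics, water-mass
comparison tables, hierarchical partitioning) plus `manifest.yaml`
recording inputs, seeds, parameters and collected warnings. Reruns with
the same configuration are byte-identical.

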