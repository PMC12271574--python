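# Methods

This note documents the models and procedures implemented in `plumedpr`,
the parameters that matter, the numerical choices made where the design
was genuinely open, what the synthetic-data generator does and does not
emulate, and known limitations.

## Preprocessing (`core_io`)

Count tables are samples × taxa integer matrices (TSV or BIOM 2.1);
phylogenies are rooted newick trees with branch lengths; metadata is CSV
keyed by `sample_id`. The preprocessing order is: 16S rRNA operon
copy-number correction (counts divided by per-taxon copy numbers, rounded
half-up so the table stays integral; taxa without a copy number default to
1 with a warning) → rarefaction to the minimum sample depth → relative
abundances. Rarefaction is an exact without-replacement draw per sample
(`multivariate_hypergeometric`); one user seed governs all samples, with
per-sample streams spawned deterministically from it, so results do not
depend on sample order and are bit-reproducible. A single draw is used —
no rarefaction replicates.

Water masses are defined by salinity: plume < 33 PSU, open-sea (SCS)
> 33.75 PSU, mixed in between. Both boundary values (33.0, 33.75) are
assigned to the mixed class, matching the strict inequalities that define
the outer classes. Bacterial production is derived from ³H-leucine
incorporation with the regional conversion factor 0.35 kg C (mol
leucine)⁻¹ and a linear 24 h day⁻¹ scaling, no isotope-dilution
correction: 1 pmol l⁻¹ h⁻¹ → 0.0084 mg C m⁻³ d⁻¹. Cell-specific
production is BP/BA expressed in fg C cell⁻¹ d⁻¹ (factor 10⁶ from the
mg m⁻³ / cells ml⁻¹ unit algebra); when all three of BP, BA, sBP are
supplied they are checked for consistency to 10⁻⁶ relative.

## Diversity (`diversity`)

Richness counts taxa with positive counts; Shannon entropy uses natural
logarithms (the common ecology default). Abundance-weighted MPD is
computed from the cophenetic matrix restricted to taxa present in the
sample; it is invariant to rescaling the weights and undefined (NaN, with
a warning) below two present taxa.

The null model performs abundance-carrying checkerboard swaps: a 2×2
submatrix with occupancy pattern [[+,0],[0,+]] has its non-zero entries
moved to the opposite diagonal. This preserves per-sample richness,
per-taxon occurrence frequency and total abundance exactly, while letting
abundance-weighted MPD vary across the null (a presence-only shuffle would
leave the weights attached to the same taxa). Defaults: 999 null
replicates, each an independent chain of 1000 successful swaps started
from the observed matrix with a replicate seed spawned from the master
seed (independent chains rather than one reused sequential chain, for
testability); the swap kernel is numba-compiled and caps attempts at 200
per requested swap, so matrices without checkerboards return unchanged.
SES_MPD uses the sample (n−1) standard deviation; null sd below 1e-12 —
e.g. a sample with no zero entries, which no swap can touch — yields NaN
with a warning. Calibration: on data generated by the null process itself
the mean SES over 50 samples is within ±0.15 of zero at 999 replicates
(checked in the test suite).

## Niche metrics (`niche`)

The abundance-weighted mean (AWM) of a per-sample variable over a taxon's
occupancy profile gives its realized optimum; AWM salinity is thresholded
with the same cuts and boundary convention as the sample water masses to
classify indicator taxa. Pairwise niche overlap defaults to Levins'
index, O_ij = Σ_h p_ih p_jh / Σ_h p_ih² on per-taxon profiles normalized
over samples; it is asymmetric, and the pair summary averages the two
directions. Pianka and Schoener indices are selectable alternatives. The
index and symmetrization are package choices (logged in the run
manifest); profiles are computed from the rarefied table, matching the
pipeline order. Taxa with zero total abundance have undefined niches and
are excluded from pair matrices rather than imputed.

## Co-occurrence networks (`conetwork`)

SparCC estimates basis correlations from log-ratio variances
t_ij = var(log(x_i/x_j)) under a sparsity assumption, with basis
variances solved from the linear system in the row sums of t and the
strongest pair above an exclusion threshold removed from the system per
iteration. Internals (all config-exposed): 20 Dirichlet resamples with
pseudocount 1 per sample, exclusion threshold 0.1, iteration cap 10,
final r the mean over resamples, clipped to [−1, 1]. Hitting the
iteration cap is routine at realistic taxon counts and logged at debug
level; exclusion keeps every taxon in at least two pairs and the solver
falls back to least squares if the system degenerates. At least 4 taxa
and 4 samples are required.

Significance uses a permutation bootstrap: each replicate permutes every
taxon's counts across samples independently and recomputes SparCC;
p = (1 + #exceedances)/(n_boot + 1), two-sided on |r|, so p is never zero
and the minimum at the default 100 bootstraps is 1/101 ≈ 0.0099 — the
p < .01 edge criterion is attainable but demands zero exceedances. Edges
require p < .01 *and* |r| ≥ 0.75; nodes of the meta-network are the taxa
participating in at least one edge.

Per-sample subnetworks keep the meta-network nodes present (> 0) in the
sample and the edges between them. Topology is computed on the unsigned
simple graph: mean degree 2E/N; clustering is the average local
clustering coefficient (degree < 2 contributes 0); modularity is Q of the
greedy agglomerative partition with nodes and edges sorted by id first,
so the partition is deterministic. Cohesion weights each taxon's relative
abundance (in the full community) by its mean positive (or negative)
edge correlation; the reported ratio is |negative|/positive cohesion,
NaN when positive cohesion is zero. The complementarity proxy is the
total branch length of the minimal subtree connecting the sample's
*co-occurring* taxa — subgraph nodes with degree ≥ 1 — excluding the stem
above their most recent common ancestor; using all present nodes instead
is config-selectable.

## Phylogenetic binning (`binning`)

Bins are the maximal clades whose largest within-clade cophenetic
distance does not exceed the threshold (default 0.1 tree distance units),
found by root-to-tip traversal; remaining tips become singletons, and no
minimum bin size is imposed. A tip-depth-cut mode is selectable. Bin ids
follow traversal order for determinism. Per bin: mean pairwise cophenetic
distance (NaN for singletons), Pearson correlations of the bin's
per-sample mean relative abundance against BP, BA and sBP (≥ 3 complete
samples required; NaN on zero variance), and mean pairwise niche overlap
and AWM-salinity difference over member pairs.

## Group statistics (`stats`)

Kruskal–Wallis (scipy, tie-corrected) with groups of fewer than two
observations excluded; pairwise follow-up uses two-sided rank-sum
(Mann–Whitney) tests BH-adjusted across the group pairs — the exact
post-hoc behind compact-letter displays in field summaries is typically
unstated, and this Dunn-style choice is flagged in the manifest. Letters
label maximal cliques of the not-significantly-different graph, ordered
by descending group median so the highest group reads "a". Hierarchical
partitioning enumerates all 2^k subsets of ≤ 10 predictor groups, fits
plain least-squares R² (minimum-norm solution under collinearity, with a
warning), and averages each group's incremental R² over all orderings
(Chevan–Sutherland); plain rather than adjusted R² guarantees the exact
sum-to-total identity used as a test oracle.

## Synthetic data (`synthetic_data`)

The generator emulates the statistical structure the analysis assumes in
an estuarine-plume survey. Defaults (the simulated study conditions): 66
samples stratified over salinity 28–34.5 PSU with ≥ 22 per water-mass
class; 250 taxa on a Yule tree rescaled to root-to-tip depth 0.5;
copiotroph fraction 0.3 placed in ≥ 3 deep clades chosen farthest-first
so they are mutually distant; salinity optima around guild means 30.5 PSU
(copiotrophs) and 34.1 PSU (oligotrophs) with Gaussian niche breadths 1.2
and 0.8 PSU and a Brownian (trait-diffusion) component so close relatives
have similar optima; per-cell production traits log-normal around guild
means with a 3× copiotroph/oligotroph contrast; expected abundances are
Gaussian salinity responses × log-normal noise (sd 0.5); counts are
multinomial at log-normal depths (median 2×10⁴ reads, so rarefaction is a
non-trivial step); BA is proportional to total expected cells
(2×10³ cells ml⁻¹ per abundance unit, landing BA in the 10⁵–10⁶ cells
ml⁻¹ range), BP couples production traits to abundance with log-normal
noise (sd 0.2), sBP = BP/BA, and a consistent leucine rate is stored so
the unit-conversion chain is exercised end to end.

Two structural choices *encode the designed contrast* rather than tune
any statistic: copiotroph dominance is spread over mutually distant
clades (plume communities phylogenetically dispersed), while
high-salinity dominance is concentrated in a single compact clade region
(diameter ≤ half the tree diameter; nearest-first extension) with the
remaining oligotroph background down-weighted (amplitude 0.4 vs 5) —
high-salinity communities are species-rich but phylogenetically
clustered. On an ultrametric Yule tree, random assemblages are already
close to maximally dispersed, so the plume/open-sea MPD contrast must
come from clustering the open-sea side; early designs that spread
oligotroph dominance tree-wide produced no recoverable contrast.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomy, copy-number bias (the truth is already in "cell" units),
multi-dimensional niches (temperature/chl-a covary with salinity but do
not drive abundances), and realistic co-occurrence sparsity — niche
sharing induces many strong environmental correlations, so synthetic
meta-networks are far denser than field networks. Consequently passing
tests demonstrate correctness and calibration of the *methods* and
recovery of the designed qualitative patterns (plume more productive and
less rich; positive MPD–BP coupling; richness decoupled; AWM salinity
recovering true optima at r > 0.8), not field-realistic magnitudes of
network statistics. One known compression: SES_MPD comes out negative
for all classes here (richer communities sit closer to their swap null),
so the *absolute* SES ordering across classes in field data is not
reproduced, only the raw-MPD contrast.

## Pipeline (`cli_pipeline`)

`run_pipeline` validates inputs (taxa against tree tips, samples against
metadata, required columns by name), spawns per-stage seeds from the
master seed, runs preprocess → diversity → niche → network → bins →
stats, and writes TSVs plus a YAML manifest containing the full
configuration, stage seeds, input paths, assumption flags and all
collected warnings; a rerun with the same configuration is
byte-identical. Stage subcommands rerun the (cheap, deterministic)
upstream stages rather than caching intermediates keyed by content hash —
determinism makes a cache an optimization only, and recomputation keeps
the bundle self-consistent. `--threads` is accepted for interface
stability; execution is serial, so results trivially cannot depend on it.

## Problem sizes

Default analysis parameters are the study-scale ones (999 nulls, 100
bootstraps, thresholds 0.01/0.75/0.1). The test suite and the acceptance
script run the full defaults on the generator's default survey (66 × 250)
and smaller fixtures (30 × 60) for unit-level checks; the SES calibration
check uses 50 samples × 40 taxa at 999 nulls, and SparCC recovery uses
the 40 taxa × 400 samples planted design. These sizes are the package's
chosen verification scales.
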