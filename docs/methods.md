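# Methods

`rhizoassembly` implements the downstream community-assembly analysis of a
two-plant (wheat, faba bean) rhizosphere/rhizoplane amplicon study at the
millimetre scale, together with a synthetic ASV-table generator that emulates
the study design so every stage is testable without sequencing data. This
note records the models, the parameter choices, the numerical conventions and
the known limitations.

## The synthetic study generator

The generator produces, per plant species, 3 soil controls plus 15
rhizosphere and 15 rhizoplane replicates over a shared species pool, with a
random pure-birth phylogeny (exponential branch lengths, mean 0.1) over the
taxa.

**Species pool.** Relative abundances are log-normal(0, `pool_sigma`),
normalized. Each taxon carries a standard-normal *compartment affinity* f_t
(its responsiveness to plant selection; each plant species draws its own
affinity vector over the shared pool) and an optional guild label.

**Soil controls** are Dirichlet-multinomial: pool proportions perturbed by a
Dirichlet with concentration `soil_concentration * p` (default 500), then a
multinomial draw of `depth_soil` reads (default 5000). The concentration
controls replicate-to-replicate overdispersion; as it grows the samples
converge on the pool composition.

**Root compartments** follow a two-step selection model. Per rhizosphere
replicate r the selection weight of taxon t is

    w_{r,t} = p_t · exp(s · f_t) · h_{r,t} · g_{r,t}

with `s = selection_strength`, replicate heterogeneity
h_{r,t} ~ log-normal(0, σ_rep), and guild coupling
g_{r,t} = exp(σ_rep · sqrt(gc/(1−gc)) · z_{r,guild(t)}) for guilded taxa,
z a per-replicate standard-normal latent factor. The scaling makes
`guild_correlation` (gc) the actual log-weight correlation between two
members of the same guild, whatever σ_rep is; without the scaling a latent
factor of unit variance would be negligible against replicate noise of
variance σ_rep² and no association strong enough to cross an |r| > 0.6 edge
threshold could ever be planted. All but the top
`ceil(richness_reduction · n_taxa)` taxa by weight are then zeroed
(rank-truncation, so root richness is exactly controllable), weights are
renormalized, and `depth_root` reads (default 2000, above the 1801-read
rarefaction depth used in the robustness branch) are drawn multinomially.

**Rhizoplane** replicates are a random subset of their paired rhizosphere
replicate: a uniformly random `rhizoplane_subset_fraction` of the present
taxa is kept, proportions renormalized, reads redrawn. This mirrors the
finding that rhizoplane communities are statistically indistinguishable from
random subsets of the rhizosphere.

**Default parameter regime.** Defaults are chosen so the generator
reproduces, as its *default* study conditions, the qualitative phenomena the
analysis is designed to detect: a large soil pool (n_taxa = 3000) of high
evenness (pool_sigma = 0.75 — soil bacterial communities are famously even),
strong richness reduction into root compartments (richness_reduction = 0.05,
i.e. ~150 taxa per root replicate against ~900 observed in soil at 5000
reads), and replicate-level heterogeneous selection dominating the shared
selection signal (sigma_rep = 2 against a combined pool+selection log-scale
spread of ~0.9). This high-turnover regime is what millimetre-scale root
samples look like: individual replicates recover small, largely
non-overlapping subsets of a much larger pool. In this regime the
within-compartment Raup-Crick dissimilarity rises monotonically with σ_rep
(measured 0.50 / 0.68 / 0.93 at σ_rep = 0/1/2) and saturates at 1 between
soil and root under strong divergent selection. In the opposite regime (small
pool, replicates retaining most of it), a ubiquitous core makes observed
pairs share *more* taxa than the frequency-weighted null and βRC collapses
toward 0 regardless of σ_rep — that regime cannot express the phenomenon the
metric exists to detect.

All randomness flows from a single integer seed through keyed
`numpy.random.SeedSequence` sub-streams; identical configurations give
bit-identical tables.

## Diversity

Alpha diversity is observed richness and the Shannon index in nats (the log
base is a convention; natural log is fixed and documented). Rarefaction
subsamples without replacement (multivariate hypergeometric); samples below
the target depth are dropped with a warning rather than resampled with
replacement. Beta diversity: Bray-Curtis on raw counts, and unweighted /
weighted UniFrac computed through scikit-bio (weighted defaults to the
normalized variant so all three metrics share the [0, 1] range). PCoA is the
Gower double-centering of −½D² followed by an eigendecomposition; negative
eigenvalues are reported, not corrected (no Cailliez/Lingoes), coordinates
exist only for positive-eigenvalue axes, and proportions explained are
relative to the sum of positive eigenvalues. Group tests are Kruskal-Wallis
plus pairwise Wilcoxon rank-sum with Benjamini-Hochberg adjustment.

## PERMANOVA

Sequential (Type I) sums of squares in the user-given factor order, computed
by projecting the Gower-centered matrix onto nested design spaces — the
behaviour of vegan's `adonis`. The permutation p-value uses the
observed-inclusive convention (1 + exceedances)/(1 + n_perm) with free
permutation of whole-sample labels (no strata). An `exhaustive` mode
enumerates all n! permutations for small n, where the p-value is exact. Note
that with small balanced groups a random permutation occasionally recreates
the observed partition, so the attainable minimum p is slightly above
1/(n_perm+1) unless groups are large.

## Raup-Crick βRC

For each sample pair, n null community pairs are drawn at the two observed
richnesses, sampling taxa without replacement with probability proportional
to their occurrence frequency in the constraint scope; with J the number of
shared taxa,

    βRC = [ #(J_null > J_obs) + ½·#(J_null = J_obs) ] / n .

Ties are split, so identical communities do not automatically score 0 — this
is the Chase-style formulation, kept because the analytic oracle
(hypergeometric enumeration for equal frequencies) is anchored to it. Note
that vegan's `raupcrick` (chase = FALSE) instead returns the
observed-inclusive p-value (1 + #{J_null ≥ J_obs})/(1 + n), counting ties in
full; the two conventions differ by half the tie probability, and the test
suite cross-checks our null sampler against vegan under vegan's own
convention. Weighted sampling without replacement is implemented by the
Gumbel top-k construction, which is exactly the sequential scheme behind R's
`sample(prob=)`.

Null models are constrained within each sample group. Pairs that straddle
two groups (soil vs rhizosphere, rhizosphere vs rhizoplane) are evaluated
against occurrence frequencies pooled over the union of the two groups — the
only scope that defines a common pool for such a pair; this is a documented
choice, since the source analysis states only that nulls were constrained
"within each group". "Richness similar to the observed richness" is read as
exactly equal. The full-matrix implementation draws one null community per
scope sample per simulation and reuses the draws across pairs within a
simulation (the same economy vegan uses); every pair's marginal null
distribution is unaffected, and the diagonal uses a second independent draw.

## Co-occurrence networks

Per plant × compartment, on the 15 replicates: taxa with more than
`min_total` = 50 reads in total (strict inequality) are kept; counts get a
pseudocount of 1 and are clr-transformed; pairwise association is the
symmetric proportionality coefficient r = 2·cov/(var+var) on clr columns
(robust to compositional closure, unlike Pearson correlation on proportions);
edges require |r| strictly greater than 0.6. Zero-variance taxa are excluded
with a warning. Topology summaries report nodes, edges, connected components
and edge signs.

Global significance compares the observed edge count with 99 null tables.
Each null preserves, per sample independently, the richness, the total and
the multiset of nonzero count values, reassigning them to taxa drawn without
replacement with probability proportional to overall occurrence frequency —
an emulation of a richness-constrained community-matrix shuffle that
preserves strictly more per-sample structure than richness alone, which is
conservative for the edge-count statistic. The empirical p-value is
(1 + #{null ≥ observed})/(1 + 99), so its floor is 0.01.

**Known limitation.** The richness-constrained null preserves per-sample
structure but not the coupling between a taxon's occupancy and its abundance.
Under the default generator even guild-free data show an edge excess over the
null (the null is liberal as an absolute test of "no association"), because
rank-truncation plus depth-limited detection make frequent taxa
systematically abundant. The test is calibrated in the exchangeable sense —
when the observed table is itself a null draw, rejections at α = 0.05 occur
at the nominal rate — and that is the sense in which the test suite checks
calibration; rejections on real or simulated data should be read as "more
structure than the null preserves", not as evidence of biotic interactions
specifically.

## Pipeline and reproducibility

`run_pipeline` sequences generation/loading, diversity, PERMANOVA, βRC and
networks, writing TSV outputs and a manifest of parameters, versions and
per-file SHA-256 checksums; per-stage seeds derive from the master seed by a
fixed keyed scheme so adding a stage never perturbs earlier streams. A
rarefaction robustness branch reruns the qualitative conclusions (sign of the
soil-vs-root richness difference, βRC group means above/below 0.5, edge-count
significance) on data rarefied to 1801 reads per sample and reports
agreement with the non-rarefied run.

## Problem sizes

The acceptance computations use the full default study (3000 taxa, 33
samples per plant) with 999 null simulations per βRC matrix: the
soil-vs-rhizosphere quantity averages 270 pairs (both plants × 3 seeds), the
within-rhizosphere quantity 1050 pairs (10 seeds × 105 pairs). PERMANOVA
calibration uses 200 null datasets of 20 samples at 199 permutations;
edge-count calibration uses 100 self-null datasets at 99 nulls each. These
sizes give Monte-Carlo standard errors well below the decision margins while
keeping a full run in minutes on one CPU.
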