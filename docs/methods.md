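# Methods

This note documents the statistical models implemented in `mycasm`, the
defaults and the reasoning behind them, what the synthetic-data generator
does and does not emulate, and the numerical conventions shared across the
package.

## Synthetic communities

`mycasm.synth.assemble_communities` draws per-sample gut-fungal communities
from a regional genus pool under an explicit mixture of the four processes
the downstream statistics are meant to detect.

**Regional pool.** Genus relative abundances follow a log-series. The shape
parameter comes from Fisher's relation `S = α ln(1 + N/α)` solved for the
community size that yields the requested number of genera, i.e.
`x = 1 − exp(−S/α)`. The default `fisher_alpha = 10` gives a few dominant
genera and a long tail of rare ones — the shape real genus pools show, and
the regime in which ubiquity and mean abundance correlate.

**Niche axes.** Each symbiont genus carries a one-dimensional niche trait
`t_g`, and each host species an environmental position `x_h`. Both are the
standardized first principal coordinate of the respective patristic distance
matrix. This "conserved niche axis" is the most phylogenetically conserved
one-dimensional trait a tree admits: tips close on the tree are close on the
axis by construction, so a selection filter over the axis always targets a
low-diameter clade. A Brownian-motion trait simulator
(`synth.brownian_traits`) is provided and is used by the phylogenetic-signal
tests, but the assembly filter deliberately uses the deterministic axis: a
single BM realization on a birth-death tree is frequently *not*
clade-structured (most tip pairs coalesce near the root, so a trait slice
picks scattered tips), which would make the selection fixtures
irreproducibly weak. Deep conservation of host preference is also the
biologically motivated choice for this symbiosis, where early-diverging
symbiont lineages track early-diverging (hindgut) hosts.

**Filter, drift, dispersal.** The host filter is

```
w(g, h) = exp(−σ_s (t_g − ρ x_h − c)²)
```

with selection strength `σ_s ≥ 0`, phylosymbiosis coupling `ρ ∈ [0, 1]` and
a shared offset `c` (`selection_target`). The limits are the designed study
conditions: `σ_s = 0` is the neutral model; `σ_s > 0, ρ = 0` is pure shared
(homogeneous) selection — every host filters toward the same clade;
`σ_s > 0, ρ = 1` couples the filter to the host phylogeny (phylosymbiosis
plus heterogeneous selection between distant hosts). A sample is a
multinomial draw of `J` individuals (default `J = 1000`; the only drift
source) from `pool × w`, with a `Binomial(J, m)` portion drawn instead from
the metacommunity mean (homogenizing dispersal, `m ∈ [0, 1]`, default 0.05).
Totals equal `J` exactly.

**What the generator does not emulate.** Conspecific samples are iid draws
from an identical distribution: there is no per-individual environmental or
temporal heterogeneity beyond multinomial noise. Two consequences matter for
interpretation. First, dispersal is only identifiable when selection makes
hosts differ (`m` mixes toward the common mean; under neutrality the local
and metacommunity distributions coincide), so the dispersal fixtures pair
`m > 0` with moderate selection. Second, within-species pairs are more
similar than repeated sampling of real animals would be, which shifts the
RC_Bray partition of within-species pairs toward homogenizing dispersal
relative to field data. Passing tests therefore demonstrate that each
statistic recovers its own generating process, not that real gut communities
assemble at these parameter values. No indels, no among-site rate
heterogeneity, no chimeras and no sequencing error are simulated.

**Markers.** `simulate_marker_pair` evolves a 700-column alignment under
Jukes–Cantor along the symbiont tree at a mean rate of 0.05 substitutions
per site per unit branch length, with the trailing 370 columns (the D2
analogue) at `rate_ratio` times the whole-marker average (default 1.75,
which reproduces the ~1.7× divergence inflation of D2 over D1/D2). The
head-region rate absorbs the complement, which bounds
`rate_ratio < len_full / len_sub`.

**Presets.** `small` (6 species / 3 families / 3 gut types / 40 genera, 3
samples each), `medium` (12 / 4 / 3 / 60), and `paper_shape` (34 species in
9 families and 3 gut types, 87 genera, 661 samples with heavily unbalanced
replication — a few livestock-like species contribute most samples).
Families are near-clades obtained by average-linkage clustering of the host
patristic matrix; gut types are assigned to whole families so that one small
family is pseudoruminant (~2.5% of samples), hindgut families cover roughly
a quarter, and ruminants take the rest.

## Taxonomic null model

All taxonomic null statistics share one randomization
(`assembly.generate_null_community`): each null sample keeps its observed
richness and read total; taxa are drawn without replacement with probability
proportional to dataset-wide occupancy; each drawn taxon receives one read
and the remainder is multinomial in proportion to the regional relative
abundances of the drawn taxa. Richness and totals are preserved exactly.
Weighted sampling without replacement is sequential (renormalizing after
each draw), and the unit tests check Monte-Carlo inclusion frequencies
against exact enumeration of that scheme.

## NST

For each sample pair, observed dissimilarity `D` (Bray–Curtis on relative
abundances or Jaccard on incidence) is compared with the mean `E(D)` over
null realizations. Normalized selection strength is
`SS = (E(D) − D)/E(D)` when `D < E(D)` and `SS = (D − E(D))/(1 − E(D))`
otherwise (`D_max = 1` for both indices); a pair with `D = E(D)` has
`SS = 0`. The pairwise normalized stochasticity is `1 − SS`; the group NST
is the pair mean in percent, with >50% read as predominantly stochastic.
The unnormalized ratio (`D/E(D)` or `E(D)/D`) is also reported. Group
uncertainty comes from resampling samples within the group with replacement
(default 1000 bootstrap draws), recomputing the pair mean over distinct
resampled pairs; observed and expected matrices are reused across draws.
The null model runs within each group, so `E(D)` reflects the group's own
pool. Caveat: when local communities saturate the pool (high `J`, small
pool) the incidence-based index degenerates — most pairs have
`D ≈ E(D) ≈ 0` and Jaccard NST pins near 100%; the abundance-based index
remains informative, which is why the validation suite discriminates on
Bray–Curtis.

## βNRI and RC_Bray

βNRI is the z-score of abundance-weighted βMPD, `f_a' Δ f_b`, where `f` are
relative-abundance profiles and `Δ` the patristic matrix; the null shuffles
taxa across the tips of the phylogeny (999 shuffles by default), keeping the
abundance matrix fixed. An unweighted (incidence-profile) variant is
available via `weighted=False`. When the null has zero variance — an
equal-branch star tree, or two samples whose profiles are identical up to a
single taxon, since a common shuffle preserves co-occurrence — βNRI is
defined as 0 and a warning is emitted. Scale invariance (z-scores cancel a
global branch-length factor) is tested.

RC_Bray compares the observed Bray–Curtis of a pair with its distribution
over null realizations: `RC = 2[(n_less + 0.5 n_equal)/n_null] − 1`, ties at
half weight (equality tolerance 1e-12). Pairs are classified exhaustively:
βNRI > +2 heterogeneous selection, βNRI < −2 homogeneous selection,
otherwise RC > 0.95 dispersal limitation, RC < −0.95 homogenizing
dispersal, else drift; the five fractions sum to one by construction.

## PERMANOVA, Mantel, MRM, PROTEST

PERMANOVA uses the hat-matrix formulation on the Gower-centered matrix with
*sequential* (Type-I) sums of squares in the user-given factor order; factor
order is material for nested designs (species within family within gut
type), and a factor repeated after itself receives zero SS by construction.
p-values come from free permutation of sample labels, always reported as
`(b + 1)/(m + 1)`. Because later nested terms absorb no variance after
`species`, the acceptance script reports single-factor models per factor;
both usages are exposed. Calibration: empirical type-I error at nominal 0.05
is verified to sit in [0.03, 0.07] over 500 label-shuffled replicates.

Mantel is the Pearson correlation of distance triangles with joint
row/column permutation of one matrix. MRM regresses the response triangle on
predictor triangles (categorical factors encoded 0 = same level, 1 =
different); per-coefficient p-values use the pseudo-t permutation method and
the model p-value the permuted-R² distribution; predictor condition numbers
above 1e10 are rejected as collinear. PROTEST uses symmetric Procrustes
(translation, scaling, rotation, reflections allowed),
`m² = 1 − (Σσ)²` after normalizing both configurations, with row
permutations of one configuration.

The repeated one-individual-per-species MRM draws one sample per species per
round (default 100 rounds), recomputes the community distance and re-runs
single-predictor MRMs; a factor is significant overall when its p-value
clears 0.05 in at least 75 rounds. With one individual per species the 0/1
"same species" predictor is constant, so the species factor is tested
through host patristic distance between the species of each pair when a host
tree is supplied — the phylosymbiosis reading of host-species effect, and
the only one identifiable under this subsampling.

## PACo and residual comparisons

Hosts and symbionts are embedded by principal coordinates (axes covering
99.9% of positive inertia; negative eigenvalues truncated with the dropped
inertia fraction logged). Association links duplicate embedding rows; the
symbiont configuration is superimposed onto the host configuration by
weighted least squares (translation, scaling, rotation), with nonzero
association values acting as link weights — passing a 0/1 matrix gives
classic PACo, passing relative abundances weights each link's residual by
abundance. The weighted form matters when presence is near-saturated (every
host carries most genera) and only abundance carries host information. The
global test permutes host rows of the association matrix
(`p = (b + 1)/(m + 1)` on the sum of squared residuals).

Raw per-host residuals confound fit quality with geometry: hosts far from
the configuration centroid have larger expected residuals and spreads under
the null. For the within/between group comparisons each host's mean residual
is therefore z-scored against its permutation-null mean and standard
deviation (20 host-permutation replicates). The comparison statistic is
`median(|Δz| between groups) − median(|Δz| within groups)` over sample pairs
of per-sample means (one value per sample, so repeated subsampling does not
pseudo-replicate), with significance from permuting group labels over the
exchangeable blocks — samples for the species level, whole species for the
family and gut-type levels — and BH adjustment across the three levels.
One-individual-per-species subsampling (default 100 rounds) supplies the
residual distributions; raw residual quantiles are reported alongside for
descriptive use.

## Phylogenetic signal and LIPA

Moran's I uses row-normalized inverse-patristic weights; Abouheif's Cmean is
the same statistic under the Abouheif proximity (inverse product of the
child counts of the internal nodes on the tip-to-tip path), both with
upper-tail permutation p-values. Pagel's λ is fitted by maximizing the
Gaussian likelihood over the λ-blended covariance
`V(λ) = λC + (1 − λ) diag(C)` (GLS mean and variance profiled out),
λ ∈ [0, 1], with a χ²₁ likelihood-ratio test against λ = 0; on ultrametric
trees `diag(C)` is constant and `V(λ)` shares `C`'s eigenvectors, so a
single eigendecomposition serves all evaluations. λ is reported as not
identifiable (NaN) below three tips.

LIPA is the local Moran statistic `I_i = z_i Σ_j w_ij z_j` with the trait
centered and scaled by the population standard deviation, which makes the
tip mean of LIPA equal the global Moran's I exactly (asserted in every
analysis). Per-tip p-values permute trait values across tips. The default
trait is `log10(relative abundance + 1e-6)`; the transform is exposed.
Strength bands partition `[0, ∞)`: below 0.2 (or non-significant) none,
0.2–0.4 weak, 0.4–1 moderate, ≥ 1 strong. Group summaries average LIPA over
the tips of each host species/family; a group counts as significant when any
member tip is, and a species-level association can legitimately vanish at
family level when the species is a small fraction of its family.

Per-sample analyses attach individuals as pendant children of their species
tip with length `1e-6 × tree height`; the same floor is applied to zero
off-diagonal patristic distances before inversion. Conspecific weights then
dominate each row, so per-sample LIPA effectively measures agreement among
conspecific samples plus their phylogenetic neighborhood — the intended
behavior for replicated host sampling.

## Seeds and p-values

Every source of randomness is an explicit integer seed expanded through
`numpy.random.SeedSequence`; per-stage seeds in the pipeline come from
stable hashes of stage names, so adding a stage never shifts another's
stream. All permutation p-values use `(b + 1)/(m + 1)` and comparisons carry
a 1e-12 tie tolerance. Tier-1 genus-assignment ties (mean distances within
1e-9) break lexicographically and are logged.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` size their simulations for a
single CPU: 30-sample fixtures with 299 null realizations for the
process-recovery and NST checks (1000 bootstrap draws), 100-taxon marker
simulations for threshold recovery, 100-tip trees with 50 replicates for λ
calibration, 100 LIPA replicates at 299 permutations for type-I error,
400–500 replicates at 99 permutations for PERMANOVA/Mantel calibration, and
the full 661-sample study shape with 199 null realizations and 199–499
permutations in the acceptance script. These counts are the package's
validation defaults; the library defaults (999 nulls, 1000 bootstraps) are
what an analysis of real data would use.

## Known limitations

* The taxonomic null is the single richness/occupancy/abundance algorithm
  described above; alternative constraint combinations are rejected
  explicitly rather than silently approximated.
* βNRI's tip-shuffle null cannot score pairs whose profiles are identical up
  to one taxon (degenerate by construction, reported as 0).
* The incidence-based NST saturates on high-coverage communities drawn from
  small pools (see above).
* Novel-genus counts on synthetic markers undercount planted lineages when
  the simulated between-genus divergence sits below the mapped genus
  threshold; the two-tier assignment itself is exact on divergent clades.
* HDF5 BIOM is not read; use the JSON profile or TSV.
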