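# Methods

This note documents the models, null-model conventions, numerical choices
and limitations of `phylocomm`. It is the place where every genuinely open
design decision is recorded.

## Phylogenetic structure

**αMPD.** The default weighting follows the focal-taxon form
αMPD = Σ_i f_i · mean_{j≠i, f_j>0} Δ_ij: the relative abundance weights sit
on the focal taxon and the partner mean is unweighted. The fully
pairwise-weighted variant (Σ w_i w_j Δ_ij / Σ w_i w_j) is available via
`alpha_mpd(..., mode="pairwise")` for sensitivity checks; the two differ
whenever abundances are uneven. Communities with fewer than two taxa have no
pairwise distance and propagate as flagged NaN records, never as silent
zeros.

**Phylogeny-pool null.** A randomization preserves the sample's richness and
its abundance multiset, and reassigns the abundances to taxa drawn uniformly
without replacement from the species pool. The pool is all tips of the
supplied tree — appropriate when every treatment derives from the same
source community, which is also the regime the synthetic generator emulates.
The null standard deviation uses the sample convention (n−1 denominator).
NRI = −SES; a null sd of zero (e.g., a star tree) yields a flagged result.
SES computations are vectorized: null communities are drawn as index
matrices and the MPD of all randomizations is evaluated with batched
gathers, chunked to bound memory (~4M matrix elements per chunk).

**βMPD/βNRI.** βMPD is the fully abundance-weighted cross-community pair
mean (the comdist convention), so identical one-taxon communities give 0 and
shared taxa contribute Δ = 0. The β null applies the phylogeny-pool
randomization to both communities independently in each iteration; this
extends the α null to β and is recorded here as an assumption, since only
the α null has a canonical name. βNRI < −2 is read as homogeneous selection,
> +2 as variable selection.

**Interpretation bands.** |NRI| ≤ 2 is treated as consistent with
stochastic assembly; > +2 clustering/filtering; < −2
overdispersion/competitive exclusion. One-sample t-tests of group NRI
values against ±2 quantify whether a whole treatment exceeds the band.

**Mantel correlogram.** Phylogenetic distances are partitioned into
`n_classes` equal-width classes (default 100) over the observed range. Per
class the statistic is the Pearson correlation between the class-membership
indicator and the environmental-optimum distance over all pairs, negated so
that positive r means positive autocorrelation (pairs in the class more
similar than average). Permutations shuffle taxon labels of the optimum
matrix (999 by default); p-values are one-tailed in the direction of the
observed sign, and the progressive Holm correction is applied in increasing
distance order (class k corrected within the first k tests). The
`significant` flag refers to the corrected p-value; classes without pairs
are reported with NaN statistics rather than raised. Environmental optima
are abundance-weighted means: each taxon's abundances are renormalized over
samples and dotted with the per-sample environmental values.

## SparCC

Basis correlations are estimated from log-ratio variances
t_ij = Var(log x_i/x_j). Under sparsity the basis variances solve
M ω² = t_rowsum with M = (D−2)I + J; ρ_ij = (ω_i²+ω_j²−t_ij)/(2ω_iω_j),
clipped to [−1, 1]. The most strongly correlated pair is excluded and the
system re-solved, up to 10 rounds, while |ρ|_max exceeds the exclusion
threshold 0.1 (the original tool's defaults, echoed in
`SparccResult.settings`). Each exclusion changes M by exactly
−(e_i+e_j)(e_i+e_j)ᵀ, so the maintained inverse is updated with one
Sherman–Morrison step (O(D²)) instead of a fresh solve (O(D³)); the initial
inverse of (D−2)I + J is closed-form. Exclusion stops, with a warning, if a
taxon would retain fewer than three partners. Counts are smoothed by
Dirichlet posterior draws from counts+1 per inner iteration (20 by default)
and the median ρ over iterations is reported.

Permutation pseudo-p-values shuffle every OTU's counts across samples
independently, which destroys all inter-OTU association while preserving
each OTU's marginal distribution; p = (1 + #{|ρ_perm| ≥ |ρ_obs|})/(n_perm+1),
so the smallest attainable p is 1/(n_perm+1). Permuted re-estimates may use
fewer inner iterations (`perm_inner_iters`) than the observed estimate; this
adds symmetric noise to the permutation distribution and is slightly
conservative.

## C-score

Observed C = mean over taxon pairs of (r_i − S)(r_j − S), rows = taxa. The
null preserves both row and column totals via sequential checkerboard swaps
(burn-in 10 × fill attempted swaps, thinning fill attempts between null
samples, fill = number of presences). SES and a two-sided rank p are
reported; a matrix with no swappable 2×2 submatrix is flagged degenerate
with p = 1.

## Networks

Edges require |ρ| strictly above the correlation threshold (default 0.85)
and p strictly below the significance threshold (default 0.01). Average path
length and diameter are computed over connected vertex pairs only (the
convention of interactive network tools for disconnected graphs), with the
component count reported alongside. Modularity uses seeded Louvain
optimization at resolution 1.0, best of 10 restarts; community detection is
stochastic, so reported Q is reproducible only under the run's seed, and a
conventional Q > 0.4 flag marks module-structured networks. Cumulative
degree distributions report P(degree ≥ k).

## Group statistics

Tukey HSD follows one-way ANOVA; the compact letter display uses
insert-absorb (groups ordered by descending mean; ties broken by label), so
two groups share a letter exactly when their Tukey-adjusted p ≥ α — this
equivalence is audited against the pairwise reject matrix in the tests.
Shapiro and Levene checks run as advisory warnings only. Quadratic fits
report the multiple R, the model F-test p and the vertex −b/(2c) when the
parabola opens downward; the linear fit is nested for comparison.

## Synthetic-data generator

The generator emulates a 7-treatment × 4-replicate fertilization trial:

- **Tree**: pure-birth (Yule) with exponential waiting times; pendant
  branches extended by one extra waiting time. Default 500 tips.
- **Trait**: Brownian motion (σ² = 1) for environmental optima — the strong
  niche-conservatism premise on which NRI-based process inference rests.
  Because a single Brownian draw can leave the trait's tail phylogenetically
  unclumped (tail values arising convergently in many clades), the study
  generator conditions the realization on conservatism where it matters: it
  redraws traits (deterministically under the seed, ≤50 tries) until the
  mean pairwise patristic distance among the filter's target taxa is at most
  0.97 of the pool mean. This mirrors practice with real data, where
  phylogenetic signal is established (via the correlogram) before NRI is
  interpreted; `evolve_trait_bm` itself remains an unconditioned Brownian
  draw.
- **Assembly**: *filtering* samples taxa ∝ exp(−(optimum − env)²/2b²);
  *overdispersion* greedily adds the taxon maximizing the minimum patristic
  distance to those chosen; *neutral* samples uniformly. Overdispersed test
  communities are kept species-poor (40 of 500 taxa): competitive exclusion
  limits coexistence, and the maximin spread's effect on mean pairwise
  distance saturates — and can even invert — once the community is a large
  fraction of the pool. Abundances over
  chosen taxa are symmetric Dirichlet (concentration 1, an uninformative
  simplex). Optional fields `env_jitter_sd` and `abundance_response`
  (defaults 0) jitter the realized environment per sample and couple
  abundances to the filter weight; this is the minimal mechanism that makes
  narrow-niche taxa co-fluctuate across replicates and is what produces the
  "stronger filtering → denser co-occurrence network" pattern.
- **Design**: all seven regimes filter toward the same environment placed
  1.5 trait-sd from the ancestral value — a managed agricultural soil as a
  harsh, distinctive habitat — and differ only in filter breadth, graded
  from 0.15 sd (NK, strongest) through 0.18 (Control) to 0.55 sd (PK,
  weakest). Communities hold 120 of 500 taxa; sequencing depths are drawn
  uniformly from 7,707–19,950 reads so tables support rarefaction to 7,000.
- **Covariates**: a latent fertility score tracks filter breadth; available
  phosphorus (AP), SOC, TN, invertase, microbial biomass C and the
  microcalorimetric rates rise with it, time-to-peak falls, yield is
  quadratic in breadth with an interior optimum, and pH/AK/Q_T are
  independent noise. Units are nominal (mg/kg, g/kg scales typical of
  agricultural topsoil).

What the generator does **not** emulate: sequencing error, chimeras and PCR
bias (counts are exact multinomials of the latent composition), taxon-level
ecological interactions (co-occurrence structure arises only through shared
environmental response), spatial blocking, and temporal dynamics. Passing
tests therefore demonstrate correctness and calibration of the statistical
machinery under the stated generative model, not robustness to those
real-data complications.

## Numerical and scaling choices

- All randomness flows from one integer seed through `SeedSequence` spawns;
  no global RNG state. Identical seeds give byte-identical result files
  (`run.log`, which contains wall-clock times, is the only exception).
- Default analysis settings: rarefaction depth 7,000; 1,000 NRI/βNRI
  randomizations; 100 correlogram classes with 999 permutations; top-500
  OTUs per regime; 999 SparCC permutations (9,999 selectable); C-score with
  1,000 nulls; thresholds |ρ| > 0.85, p < 0.01.
- `RunConfig.fast()` is the desk-scale profile used by the test suite and
  the demo: 99 randomizations, 99 correlogram permutations, 199 SparCC
  permutations (the minimum pseudo-p must stay below the strict p < 0.01
  edge rule, which 99 cannot), 5 inner iterations for permuted SparCC
  re-estimates, 199 C-score nulls. Calibration tests run at 200 neutral
  communities on a 500-tip tree; correlogram calibration at 40 tips,
  20 classes, 99 permutations, 100 replicates; the end-to-end determinism
  check at 300 tips. These sizes are the package's chosen defaults for a
  single-CPU run of a few minutes.
- Rank p-values are two-sided pseudo-p's, (1+count)/(n+1), capped at 1.
- Tie-breaks are deterministic everywhere: top-k dominance ties resolve
  lexicographically by OTU id; letter-display ordering by mean then label.

## Known limitations

- NRI/βNRI are MPD-based (basal) statistics; nearest-taxon variants (NTI)
  and quantitative process partitioning beyond the ±2 rules are out of
  scope.
- The β null model is an extension of the phylogeny-pool null, not a named
  published null; alternative βNRI nulls can shift absolute values.
- Modularity values depend on the optimizer seed; comparisons between
  networks of very different sizes should use the flag (Q > 0.4) rather
  than raw Q differences.
- SparCC assumes a sparse true correlation structure; dense structure
  violates the basis-variance approximation for all SparCC implementations,
  including this one.
- With 4 replicate samples per regime (the emulated design), per-regime
  SparCC estimates are noisy; the pipeline reproduces the design rather
  than improving on it.
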