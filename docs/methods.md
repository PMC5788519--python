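# Methods

`magicqtl` maps main-effect, two-way and three-way epistatic QTL in
multiparent (MAGIC) doubled-haploid populations with a staged Bayesian
multilocus analysis, and ships a MAGIC simulator with known ground truth so
every stage is testable offline.

## Model

Genotypes are biallelic homozygous calls coded x ∈ {+1, −1} (AA/BB; a DH
population has no heterozygotes). The multilocus association model is

    y_i = β0 + Σ_j x_ij β_j + e_i,        e_i ~ N(0, σ0²),

extended to interactions by product pseudomarkers: a two-way term uses
x_ik·x_il and a three-way term x_ij·x_ik·x_il, each again a ±1 column.
Effects carry automatic-relevance-determination priors, β_j | σ_j² ~
N(0, σ_j²) with the scale-invariant prior p(σ_j²) ∝ 1/σ_j²; the intercept is
flat and p(σ0²) ∝ 1/σ0². A systematic-scan Gibbs sampler draws from the full
conditionals (see the `gibbs_arm` module docstring for the exact kernels;
x_jᵀx_j = n exactly under ±1 coding).

## Staged procedure

1. Remove duplicated markers (|Pearson r| ≥ 0.99 with an earlier kept marker,
   scanning in map order; sign-flips count; monomorphic markers are dropped).
   Near-perfect duplicates make MCMC variable selection alternate between
   interchangeable columns, so chain-averaged effects cancel.
2. Fit all p markers jointly; declare main QTL by consensus selection
   (below); residual E1 subtracts the intercept and the *declared* QTL
   effects (cross-chain averages).
3. Sure-independence screening (SIS): enumerate all C(p,2) pairwise product
   pseudomarkers, score each by |Pearson r| with E1, keep the top d (default
   1000) in an O(d + n) bounded buffer.
4. Fit the d pseudo-columns jointly on E1; declare interacting pairs;
   annotate each selected pair with the LD r² of its two markers and flag it
   as a spurious LD signal when r² > 0.8.
5. Residual E2 subtracts the declared pair effects from E1.
6. Screen all C(p,3) three-way products against E2, keep the top t (1000).
7. Fit, declare candidate trios, and confirm each by a nested OLS F-test on
   the original phenotype: reduced model 1+M1+M2+M3+M1M2+M1M3+M2M3 vs the
   full model adding M1M2M3; F = (RSS_r − RSS_f)/(RSS_f/(n−8)) with
   p from F(1, n−8), significance at α = 1e−5. Rank-deficient trio designs
   are reported non-testable instead of fabricating a p-value.

Five chains with distinct seeds (50,000 iterations, 10,000 burn-in at full
scale; a `desk` preset of 5 × 5,000/1,000 serves simulation studies) are
averaged, and a column is selected only if it clears the effect threshold in
*every* chain.

### Why residuals subtract only declared effects

The Jeffreys/ARD joint posterior is improper: it degenerates both at
σ_j² → 0 (all effects excluded) and at σ0² → 0 (perfect interpolation).
When the screened design is wider than n — d = 1000 columns against a few
hundred lines — a fit that subtracts *every* column's averaged effect leaves
a residual that is an in-sample interpolation residue with essentially no
variance and no retrievable three-way signal, which would make stage 6
vacuous. Subtracting only the declared-QTL effects keeps the staged
residuals meaningful: whatever was not called a QTL is passed on to the next
stage. The lower-level `compute_residuals` still defaults to the all-columns
reconstruction; the pipeline passes the selected subset explicitly.

### Degenerate-state guards

Two floors keep finite chains out of the improper posterior's absorbing
regions, and both are configurable:

* `variance_floor` (default 1e−10): the conditional Inv-Gamma(1/2, β_j²/2)
  collapses as β_j → 0; the floor prevents numerical underflow while leaving
  shrinkage of small effects intact. Effect variances are also *initialised*
  at this floor, so every effect starts excluded and must be recruited by
  the data — initialising them large instead makes the first sweeps behave
  like unpenalised least squares and drives wide designs straight into the
  interpolation state.
* `residual_floor_fraction` (default 0.1): σ0² is floored at 10% of the
  response variance during sampling, i.e. a stage may explain at most ~90%
  of its response — about the upper end of line-mean heritabilities for
  flowering time. On honest fits the floor never binds (on a pure-noise
  fixture the posterior mean of σ0² stays within 10% of the generating
  noise variance).

### Consensus selection threshold

What "selected in a chain" means is a genuinely open choice. A threshold
proportional to SD(response) cannot work on both ends: on a pure-noise trait
the largest in-sample marginal effects among hundreds of markers reach
~0.16·SD while any useful fraction sits lower, and on staged residuals the
same fraction overshoots genuinely attenuated interaction estimates. The
default is therefore referenced to the noise, not the spread: a column is
flagged in a chain when |posterior mean| ≥ z_{α/2q}·sqrt(σ̄0²/n), a
Bonferroni-corrected (α = 0.05, q design columns) z-quantile on the sampling
standard error of one effect, with σ̄0² the cross-chain posterior-mean
residual variance of the same fit. An absolute threshold in trait units can
be supplied instead (`PipelineConfig.effect_threshold`).

## Simulator

`synthetic_magic` emulates the statistical structure the analysis assumes,
not any particular pedigree: eight founder lines with iid ±1 alleles
(allele frequency 0.5; monomorphic markers resampled once, then dropped),
a fixed crossing funnel (1,2)(3,4)(5,6)(7,8) → two four-way crosses → one
eight-way cross, and DH lines formed by doubling one gamete of an eight-way
individual. Each meiosis recombines between adjacent markers with the
Haldane probability r = ½(1 − e^(−2Δd/100)) (no interference; chromosomes
independent). Linkage through the funnel produces LD blocks whose r² decays
with map distance. Phenotypes follow the generative model above with
sparse planted effects plus N(0, σ²) noise.

Named presets (n = 300 lines, p = 500 markers on seven ~140 cM chromosomes
at 2 cM spacing, noise SD 1 day, intercept 80 days):

* `null` — no genetic effects;
* `recovery_main` — three additive QTL of +2.0, −1.5, +1.0 days on distinct
  chromosomes;
* `recovery_epistasis` — adds two pairwise effects (+1.5, −1.5) and one
  three-way effect (+2.0) on markers disjoint from the main QTL;
* `duplicates` — recovery_main plus 20 exact-copy marker columns.

Planted QTL are placed on frequency-balanced markers (coded column mean
nearest zero within ±15 cM of the target position). This is not cosmetic:
under ±1 product coding an interaction at unbalanced markers genuinely
induces marginal main effects of size β·E[x_partner], so "pure" planted
interactions require balanced partners.

What the simulator does **not** model: genotyping error, missing calls,
population/field structure, funnel randomisation, selfing generations, or
crossover interference. Passing recovery tests therefore demonstrates the
machinery under the model's own assumptions, not performance on real data,
where collinearity is heavier (a third of real markers can be duplicates)
and effects smaller.

## Numerical and design notes

* Scaled-down problem sizes used by the test-suite and the acceptance
  script: desk preset chains (5 × 5,000), n = 300, p = 500, d = t = 1000;
  the full three-way screen then enumerates C(500,3) ≈ 20.7M trios.
  Full-scale settings (5 × 50,000 iterations, thousands of markers) are the
  library defaults.
* The SIS buffer replaces its minimum only on strictly larger scores, and
  final ties sort by ascending tuple, so bounded screening reproduces the
  full materialise-and-sort ranking exactly; enumeration visits each
  unordered tuple once. The p(p−1)(p−2)/3 counting convention some reports
  use for the three-way space is exposed via
  `search_space_size(..., "paper")` alongside the unordered C(p,3).
* Interaction effect estimates from the wide screened fits are attenuated
  (roughly 3–4× on the recovery fixture): the top-d screened columns are
  order statistics of 10⁵–10⁷ candidate correlations and collectively
  compete for the same variance. Selection (consensus + noise-referenced
  threshold) is robust to this; reported `effect_days` for pairs/trios
  should be read as conservative lower bounds. The confirmatory F-test is
  run on the raw phenotype, making trio significance independent of the
  attenuation.
* The residual of the Gibbs kernel is updated incrementally and refreshed
  every 256 iterations to stop floating-point drift; fixed seeds give
  bit-identical chains, and the pipeline derives per-stage chain seeds from
  one master seed via `numpy.random.SeedSequence`.
* Main-effect QTL whose markers lie within one LD window (r² > 0.8) are
  merged into a single region reported under its strongest marker.
* The trio F-test response defaults to the raw phenotype y rather than the
  staged residual E2: the nested-model comparison is then self-contained and
  conservative (main and pairwise terms of the trio are re-estimated inside
  the test). `ftest_on_raw_phenotype=False` switches to E2.

## Known limitations

* The Jeffreys/ARD posterior is improper; results are metastable-state
  summaries, which is why multi-chain consensus and the two floors exist.
  A proper weakly-informative prior would be a principled alternative at
  the cost of changing the model.
* Effect-size estimates for screened interaction terms are attenuated (see
  above); only their identity and sign are well determined at desk scale.
* Recovery of a +1.0-day main effect at n = 300 against ~10 days² of
  residual-plus-epistatic variance sits near the detection boundary; across
  random simulator seeds it is found in most but not all runs.
* No multiple-testing correction beyond the fixed 1e−5 trio threshold, and
  no permutation-based thresholds.
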