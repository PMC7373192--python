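# Methods

## The problem

Amplicon sequencing returns a fixed complement of reads regardless of how
much genuine template entered the library.  At high biomass those reads
are overwhelmingly template-derived; as template falls, two other sources
take over.  Reagent (kit) contamination is DNA physically present in the
isolation/amplification reagents: it is reproduced between technical
replicates processed with the same kit and appears in negative controls.
Stochastic sequencing noise is different: classifiable reads that are
*not* reproduced between technical replicates of the same extract.  The
two call for different defenses (controls for contamination, replicate
concordance for noise), and confusing them produces irreproducible
"communities" — a sample can differ significantly from its controls by
PERMANOVA while containing nothing reproducible at all.

This package quantifies replicate concordance, classifies specimens into
regimes, locates the biomass threshold where noise takes over, and ships
a generative model of the noise process for calibration.

## Distance machinery

All distances are Bray–Curtis, the only dissimilarity used throughout:
`BC(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ)`, on per-sample relative abundances
by default.  Relative abundance (total-sum scaling) is the deterministic
default; rarefaction to a stated depth with a stated seed is available
for sensitivity analysis.  Zero-total samples are retained on read but
rejected by distance operations with an explicit error, never silently
dropped.

The distance partition has two stratum modes:

* `kit` — groups are (kit, dilution); intra pairs are a kit's technical
  replicates at one dilution, inter pairs cross kits at the same
  dilution.  Inter distances pool all kit pairs (provenance records
  which, so per-pair views are recoverable).
* `specimen` — groups are specimens; intra pairs are a specimen's
  technical replicates, and inter pairs join specimens to negative
  controls of the same sample type.

Distance distributions on [0, 1] are summarized by a Gaussian KDE with
Silverman bandwidth, boundary-corrected by reflecting the sample at 0 and
1 and renormalizing to unit trapezoid integral on a 512-point grid.  The
bandwidth is floored at 0.01 because degenerate all-equal distance sets
(clean technical replicates, where every distance is ~0) occur routinely;
the floor turns them into a narrow peak instead of a singular estimate.
The overlap coefficient `∫ min(f_intra, f_inter)` ∈ [0, 1] measures how
separable the two populations are.

## Regime classification

Evidence per specimen/kit: median intra distance, median inter distance,
overlap.  Default thresholds (all configurable): `intra_low = 0.35`
(replicates "agree" below this), `separation = 0.20`, `noise_floor =
0.50`, `overlap_min = 0.50`.  These were calibrated on the simulator's
three clear-cut parameterizations, which they classify perfectly; they
are configuration, not constants of nature.

The decision rule depends on what the inter set compares (`pairing`):

* `replicate` (kit-vs-kit): low intra + small separation → signal (all
  kits recover the same community); low intra + large separation →
  contamination (each kit reproduces its own reagent community).
* `control` (specimen-vs-matched-control): the separation test inverts —
  a reproducible specimen *distinct from* its negative controls is
  signal; one that resembles them is carrying the reagent background.

Noise is called when median intra exceeds the noise floor *and* either
the intra/inter densities overlap (≥ 0.5, the dilution-series signature)
or the median inter distance is also above the floor.  The second clause
matters for small replicate sets (3 per specimen), where the
floor-bandwidth KDEs degenerate to near-disjoint spikes and the overlap
statistic is uninformative; replicates that disagree among themselves as
much as with their controls are noise either way.  Anything else is
`indeterminate` — deliberately: the rule never stretches to cover
boundary cases.  Summaries too small for a KDE fall back to a coarse
interval-overlap statistic.

## Biomass–reproducibility transition

A four-parameter logistic in x = log₁₀(copies),
`d(x) = ℓ + (u − ℓ)/(1 + exp(k(x − m)))` with k > 0 (distance falls as
copies rise), is fitted by bounded least squares (`scipy.optimize
.least_squares`; bounds ℓ, u ∈ [0, 1.5], k ∈ [0.05, 50], m within the
data span ± 2 decades; initialized at ℓ = min d, u = max d, m = median x,
k = 2).  Preconditions: ≥ 5 points spanning ≥ 2 decades, copies > 0.
The fit is reported non-converged — and no transition range is given —
when the optimizer fails, the fitted span u − ℓ is below 0.1, the data
are flat (range < 0.05), or the midpoint lands outside the data span
(unidentified).  The transition range is where the curve passes 10% and
90% of its span, i.e. m ∓ ln(9)/k on the log scale; the 10–90 convention
is this package's definition, chosen because the underlying observation
is a range, not a point.

The screening rule `flag_low_biomass` flags specimens with strictly
fewer than 10⁵ 16S copies/sample (configurable); specimens with no
biomass record are flagged `unknown` rather than passed.  Copies are per
specimen (ddPCR on the extract); replicates inherit the specimen value.

## Consensus and contaminants

Counts are converted to within-replicate relative abundances, then for
each specimen and OTU the median across replicates is taken (midpoint
convention for even replicate counts), then the mean ± SEM across
specimens.  With r replicates, an OTU absent from a strict majority —
present in at most ⌊(r−1)/2⌋ — has median exactly 0 in that specimen;
this is the noise-suppression guarantee.  Note the midpoint convention
means presence in exactly r/2 of an even r is *not* suppressed (median =
half the smaller nonzero value).  The consensus vector need not sum
to 1: mass lost to irreproducible OTUs is exactly the noise and is not
redistributed.  Specimens with one replicate are excluded with a warning
(configurable to a hard error); medians are taken on relative abundances,
not counts, so depth differences between replicates do not distort them.

Contaminant OTUs are flagged from replicated negative controls when both
hold: control mean-of-replicate-medians abundance ≥ `min_abund` (default
0.01) *and* detection in ≥ `min_prevalence` (default 2/3) of at least one
control kit's replicates.  The numeric rule is this package's surrogate
for the qualitative practice of reading contaminants off a control
consensus; defaults recover the simulator's planted contaminants with on
average ≤ 1 false positive per run against a pure-noise background.
Removal drops the flagged columns and always reports per-sample and mean
read retention (new total / old total); a sample emptied by removal is
reported, not dropped.

`concordance_score` is the fraction of a specimen's pooled reads carried
by OTUs detected in *all* of its replicates — the scalar version of
asking how much mass sits on the diagonal when replicates are plotted
against each other.  Identical replicates score 1; disjoint ones 0.

## PERMANOVA

One-factor pseudo-F on squared distances via the standard within/between
decomposition: `SS_total = (1/n) Σ_{i<j} d²`, `SS_within = Σ_g (1/n_g)
Σ_{i<j∈g} d²`, `F = (SS_between/(g−1)) / (SS_within/(n−g))`, with
Monte-Carlo p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) (default 999
permutations, ≥ 99 enforced, seeded).  When every pairwise distance is 0
the statistic is defined as 0 with p = 1; note that *equal nonzero*
distances give the same F for every labeling (equidistant points), hence
p = 1 through permutation invariance, not through F = 0.  Free
permutation is the default, mirroring common practice of treating
replicates as exchangeable — which is exactly the practice whose failure
mode this package demonstrates; block permutation (whole specimens
permuted together) is provided for the honest test.  Type-I error at
α = 0.05 is calibrated to [0.03, 0.07] over 1,000 null simulations in
the test suite.

## The generative noise model

One library of depth R is generated as:

1. effective templates T ~ Poisson(N) for the true community and
   T_c ~ Poisson(N_c) for the kit's contaminant community;
2. signal weight w = (T + T_c)/(T + T_c + λ);
3. template reads ~ Binomial(R, w), allocated multinomially with
   proportions ∝ T·(true profile) + T_c·(kit profile);
4. the remaining reads are allocated over a noise community drawn fresh
   per replicate: K OTUs chosen uniformly from a shared pool, weights ~
   symmetric Dirichlet(α);
5. counts sum exactly to R.

Noise enters as *competition for fixed depth* (weight λ), not as
additive reads: read depth stays normal while the noise share
λ/(N + N_c + λ) grows as input falls — the signature behavior in a
dilution series.  Poisson template sampling supplies the ultra-low-input
stochasticity of the signal itself (the true OTU can drop out entirely
when N is of order 1).  In the corner case T = T_c = 0 with λ = 0, the
library is filled with noise reads so the depth contract holds (the
instrument reports reads regardless); a configuration with N = N_c =
λ = 0 is rejected outright.

Defaults are the study conditions the generator emulates: a single-OTU
true community; 3 kits × 4 replicates × 6 tenfold dilutions (undiluted
input 10⁸ copies); read depth 20,000; noise pool 2,000 OTUs with K = 200
active per replicate and α = 0.05; noise scale λ = 5 × 10³ (within the
10³–10⁴ transition window the framework is designed to detect); kit
contaminant communities of 10 OTUs each, Dirichlet(1)-weighted, disjoint
between kits (the idealization that kits share no reagent flora).
Control simulations use 7 kits × 3 replicates with 2 contaminated kits
(N = 0, N_c = 10⁶) and 5 clean ones (pure noise).  The clinical preset
contrasts high-biomass specimens (10⁷ copies, 30-OTU Dirichlet
communities) with ultra-low-biomass ones (10³ copies) and matched
no-template controls.

All randomness flows from one seed; each replicate's stream is derived
from (seed, kit, dilution, replicate), so output is bit-reproducible and
independent of generation order.

What the generator does *not* emulate: sequence-level error, chimeras,
index switching, well-to-well crossover, PCR-cycle dynamics,
compositional correlations among real contaminant taxa, or taxonomic
structure in the noise pool.  Passing tests therefore show that the
*statistical machinery* behaves as designed under the stated noise
mechanism — not that real sequencers produce noise by this mechanism.

## Problem sizes

The test suite and `scripts/acceptance.py` use desk-scale runs chosen to
make the stochastic checks stable: 10–20 seeds per simulation property,
1,000 null datasets (n = 10, 199 permutations each) for PERMANOVA
calibration, exact enumeration at n = 6, 200 Monte-Carlo replicate pairs
for the noise-dissimilarity bound, and the full 72-library dilution
series per seed for transition recovery.

## Known limitations

* Regime thresholds are simulator-calibrated defaults, not universal
  constants; real studies near the boundaries should inspect the evidence
  columns, not just the calls.
* The contaminant rule is prevalence/abundance-based; it will miss
  contaminants below 1% consensus abundance and is not a substitute for
  model-based decontamination when biomass varies widely across samples.
* The transition fit assumes a single logistic transition; mixtures of
  sample types with different contamination loads can flatten or split
  the transition.
* `.shared`/`.cons.taxonomy` I/O covers the mothur tab-delimited dialects
  only (no BIOM-HDF5, no QIIME artifacts).
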