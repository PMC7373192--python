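# replinoise

Replicate-concordance quality control for low-biomass 16S rRNA gene
sequencing.

When the bacterial template entering a sequencing library is scarce, the
instrument still returns a full complement of reads — and a large share of
them can be *stochastic sequencing noise*: classifiable sequences that are
not reproduced between technical replicates of the same DNA extract.  Such
noise is distinct from reagent ("kit") contamination, which *is*
reproducible within a kit and detectable in negative controls.  A sample
can therefore test significantly different from its controls by PERMANOVA
and still contain no reproducible community at all.

`replinoise` is for microbiome researchers working with low-biomass sample
types (airway specimens, breath condensate, blood, placenta, environmental
swabs) who sequence technical replicates and need to decide, specimen by
specimen, whether a result is signal, contamination, or noise.

## What it computes

* **Intra/inter replicate Bray–Curtis partition.**  For abundance vectors
  x, y the dissimilarity is `BC(x, y) = Σᵢ|xᵢ − yᵢ| / Σᵢ(xᵢ + yᵢ)`.
  Distances *within* a group of technical replicates (intrareplicate) are
  separated from distances *between* groups at the same level
  (kit-vs-kit at one dilution, or specimen-vs-control within a sample
  type), each distribution summarized by a boundary-corrected KDE on
  [0, 1] and their overlap coefficient `∫ min(f_intra, f_inter)`.
* **Regime classification.**  A specimen is *signal-dominated* when its
  replicates agree (low median intra distance), *contamination-dominated*
  when replicates agree but carry the kit-specific reagent community, and
  *noise-dominated* when replicates disagree among themselves
  (median intra > 0.5) as much as with their comparators.
* **Biomass–reproducibility transition.**  A four-parameter logistic in
  log₁₀(16S copies), `d(x) = ℓ + (u − ℓ)/(1 + exp(k(x − m)))`, fitted to
  (copies, mean intra distance) points locates the copy-number window
  where results flip from reproducible to noise-dominated, plus the
  conservative screening rule that specimens with < 10⁵ copies/sample are
  noise-prone.
* **Mean of replicate medians.**  Consensus profiles take the per-OTU
  *median* across a specimen's replicates (suppressing OTUs absent from a
  majority of replicates to exactly zero) and then the mean ± SEM across
  specimens.  Applied to replicated negative controls, the same estimator
  flags reagent-contaminant OTUs, which can be removed with explicit
  read-retention accounting.
* **PERMANOVA** (one-factor pseudo-F permutation test, with optional
  whole-specimen block permutation) — implemented in-package so the
  pipeline can demonstrate the "significant yet irreproducible" failure
  mode end to end.
* **A generative noise simulator.**  Reads compete for fixed depth R:
  genuine template (T ~ Poisson(N)), kit contamination (T_c ~ Poisson(N_c),
  shared within a kit, disjoint between kits), and a per-replicate noise
  community redrawn from a shared OTU pool, with signal weight
  w = (T + T_c)/(T + T_c + λ).  Defaults mirror a single-strain dilution
  series: 3 kits × 4 replicates × 6 tenfold dilutions at 20,000 reads.

## Worked example

```python
import numpy as np
from replinoise import (SimConfig, simulate_dilution_series,
                        intra_inter_distances, transition_fit)

cfg = SimConfig(seed=1, input_copies=1e8, noise_scale=5e3)
table, design, biomass = simulate_dilution_series(cfg)   # 72 libraries

s = intra_inter_distances(table, design, stratum="kit")
mean_by = s.intra.groupby("level")["distance"].mean()
print(mean_by.round(3))

spec = s.intra["group_a"].str.replace("|", "_", regex=False)
by_specimen = s.intra.groupby(spec)["distance"].mean()
copies = np.array([biomass[sp] for sp in by_specimen.index])
fit = transition_fit(copies, by_specimen.to_numpy())
print(f"transition midpoint: {fit.midpoint_copies:.0f} copies")
```

prints

```
level
1e-1     0.001
1e-2     0.005
1e-3     0.048
1e-4     0.334
1e-5     0.822
neat     0.000
transition midpoint: 5185 copies
```

Undiluted template (10⁸ copies) gives near-identical technical replicates
(mean intrareplicate Bray–Curtis ≈ 0.000); by the 10⁻⁵ dilution (10³
copies, below the noise scale λ = 5 × 10³) replicates of the *same*
extract differ almost completely (0.822).  The fitted logistic locates
the reproducibility transition at ≈ 5,200 copies — recovering the λ that
generated the data and illustrating how the same fit, applied to real
ddPCR-quantified specimens, identifies the copy-number window below which
technical replication is mandatory.

The same analyses are available from the shell:

```sh
replinoise simulate --preset dilution --seed 1 --out sim
replinoise run --table sim.shared --design sim.design.tsv \
               --biomass sim.biomass.tsv --stratum kit --out report/
```

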