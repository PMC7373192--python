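"""Generative model of low-biomass amplicon sequencing.

The simulator formalizes a competition picture of what a sequencer returns
when template is scarce but read depth stays fixed.  Three read sources
compete for the R reads of a library:

1. genuine template — the specimen's true community, with an effective
   template count T ~ Poisson(N) where N is the 16S copy input;
2. reagent (kit) contamination — a kit-specific community c_k with its own
   template count T_c ~ Poisson(N_c), identical across a kit's replicates
   but disjoint between kits;
3. stochastic noise — an effective pseudo-template pool of scale λ whose
   composition is redrawn *per replicate*: K OTUs chosen uniformly from a
   shared pool, weighted by a sparse symmetric Dirichlet.

The fraction of reads drawn from real templates is Binomial(R, w) with
w = (T + T_c)/(T + T_c + λ); the rest of the depth is filled with that
replicate's private noise community.  Because λ is fixed while N falls
tenfold per dilution step, the noise share of reads grows as input falls,
which is exactly the dilution-series behavior the framework is built to
detect: intrareplicate distances rise with dilution and eventually overlap
the interreplicate ones.

Poisson template sampling matters at the bottom of the series: when N is
of order 1, the true community can drop out of a replicate entirely.

All randomness flows from a single seed; each replicate's stream is
derived deterministically from (seed, kit, dilution, replicate), so tables
are bit-reproducible and insensitive to generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tables_io import CountTable, ReplicateDesign

__all__ = [
    "SimConfig",
    "simulate_replicate",
    "simulate_dilution_series",
    "simulate_controls",
    "simulate_clinical",
]

DEFAULT_DILUTION_FACTORS = (1.0, 1e-1, 1e-2, 1e-3, 1e-4, 1e-5)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the generative noise model.

    Parameters
    ----------
    true_profile
        Composition of the genuine community over signal OTUs (sums to 1).
        The default is a single-strain community (one OTU at 1.0),
        mirroring a pure-culture dilution series.
    input_copies
        16S gene copies N fed to the assay for the undiluted specimen.
    contamination_copies
        Copy number N_c of each kit's reagent contaminant community.
    noise_scale
        λ, the effective noise pseudo-template count.  Noise takes over
        when template input falls toward λ.
    noise_pool_size, noise_subset_size, noise_concentration
        The shared noise OTU pool, the number K of pool OTUs active in any
        one replicate, and the symmetric Dirichlet concentration α of
        their weights.  The pool is shared across the run so chance OTU
        overlaps between replicates occur, as in real data.
    read_depth
        Fixed library size R; every simulated library sums exactly to R.
    n_kits, n_replicates, dilution_factors
        Experimental shape; defaults mirror a 3-kit x 4-replicate x
        6-dilution single-strain series.
    n_contaminant_otus
        Number of OTUs in each kit's (disjoint) contaminant community.
    """

    true_profile: tuple[float, ...] = (1.0,)
    input_copies: float = 1e8
    contamination_copies: float = 0.0
    noise_scale: float = 5e3
    noise_pool_size: int = 2000
    noise_subset_size: int = 200
    noise_concentration: float = 0.05
    read_depth: int = 20_000
    n_kits: int = 3
    n_replicates: int = 4
    dilution_factors: tuple[float, ...] = DEFAULT_DILUTION_FACTORS
    n_contaminant_otus: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.true_profile, dtype=float)
        if p.size == 0 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("true_profile must be a composition summing to 1")
        for name in ("input_copies", "contamination_copies", "noise_scale"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.input_copies == 0 and self.contamination_copies == 0 and self.noise_scale == 0:
            raise ConfigError("no read source: input_copies, contamination_copies and noise_scale are all 0")
        if not self.dilution_factors:
            raise ConfigError("dilution_factors must be non-empty")
        if any(f <= 0 or f > 1 for f in self.dilution_factors):
            raise ConfigError("dilution factors must lie in (0, 1]")
        if self.noise_subset_size > self.noise_pool_size:
            raise ConfigError("noise_subset_size cannot exceed noise_pool_size")
        if self.read_depth < 1 or self.n_kits < 1 or self.n_replicates < 1:
            raise ConfigError("read_depth, n_kits and n_replicates must be >= 1")

    # -- OTU namespace --------------------------------------------------

    @property
    def signal_otus(self) -> list[str]:
        n = len(self.true_profile)
        return ["Otu_signal" if n == 1 else f"Otu_signal{i + 1:03d}" for i in range(n)]

    def contaminant_otus(self, kit: int) -> list[str]:
        return [f"Otu_{self._kit_name(kit)}contam{i + 1:03d}" for i in range(self.n_contaminant_otus)]

    @property
    def noise_otus(self) -> list[str]:
        return [f"Otu_noise{i + 1:04d}" for i in range(self.noise_pool_size)]

    @staticmethod
    def _kit_name(kit: int) -> str:
        return f"K{kit + 1}"

    def otu_ids(self, n_kits: int | None = None) -> list[str]:
        n_kits = self.n_kits if n_kits is None else n_kits
        ids = list(self.signal_otus)
        for k in range(n_kits):
            ids.extend(self.contaminant_otus(k))
        ids.extend(self.noise_otus)
        return ids

    def contaminant_profile(self, kit: int) -> np.ndarray:
        """Kit-specific contaminant composition, fixed by (seed, kit).

        Contaminant communities of different kits occupy disjoint OTUs,
        matching the idealization that one kit's reagent flora shares
        nothing with another's.
        """
        rng = np.random.default_rng([int(self.seed), 104729, kit])
        w = rng.dirichlet(np.ones(self.n_contaminant_otus))
        return w


def _replicate_rng(cfg: SimConfig, kit: int, dilution: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), kit, dilution, replicate])


def simulate_replicate(
    cfg: SimConfig,
    kit: int,
    rng: np.random.Generator,
    input_copies: float | None = None,
    n_kits: int | None = None,
) -> np.ndarray:
    """Simulate one library; returns counts over ``cfg.otu_ids(n_kits)``.

    *input_copies* overrides ``cfg.input_copies`` (used per dilution).
    If both Poisson template draws come out 0 and λ = 0, the library is
    filled with noise reads: the sequencer still reports R reads.
    """
    n_kits = cfg.n_kits if n_kits is None else n_kits
    if not 0 <= kit < n_kits:
        raise ConfigError(f"kit index {kit} outside [0, {n_kits})")
    n = cfg.input_copies if input_copies is None else float(input_copies)

    n_signal = len(cfg.true_profile)
    n_contam = cfg.n_contaminant_otus
    offsets_contam = n_signal + kit * n_contam
    offset_noise = n_signal + n_kits * n_contam
    total_otus = offset_noise + cfg.noise_pool_size
    counts = np.zeros(total_otus, dtype=np.int64)

    t_sig = int(rng.poisson(n)) if n > 0 else 0
    t_con = int(rng.poisson(cfg.contamination_copies)) if cfg.contamination_copies > 0 else 0

    denom = t_sig + t_con + cfg.noise_scale
    w = (t_sig + t_con) / denom if denom > 0 else 0.0
    template_reads = int(rng.binomial(cfg.read_depth, w)) if w > 0 else 0
    noise_reads = cfg.read_depth - template_reads

    if template_reads > 0:
        props = np.concatenate(
            [
                t_sig * np.asarray(cfg.true_profile, dtype=float),
                t_con * cfg.contaminant_profile(kit),
            ]
        )
        props = props / props.sum()
        draw = rng.multinomial(template_reads, props)
        counts[:n_signal] += draw[:n_signal]
        counts[offsets_contam : offsets_contam + n_contam] += draw[n_signal:]

    if noise_reads > 0:
        chosen = rng.choice(cfg.noise_pool_size, size=cfg.noise_subset_size, replace=False)
        weights = rng.dirichlet(np.full(cfg.noise_subset_size, cfg.noise_concentration))
        # guard against exact zeros from the sparse Dirichlet
        if weights.sum() <= 0:
            weights = np.full(cfg.noise_subset_size, 1.0 / cfg.noise_subset_size)
        draw = rng.multinomial(noise_reads, weights / weights.sum())
        counts[offset_noise + chosen] += draw

    assert counts.sum() == cfg.read_depth
    return counts


def _dilution_label(factor: float) -> str:
    return "neat" if factor == 1.0 else f"1e{int(round(np.log10(factor)))}"


def simulate_dilution_series(
    cfg: SimConfig,
) -> tuple[CountTable, ReplicateDesign, dict[str, float]]:
    """Simulate the full dilution-series experiment.

    Default shape: 3 kits x 4 technical replicates x 6 tenfold dilutions
    (undiluted through 1e-5) of a single-strain community = 72 libraries.
    Each (kit, dilution) pair is a specimen; the returned biomass map
    carries its template input N (copies/sample).
    """
    otu_ids = cfg.otu_ids()
    rows, design_rows = [], []
    biomass: dict[str, float] = {}
    for d, factor in enumerate(cfg.dilution_factors):
        n = cfg.input_copies * factor
        label = _dilution_label(factor)
        for k in range(cfg.n_kits):
            kit_name = SimConfig._kit_name(k)
            specimen = f"{kit_name}_{label}"
            biomass[specimen] = n
            for r in range(cfg.n_replicates):
                rng = _replicate_rng(cfg, k, d, r)
                rows.append(simulate_replicate(cfg, k, rng, input_copies=n))
                design_rows.append(
                    {
                        "sample_id": f"{specimen}_r{r + 1}",
                        "specimen_id": specimen,
                        "replicate_index": r + 1,
                        "kit_id": kit_name,
                        "is_control": False,
                        "sample_type": "dilution",
                        "dilution_label": label,
                    }
                )
    design = ReplicateDesign(pd.DataFrame(design_rows))
    table = CountTable([r["sample_id"] for r in design_rows], otu_ids, np.vstack(rows))
    return table, design, biomass


def simulate_controls(
    cfg: SimConfig,
    n_kits: int = 7,
    n_replicates: int = 3,
    contaminated_kits: tuple[int, ...] = (0, 1),
) -> tuple[CountTable, ReplicateDesign]:
    """Simulate replicated reagent-only negative controls.

    Kits listed in *contaminated_kits* carry reagent DNA (N = 0,
    N_c = ``cfg.contamination_copies`` > 0): their replicates agree with
    each other but kits disagree.  The remaining kits are clean (N = N_c
    = 0): their libraries are pure per-replicate noise and share OTUs only
    by chance.  This reproduces the structure of a control experiment in
    which a minority of kits show reproducible contamination.
    """
    if cfg.contamination_copies <= 0 and contaminated_kits:
        raise ConfigError("contaminated kits requested but contamination_copies is 0")
    if cfg.noise_scale <= 0:
        raise ConfigError("controls need noise_scale > 0 (clean kits have no other read source)")
    contaminated = set(contaminated_kits)
    if any(k < 0 or k >= n_kits for k in contaminated):
        raise ConfigError(f"contaminated kit indices must lie in [0, {n_kits})")

    otu_ids = cfg.otu_ids(n_kits=n_kits)
    rows, design_rows = [], []
    for k in range(n_kits):
        kit_cfg = cfg if k in contaminated else replace(cfg, contamination_copies=0.0)
        kit_name = SimConfig._kit_name(k)
        for r in range(n_replicates):
            rng = _replicate_rng(cfg, k, 0, r)
            rows.append(
                simulate_replicate(kit_cfg, k, rng, input_copies=0.0, n_kits=n_kits)
            )
            design_rows.append(
                {
                    "sample_id": f"{kit_name}_ctrl_r{r + 1}",
                    "specimen_id": f"{kit_name}_ctrl",
                    "replicate_index": r + 1,
                    "kit_id": kit_name,
                    "is_control": True,
                    "sample_type": "isolation_control",
                    "dilution_label": "",
                }
            )
    design = ReplicateDesign(pd.DataFrame(design_rows))
    table = CountTable([r["sample_id"] for r in design_rows], otu_ids, np.vstack(rows))
    return table, design


def simulate_clinical(
    cfg: SimConfig,
    n_specimens: int = 3,
    n_replicates: int = 3,
    high_copies: float = 1e7,
    low_copies: float = 1e3,
    n_community_otus: int = 30,
) -> tuple[CountTable, ReplicateDesign, dict[str, float]]:
    """Clinical-style preset: high-biomass vs ultra-low-biomass specimens.

    Emulates the contrast between an oral rinse (abundant template, a
    diverse reproducible community) and exhaled breath condensate
    (template at or below the noise scale, so libraries are mostly
    replicate-private noise), each with matched negative controls of the
    same sample type (no template at all).  Every specimen carries its own
    community so that specimen-vs-control comparisons have real structure.
    """
    rng_prof = np.random.default_rng([int(cfg.seed), 15485863])
    groups = [("oral", high_copies), ("EBC", low_copies)]
    rows, design_rows = [], []
    biomass: dict[str, float] = {}

    base = replace(
        cfg,
        true_profile=tuple(np.full(n_community_otus, 1.0 / n_community_otus)),
        n_kits=1,
        contamination_copies=0.0,
    )
    otu_ids = base.otu_ids(n_kits=1)
    n_signal = n_community_otus

    for gi, (sample_type, copies) in enumerate(groups):
        for s in range(n_specimens):
            profile = rng_prof.dirichlet(np.full(n_signal, 0.3))
            spec_cfg = replace(base, true_profile=tuple(profile / profile.sum()))
            specimen = f"{sample_type}_{s + 1}"
            biomass[specimen] = copies
            for r in range(n_replicates):
                rng = np.random.default_rng([int(cfg.seed), 7001 + gi, s, r])
                rows.append(
                    simulate_replicate(spec_cfg, 0, rng, input_copies=copies, n_kits=1)
                )
                design_rows.append(
                    {
                        "sample_id": f"{specimen}_r{r + 1}",
                        "specimen_id": specimen,
                        "replicate_index": r + 1,
                        "kit_id": "K1",
                        "is_control": False,
                        "sample_type": sample_type,
                        "dilution_label": "",
                    }
                )
        # matched controls: no template, pure noise
        for s in range(n_specimens):
            specimen = f"{sample_type}_control_{s + 1}"
            biomass[specimen] = 0.0
            for r in range(n_replicates):
                rng = np.random.default_rng([int(cfg.seed), 8001 + gi, 1000 + s, r])
                rows.append(simulate_replicate(base, 0, rng, input_copies=0.0, n_kits=1))
                design_rows.append(
                    {
                        "sample_id": f"{specimen}_r{r + 1}",
                        "specimen_id": specimen,
                        "replicate_index": r + 1,
                        "kit_id": "K1",
                        "is_control": True,
                        "sample_type": sample_type,
                        "dilution_label": "",
                    }
                )
    design = ReplicateDesign(pd.DataFrame(design_rows))
    table = CountTable([r["sample_id"] for r in design_rows], otu_ids, np.vstack(rows))
    return table, design, biomass
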