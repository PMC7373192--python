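"""End-to-end QC pipeline: distances → regimes → consensus → decontamination.

:func:`run_pipeline` sequences the stages on one set of inputs and writes
a bundle of diff-able TSVs plus a human-readable summary.  The run
configuration (and the seed) is serialized verbatim into the output
directory, so a bundle is a pure function of (inputs, config, seed) and a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import identify_contaminants, mean_of_replicate_medians, remove_contaminants
from .dissimilarity import group_summaries, intra_inter_distances, pairwise_bray_curtis
from .errors import DesignError
from .noise_regime import RegimeThresholds, classify_regime, flag_low_biomass
from .permanova import permanova
from .tables_io import CountTable, ReplicateDesign

logger = logging.getLogger("replinoise")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters for one pipeline run."""

    stratum: str = "specimen"
    normalize: str = "relabund"
    thresholds: RegimeThresholds = field(default_factory=RegimeThresholds)
    biomass_threshold: float = 1e5
    contaminant_min_abund: float = 0.01
    contaminant_min_prevalence: float = 2.0 / 3.0
    n_permutations: int = 999
    permanova_group: str = "is_control"
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    distances: pd.DataFrame
    regimes: pd.DataFrame
    biomass_flags: pd.DataFrame | None
    consensus: pd.DataFrame | None
    contaminants: pd.DataFrame | None
    retention: pd.DataFrame | None
    permanova: pd.DataFrame | None
    summary_text: str


def _check_consistency(table: CountTable, design: ReplicateDesign, biomass) -> None:
    missing = [s for s in table.sample_ids if s not in design.frame.index]
    if missing:
        raise DesignError(f"samples in table but not in design: {missing[:10]}")
    if biomass is not None:
        specs = set(design.frame.loc[table.sample_ids, "specimen_id"])
        unknown = set(biomass) - specs
        if unknown:
            logger.warning("biomass records for unknown specimens: %s", sorted(unknown)[:5])


def run_pipeline(
    table: CountTable,
    design: ReplicateDesign,
    biomass: dict[str, float] | None = None,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every QC stage and (optionally) write the report bundle.

    Stages: intra/inter distance partition; per-specimen (or per-kit)
    regime calls; low-biomass flags; contaminant identification from the
    control samples and removal from the biological ones; consensus
    profile of the biological specimens; PERMANOVA of samples vs controls
    per sample type.
    """
    _check_consistency(table, design, biomass)
    design = design.subset(table.sample_ids)
    df = design.frame

    logger.info("pipeline start: %d samples, %d OTUs", table.n_samples, table.n_otus)

    # 1. distances
    summary = intra_inter_distances(
        table, design, stratum=config.stratum, normalize=config.normalize, seed=config.seed
    )
    distances = summary.to_long_frame()
    logger.info(
        "distances: %d intra pairs, %d inter pairs", len(summary.intra), len(summary.inter)
    )

    # 2. regimes per group
    per_group = group_summaries(table, design, stratum=config.stratum, normalize=config.normalize)
    # specimen-stratum inter pairs compare specimens to their matched
    # controls, which flips the meaning of the separation test
    pairing = (
        "control"
        if config.stratum == "specimen" and design.frame["is_control"].any()
        else "replicate"
    )
    regime_rows = []
    for gid, gsum in sorted(per_group.items()):
        if len(gsum.inter) == 0:
            continue
        call = classify_regime(gsum, config.thresholds, specimen_id=gid, pairing=pairing)
        regime_rows.append(
            {
                "specimen_id": gid,
                "regime": call.regime,
                "median_intra": call.median_intra,
                "median_inter": call.median_inter,
                "overlap": call.overlap,
            }
        )
    regimes = pd.DataFrame(regime_rows)

    # 3. biomass flags
    biomass_flags = None
    if biomass is not None:
        specimens = list(dict.fromkeys(df["specimen_id"]))
        biomass_flags = flag_low_biomass(biomass, specimens, threshold=config.biomass_threshold)

    # 4. contaminants from controls, removal from biological samples
    contaminants = retention = None
    cleaned = table
    ctrl_ids = list(df.index[df["is_control"]])
    bio_ids = list(df.index[~df["is_control"]])
    if ctrl_ids:
        ctrl_table = table.select_samples(ctrl_ids)
        report = identify_contaminants(
            ctrl_table,
            design,
            min_abund=config.contaminant_min_abund,
            min_prevalence=config.contaminant_min_prevalence,
        )
        contaminants = report.flagged
        if bio_ids:
            bio_table = table.select_samples(bio_ids)
            cleaned, report = remove_contaminants(bio_table, report)
            retention = report.retention
            logger.info(
                "decontamination: %d OTUs removed, mean retention %.3f",
                len(report.flagged),
                report.mean_retention,
            )

    # 5. consensus over biological specimens
    consensus_df = None
    if bio_ids:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = mean_of_replicate_medians(cleaned, design, controls=False)
        consensus_df = prof.profile.sort_values("mean", ascending=False).reset_index(drop=True)

    # 6. PERMANOVA samples vs controls per sample type
    perm_rows = []
    if ctrl_ids and bio_ids:
        rel = table.relative_abundance()
        for stype, sub in df.groupby("sample_type", sort=False):
            has_both = sub["is_control"].nunique() == 2
            if not has_both or sub["is_control"].value_counts().min() < 2:
                continue
            idx = [table.sample_index(s) for s in sub.index]
            dm = pairwise_bray_curtis(rel[idx])
            labels = np.where(sub["is_control"], "control", "sample")
            res = permanova(
                dm, labels, n_permutations=config.n_permutations, seed=config.seed
            )
            perm_rows.append(
                {
                    "sample_type": stype,
                    "pseudo_f": res.pseudo_f,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "n_samples": int((~sub["is_control"]).sum()),
                    "n_controls": int(sub["is_control"].sum()),
                }
            )
    permanova_df = pd.DataFrame(perm_rows) if perm_rows else None

    summary_text = _render_summary(table, regimes, biomass_flags, contaminants, retention, permanova_df)

    result = PipelineResult(
        distances=distances,
        regimes=regimes,
        biomass_flags=biomass_flags,
        consensus=consensus_df,
        contaminants=contaminants,
        retention=retention,
        permanova=permanova_df,
        summary_text=summary_text,
    )
    if out_dir is not None:
        _write_bundle(result, config, Path(out_dir))
    return result


def _render_summary(table, regimes, biomass_flags, contaminants, retention, permanova_df) -> str:
    lines = [
        f"replinoise {__version__} QC report",
        f"samples: {table.n_samples}   OTUs: {table.n_otus}",
        "",
        "regime calls:",
    ]
    if len(regimes):
        for regime, n in regimes["regime"].value_counts().items():
            lines.append(f"  {regime}: {n}")
    else:
        lines.append("  (none)")
    if biomass_flags is not None:
        n_low = int((biomass_flags["flag"] == "low_biomass").sum())
        n_unknown = int((biomass_flags["flag"] == "unknown").sum())
        lines += ["", f"low-biomass specimens (<1e5 copies): {n_low}; unknown biomass: {n_unknown}"]
    if contaminants is not None:
        lines += ["", f"contaminant OTUs flagged from controls: {len(contaminants)}"]
    if retention is not None and len(retention):
        lines.append(f"mean read retention after removal: {retention['fraction_retained'].mean():.3f}")
    if permanova_df is not None:
        lines += ["", "PERMANOVA sample vs control:"]
        for _, row in permanova_df.iterrows():
            lines.append(
                f"  {row['sample_type']}: pseudo-F={row['pseudo_f']:.3f} p={row['p_value']:.4f}"
            )
    lines.append("")
    lines.append(
        "note: a significant PERMANOVA does not certify a real community; "
        "check the regime call and median intrareplicate distance."
    )
    return "\n".join(lines)


def _write_bundle(result: PipelineResult, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.to_json() + "\n")
    result.distances.to_csv(out_dir / "distances.tsv", sep="\t", index=False)
    result.regimes.to_csv(out_dir / "regimes.tsv", sep="\t", index=False)
    if result.biomass_flags is not None:
        result.biomass_flags.to_csv(out_dir / "biomass_flags.tsv", sep="\t", index=False)
    if result.consensus is not None:
        result.consensus.to_csv(out_dir / "consensus.tsv", sep="\t", index=False)
    if result.contaminants is not None:
        result.contaminants.to_csv(out_dir / "contaminants.tsv", sep="\t", index=False)
    if result.retention is not None:
        result.retention.to_csv(out_dir / "retention.tsv", sep="\t", index=False)
    if result.permanova is not None:
        result.permanova.to_csv(out_dir / "permanova.tsv", sep="\t", index=False)
    (out_dir / "summary.txt").write_text(result.summary_text + "\n")
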