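"""Consensus profiles, contaminant identification, and replicate concordance.

The mean of replicate medians is the consensus estimator used throughout:
counts are first converted to within-replicate relative abundances, the
per-OTU *median* across a specimen's technical replicates suppresses any
OTU seen in fewer than a majority of replicates (with r replicates, an OTU
absent from more than half of them has median exactly 0), and the mean of
those medians across specimens — with its SEM — summarizes the cohort.
This deliberately de-emphasizes stochastic sequencing noise, which by
definition is not reproduced between replicates.

Applied to negative-control libraries, the same estimator identifies
reagent contaminants: an OTU with appreciable consensus abundance in the
controls that is detected in most replicates of at least one control kit
is reproducible control signal, i.e., reagent DNA.  Flagged OTUs can be
removed from clinical tables with explicit read-retention accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, DistanceError
from .tables_io import CountTable, ReplicateDesign

__all__ = [
    "ConsensusProfile",
    "mean_of_replicate_medians",
    "ContaminantReport",
    "identify_contaminants",
    "remove_contaminants",
    "concordance_score",
]


@dataclass
class ConsensusProfile:
    """Per-OTU consensus relative abundance (mean of replicate medians).

    ``profile`` has columns ``otu_id, mean, sem``; ``specimen_medians`` is
    the intermediate specimen x OTU matrix of within-specimen replicate
    medians.  The consensus vector need not sum to 1: medians are taken
    per OTU, so mass lost to irreproducible OTUs is *not* redistributed —
    a deliberate property, since that mass is exactly the noise.
    """

    profile: pd.DataFrame
    specimen_medians: pd.DataFrame = field(repr=False)
    n_replicates: dict[str, int] = field(default_factory=dict)

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_medians)

    def top(self, n: int = 20) -> pd.DataFrame:
        return self.profile.sort_values("mean", ascending=False).head(n).reset_index(drop=True)


def mean_of_replicate_medians(
    table: CountTable,
    design: ReplicateDesign,
    sample_type: str | None = None,
    controls: bool | None = False,
    min_replicates: int = 2,
    on_single_replicate: str = "warn",
) -> ConsensusProfile:
    """Consensus community profile across specimens.

    Parameters
    ----------
    sample_type
        Restrict to one sample type (e.g. ``"CBAL"``); ``None`` keeps all.
    controls
        ``False`` (default) keeps biological specimens only, ``True``
        keeps controls only, ``None`` keeps both.
    min_replicates
        Specimens with fewer replicates are excluded (``on_single_replicate
        ="warn"``) or rejected (``="error"``): a median over one replicate
        provides no noise suppression.
    """
    design.check_against(table)
    df = design.frame.loc[table.sample_ids]
    keep = pd.Series(True, index=df.index)
    if sample_type is not None:
        keep &= df["sample_type"] == sample_type
    if controls is not None:
        keep &= df["is_control"] == controls
    df = df[keep]
    if df.empty:
        raise DesignError("no samples match the consensus filter")

    rel = pd.DataFrame(
        table.relative_abundance(), index=table.sample_ids, columns=table.otu_ids
    ).loc[df.index]

    medians: dict[str, np.ndarray] = {}
    n_reps: dict[str, int] = {}
    for specimen, sub in df.groupby("specimen_id", sort=False):
        r = len(sub)
        if r < min_replicates:
            msg = f"specimen {specimen!r} has {r} replicate(s) (< {min_replicates}); excluded"
            if on_single_replicate == "error":
                raise DesignError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        medians[specimen] = np.median(rel.loc[sub.index].to_numpy(), axis=0)
        n_reps[specimen] = r
    if not medians:
        raise DesignError(
            f"no specimen has >= {min_replicates} replicates; consensus undefined"
        )

    med = pd.DataFrame.from_dict(medians, orient="index", columns=table.otu_ids)
    mean = med.mean(axis=0)
    sem = med.std(axis=0, ddof=1) / np.sqrt(len(med)) if len(med) > 1 else mean * 0.0
    profile = pd.DataFrame({"otu_id": table.otu_ids, "mean": mean.to_numpy(), "sem": sem.to_numpy()})
    return ConsensusProfile(profile=profile, specimen_medians=med, n_replicates=n_reps)


# ---------------------------------------------------------------------------
# Contaminant identification / removal
# ---------------------------------------------------------------------------


@dataclass
class ContaminantReport:
    """Evidence for flagged contaminant OTUs and removal accounting.

    ``flagged`` columns: ``otu_id, consensus_abundance, max_kit_prevalence,
    n_kits_detected``.  After :func:`remove_contaminants`, ``retention``
    holds per-sample retained read fractions and ``emptied_samples`` any
    samples whose reads were entirely removed.
    """

    flagged: pd.DataFrame
    min_abund: float
    min_prevalence: float
    retention: pd.DataFrame | None = None
    emptied_samples: list[str] = field(default_factory=list)

    @property
    def flagged_otus(self) -> list[str]:
        return list(self.flagged["otu_id"])

    @property
    def mean_retention(self) -> float:
        if self.retention is None or len(self.retention) == 0:
            return 1.0
        return float(self.retention["fraction_retained"].mean())


def identify_contaminants(
    controls: CountTable,
    design: ReplicateDesign,
    min_abund: float = 0.01,
    min_prevalence: float = 2.0 / 3.0,
) -> ContaminantReport:
    """Flag reagent-contaminant OTUs from replicated negative controls.

    An OTU is called a contaminant when both hold:

    * its mean-of-replicate-medians abundance across the control kits is
      at least *min_abund* (reproducible mass in the controls), and
    * it is detected (count > 0) in at least *min_prevalence* of the
      replicates of at least one control kit (kit-level reproducibility).

    Stochastic noise fails both: it rarely recurs across a kit's
    replicates, and when it does its median abundance is tiny.
    """
    design.check_against(controls)
    df = design.frame.loc[controls.sample_ids]
    if not df["is_control"].all():
        raise DesignError("identify_contaminants expects a controls-only table")
    if df.empty:
        raise DesignError("no control samples provided")

    consensus = mean_of_replicate_medians(controls, design, controls=True)
    mean_abund = consensus.profile.set_index("otu_id")["mean"]

    detected = pd.DataFrame(
        controls.counts > 0, index=controls.sample_ids, columns=controls.otu_ids
    )
    kit_prev = detected.groupby(df["kit_id"]).mean()  # kits x OTUs
    max_prev = kit_prev.max(axis=0)
    n_kits = (kit_prev >= min_prevalence).sum(axis=0)

    mask = (mean_abund >= min_abund) & (max_prev >= min_prevalence)
    flagged = pd.DataFrame(
        {
            "otu_id": mean_abund.index[mask],
            "consensus_abundance": mean_abund[mask].to_numpy(),
            "max_kit_prevalence": max_prev[mask].to_numpy(),
            "n_kits_detected": n_kits[mask].to_numpy(),
        }
    ).sort_values("consensus_abundance", ascending=False).reset_index(drop=True)
    return ContaminantReport(flagged=flagged, min_abund=min_abund, min_prevalence=min_prevalence)


def remove_contaminants(
    table: CountTable,
    flagged: list[str] | ContaminantReport,
) -> tuple[CountTable, ContaminantReport]:
    """Drop flagged OTU columns and account for retained reads.

    Per-sample retained fraction = (total after removal) / (total before).
    A sample emptied by removal (retention 0) is recorded in
    ``emptied_samples`` but kept in the table so the loss is visible.
    """
    if isinstance(flagged, ContaminantReport):
        report = flagged
        otus = report.flagged_otus
    else:
        otus = list(flagged)
        report = ContaminantReport(
            flagged=pd.DataFrame({"otu_id": otus}), min_abund=np.nan, min_prevalence=np.nan
        )
    unknown = set(otus) - set(table.otu_ids)
    if unknown:
        raise KeyError(f"flagged OTUs not present in table: {sorted(unknown)[:5]}")

    before = table.totals().astype(float)
    cleaned = table.drop_otus(otus) if otus else table
    after = cleaned.totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(before > 0, after / np.where(before > 0, before, 1.0), 1.0)
    retention = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "reads_before": before.astype(int),
            "reads_after": after.astype(int),
            "reads_removed": (before - after).astype(int),
            "fraction_retained": frac,
        }
    )
    report.retention = retention
    report.emptied_samples = [
        s for s, b, a in zip(table.sample_ids, before, after) if b > 0 and a == 0
    ]
    return cleaned, report


# ---------------------------------------------------------------------------
# Replicate concordance
# ---------------------------------------------------------------------------


def concordance_score(
    table: CountTable,
    design: ReplicateDesign,
    specimen_id: str,
) -> float:
    """Fraction of a specimen's reads carried by OTUs seen in ALL replicates.

    A specimen whose replicates are pure reproducible signal scores 1
    (every read belongs to a universally detected OTU); one whose
    replicates share no OTUs scores 0.  This is the scalar analogue of
    plotting replicate abundances against each other and asking how much
    mass sits on the diagonal.
    """
    design.check_against(table)
    samples = [s for s in design.samples_of_specimen(specimen_id) if s in set(table.sample_ids)]
    if len(samples) < 2:
        raise DistanceError(
            f"specimen {specimen_id!r} has {len(samples)} replicate(s); concordance needs >= 2"
        )
    sub = table.select_samples(samples)
    totals = sub.totals()
    if (totals == 0).any():
        raise DistanceError(f"specimen {specimen_id!r} has a zero-total replicate")
    shared = (sub.counts > 0).all(axis=0)
    return float(sub.counts[:, shared].sum() / sub.counts.sum())
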