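"""Regime classification and the biomass-reproducibility transition.

A low-biomass sequencing result can be driven by three different sources:
genuine template (signal), DNA present in the reagents (contamination), or
run-to-run stochastic noise.  The three leave distinct fingerprints in the
intra/inter replicate distance partition:

* signal dominated — replicates agree with each other *and* with replicates
  from other kits/specimens: low median intra, low intra/inter separation;
* contamination dominated — replicates agree within a kit but kits disagree
  (each kit carries its own reagent community): low median intra, large
  intra/inter separation;
* noise dominated — replicates do not even agree with themselves: high
  median intra, and the intra and inter distance distributions overlap.

:func:`classify_regime` turns a :class:`~replinoise.dissimilarity.DistanceSummary`
into one of these calls.  :func:`transition_fit` fits a four-parameter
logistic in log10(copies) to (biomass, mean intrareplicate distance)
points, locating the copy-number window where results flip from
reproducible to noise-dominated.  :func:`flag_low_biomass` applies the
conservative screening rule that samples below 1e5 16S copies should be
treated as noise-prone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dissimilarity import DistanceSummary
from .errors import DistanceError, FitError

__all__ = [
    "RegimeThresholds",
    "RegimeCall",
    "classify_regime",
    "classify_from_evidence",
    "TransitionFit",
    "transition_fit",
    "flag_low_biomass",
    "LOW_BIOMASS_THRESHOLD",
]

#: 16S rRNA gene copies/sample below which a result is likely noise-affected.
LOW_BIOMASS_THRESHOLD = 1e5

REGIMES = ("signal_dominated", "contamination_dominated", "noise_dominated", "indeterminate")


@dataclass(frozen=True)
class RegimeThresholds:
    """Decision thresholds for :func:`classify_regime`.

    Defaults were calibrated on the generative simulator so that its three
    clear-cut parameterizations (abundant template, reagent contamination
    at zero template, pure noise at zero template) are always recovered;
    they are deliberately configurable because real studies may sit closer
    to the boundaries.
    """

    intra_low: float = 0.35  # replicates "agree" below this median intra distance
    separation: float = 0.20  # median inter - median intra that implies kit-specific signal
    noise_floor: float = 0.50  # median intra above this means replicates disagree
    overlap_min: float = 0.50  # intra/inter KDE overlap required to call noise


@dataclass(frozen=True)
class RegimeCall:
    specimen_id: str
    regime: str
    median_intra: float
    median_inter: float
    overlap: float
    thresholds: RegimeThresholds = field(default_factory=RegimeThresholds)


def classify_from_evidence(
    median_intra: float,
    median_inter: float,
    overlap: float,
    thresholds: RegimeThresholds = RegimeThresholds(),
    specimen_id: str = "",
    pairing: str = "replicate",
) -> RegimeCall:
    """Pure decision rule on (median intra, median inter, overlap).

    Idempotent and deterministic: the call is a function of the evidence
    and thresholds only.

    *pairing* states what the interreplicate set compares and hence what a
    large intra/inter separation means:

    * ``"replicate"`` (kit-vs-kit at the same dilution): reproducible
      replicates whose kits *disagree* carry kit-specific reagent DNA →
      separation implies contamination; kits that also agree with each
      other are recovering the same genuine community → signal.
    * ``"control"`` (specimen-vs-matched-control): a reproducible specimen
      *distinct from* its negative controls is genuine signal, while one
      that resembles the controls is carrying the reagent background →
      the separation test inverts.
    """
    t = thresholds
    if pairing not in ("replicate", "control"):
        raise ValueError(f"unknown pairing {pairing!r}; use 'replicate' or 'control'")
    if median_intra <= t.intra_low:
        separated = median_inter - median_intra >= t.separation
        if pairing == "replicate":
            regime = "contamination_dominated" if separated else "signal_dominated"
        else:
            regime = "signal_dominated" if separated else "contamination_dominated"
    elif median_intra > t.noise_floor and (
        overlap >= t.overlap_min or median_inter > t.noise_floor
    ):
        # replicates disagree among themselves; noise is called either when
        # the intra/inter distance distributions overlap (dilution-series
        # signature) or when both medians sit above the noise floor (tiny
        # replicate sets make the KDE overlap unreliable)
        regime = "noise_dominated"
    else:
        regime = "indeterminate"
    return RegimeCall(
        specimen_id=specimen_id,
        regime=regime,
        median_intra=float(median_intra),
        median_inter=float(median_inter),
        overlap=float(overlap),
        thresholds=t,
    )


def classify_regime(
    summary: DistanceSummary,
    thresholds: RegimeThresholds = RegimeThresholds(),
    specimen_id: str = "",
    pairing: str = "replicate",
) -> RegimeCall:
    """Classify one specimen/kit from its distance summary."""
    if len(summary.intra) == 0 or len(summary.inter) == 0:
        raise DistanceError("regime classification needs both intra and inter distances")
    overlap = summary.overlap
    if overlap is None:
        # too few distances for a KDE; fall back to a coarse interval overlap
        overlap = _range_overlap(summary.intra_values, summary.inter_values)
    return classify_from_evidence(
        summary.median_intra, summary.median_inter, overlap, thresholds, specimen_id, pairing
    )


def _range_overlap(a: np.ndarray, b: np.ndarray) -> float:
    lo = max(a.min(), b.min())
    hi = min(a.max(), b.max())
    span = max(a.max(), b.max()) - min(a.min(), b.min())
    if span <= 0:
        return 1.0
    return max(0.0, (hi - lo) / span)


# ---------------------------------------------------------------------------
# Biomass-reproducibility transition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionFit:
    """Four-parameter logistic fit of intra distance vs log10 copies.

    distance(x) = lower + (upper - lower) / (1 + exp(slope * (x - midpoint)))

    with x = log10(copies) and slope > 0, so distance falls from *upper*
    (noise-dominated, few copies) to *lower* (reproducible, many copies)
    as biomass rises.  The transition range brackets 10%-90% of the span.
    """

    lower: float
    upper: float
    midpoint_log10: float
    slope: float
    residual_ss: float
    converged: bool

    @property
    def midpoint_copies(self) -> float:
        return 10.0**self.midpoint_log10

    @property
    def transition_range_copies(self) -> tuple[float, float]:
        """Copy numbers where the fitted curve passes 90% and 10% of its span."""
        if not self.converged:
            raise FitError("no transition range: fit did not converge")
        half_width = math.log(9.0) / self.slope
        return (
            10.0 ** (self.midpoint_log10 - half_width),
            10.0 ** (self.midpoint_log10 + half_width),
        )

    def predict(self, copies: np.ndarray) -> np.ndarray:
        x = np.log10(np.asarray(copies, dtype=float))
        return self.lower + (self.upper - self.lower) / (
            1.0 + np.exp(self.slope * (x - self.midpoint_log10))
        )


def transition_fit(
    copies: np.ndarray,
    mean_intra: np.ndarray,
    min_span: float = 0.1,
) -> TransitionFit:
    """Fit the logistic biomass-reproducibility transition.

    Parameters
    ----------
    copies
        16S gene copies per specimen (> 0); must span >= 2 decades with
        >= 5 points.
    mean_intra
        Mean intrareplicate Bray-Curtis distance per specimen, same order.
    min_span
        Minimum fitted upper-lower span to consider a transition real;
        flatter data yields ``converged=False``.
    """
    c = np.asarray(copies, dtype=float)
    y = np.asarray(mean_intra, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise FitError("copies and mean_intra must be equal-length 1-D arrays")
    if c.size < 5:
        raise FitError("transition fit needs >= 5 (copies, distance) points")
    if (c <= 0).any():
        raise FitError("copies must be strictly positive")
    x = np.log10(c)
    if x.max() - x.min() < 2.0:
        raise FitError("copies must span at least 2 decades")

    flat = float(np.ptp(y)) < 0.05

    def model(p, xx):
        lo, hi, mid, k = p
        return lo + (hi - lo) / (1.0 + np.exp(np.clip(k * (xx - mid), -500, 500)))

    p0 = (float(y.min()), float(y.max()), float(np.median(x)), 2.0)
    bounds = (
        [0.0, 0.0, x.min() - 2.0, 0.05],
        [1.5, 1.5, x.max() + 2.0, 50.0],
    )
    sol = least_squares(lambda p: model(p, x) - y, p0, bounds=bounds)
    lo, hi, mid, k = sol.x
    span_ok = (hi - lo) >= min_span
    # the midpoint is only identified if the data actually bracket it
    mid_in_range = x.min() - 0.5 <= mid <= x.max() + 0.5
    converged = bool(sol.success and span_ok and not flat and mid_in_range)
    return TransitionFit(
        lower=float(lo),
        upper=float(hi),
        midpoint_log10=float(mid),
        slope=float(k),
        residual_ss=float(2.0 * sol.cost),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Low-biomass screening rule
# ---------------------------------------------------------------------------


def flag_low_biomass(
    biomass: dict[str, float],
    specimens: list[str] | None = None,
    threshold: float = LOW_BIOMASS_THRESHOLD,
) -> pd.DataFrame:
    """Flag specimens whose 16S copy number falls below *threshold*.

    The rule is a strict inequality: a specimen at exactly the threshold
    is not flagged.  Specimens requested via *specimens* but absent from
    *biomass* are returned with flag ``"unknown"`` rather than silently
    passing.

    Returns a DataFrame with columns ``specimen_id, copies, flag`` where
    flag is one of ``low_biomass`` (copies < threshold), ``ok``, or
    ``unknown``.
    """
    if specimens is None:
        specimens = list(biomass)
    rows = []
    for spec in specimens:
        if spec in biomass:
            copies = float(biomass[spec])
            if copies < 0:
                raise FitError(f"negative copy number for specimen {spec!r}")
            flag = "low_biomass" if copies < threshold else "ok"
            rows.append((spec, copies, flag))
        else:
            rows.append((spec, np.nan, "unknown"))
    return pd.DataFrame(rows, columns=["specimen_id", "copies", "flag"])
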