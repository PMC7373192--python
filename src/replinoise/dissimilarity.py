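"""Bray-Curtis dissimilarity partitioned by replicate structure.

The reproducibility diagnostics of this package all start from one
partition: Bray-Curtis distances *within* a group of technical replicates
(intrareplicate) versus distances *between* groups measured at the same
level (interreplicate).  For a dilution series the group is the
DNA-isolation kit and the level is the dilution; for clinical specimens
the group is the specimen and the interreplicate set is specimen versus
matched control within the same sample type.

Distances in both sets live on [0, 1]; their distributions are summarized
by boundary-corrected Gaussian kernel density estimates and by the overlap
coefficient (integral of the pointwise minimum of the two densities),
which quantifies how separable the two distance populations are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DistanceError
from .tables_io import CountTable, ReplicateDesign

__all__ = [
    "bray_curtis",
    "pairwise_bray_curtis",
    "kde",
    "overlap_coefficient",
    "DistanceSummary",
    "intra_inter_distances",
    "group_summaries",
    "KDE_GRID_SIZE",
    "BANDWIDTH_FLOOR",
]

KDE_GRID_SIZE = 512
BANDWIDTH_FLOOR = 0.01


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity Σ|x_i − y_i| / Σ(x_i + y_i).

    Symmetric, 0 iff the vectors are element-wise equal, 1 when supports
    are disjoint.  Raises :class:`DistanceError` on negative entries or
    when both vectors are all-zero (the distance is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DistanceError(f"vectors must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise DistanceError("Bray-Curtis requires non-negative abundances")
    denom = float(x.sum() + y.sum())
    if denom == 0.0:
        raise DistanceError("Bray-Curtis is undefined for two all-zero vectors")
    # roundoff can push a disjoint-support pair infinitesimally past 1
    return float(min(1.0, np.abs(x - y).sum() / denom))


def pairwise_bray_curtis(matrix: np.ndarray) -> np.ndarray:
    """Square symmetric Bray-Curtis matrix over the rows of *matrix*."""
    m = np.asarray(matrix, dtype=float)
    if (m < 0).any():
        raise DistanceError("Bray-Curtis requires non-negative abundances")
    totals = m.sum(axis=1)
    if (totals == 0).any():
        raise DistanceError("rows with zero total have undefined Bray-Curtis distances")
    n = m.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(m[i] - m[i + 1 :]).sum(axis=1)
        dm[i, i + 1 :] = diff / (totals[i] + totals[i + 1 :])
    np.clip(dm, 0.0, 1.0, out=dm)
    return dm + dm.T


# ---------------------------------------------------------------------------
# Bounded-support KDE and overlap
# ---------------------------------------------------------------------------


def kde(
    values: np.ndarray,
    grid_size: int = KDE_GRID_SIZE,
    bandwidth: float | None = None,
    bandwidth_floor: float = BANDWIDTH_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE on [0, 1] with boundary correction by reflection.

    Bandwidth defaults to Silverman's rule, floored at *bandwidth_floor*
    so that degenerate all-equal inputs (common for clean technical
    replicates, where every distance is ~0) yield a narrow peak rather
    than a singular estimate.  The density is renormalized to integrate
    to 1 over [0, 1] by the trapezoid rule.

    Returns ``(grid, density)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DistanceError("KDE requires at least 2 values")
    if (v < 0).any() or (v > 1).any():
        raise DistanceError("KDE support is [0, 1]; values outside found")
    if bandwidth is None:
        sd = float(np.std(v, ddof=1))
        iqr = float(np.subtract(*np.percentile(v, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = 0.9 * spread * v.size ** (-0.2)
    bandwidth = max(float(bandwidth), bandwidth_floor)
    grid = np.linspace(0.0, 1.0, grid_size)
    # reflect the sample at both boundaries so mass does not leak out
    pts = np.concatenate([v, -v, 2.0 - v])
    z = (grid[:, None] - pts[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (v.size * bandwidth * np.sqrt(2.0 * np.pi))
    area = float(np.trapezoid(dens, grid))
    if area <= 0:
        raise DistanceError("degenerate KDE: zero integrated density")
    return grid, dens / area


def overlap_coefficient(
    kde_a: tuple[np.ndarray, np.ndarray], kde_b: tuple[np.ndarray, np.ndarray]
) -> float:
    """Overlap of two densities: trapezoid integral of their pointwise min.

    1 for identical densities, ~0 for well-separated ones.  Both curves
    must be tabulated on the same grid.
    """
    grid_a, dens_a = kde_a
    grid_b, dens_b = kde_b
    if grid_a.shape != grid_b.shape or not np.allclose(grid_a, grid_b):
        raise DistanceError("overlap requires both densities on the same grid")
    return float(min(1.0, np.trapezoid(np.minimum(dens_a, dens_b), grid_a)))


# ---------------------------------------------------------------------------
# Intra / inter partition
# ---------------------------------------------------------------------------


@dataclass
class DistanceSummary:
    """Intra- and interreplicate Bray-Curtis distances with provenance.

    ``intra`` and ``inter`` are DataFrames with columns
    ``sample_a, sample_b, group_a, group_b, level, distance``.  KDEs (on a
    shared 512-point grid over [0, 1]) and the overlap coefficient are
    computed when both sets hold at least 2 distances.
    """

    intra: pd.DataFrame
    inter: pd.DataFrame
    stratum: str
    kde_intra: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)
    kde_inter: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)
    overlap: float | None = None

    def __post_init__(self) -> None:
        for name, df in (("intra", self.intra), ("inter", self.inter)):
            if len(df) and ((df["distance"] < 0).any() or (df["distance"] > 1).any()):
                raise DistanceError(f"{name} distances outside [0, 1]")
        if (
            self.kde_intra is None
            and len(self.intra) >= 2
            and len(self.inter) >= 2
        ):
            self.kde_intra = kde(self.intra["distance"].to_numpy())
            self.kde_inter = kde(self.inter["distance"].to_numpy())
            self.overlap = overlap_coefficient(self.kde_intra, self.kde_inter)

    @property
    def intra_values(self) -> np.ndarray:
        return self.intra["distance"].to_numpy()

    @property
    def inter_values(self) -> np.ndarray:
        return self.inter["distance"].to_numpy()

    @property
    def median_intra(self) -> float:
        if len(self.intra) == 0:
            raise DistanceError("no intrareplicate distances")
        return float(np.median(self.intra_values))

    @property
    def median_inter(self) -> float:
        if len(self.inter) == 0:
            raise DistanceError("no interreplicate distances")
        return float(np.median(self.inter_values))

    @classmethod
    def from_values(
        cls,
        intra: np.ndarray,
        inter: np.ndarray,
        stratum: str = "manual",
    ) -> "DistanceSummary":
        """Build a summary from bare distance arrays (no provenance)."""

        def frame(vals):
            vals = np.asarray(vals, dtype=float)
            return pd.DataFrame(
                {
                    "sample_a": [""] * vals.size,
                    "sample_b": [""] * vals.size,
                    "group_a": [""] * vals.size,
                    "group_b": [""] * vals.size,
                    "level": [""] * vals.size,
                    "distance": vals,
                }
            )

        return cls(intra=frame(intra), inter=frame(inter), stratum=stratum)

    def to_long_frame(self) -> pd.DataFrame:
        a = self.intra.assign(kind="intra")
        b = self.inter.assign(kind="inter")
        return pd.concat([a, b], ignore_index=True)


def _grouping(design: ReplicateDesign, stratum: str) -> tuple[pd.Series, pd.Series]:
    """Return (group label, level label) per sample for a stratum.

    stratum="kit": group = (kit, dilution); level = dilution — intra pairs
    are technical replicates of one kit at one dilution, inter pairs cross
    kits at the same dilution.

    stratum="specimen": group = specimen; level = sample_type — intra pairs
    are a specimen's technical replicates, inter pairs join a specimen's
    samples with control samples of the same sample type.
    """
    df = design.frame
    if stratum == "kit":
        group = df["kit_id"].astype(str) + "|" + df["dilution_label"].astype(str)
        level = df["dilution_label"].astype(str)
    elif stratum == "specimen":
        group = df["specimen_id"].astype(str)
        level = df["sample_type"].astype(str)
    else:
        raise DistanceError(f"unknown stratum {stratum!r}; use 'kit' or 'specimen'")
    return group, level


def _normalized_matrix(
    table: CountTable,
    normalize: str,
    rarefy_depth: int | None,
    seed: int | None,
) -> np.ndarray:
    totals = table.totals()
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise DistanceError(f"zero-total samples cannot enter distances: {bad[:5]}")
    if normalize == "relabund":
        return table.relative_abundance()
    if normalize == "rarefy":
        depth = rarefy_depth if rarefy_depth is not None else int(totals.min())
        if (totals < depth).any():
            bad = [s for s, t in zip(table.sample_ids, totals) if t < depth]
            raise DistanceError(f"samples below rarefaction depth {depth}: {bad[:5]}")
        rng = np.random.default_rng(seed)
        out = np.zeros(table.counts.shape, dtype=float)
        for i, row in enumerate(table.counts):
            reads = np.repeat(np.arange(table.n_otus), row)
            pick = rng.choice(reads, size=depth, replace=False)
            out[i] = np.bincount(pick, minlength=table.n_otus)
        return out
    if normalize == "none":
        return table.counts.astype(float)
    raise DistanceError(f"unknown normalize mode {normalize!r}")


def intra_inter_distances(
    table: CountTable,
    design: ReplicateDesign,
    stratum: str = "kit",
    normalize: str = "relabund",
    rarefy_depth: int | None = None,
    seed: int | None = None,
) -> DistanceSummary:
    """Partition all pairwise Bray-Curtis distances into intra/inter sets.

    Counts are normalized first (default: per-sample relative abundance;
    ``rarefy`` subsamples without replacement to a common depth using
    *seed*).  Intra pairs share a stratum group; inter pairs come from
    different groups at the same level.  For ``stratum="specimen"`` the
    inter set is restricted to specimen-versus-control pairs within the
    same sample type; controls contribute their own intra pairs too.
    """
    design.check_against(table)
    design = design.subset(table.sample_ids)
    group, level = _grouping(design, stratum)
    mat = _normalized_matrix(table, normalize, rarefy_depth, seed)
    dm = pairwise_bray_curtis(mat)

    ids = table.sample_ids
    grp = group.loc[ids].to_numpy()
    lvl = level.loc[ids].to_numpy()
    is_ctrl = design.frame.loc[ids, "is_control"].to_numpy()

    intra_rows, inter_rows = [], []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            rec = {
                "sample_a": ids[i],
                "sample_b": ids[j],
                "group_a": grp[i],
                "group_b": grp[j],
                "level": lvl[i],
                "distance": dm[i, j],
            }
            if grp[i] == grp[j]:
                intra_rows.append(rec)
            elif lvl[i] == lvl[j]:
                if stratum == "specimen" and is_ctrl.any():
                    # clinical pairing: specimen vs its matched controls
                    if is_ctrl[i] != is_ctrl[j]:
                        inter_rows.append(rec)
                else:
                    inter_rows.append(rec)

    cols = ["sample_a", "sample_b", "group_a", "group_b", "level", "distance"]
    intra = pd.DataFrame(intra_rows, columns=cols)
    inter = pd.DataFrame(inter_rows, columns=cols)
    if len(intra) == 0:
        raise DistanceError(
            "no intrareplicate pairs found: technical replicates (>=2 samples per "
            f"{stratum} group) are required for concordance analysis"
        )
    return DistanceSummary(intra=intra, inter=inter, stratum=stratum)


def group_summaries(
    table: CountTable,
    design: ReplicateDesign,
    stratum: str = "kit",
    normalize: str = "relabund",
) -> dict[str, DistanceSummary]:
    """Per-group view of the intra/inter partition.

    For each stratum group (kit for ``stratum="kit"``, specimen for
    ``stratum="specimen"``) returns a :class:`DistanceSummary` whose intra
    set is the group's own replicate pairs and whose inter set is every
    pair joining that group to a different group at the same level.  This
    is the unit on which regimes are classified.
    """
    pooled = intra_inter_distances(table, design, stratum=stratum, normalize=normalize)
    key = "kit_id" if stratum == "kit" else "specimen_id"
    sample_group = design.frame[key].astype(str)

    out: dict[str, DistanceSummary] = {}
    for g in dict.fromkeys(sample_group.loc[table.sample_ids]):
        in_g = set(sample_group.index[sample_group == g]) & set(table.sample_ids)
        intra = pooled.intra[
            pooled.intra["sample_a"].isin(in_g) & pooled.intra["sample_b"].isin(in_g)
        ].reset_index(drop=True)
        inter = pooled.inter[
            pooled.inter["sample_a"].isin(in_g) ^ pooled.inter["sample_b"].isin(in_g)
        ].reset_index(drop=True)
        if len(intra) == 0:
            continue
        out[g] = DistanceSummary(intra=intra, inter=inter, stratum=stratum)
    return out
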