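"""Data model and readers/writers for replicated OTU count tables.

The central container is :class:`CountTable`: an integer matrix of read
counts with samples as rows and OTUs as columns, optionally annotated with
consensus taxonomy strings.  Tables are read from and written to the mothur
``.shared`` dialect (tab-delimited ``label  Group  numOtus  Otu1 ...``) and
taxonomy from the mothur ``.cons.taxonomy`` dialect (``OTU  Size
Taxonomy``).  Sample-level metadata — which specimen a sequencing library
belongs to, which technical replicate it is, which DNA-isolation kit or
batch produced it, whether it is a negative control — lives in
:class:`ReplicateDesign`.  Per-specimen bacterial biomass (16S rRNA gene
copies per sample, typically from droplet digital PCR) is a plain mapping
handled by :func:`read_biomass`.

A small packaged fixture with the demographics of the 20 healthy volunteers
of the clinical cohort is exposed through :func:`load_demographics` /
:func:`summarize_demographics`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, DistanceError, FormatError

__all__ = [
    "CountTable",
    "ReplicateDesign",
    "read_shared",
    "write_shared",
    "read_taxonomy",
    "write_taxonomy",
    "split_taxonomy",
    "read_design",
    "write_design",
    "read_biomass",
    "write_biomass",
    "load_demographics",
    "summarize_demographics",
]

DESIGN_COLUMNS = (
    "sample_id",
    "specimen_id",
    "replicate_index",
    "kit_id",
    "is_control",
    "sample_type",
    "dilution_label",
)


@dataclass
class CountTable:
    """Read counts for a set of sequencing libraries.

    Parameters
    ----------
    sample_ids
        Ordered, unique library identifiers (the ``Group`` column of a
        ``.shared`` file); one per matrix row.
    otu_ids
        Ordered, unique OTU identifiers; one per matrix column.
    counts
        Non-negative integer matrix of shape ``(n_samples, n_otus)``.
    taxonomy
        Optional map from OTU id to its consensus taxonomy string, kept
        verbatim (use :func:`split_taxonomy` to break it into ranks).
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=1e-9):
                raise FormatError("counts must be integers")
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            raise FormatError("counts must be non-negative")
        self.counts = counts.astype(np.int64, copy=False)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.otu_ids)
            if unknown:
                raise FormatError(f"taxonomy keys not in table: {sorted(unknown)[:5]}")

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_index(sample_id)]

    def totals(self) -> np.ndarray:
        """Per-sample read totals (library sizes)."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Total-sum-scaled matrix; zero-total rows stay all-zero."""
        totals = self.totals().astype(float)
        out = np.zeros(self.counts.shape, dtype=float)
        nz = totals > 0
        out[nz] = self.counts[nz] / totals[nz, None]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = [str(s) for s in sample_ids]
        idx = [self.sample_index(s) for s in ids]
        return CountTable(ids, list(self.otu_ids), self.counts[idx], self.taxonomy)

    def drop_otus(self, otu_ids: Iterable[str]) -> "CountTable":
        drop = set(otu_ids)
        unknown = drop - set(self.otu_ids)
        if unknown:
            raise KeyError(f"unknown OTU ids: {sorted(unknown)[:5]}")
        keep = [i for i, o in enumerate(self.otu_ids) if o not in drop]
        kept_ids = [self.otu_ids[i] for i in keep]
        tax = None
        if self.taxonomy is not None:
            tax = {o: t for o, t in self.taxonomy.items() if o in set(kept_ids)}
        return CountTable(list(self.sample_ids), kept_ids, self.counts[:, keep], tax)


@dataclass
class ReplicateDesign:
    """Maps each sequenced library to its specimen, replicate and batch.

    Backed by a DataFrame indexed by ``sample_id`` with columns
    ``specimen_id, replicate_index, kit_id, is_control, sample_type,
    dilution_label``.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        missing = {"specimen_id", "replicate_index", "kit_id", "is_control", "sample_type"} - set(
            df.columns
        )
        if missing:
            raise DesignError(f"design is missing required columns: {sorted(missing)}")
        if "dilution_label" not in df.columns:
            df = df.assign(dilution_label="")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise DesignError(f"duplicate sample_id rows in design: {dup[:5]}")
        df = df.copy()
        df.index = df.index.astype(str)
        df["replicate_index"] = df["replicate_index"].astype(int)
        if (df["replicate_index"] < 1).any():
            raise DesignError("replicate_index must be >= 1 (1-based)")
        df["is_control"] = df["is_control"].map(_to_bool)
        df["dilution_label"] = df["dilution_label"].fillna("").astype(str)
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def loc(self, sample_id: str) -> pd.Series:
        return self.frame.loc[str(sample_id)]

    def specimens(self) -> list[str]:
        return list(dict.fromkeys(self.frame["specimen_id"]))

    def samples_of_specimen(self, specimen_id: str) -> list[str]:
        mask = self.frame["specimen_id"] == specimen_id
        return list(self.frame.index[mask])

    def subset(self, sample_ids: Iterable[str]) -> "ReplicateDesign":
        ids = [str(s) for s in sample_ids]
        return ReplicateDesign(self.frame.loc[ids].copy())

    def check_against(self, table: CountTable) -> None:
        """Every sample of *table* must appear exactly once in the design."""
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise DesignError(f"samples missing from design: {missing[:5]}")


def _to_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"1", "true", "t", "yes", "y"}:
        return True
    if s in {"0", "false", "f", "no", "n", ""}:
        return False
    raise DesignError(f"cannot interpret is_control value {x!r} as boolean")


# ---------------------------------------------------------------------------
# mothur .shared / .cons.taxonomy
# ---------------------------------------------------------------------------


def read_shared(path: str | Path, taxonomy: Mapping[str, str] | None = None) -> CountTable:
    """Read a mothur ``.shared`` file into a :class:`CountTable`.

    The dialect is tab-delimited with header ``label  Group  numOtus``
    followed by one column per OTU; one row per sequencing library
    (``Group``).  ``numOtus`` is checked against the parsed OTU count.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in ("label", "Group", "numOtus"):
            if col not in header[:3]:
                raise FormatError(f".shared header is missing column {col!r} in {path}")
        otu_ids = header[3:]
        if not otu_ids:
            raise FormatError(f".shared file {path} has no OTU columns")
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, found {len(parts)}"
                )
            group = parts[1]
            try:
                num_otus = int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: numOtus {parts[2]!r} is not an integer")
            if num_otus != len(otu_ids):
                raise FormatError(
                    f"{path}:{lineno}: numOtus={num_otus} but header lists {len(otu_ids)} OTUs"
                )
            row = []
            for col, val in zip(otu_ids, parts[3:]):
                try:
                    row.append(int(val))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer count {val!r} in column {col}"
                    ) from None
            sample_ids.append(group)
            rows.append(row)
    if not rows:
        raise FormatError(f".shared file {path} has no data rows")
    table = CountTable(sample_ids, otu_ids, np.array(rows, dtype=np.int64))
    if taxonomy is not None:
        table.taxonomy = {o: taxonomy[o] for o in table.otu_ids if o in taxonomy}
    return table


def write_shared(table: CountTable, path: str | Path, label: str = "0.03") -> None:
    """Write *table* in the mothur ``.shared`` dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["label", "Group", "numOtus", *table.otu_ids]) + "\n")
        for sid, row in zip(table.sample_ids, table.counts):
            fields = [label, sid, str(table.n_otus), *(str(int(c)) for c in row)]
            fh.write("\t".join(fields) + "\n")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a mothur ``.cons.taxonomy`` file (``OTU  Size  Taxonomy``).

    The taxonomy string is stored verbatim, trailing semicolon included.
    """
    path = Path(path)
    out: dict[str, str] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "OTU" or header[2] != "Taxonomy":
            raise FormatError(f".cons.taxonomy header malformed in {path}: {header[:3]}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields")
            if parts[0] in out:
                raise FormatError(f"{path}:{lineno}: duplicate OTU {parts[0]!r}")
            out[parts[0]] = parts[2]
    return out


def write_taxonomy(taxonomy: Mapping[str, str], path: str | Path, sizes: Mapping[str, int] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("OTU\tSize\tTaxonomy\n")
        for otu, tax in taxonomy.items():
            size = sizes.get(otu, 0) if sizes else 0
            fh.write(f"{otu}\t{size}\t{tax}\n")


def split_taxonomy(tax: str) -> list[str]:
    """Split a ``;``-delimited taxonomy string into clean rank names.

    Bootstrap confidence suffixes like ``(100)`` are stripped.
    """
    ranks = []
    for part in tax.strip().strip(";").split(";"):
        part = part.strip()
        if part.endswith(")") and "(" in part:
            part = part[: part.rindex("(")]
        if part:
            ranks.append(part)
    return ranks


# ---------------------------------------------------------------------------
# Design and biomass TSVs
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> ReplicateDesign:
    """Read a replicate-design TSV.

    Required columns: ``sample_id, specimen_id, replicate_index, kit_id,
    is_control, sample_type``; ``dilution_label`` is optional and unknown
    columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise DesignError(f"design file {path} is missing the sample_id column")
    return ReplicateDesign(df)


def write_design(design: ReplicateDesign, path: str | Path) -> None:
    design.frame.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def read_biomass(path: str | Path) -> dict[str, float]:
    """Read per-specimen 16S copy numbers (``specimen_id  copies`` TSV).

    Copies are per sample as quantified by ddPCR; scientific notation such
    as ``1e6`` is accepted.
    """
    df = pd.read_csv(path, sep="\t", dtype={"specimen_id": str})
    for col in ("specimen_id", "copies"):
        if col not in df.columns:
            raise FormatError(f"biomass file {path} is missing the {col!r} column")
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise FormatError(f"duplicate specimen rows in biomass file: {dup[:5]}")
    copies = df["copies"].astype(float)
    if (copies < 0).any():
        raise FormatError("16S copy numbers must be non-negative")
    return dict(zip(df["specimen_id"], copies))


def write_biomass(biomass: Mapping[str, float], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("specimen_id\tcopies\n")
        for spec, copies in biomass.items():
            fh.write(f"{spec}\t{copies:g}\n")


# ---------------------------------------------------------------------------
# Cohort demographics fixture
# ---------------------------------------------------------------------------


def load_demographics() -> pd.DataFrame:
    """Demographics of the 20 healthy volunteers of the clinical cohort.

    Columns: sex, age (years), race, pack-years, smoking status, FEV1 and
    FVC (liters and % predicted) and the FEV1/FVC ratio.
    """
    ref = importlib.resources.files("replinoise") / "data" / "demographics.tsv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    return df


def summarize_demographics(demographics: pd.DataFrame) -> dict[str, float]:
    """Cohort summary: mean/SD age, percent female and percent per race.

    Mean age is also reported rounded to the nearest integer year
    (``mean_age_years_rounded``); percentages are over all participants.
    """
    if len(demographics) == 0:
        raise DesignError("demographics table is empty")
    n = len(demographics)
    age = demographics["age_years"].astype(float)
    out: dict[str, float] = {
        "n_participants": float(n),
        "mean_age_years": float(age.mean()),
        "sd_age_years": float(age.std(ddof=1)) if n > 1 else 0.0,
        "mean_age_years_rounded": float(round(age.mean())),
        "pct_female": 100.0 * float((demographics["sex"] == "Female").sum()) / n,
    }
    for race, count in demographics["race"].value_counts().items():
        out[f"pct_race_{str(race).lower()}"] = 100.0 * float(count) / n
    return out


def reject_zero_total_samples(table: CountTable) -> None:
    """Raise if any sample has zero total reads (distance ops require > 0)."""
    totals = table.totals()
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise DistanceError(
            f"samples with zero total reads cannot enter distance computations: {bad[:5]}"
        )
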