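"""Long-format seed-trait observations and design validation.

The canonical data model is tidy/long: one row per
``(accession, year, replicate, trait)`` with a numeric value.  A balanced
germplasm trial of ``a`` accessions grown in ``nl`` years with ``nr``
replicate measurements per cell produces ``a * nl * nr`` rows per trait.
Replicate indices label measurement batches within a cell; they carry no
meaning across accessions and are never matched across accessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "TraitDataset",
    "DesignSummary",
    "SiteMetadata",
    "SchemaError",
    "DuplicateKeyError",
    "load_trait_table",
    "write_trait_table",
    "validate_design",
    "load_site_metadata",
]

#: canonical column order of the long-format trait table
COLUMNS = ("accession", "year", "replicate", "trait", "value")

KEY = ("accession", "year", "replicate", "trait")


class SchemaError(ValueError):
    """A required column is missing or a value does not parse."""


class DuplicateKeyError(ValueError):
    """Two records share the same (accession, year, replicate, trait)."""


def _ordered_unique(values: Sequence) -> list:
    """Distinct values in order of first appearance."""
    seen: dict = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return list(seen)


@dataclass(frozen=True)
class TraitDataset:
    """Replicate-level trait observations plus deterministic design metadata.

    Parameters
    ----------
    records
        Long-format table with columns ``accession, year, replicate,
        trait, value``.  Key uniqueness and finite values are enforced.

    Attributes
    ----------
    traits, accessions, years
        Distinct values present in ``records``, ordered by first
        appearance (so two loads of the same file agree exactly).
    """

    records: pd.DataFrame
    traits: tuple = field(init=False)
    accessions: tuple = field(init=False)
    years: tuple = field(init=False)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise ValueError("empty trait dataset")
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        df["accession"] = df["accession"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["year"] = df["year"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        if not np.isfinite(df["value"].to_numpy()).all():
            bad = df.index[~np.isfinite(df["value"].to_numpy())][0]
            raise ValueError(f"non-finite value at record {bad}")
        dup = df.duplicated(subset=list(KEY))
        if dup.any():
            key = tuple(df.loc[dup.idxmax(), list(KEY)])
            raise DuplicateKeyError(
                f"duplicate record for (accession, year, replicate, trait) = {key}"
            )
        object.__setattr__(self, "records", df)
        object.__setattr__(self, "traits", tuple(_ordered_unique(df["trait"])))
        object.__setattr__(self, "accessions", tuple(_ordered_unique(df["accession"])))
        object.__setattr__(self, "years", tuple(_ordered_unique(df["year"])))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraitDataset):
            return NotImplemented
        return self.records.equals(other.records)

    def subset(self, *, trait: str | None = None, year: int | None = None) -> "TraitDataset":
        """Restrict to one trait and/or one year, preserving record order."""
        df = self.records
        if trait is not None:
            if trait not in self.traits:
                raise KeyError(f"trait {trait!r} not in dataset")
            df = df[df["trait"] == trait]
        if year is not None:
            if year not in self.years:
                raise KeyError(f"year {year!r} not in dataset")
            df = df[df["year"] == year]
        return TraitDataset(df.reset_index(drop=True))


@dataclass(frozen=True)
class DesignSummary:
    """Shape of the experimental design implied by a :class:`TraitDataset`."""

    n_accessions: int
    nl: int
    nr: int
    balanced: bool
    missing_cells: tuple  # (accession, year, trait) cells below the modal count


@dataclass(frozen=True)
class SiteMetadata:
    """Per-accession site covariates (altitude, temperature summaries, ...)."""

    table: pd.DataFrame  # indexed by accession, one numeric column per covariate

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate metadata row for accession {dup!r}")

    @property
    def covariates(self) -> tuple:
        return tuple(self.table.columns)

    @property
    def accessions(self) -> tuple:
        return tuple(self.table.index)


def load_trait_table(path: str | Path, schema: Mapping[str, str] | None = None) -> TraitDataset:
    """Read a long-format trait CSV.

    Parameters
    ----------
    path
        CSV with a header row; comma-separated, UTF-8, ``.`` decimals.
    schema
        Optional mapping from canonical names (``accession``, ``year``,
        ``replicate``, ``trait``, ``value``) to the column names actually
        present in the file.

    Raises
    ------
    SchemaError
        A mapped column is missing, or a value fails to parse (the error
        names the 1-based data row).
    DuplicateKeyError
        Two rows share an (accession, year, replicate, trait) key.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) in {path.name}: {', '.join(missing)}")
    df = df.rename(columns=rename)
    for col, kind in (("year", int), ("replicate", int), ("value", float)):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = int(parsed.index[parsed.isna()][0]) + 1
            raise SchemaError(
                f"column {col!r}: cannot parse value {df[col].iloc[row - 1]!r} "
                f"in data row {row}"
            )
        # convert from the original strings: Python's float() is correctly
        # rounded, so repr-written values round-trip bit for bit
        df[col] = df[col].astype(kind)
    return TraitDataset(df)


def write_trait_table(ds: TraitDataset, path: str | Path) -> None:
    """Write the canonical CSV; round-trips through :func:`load_trait_table`.

    Values are written with ``repr`` round-trip precision so that
    load(write(ds)) equals ds exactly.
    """
    df = ds.records.copy()
    df["value"] = [repr(v) for v in df["value"]]
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def validate_design(ds: TraitDataset) -> DesignSummary:
    """Summarise the design: accession count, years ``nl``, replicates ``nr``.

    ``nr`` is the modal replicate count over (accession, year, trait)
    cells; the design is balanced iff every cell of the full
    accession x year x trait grid has exactly ``nr`` records.
    """
    counts = ds.records.groupby(["accession", "year", "trait"], sort=False).size()
    nr = int(counts.mode().iloc[0])
    full = len(ds.accessions) * len(ds.years) * len(ds.traits)
    missing = [k for k, c in counts.items() if c < nr]
    # cells absent from the grid entirely
    if len(counts) < full:
        have = set(counts.index)
        for a in ds.accessions:
            for y in ds.years:
                for t in ds.traits:
                    if (a, y, t) not in have:
                        missing.append((a, y, t))
    balanced = not missing and counts.nunique() == 1 and len(counts) == full
    return DesignSummary(
        n_accessions=len(ds.accessions),
        nl=len(ds.years),
        nr=nr,
        balanced=bool(balanced),
        missing_cells=tuple(sorted(missing)),
    )


def load_site_metadata(path: str | Path) -> SiteMetadata:
    """Read a site-metadata CSV with header ``accession,<covariate>,...``."""
    df = pd.read_csv(path, encoding="utf-8")
    if "accession" not in df.columns:
        raise SchemaError("missing column(s): accession")
    df["accession"] = df["accession"].astype(str)
    return SiteMetadata(df.set_index("accession").astype(float))
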