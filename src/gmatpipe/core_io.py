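"""Data model, file I/O and trait preprocessing shared by all pipeline stages.

The central container is :class:`PhenotypeTable`, a thin validated wrapper
around a long-format :class:`pandas.DataFrame` with one row per individual:
pedigree columns (``sire_id``, ``dam_id``, ``block_id``), grouping labels
(``species``, ``environment``), one column per continuous trait, and the
binary status flags ``emerged``, ``measured`` and ``survived``.

Traits are mean standardized (divided by a reference mean) before any
quantitative-genetic analysis, so that variances are expressed on the
evolvability scale and are comparable across traits measured in different
units.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ID_COLUMNS = ["individual_id", "sire_id", "dam_id", "block_id"]
GROUP_COLUMNS = ["species", "environment"]
FLAG_COLUMNS = ["emerged", "measured", "survived"]


class SchemaError(ValueError):
    """Raised when a phenotype table violates the expected schema."""


def log(stage: str, message: str) -> None:
    """Write a stage-tagged log line to standard error."""
    print(f"[{stage}] {message}", file=sys.stderr)


@dataclass
class PhenotypeTable:
    """Individual-level phenotype records from a nested half-sib design.

    Parameters
    ----------
    data
        Long-format table, one row per individual.
    traits
        Names of the continuous trait columns, in analysis order.
    """

    data: pd.DataFrame
    traits: list[str]

    def __post_init__(self) -> None:
        self.traits = list(self.traits)
        validate_phenotypes(self.data, self.traits)

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def measured(self) -> pd.DataFrame:
        """Rows with measured traits (trait values guaranteed present)."""
        return self.data[self.data["measured"] == 1]

    def subset(self, species: str | None = None, environment: str | None = None) -> "PhenotypeTable":
        """Restrict to one species and/or environment context."""
        df = self.data
        if species is not None:
            df = df[df["species"] == species]
        if environment is not None:
            df = df[df["environment"] == environment]
        return PhenotypeTable(df.reset_index(drop=True), self.traits)

    def contexts(self) -> list[tuple[str, str]]:
        """All (species, environment) pairs present, in stable order."""
        seen = self.data[["species", "environment"]].drop_duplicates()
        return [tuple(r) for r in seen.itertuples(index=False)]

    def trait_matrix(self, measured_only: bool = True) -> np.ndarray:
        df = self.measured() if measured_only else self.data
        return df[self.traits].to_numpy(dtype=float)


def validate_phenotypes(df: pd.DataFrame, traits: Sequence[str]) -> None:
    """Check schema and design invariants; raise :class:`SchemaError` on failure.

    Enforces: required columns present, unique individual ids, trait values
    present iff ``measured == 1`` (listwise: all traits of a row present or
    all absent), and parents belonging to a single species.  ``block_id``
    is the experimental (planting) block, crossed with families, so parents
    legitimately appear in many blocks.
    """
    required = ID_COLUMNS + GROUP_COLUMNS + list(traits) + FLAG_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype table is missing required columns: {missing}")
    if df["individual_id"].duplicated().any():
        dupes = df.loc[df["individual_id"].duplicated(), "individual_id"].head(3).tolist()
        raise SchemaError(f"duplicate individual_ids (e.g. {dupes})")

    trait_block = df[list(traits)]
    measured = df["measured"].astype(int)
    has_all = trait_block.notna().all(axis=1)
    has_any = trait_block.notna().any(axis=1)
    if (has_any & ~has_all).any():
        raise SchemaError("rows with partially missing trait values (traits are all-or-none per row)")
    if ((measured == 1) & ~has_all).any():
        raise SchemaError("measured rows with missing trait values")
    if ((measured == 0) & has_any).any():
        raise SchemaError("unmeasured rows carry trait values")

    for parent in ("sire_id", "dam_id"):
        per_parent = df.groupby(parent)["species"].nunique()
        bad = per_parent[per_parent > 1]
        if len(bad):
            raise SchemaError(f"{parent}(s) shared across species: {bad.index[:3].tolist()}")


def read_phenotypes(path, traits: Sequence[str] | None = None) -> PhenotypeTable:
    """Read a phenotype CSV and validate it.

    If ``traits`` is not given, every column that is not an id/group/flag
    column is taken to be a trait, in file order.
    """
    df = pd.read_csv(path)
    if traits is None:
        known = set(ID_COLUMNS + GROUP_COLUMNS + FLAG_COLUMNS)
        traits = [c for c in df.columns if c not in known]
    return PhenotypeTable(df, list(traits))


def write_phenotypes(table: PhenotypeTable, path) -> None:
    """Write a phenotype table as CSV with a stable column order."""
    cols = ID_COLUMNS + GROUP_COLUMNS + table.traits + FLAG_COLUMNS
    table.data[cols].to_csv(path, index=False)


@dataclass
class StandardizationReference:
    """Per-trait reference means used for mean standardization.

    ``means`` maps species label -> per-trait mean vector (aligned with the
    table's trait order). ``source`` records how the reference was obtained:
    ``"species_grand_mean"`` (default: per-species mean pooled across all
    environments), ``"context_mean"`` (per species x environment), or
    ``"user"``.
    """

    means: Mapping[str, np.ndarray]
    source: str = "species_grand_mean"
    traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sp, m in self.means.items():
            m = np.asarray(m, dtype=float)
            if np.any(m == 0) or np.any(~np.isfinite(m)):
                raise ValueError(f"reference means for {sp!r} must be finite and nonzero: {m}")
            if np.any(m < 0):
                raise ValueError(
                    f"negative reference mean for {sp!r}; mean standardization of a "
                    "positive trait by a negative mean is unstable"
                )


def grand_mean_reference(table: PhenotypeTable, per_context: bool = False) -> StandardizationReference:
    """Compute reference means from the table itself (measured rows only).

    With ``per_context=False`` (default) the reference is the per-species
    grand mean pooled across environments, which keeps environment-to-
    environment differences in standardized means (the plasticity signal)
    intact.  With ``per_context=True`` each species x environment cell is
    standardized by its own mean, forcing every standardized context mean
    to exactly 1 — useful for variance comparisons only.
    """
    df = table.measured()
    means: dict = {}
    if per_context:
        for (sp, env), sub in df.groupby(["species", "environment"], sort=False):
            means[(sp, env)] = sub[table.traits].mean().to_numpy()
        return StandardizationReference(means, source="context_mean", traits=table.traits)
    for sp, sub in df.groupby("species", sort=False):
        means[sp] = sub[table.traits].mean().to_numpy()
    return StandardizationReference(means, source="species_grand_mean", traits=table.traits)


def mean_standardize(table: PhenotypeTable, ref: StandardizationReference | None = None) -> PhenotypeTable:
    """Divide each trait by its reference mean.

    With the default per-species grand-mean reference, the species-wide mean
    of every standardized trait equals 1 and trait variances become
    mean-standardized variances (evolvabilities).
    """
    if ref is None:
        ref = grand_mean_reference(table)
    df = table.data.copy()
    if ref.source == "context_mean":
        for (sp, env), m in ref.means.items():
            mask = (df["species"] == sp) & (df["environment"] == env)
            df.loc[mask, table.traits] = df.loc[mask, table.traits].to_numpy() / np.asarray(m)
    else:
        for sp, m in ref.means.items():
            mask = df["species"] == sp
            df.loc[mask, table.traits] = df.loc[mask, table.traits].to_numpy() / np.asarray(m)
    return PhenotypeTable(df, table.traits)


def group_means(
    table: PhenotypeTable,
    by: Iterable[str] = ("species", "environment"),
) -> pd.DataFrame:
    """Arithmetic trait means per group over measured individuals.

    Returns a DataFrame indexed by the grouping columns with one column per
    trait.  Raises if any requested group has no measured individuals.
    """
    by = list(by)
    df = table.measured()
    if df.empty:
        raise ValueError("no measured individuals")
    out = df.groupby(by, sort=False)[table.traits].mean()
    present = set(map(tuple, table.data[by].drop_duplicates().itertuples(index=False)))
    have = set(out.index if len(by) > 1 else [(i,) for i in out.index])
    empty = present - have
    if empty:
        raise ValueError(f"group(s) with no measured individuals: {sorted(empty)}")
    return out
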