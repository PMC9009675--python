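"""Data model and I/O for multi-environment trial (MET) phenotypes.

A trial is a set of genotypes evaluated in one or more environments in a
randomized complete block design: each block within an environment contains
every genotype once.  Phenotypes live in a long/wide hybrid table with one
row per plot (genotype x environment x block) and one column per trait.

Traits carry a *direction*: the desired sense of selection ("increase" for
yield-like traits, "decrease" for traits such as sodium accumulation where
lower is better).  The direction drives the rescaling step of the
genotype-ideotype index downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TraitSpec",
    "TrialData",
    "DesignSummary",
    "TrialDataError",
    "load_trial_table",
    "load_trait_specs",
    "summarize_design",
    "trait_summary",
]

#: Columns every trial table must carry besides the trait columns.
KEY_COLUMNS = ("genotype", "environment", "block")

Direction = Literal["increase", "decrease"]


class TrialDataError(ValueError):
    """Raised for schema, parse and invariant violations in trial tables."""


@dataclass(frozen=True)
class TraitSpec:
    """A measured trait and the desired sense of selection.

    Parameters
    ----------
    name
        Column name in the trial table (unique within a trait set).
    direction
        ``"increase"`` if higher values are desirable, ``"decrease"``
        otherwise.
    units
        Free-text units, for reporting only.
    """

    name: str
    direction: Direction = "increase"
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise TrialDataError(
                f"trait {self.name!r}: direction must be 'increase' or "
                f"'decrease', got {self.direction!r}"
            )


def _check_unique_names(specs: Sequence[TraitSpec]) -> None:
    names = [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise TrialDataError(f"duplicate trait names: {sorted(dupes)}")


@dataclass
class TrialData:
    """Phenotype records for a g x e x b trial over p traits.

    ``table`` has the key columns genotype / environment / block plus one
    numeric column per declared trait; missing plots are NaN, never dropped.
    """

    table: pd.DataFrame
    trait_specs: list[TraitSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique_names(self.trait_specs)
        missing = [c for c in KEY_COLUMNS if c not in self.table.columns]
        if missing:
            raise TrialDataError(f"missing required column(s): {missing}")
        for spec in self.trait_specs:
            if spec.name not in self.table.columns:
                raise TrialDataError(f"trait column {spec.name!r} not in table")
        if len(self.table):
            dup = self.table.duplicated(subset=list(KEY_COLUMNS))
            if dup.any():
                rows = self.table.loc[dup, list(KEY_COLUMNS)].iloc[0].tolist()
                raise TrialDataError(
                    f"duplicate plot record for (genotype, environment, block)={tuple(rows)}"
                )
            for spec in self.trait_specs:
                col = self.table[spec.name]
                if not np.isfinite(col.to_numpy(dtype=float, na_value=np.nan)).all():
                    bad = col[~np.isfinite(col.astype(float))]
                    if not bad.isna().all():
                        raise TrialDataError(
                            f"non-finite value in trait {spec.name!r}"
                        )

    @property
    def trait_names(self) -> list[str]:
        return [s.name for s in self.trait_specs]

    @property
    def genotypes(self) -> list:
        return sorted(self.table["genotype"].unique().tolist())

    @property
    def environments(self) -> list:
        return sorted(self.table["environment"].unique().tolist())

    def spec(self, trait: str) -> TraitSpec:
        for s in self.trait_specs:
            if s.name == trait:
                return s
        raise TrialDataError(f"unknown trait {trait!r}")

    def values(self, trait: str) -> pd.Series:
        self.spec(trait)
        return self.table[trait].astype(float)

    def write_csv(self, path: str | Path, *, sep: str = ",") -> None:
        """Write the trial table in the same dialect ``load_trial_table`` reads."""
        decimal = "," if sep == ";" else "."
        self.table.to_csv(path, index=False, sep=sep, decimal=decimal)


@dataclass(frozen=True)
class DesignSummary:
    """Counts of design levels; ``balanced`` means every (genotype,
    environment) cell holds exactly ``b`` plots."""

    g: int
    e: int
    b: int
    n: int
    balanced: bool


def load_trait_specs(path: str | Path) -> list[TraitSpec]:
    """Read trait specs from YAML (list of mappings) or CSV (name, direction[, units])."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        specs = [
            TraitSpec(
                name=str(item["name"]),
                direction=item.get("direction", "increase"),
                units=str(item.get("units", "")),
            )
            for item in raw
        ]
    else:
        df = pd.read_csv(path)
        if "name" not in df.columns:
            raise TrialDataError(f"trait-spec file {path} lacks a 'name' column")
        specs = [
            TraitSpec(
                name=str(row["name"]),
                direction=str(row.get("direction", "increase")),
                units=str(row["units"]) if "units" in df.columns and pd.notna(row.get("units")) else "",
            )
            for _, row in df.iterrows()
        ]
    _check_unique_names(specs)
    return specs


def load_trial_table(
    path: str | Path,
    trait_specs: Sequence[TraitSpec],
    *,
    sep: str = ",",
) -> TrialData:
    """Load a long-format trial CSV.

    The header must contain ``genotype``, ``environment``, ``block`` and one
    column per declared trait.  Empty cells are kept as missing (NaN).  Use
    ``sep=";"`` for semicolon-separated files with ',' decimals.

    Raises
    ------
    TrialDataError
        If a required column is absent, a trait cell is non-numeric, or a
        (genotype, environment, block) plot appears twice.
    """
    decimal = "," if sep == ";" else "."
    df = pd.read_csv(path, sep=sep, decimal=decimal)
    missing = [c for c in (*KEY_COLUMNS, *(s.name for s in trait_specs)) if c not in df.columns]
    if missing:
        raise TrialDataError(f"{path}: missing required column(s): {missing}")
    for spec in trait_specs:
        coerced = pd.to_numeric(df[spec.name], errors="coerce")
        bad = coerced.isna() & df[spec.name].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TrialDataError(
                f"{path}: non-numeric value {df[spec.name].iloc[row]!r} for trait "
                f"{spec.name!r} at data row {row}"
            )
        df[spec.name] = coerced
    return TrialData(table=df, trait_specs=list(trait_specs))


def summarize_design(data: TrialData) -> DesignSummary:
    """Count genotypes, environments and blocks; flag unbalanced designs.

    ``n`` is the number of plots (rows); for a balanced trial it equals
    g * e * b.  Balance requires every (genotype, environment) cell to hold
    exactly ``b`` plots, where ``b`` is the modal block count.
    """
    if not len(data.table):
        raise TrialDataError("cannot summarize an empty trial")
    tab = data.table
    g = tab["genotype"].nunique()
    e = tab["environment"].nunique()
    b = int(tab.groupby(["environment"])["block"].nunique().max())
    n = len(tab)
    cell_counts = tab.groupby(["genotype", "environment"]).size()
    balanced = bool(
        len(cell_counts) == g * e and (cell_counts == b).all() and n == g * e * b
    )
    return DesignSummary(g=g, e=e, b=b, n=n, balanced=balanced)


def trait_summary(
    data: TrialData,
    trait: str,
    by: Literal["environment", "genotype-environment"] = "environment",
) -> pd.DataFrame:
    """Five-number-plus-mean summary of one trait per group.

    Quantiles use linear interpolation between order statistics (the
    convention of numpy's default / R's type 7), so box-plot style summaries
    are reproducible elsewhere.
    """
    data.spec(trait)
    keys = ["environment"] if by == "environment" else ["genotype", "environment"]
    if by not in ("environment", "genotype-environment"):
        raise TrialDataError(f"unknown grouping {by!r}")
    grp = data.table.groupby(keys)[trait]
    out = grp.agg(
        min="min",
        q1=lambda s: s.quantile(0.25),
        median="median",
        q3=lambda s: s.quantile(0.75),
        max="max",
        mean="mean",
    ).reset_index()
    return out
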