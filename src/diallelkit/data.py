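"""Data model and I/O for full-diallel phenotype tables.

A full diallel on ``p`` parents evaluates all ``p**2`` matings — the ``p``
selfed parents on the diagonal, the p(p-1)/2 straight crosses and their
reciprocals — in ``r`` complete blocks.  The long input format is one CSV row
per plot: ``female,male,rep,<trait1>,...``, parent labels opaque strings, rep
a 1-based integer.  Every (female, male, rep) triple must be present exactly
once; missing data are a hard error because all downstream closed-form
estimators assume a balanced, complete table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("female", "male", "rep")


class DiallelError(ValueError):
    """Base class for diallel data validation errors."""


class CompletenessError(DiallelError):
    """Raised when (female, male, rep) combinations are missing."""

    def __init__(self, missing: Sequence[tuple]) -> None:
        self.missing = list(missing)
        shown = ", ".join(map(str, self.missing[:10]))
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"incomplete diallel; missing (female, male, rep): {shown}{more}")


class DuplicateError(DiallelError):
    """Raised when a (female, male, rep) triple occurs more than once."""


@dataclass(frozen=True)
class DiallelDesign:
    """The mating design: ordered parents, replication count, trait names."""

    parents: tuple[str, ...]
    n_reps: int
    traits: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(str(x) for x in self.parents))
        object.__setattr__(self, "traits", tuple(str(x) for x in self.traits))
        if self.n_parents < 3:
            raise DiallelError(f"need at least 3 parents, got {self.n_parents}")
        if self.n_reps < 1:
            raise DiallelError(f"need at least 1 replication, got {self.n_reps}")
        if len(set(self.parents)) != self.n_parents:
            raise DiallelError("parent labels must be unique")
        if len(set(self.traits)) != len(self.traits):
            raise DiallelError("trait names must be unique")
        if not self.traits:
            raise DiallelError("at least one trait is required")

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def n_entries(self) -> int:
        """Number of diallel entries: p**2 (selfs + straight + reciprocal)."""
        return self.n_parents**2


@dataclass
class PlotData:
    """Validated replicated plot-level phenotypes for a complete full diallel."""

    design: DiallelDesign
    df: pd.DataFrame = field(repr=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, design: DiallelDesign | None = None) -> "PlotData":
        df = df.copy()
        for col in RESERVED_COLUMNS:
            if col not in df.columns:
                raise DiallelError(f"required column {col!r} not found")
        df["female"] = df["female"].astype(str)
        df["male"] = df["male"].astype(str)
        try:
            df["rep"] = df["rep"].astype(int)
        except (TypeError, ValueError) as exc:
            raise DiallelError(f"rep column is not integer: {exc}") from None

        if design is None:
            parents = sorted(set(df["female"]) | set(df["male"]))
            reps = sorted(df["rep"].unique())
            traits = tuple(c for c in df.columns if c not in RESERVED_COLUMNS)
            design = DiallelDesign(tuple(parents), len(reps), traits)

        bad = set(df["female"]) | set(df["male"]) - set(design.parents)
        bad -= set(design.parents)
        if bad:
            raise DiallelError(f"records with parents outside the declared set: {sorted(bad)}")
        missing_traits = [t for t in design.traits if t not in df.columns]
        if missing_traits:
            raise DiallelError(f"trait columns missing from table: {missing_traits}")

        for trait in design.traits:
            vals = pd.to_numeric(df[trait], errors="coerce")
            nan_rows = df.index[vals.isna()].tolist()
            if nan_rows:
                raise DiallelError(
                    f"non-numeric or missing value for trait {trait!r} at rows {nan_rows[:10]}"
                )
            df[trait] = vals.astype(float)

        keys = list(zip(df["female"], df["male"], df["rep"]))
        if len(keys) != len(set(keys)):
            seen: set[tuple] = set()
            dups = []
            for k in keys:
                if k in seen:
                    dups.append(k)
                seen.add(k)
            raise DuplicateError(f"duplicated (female, male, rep) triples: {sorted(set(dups))[:10]}")
        expected = {
            (f, m, k)
            for f in design.parents
            for m in design.parents
            for k in range(1, design.n_reps + 1)
        }
        missing = expected - set(keys)
        if missing:
            raise CompletenessError(sorted(missing))
        extra = set(keys) - expected
        if extra:
            raise DiallelError(f"unexpected (female, male, rep) triples: {sorted(extra)[:10]}")

        order = {p: i for i, p in enumerate(design.parents)}
        df = df.sort_values(
            by=["rep", "female", "male"],
            key=lambda s: s.map(order) if s.name in ("female", "male") else s,
            kind="mergesort",
        ).reset_index(drop=True)
        return cls(design=design, df=df)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def to_array(self, trait: str) -> np.ndarray:
        """Plot values as an (r, p, p) array indexed [rep, female, male]."""
        if trait not in self.design.traits:
            raise KeyError(f"unknown trait {trait!r}; have {list(self.design.traits)}")
        p, r = self.design.n_parents, self.design.n_reps
        idx = {lab: i for i, lab in enumerate(self.design.parents)}
        out = np.empty((r, p, p))
        fi = self.df["female"].map(idx).to_numpy()
        mi = self.df["male"].map(idx).to_numpy()
        ki = self.df["rep"].to_numpy() - 1
        out[ki, fi, mi] = self.df[trait].to_numpy()
        return out


@dataclass
class CrossMeanTable:
    """Entry means x[i, j] for one trait: female i crossed to male j.

    The diagonal holds selfed-parent means.  Marginals follow the classical
    diallel notation: x_i. is the sum of row i (parent i as female over all
    males, self included), x_.i the sum of column i, x_.. the grand sum.
    """

    trait: str
    parents: tuple[str, ...]
    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        p = len(self.parents)
        if self.x.shape != (p, p):
            raise DiallelError(f"mean table must be {p}x{p}, got {self.x.shape}")

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def row_totals(self) -> np.ndarray:
        """x_i. — sum of the i-th female row over all males."""
        return self.x.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """x_.i — sum of the i-th male column over all females."""
        return self.x.sum(axis=0)

    @property
    def grand_total(self) -> float:
        """x_.. — sum over all p**2 entries."""
        return float(self.x.sum())


def entry_means(data: PlotData, trait: str) -> CrossMeanTable:
    """Average the r replicate plots of each (female, male) entry."""
    arr = data.to_array(trait)
    return CrossMeanTable(trait=trait, parents=data.design.parents, x=arr.mean(axis=0))


def load_plot_data(path: str | Path, design: DiallelDesign | None = None) -> PlotData:
    """Read and validate a long-format diallel CSV (UTF-8, header row)."""
    df = pd.read_csv(path, dtype={"female": str, "male": str})
    return PlotData.from_dataframe(df, design=design)


def write_plot_data(data: PlotData, path: str | Path) -> None:
    """Write a PlotData back to the long CSV dialect accepted by load_plot_data."""
    data.df.to_csv(path, index=False, float_format="%.17g")


def records(data: PlotData) -> list[dict]:
    """Plot records as dicts: female, male, rep and a trait->value map."""
    out = []
    for _, row in data.df.iterrows():
        out.append(
            {
                "female": row["female"],
                "male": row["male"],
                "rep": int(row["rep"]),
                "values": {t: float(row[t]) for t in data.design.traits},
            }
        )
    return out
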