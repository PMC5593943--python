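"""Count aggregation: per-accession tables, the 7-category matrix, proportions.

The unit of the whole analysis is the number of clean reads mapped to each
reference accession per library, where a library is one (condition, assay)
pair: {precocious, normal} x {MeDIP, hMeDIP}.  Counts are real-valued, not
integer: published per-category tables of this kind can carry fractional
values from an upstream normalization, and the chi-squared machinery is
well-defined on positive reals, so fractional counts are accepted verbatim
rather than rounded.

Library totals (total clean reads per library, mapped or not) are recorded
when available so that mapped proportions can be reported, but no headline
statistic depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .catalog import CATEGORY_ORDER, Catalog, CatalogError, Category

CONDITIONS = ("precocious", "normal")
ASSAYS = ("MeDIP", "hMeDIP")

#: All four libraries in canonical column order.
LIBRARIES = tuple((c, a) for a in ASSAYS for c in CONDITIONS)

CellKey = tuple[str, str, str]  # (accession, condition, assay)
LibraryKey = tuple[str, str]  # (condition, assay)


def _check_library(condition: str, assay: str) -> LibraryKey:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected {ASSAYS}")
    return (condition, assay)


@dataclass
class CountTable:
    """Real-valued mapped-read counts keyed by (accession, condition, assay)."""

    cells: dict[CellKey, float] = field(default_factory=dict)
    library_totals: dict[LibraryKey, float] | None = None

    def add(self, accession: str, condition: str, assay: str, weight: float = 1.0) -> None:
        if weight < 0:
            raise ValueError("counts must be nonnegative")
        _check_library(condition, assay)
        key = (accession, condition, assay)
        self.cells[key] = self.cells.get(key, 0.0) + weight

    def get(self, accession: str, condition: str, assay: str) -> float:
        return self.cells.get((accession, condition, assay), 0.0)

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(sorted({k[0] for k in self.cells}))

    @property
    def libraries(self) -> tuple[LibraryKey, ...]:
        present = {(k[1], k[2]) for k in self.cells}
        if self.library_totals:
            present |= set(self.library_totals)
        return tuple(lib for lib in LIBRARIES if lib in present)

    def mapped_total(self, condition: str, assay: str) -> float:
        return sum(v for (a, c, s), v in self.cells.items() if (c, s) == (condition, assay))

    def validate(self) -> None:
        for key, v in self.cells.items():
            if v < 0:
                raise ValueError(f"negative count at {key}")
        if self.library_totals:
            for lib, total in self.library_totals.items():
                mapped = self.mapped_total(*lib)
                if mapped > total + 1e-9:
                    raise ValueError(
                        f"mapped reads ({mapped}) exceed library total ({total}) for {lib}"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"accession": a, "condition": c, "assay": s, "count": v}
            for (a, c, s), v in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["accession", "condition", "assay", "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"accession": str})
        table = cls()
        for row in df.itertuples(index=False):
            table.add(row.accession, row.condition, row.assay, float(row.count))
        return table


class CategoryCountMatrix:
    """The 7-category x (condition, assay) aggregate count matrix.

    ``values`` is a DataFrame indexed by the seven category names in
    canonical order, with a (condition, assay) MultiIndex on the columns.
    ``provenance`` records whether the numbers are raw aggregates, a
    hand-entered fixture, or normalized values from elsewhere.
    """

    def __init__(self, values: pd.DataFrame, provenance: str = "raw"):
        index = [c.value for c in CATEGORY_ORDER]
        if set(values.index) - set(index):
            raise ValueError(f"unknown categories: {set(values.index) - set(index)}")
        vals = values.reindex(index).fillna(0.0).astype(float)
        if (vals.to_numpy() < 0).any():
            raise ValueError("category counts must be nonnegative")
        if not isinstance(vals.columns, pd.MultiIndex):
            raise ValueError("columns must be a (condition, assay) MultiIndex")
        for cond, assay in vals.columns:
            _check_library(cond, assay)
        # canonical column order and bare index, so equal content compares equal
        order = [lib for lib in LIBRARIES if lib in vals.columns]
        vals = vals[order]
        vals.index.name = None
        vals.columns = pd.MultiIndex.from_tuples(order, names=["condition", "assay"])
        self.values = vals
        self.provenance = provenance

    @classmethod
    def from_dict(
        cls,
        data: Mapping[LibraryKey, Mapping[str, float]],
        provenance: str = "raw",
    ) -> "CategoryCountMatrix":
        cols = {}
        for lib, col in data.items():
            cols[lib] = pd.Series({str(Category(k)): float(v) for k, v in col.items()})
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["condition", "assay"])
        return cls(df, provenance=provenance)

    def get(self, category: Category | str, condition: str, assay: str) -> float:
        return float(self.values.loc[str(Category(category)), (condition, assay)])

    def column(self, condition: str, assay: str) -> pd.Series:
        return self.values[(condition, assay)]

    def has_library(self, condition: str, assay: str) -> bool:
        return (condition, assay) in self.values.columns

    @property
    def libraries(self) -> tuple[LibraryKey, ...]:
        return tuple(lib for lib in LIBRARIES if lib in self.values.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CategoryCountMatrix):
            return NotImplemented
        return self.provenance == other.provenance and self.values.equals(other.values)

    def to_tsv(self, path: str | Path) -> None:
        long = (
            self.values.stack(["condition", "assay"], future_stack=True)
            .rename("count")
            .reset_index()
            .rename(columns={"level_0": "category"})
        )
        long.columns = ["category", "condition", "assay", "count"]
        long["provenance"] = self.provenance
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CategoryCountMatrix":
        df = pd.read_csv(path, sep="\t")
        provenance = df["provenance"].iloc[0] if "provenance" in df else "raw"
        wide = df.pivot_table(
            index="category", columns=["condition", "assay"], values="count", aggfunc="sum"
        )
        return cls(wide, provenance=str(provenance))


def aggregate_by_category(table: CountTable, catalog: Catalog) -> CategoryCountMatrix:
    """Sum per-accession counts into the seven category rows.

    Conservation holds exactly: per library, the category sums equal the
    sum over member accessions.  Every accession in the table must exist
    in the catalog.
    """
    missing = [a for a in table.accessions if a not in catalog]
    if missing:
        raise CatalogError(f"accessions not in catalog: {', '.join(missing)}")
    libs = table.libraries or LIBRARIES
    index = [c.value for c in CATEGORY_ORDER]
    values = pd.DataFrame(0.0, index=index, columns=pd.MultiIndex.from_tuples(libs))
    for (acc, cond, assay), v in table.cells.items():
        values.loc[catalog.category_of(acc).value, (cond, assay)] += v
    values.columns.names = ["condition", "assay"]
    return CategoryCountMatrix(values, provenance="raw")


def library_proportion(mapped: float, library_total: float) -> float:
    """Fraction of a library's clean reads that mapped to the reference set."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    if mapped < 0 or mapped > library_total:
        raise ValueError("mapped count must lie in [0, library_total]")
    return mapped / library_total


def format_percent(fraction: float, decimals: int = 2) -> str:
    """Render a fraction as a percentage string, e.g. ``0.0027 -> '0.27%'``."""
    return f"{fraction * 100:.{decimals}f}%"


def modification_ratio(a: float, b: float) -> float:
    """Plain ratio a/b, used for hMe:Me and precocious:normal comparisons."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return a / b
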