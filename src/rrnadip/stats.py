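"""Reliability filters, fold changes and the hierarchy of Pearson chi-squared tests.

The differential analysis is a hierarchy of contingency-table tests on
mapped-read counts:

* a full-design test (7 categories x 4 libraries, df 18),
* a modification test (categories x {MeDIP, hMeDIP} pooled over
  conditions, df 6),
* a per-assay condition test (categories x {precocious, normal}, df 6),
* per-category 2x2 tests of one category against the pooled other six,
* pairwise 2x2 tests between categories,
* and per-accession 2x2 tests of one accession against the rest of its
  category.

All tests are Pearson chi-squared with expected counts from the margins
and NO continuity correction; significance is flagged both against the
conventional critical values at alpha = 0.05 / 0.01 and by the computed
upper-tail p-value.  Counts may be real-valued (fractional); the formula
is applied to them as-is.

Two reliability filters accompany every two-group comparison: results
are marked low-count when the two groups together carry fewer than 50
mapped reads, and grey-zone when the fold change lies strictly between
0.5 and 2.  Grey-zone results are flagged, never removed.  No
multiple-testing correction is applied; reports state the number of
tests performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
import numpy as np
from scipy import stats as sps

from .catalog import CATEGORY_ORDER, Catalog, Category
from .counts import ASSAYS, CONDITIONS, CategoryCountMatrix, CountTable


class DegenerateTableError(ValueError):
    """A contingency table has a zero row or column margin."""


@dataclass(frozen=True)
class ContingencyTable:
    """An observed r x c grid of nonnegative real counts with labels."""

    observed: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        if obs.ndim != 2:
            raise ValueError("observed must be a 2-D grid")
        if obs.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match the observed grid")
        if (obs < 0).any():
            raise ValueError("observed counts must be nonnegative")
        object.__setattr__(self, "observed", obs)

    @property
    def N(self) -> float:
        return float(self.observed.sum())

    @property
    def expected(self) -> np.ndarray:
        """Expected counts under independence: row_total x col_total / N."""
        obs = self.observed
        return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()


@dataclass(frozen=True)
class ChiSquareResult:
    """A chi-squared statistic with its df, p-value and significance flag."""

    statistic: float
    df: int
    p_value: float
    flag: str  # "ns", "*" or "**"
    critical_05: float
    critical_01: float
    observed: np.ndarray = field(repr=False)
    expected: np.ndarray = field(repr=False)
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.flag in ("*", "**")


def _flag(statistic: float, crit05: float, crit01: float) -> str:
    if statistic > crit01:
        return "**"
    if statistic > crit05:
        return "*"
    return "ns"


def pearson_chi2(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-squared test of independence, without continuity correction.

    Raises
    ------
    DegenerateTableError
        If the grand total is zero or any row/column margin is zero (an
        expected count would be zero).
    """
    obs = table.observed
    if obs.sum() <= 0:
        raise DegenerateTableError("empty contingency table")
    if (obs.sum(axis=1) <= 0).any() or (obs.sum(axis=0) <= 0).any():
        raise DegenerateTableError(
            "zero row or column margin; the test is undefined"
        )
    statistic, p_value, df, expected = sps.chi2_contingency(obs, correction=False)
    crit05 = float(sps.chi2.isf(0.05, df))
    crit01 = float(sps.chi2.isf(0.01, df))
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p_value),
        flag=_flag(float(statistic), crit05, crit01),
        critical_05=crit05,
        critical_01=crit01,
        observed=obs,
        expected=expected,
        row_labels=table.row_labels,
        col_labels=table.col_labels,
    )


def _matrix_2x2(
    top: tuple[float, float], bottom: tuple[float, float], rows: tuple[str, str]
) -> ContingencyTable:
    return ContingencyTable(
        np.array([top, bottom], dtype=float),
        row_labels=rows,
        col_labels=CONDITIONS,
    )


def category_vs_rest_test(
    matrix: CategoryCountMatrix, category: Category | str, assay: str = "hMeDIP"
) -> ChiSquareResult:
    """2x2 test of one category against the pooled other six, across conditions."""
    cat = Category(category)
    _require_conditions(matrix, assay)
    counts = tuple(matrix.get(cat, cond, assay) for cond in CONDITIONS)
    totals = tuple(float(matrix.column(cond, assay).sum()) for cond in CONDITIONS)
    rest = tuple(t - c for t, c in zip(totals, counts))
    return pearson_chi2(
        _matrix_2x2(counts, rest, rows=(cat.value, "rest"))
    )


def pairwise_category_test(
    matrix: CategoryCountMatrix,
    category_a: Category | str,
    category_b: Category | str,
    assay: str = "hMeDIP",
) -> ChiSquareResult:
    """2x2 test between two categories across conditions (symmetric in A, B)."""
    a, b = Category(category_a), Category(category_b)
    if a == b:
        raise ValueError("pairwise test requires two distinct categories")
    _require_conditions(matrix, assay)
    row_a = tuple(matrix.get(a, cond, assay) for cond in CONDITIONS)
    row_b = tuple(matrix.get(b, cond, assay) for cond in CONDITIONS)
    return pearson_chi2(_matrix_2x2(row_a, row_b, rows=(a.value, b.value)))


def overall_condition_test(
    matrix: CategoryCountMatrix, assay: str = "hMeDIP"
) -> ChiSquareResult:
    """7x2 test of category composition between conditions, for one assay; df 6."""
    _require_conditions(matrix, assay)
    obs = np.column_stack(
        [matrix.column(cond, assay).to_numpy() for cond in CONDITIONS]
    )
    table = ContingencyTable(
        obs,
        row_labels=tuple(c.value for c in CATEGORY_ORDER),
        col_labels=CONDITIONS,
    )
    return pearson_chi2(table)


def modification_test(matrix: CategoryCountMatrix) -> ChiSquareResult:
    """7x2 test of MeDIP vs hMeDIP composition, counts pooled over conditions; df 6."""
    for assay in ASSAYS:
        if not any(matrix.has_library(cond, assay) for cond in CONDITIONS):
            raise ValueError(f"assay {assay!r} not present in the matrix")
    obs = np.column_stack(
        [
            sum(
                matrix.column(cond, assay).to_numpy()
                for cond in CONDITIONS
                if matrix.has_library(cond, assay)
            )
            for assay in ASSAYS
        ]
    )
    table = ContingencyTable(
        obs,
        row_labels=tuple(c.value for c in CATEGORY_ORDER),
        col_labels=ASSAYS,
    )
    return pearson_chi2(table)


def full_design_test(matrix: CategoryCountMatrix) -> ChiSquareResult:
    """7x4 test over all four (condition, assay) libraries; df 18."""
    libs = [(c, a) for a in ASSAYS for c in CONDITIONS]
    missing = [lib for lib in libs if not matrix.has_library(*lib)]
    if missing:
        raise ValueError(f"libraries missing from the matrix: {missing}")
    obs = np.column_stack([matrix.column(*lib).to_numpy() for lib in libs])
    table = ContingencyTable(
        obs,
        row_labels=tuple(c.value for c in CATEGORY_ORDER),
        col_labels=tuple(f"{c}-{a}" for c, a in libs),
    )
    return pearson_chi2(table)


def _require_conditions(matrix: CategoryCountMatrix, assay: str) -> None:
    missing = [c for c in CONDITIONS if not matrix.has_library(c, assay)]
    if missing:
        raise ValueError(
            f"assay {assay!r} lacks conditions {missing}; cannot compare"
        )


@dataclass(frozen=True)
class FoldChange:
    """Ratio of normal-condition to precocious-condition counts."""

    numerator_label: str
    denominator_label: str
    value: float

    @property
    def rounded(self) -> float:
        """2-decimal rendering, rounding halves away from zero."""
        return float(
            Decimal(repr(self.value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
        )


def fold_change(normal_count: float, precocious_count: float) -> FoldChange:
    """Fold change of the normal condition over the precocious one."""
    if precocious_count <= 0:
        raise ValueError("precocious count must be positive for a fold change")
    return FoldChange("normal", "precocious", normal_count / precocious_count)


@dataclass(frozen=True)
class FilterDecision:
    """Reliability filter outcome for a two-group comparison."""

    status: str  # "pass", "low_count" or "grey_zone"
    total_reads: float
    fold_change: float


def apply_filters(
    precocious_count: float,
    normal_count: float,
    min_total: float = 50.0,
    grey_zone: tuple[float, float] = (0.5, 2.0),
) -> FilterDecision:
    """Apply the minimum-count and fold-change reliability filters.

    Low-count: the two groups together carry fewer than ``min_total``
    mapped reads.  Grey-zone: the fold change lies strictly inside
    ``grey_zone``.  Grey-zone results are flagged in reports, not removed.
    """
    if precocious_count < 0 or normal_count < 0:
        raise ValueError("counts must be nonnegative")
    total = precocious_count + normal_count
    fc = normal_count / precocious_count if precocious_count > 0 else float("inf")
    if total < min_total:
        status = "low_count"
    elif grey_zone[0] < fc < grey_zone[1]:
        status = "grey_zone"
    else:
        status = "pass"
    return FilterDecision(status=status, total_reads=total, fold_change=fc)


@dataclass(frozen=True)
class AccessionTestResult:
    accession: str
    precocious_count: float
    normal_count: float
    chi2: ChiSquareResult | None  # None when the 2x2 table is degenerate
    filter: FilterDecision
    note: str = ""


@dataclass(frozen=True)
class PerAccessionReport:
    category: Category
    assay: str
    entries: tuple[AccessionTestResult, ...]

    @property
    def n_tested(self) -> int:
        return sum(1 for e in self.entries if e.chi2 is not None)

    @property
    def n_significant(self) -> int:
        """Significant results among pass/grey-zone accessions (low-count excluded)."""
        return sum(
            1
            for e in self.entries
            if e.chi2 is not None
            and e.chi2.significant
            and e.filter.status in ("pass", "grey_zone")
        )

    @property
    def significant_accessions(self) -> tuple[str, ...]:
        return tuple(
            e.accession
            for e in self.entries
            if e.chi2 is not None
            and e.chi2.significant
            and e.filter.status in ("pass", "grey_zone")
        )


def per_accession_tests(
    table: CountTable,
    catalog: Catalog,
    category: Category | str = Category.MERGED,
    assay: str = "hMeDIP",
    min_total: float = 50.0,
    grey_zone: tuple[float, float] = (0.5, 2.0),
) -> PerAccessionReport:
    """Accession-vs-rest-of-category 2x2 tests for every member of a category.

    Each member accession is tested against the pooled counts of the other
    members of the same category, across conditions.  Degenerate tables
    (zero margins, e.g. a single-accession category) are reported as
    untestable rather than raised.
    """
    cat = Category(category)
    members = catalog.members(cat)
    if not members:
        warnings.warn(f"category {cat.value} has no members in the catalog")
        return PerAccessionReport(cat, assay, ())
    totals = {
        cond: sum(table.get(acc, cond, assay) for acc in members) for cond in CONDITIONS
    }
    entries: list[AccessionTestResult] = []
    for acc in members:
        counts = tuple(table.get(acc, cond, assay) for cond in CONDITIONS)
        rest = tuple(totals[cond] - c for cond, c in zip(CONDITIONS, counts))
        decision = apply_filters(counts[0], counts[1], min_total, grey_zone)
        try:
            result = pearson_chi2(_matrix_2x2(counts, rest, rows=(acc, "rest")))
            note = ""
        except DegenerateTableError as exc:
            result, note = None, f"untestable: {exc}"
        entries.append(
            AccessionTestResult(acc, counts[0], counts[1], result, decision, note)
        )
    return PerAccessionReport(cat, assay, tuple(entries))
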