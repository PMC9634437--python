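"""Chi-squared enrichment of categories against expected frequencies.

Expected cell counts follow the classical independence formula
(row total x column total / grand total); the test statistic is
sum((observed - expected)^2 / expected) with (rows-1)(cols-1) degrees of
freedom.  No Yates continuity correction is applied, including for 2x2
tables.  Cells with expected counts below 5 are flagged with a warning
annotation but do not block the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "ChiSquaredResult",
    "EnrichmentResult",
    "expected_counts",
    "chi_squared_test",
    "biotype_enrichment",
]


@dataclass
class ContingencyTable:
    """Observed counts for categories (rows) x samples/datasets (columns)."""

    row_labels: list[str]
    col_labels: list[str]
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("observed shape does not match labels")
        if np.any(self.observed < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_category_sets(
        cls, sets_by_column: Mapping[str, Iterable[str]]
    ) -> "ContingencyTable":
        """Build a table from per-column iterables of category labels."""
        col_labels = list(sets_by_column)
        row_labels = sorted(
            {cat for cats in sets_by_column.values() for cat in cats}
        )
        obs = np.zeros((len(row_labels), len(col_labels)))
        ridx = {r: i for i, r in enumerate(row_labels)}
        for j, col in enumerate(col_labels):
            for cat in sets_by_column[col]:
                obs[ridx[cat], j] += 1
        return cls(row_labels, col_labels, obs)


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    dof: int
    p: float
    low_expected_cells: int = 0  # cells with expected < 5 (validity caveat)


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable
    expected: np.ndarray
    residuals: np.ndarray  # (obs - exp) / sqrt(exp) per cell
    test: ChiSquaredResult

    def residual(self, row_label: str, col_label: str) -> float:
        i = self.table.row_labels.index(row_label)
        j = self.table.col_labels.index(col_label)
        return float(self.residuals[i, j])

    def enriched(self, row_label: str, col_label: str) -> bool:
        """Positive residual = category observed above expectation."""
        return self.residual(row_label, col_label) > 0


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts under independence.

    expected[i, j] = (sum of category i across all columns)
                   x (sum of column j across all categories)
                   / (grand total).
    """
    obs = table.observed
    if obs.size == 0:
        raise ValueError("empty table")
    grand = obs.sum()
    if grand <= 0:
        raise ValueError("grand total must be > 0")
    row_tot = obs.sum(axis=1, keepdims=True)
    col_tot = obs.sum(axis=0, keepdims=True)
    return row_tot * col_tot / grand


def chi_squared_test(table: ContingencyTable) -> ChiSquaredResult:
    """Pearson chi-squared test of the observed table against independence."""
    obs = table.observed
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns (dof >= 1)")
    exp = expected_counts(table)
    if np.any(exp == 0):
        raise ValueError("expected cell count of 0; drop empty margins first")
    statistic = float(((obs - exp) ** 2 / exp).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, dof))
    return ChiSquaredResult(
        statistic=statistic,
        dof=dof,
        p=p,
        low_expected_cells=int((exp < 5).sum()),
    )


def biotype_enrichment(
    gene_sets_by_category: Mapping[str, Iterable[str]] | ContingencyTable,
) -> EnrichmentResult:
    """Test whether gene biotypes are enriched/depleted across datasets.

    ``gene_sets_by_category`` maps a dataset label (e.g. "transcriptome_up",
    "translatome_up") to the biotype labels of its member genes, or is a
    pre-built :class:`ContingencyTable`.  Returns the table, expected counts,
    per-cell standardized residuals (obs - exp) / sqrt(exp), and the omnibus
    chi-squared test.  The residual sign is the per-cell enrichment flag.
    """
    if isinstance(gene_sets_by_category, ContingencyTable):
        table = gene_sets_by_category
    else:
        table = ContingencyTable.from_category_sets(gene_sets_by_category)
    test = chi_squared_test(table)
    exp = expected_counts(table)
    residuals = (table.observed - exp) / np.sqrt(exp)
    return EnrichmentResult(table=table, expected=exp, residuals=residuals, test=test)
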