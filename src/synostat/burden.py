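"""Cohort-level burden statistics: prevalence tables by suture class,
loss-of-function enrichment against a reference population, and subtype
contrasts, all resting on Fisher's exact test for 2x2 tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DataError, DomainError

__all__ = [
    "SutureClass",
    "ProbandRecord",
    "ContingencyTable2x2",
    "EnrichmentResult",
    "classify_presentation",
    "prevalence_table",
    "fisher_exact",
    "lof_enrichment",
    "subtype_contrast",
    "rank_correlation",
]


class SutureClass(str, Enum):
    METOPIC = "metopic"
    SAGITTAL = "sagittal"
    UNICORONAL = "unicoronal"
    BICORONAL = "bicoronal"
    LAMBDOID = "lambdoid"
    MULTISUTURE = "multisuture"
    UNSPECIFIED = "unspecified"

    @classmethod
    def parse(cls, value: str) -> "SutureClass":
        try:
            return cls(value.strip().lower())
        except ValueError:
            accepted = ", ".join(m.value for m in cls)
            raise DataError(
                f"unknown suture class {value!r}; accepted values: {accepted}"
            ) from None


@dataclass(frozen=True)
class ProbandRecord:
    """One proband's suture class, syndromic status and gene findings."""

    proband_id: str
    suture: SutureClass
    syndromic: bool
    gene_positive: bool = False
    lof_positive: bool = False
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lof_positive and not self.gene_positive:
            raise DataError(
                f"proband {self.proband_id}: lof_positive implies gene_positive"
            )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Integer 2x2 counts; rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise DataError(
                    f"cell {name} must be a non-negative integer, got {value!r}"
                )

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def __add__(self, other: "ContingencyTable2x2") -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.a + other.a, self.b + other.b, self.c + other.c, self.d + other.d
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Rate-ratio enrichment with its exact-test P value and source table."""

    fold: float
    p_value: float
    table: ContingencyTable2x2
    note: Optional[str] = None


def classify_presentation(
    dysmorphic_or_anomalies: bool = False,
    significant_developmental_delay: bool = False,
    affected_first_degree_relative: bool = False,
) -> bool:
    """Syndromic iff any of the three clinical criteria holds: dysmorphic
    features or congenital anomalies, significant developmental delay, or
    an affected first-degree relative."""
    return bool(
        dysmorphic_or_anomalies
        or significant_developmental_delay
        or affected_first_degree_relative
    )


def prevalence_table(probands: Iterable[ProbandRecord]) -> pd.DataFrame:
    """Counts and gene-positive percentages by suture class and syndromic
    status.

    One row per suture class plus a ``combined`` margin row; for each of the
    nonsyndromic / syndromic / combined column groups, the total number of
    probands, the gene-positive count and the percentage positive
    (positive/total x 100).  Combined counts equal syndromic + nonsyndromic
    in every cell.
    """
    probands = list(probands)
    ids = [p.proband_id for p in probands]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"duplicate proband ids: {dupes}")

    rows = []
    order = list(SutureClass)
    for suture in order + [None]:  # None = combined margin
        subset = [p for p in probands if suture is None or p.suture is suture]
        row: dict = {"suture": "combined" if suture is None else suture.value}
        for label, selector in (
            ("nonsyndromic", lambda p: not p.syndromic),
            ("syndromic", lambda p: p.syndromic),
            ("combined", lambda p: True),
        ):
            group = [p for p in subset if selector(p)]
            total = len(group)
            positive = sum(1 for p in group if p.gene_positive)
            row[f"{label}_total"] = total
            row[f"{label}_positive"] = positive
            row[f"{label}_pct"] = (positive / total * 100.0) if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("suture")


def fisher_exact(
    table: ContingencyTable2x2,
    sided: Literal["one_tailed", "two_tailed"] = "two_tailed",
    direction: Optional[Literal["greater", "less"]] = None,
) -> float:
    """Fisher's exact test P value for a 2x2 table.

    One-tailed: the hypergeometric tail in the direction of the observed
    association (more extreme tables on the observed side), unless a
    ``direction`` for cell ``a`` is fixed a priori.  Two-tailed: the sum of
    probabilities, over all tables with the same margins, whose point
    probability does not exceed the observed one (the convention of
    mainstream statistical software).  Degenerate tables (any zero margin)
    carry no information and return 1.
    """
    arr = table.as_array()
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if table.total == 0 or 0 in row or 0 in col:
        return 1.0
    if sided == "one_tailed":
        if direction is None:
            # direction of the observed association: enrichment of cell a
            # relative to its expectation under independence
            expected_a = row[0] * col[0] / table.total
            direction = "greater" if table.a >= expected_a else "less"
        return float(stats.fisher_exact(arr, alternative=direction).pvalue)
    if sided == "two_tailed":
        return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)
    raise DomainError(f"sided must be 'one_tailed' or 'two_tailed', got {sided!r}")


def lof_enrichment(
    case_count: int,
    case_denominator: int,
    ref_count: int,
    ref_denominator: int,
) -> EnrichmentResult:
    """Fold enrichment of a variant class in cases over a reference, with a
    one-tailed exact P value.

    fold = (case_count/case_denominator) / (ref_count/ref_denominator); the
    P value is the one-tailed Fisher's exact test on the implied 2x2 table.
    Denominators are whatever unit the rates share (alleles or individuals).
    """
    if case_denominator <= 0 or ref_denominator <= 0:
        raise DomainError("denominators must be positive")
    if case_count > case_denominator or ref_count > ref_denominator:
        raise DataError("count exceeds its denominator")
    table = ContingencyTable2x2(
        case_count,
        case_denominator - case_count,
        ref_count,
        ref_denominator - ref_count,
    )
    case_rate = case_count / case_denominator
    note = None
    if ref_count == 0:
        fold = math.inf
        note = "reference count is zero; fold undefined (reported as +inf)"
    else:
        fold = case_rate / (ref_count / ref_denominator)
    p = fisher_exact(table, sided="one_tailed")
    return EnrichmentResult(fold=fold, p_value=p, table=table, note=note)


def subtype_contrast(
    pos_a: int, n_a: int, pos_b: int, n_b: int
) -> tuple[float, float]:
    """Rate ratio between two cohort subtypes and the two-tailed exact P.

    Returns ``(rate_ratio, p_two_tailed)`` where rate_ratio =
    (pos_a/n_a)/(pos_b/n_b); +inf when group B has no positives.
    """
    if n_a <= 0 or n_b <= 0:
        raise DomainError("group sizes must be positive")
    if pos_a > n_a or pos_b > n_b:
        raise DataError("positives exceed group size")
    ratio = math.inf if pos_b == 0 else (pos_a / n_a) / (pos_b / n_b)
    table = ContingencyTable2x2(pos_a, n_a - pos_a, pos_b, n_b - pos_b)
    p = fisher_exact(table, sided="two_tailed")
    return ratio, p


def rank_correlation(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Spearman rank correlation with midranks for ties.

    Returns NaN (the correlation is undefined) if either vector is
    constant.  Sign convention: y decreasing with increasing x gives a
    negative coefficient.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise DomainError("xs and ys must be equal-length 1-D vectors")
    if xs.size < 3:
        raise DomainError(f"need at least 3 observations, got {xs.size}")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return math.nan
    return float(stats.spearmanr(xs, ys).statistic)
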