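"""Two-group differential statistics, fold changes, and volcano calls.

For every lipid and every ordered comparison pair (e.g. tumor vs healthy)
the pipeline computes a two-sided t-test p-value and the fold change

    fold_change = mean(group1) / mean(group2)

on the raw intensity scale, then classifies each lipid on the volcano
plane: significant iff p is below the p threshold AND |log2 fold change|
exceeds the log2 threshold, with direction from the sign of the log2
fold change.

The t statistic is computed from the textbook formulas (pooled variance
with n1+n2-2 degrees of freedom for the classical Student variant,
Satterthwaite degrees of freedom for Welch); only the t distribution's
CDF comes from scipy. Zero pooled variance is handled totally: equal
means give t=0, p=1; unequal means with zero variance are un-testable
and raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .nomenclature import ClassCategory, classify_category, parse_lipid_name

__all__ = [
    "ComparisonSpec",
    "DiffResult",
    "DegenerateDataError",
    "student_t",
    "fold_change",
    "classify_volcano",
    "run_comparison",
    "unique_significant_union",
]


class DegenerateDataError(ValueError):
    """Raised for inputs on which the requested statistic is undefined."""


@dataclass(frozen=True)
class ComparisonSpec:
    """Ordered group pair; fold-change direction is group1 over group2."""

    group1: str
    group2: str

    def __post_init__(self):
        if self.group1 == self.group2:
            raise ValueError(f"comparison needs two distinct groups, got {self.group1!r} twice")

    @property
    def tag(self) -> str:
        return f"{self.group1}_vs_{self.group2}"


@dataclass(frozen=True)
class DiffResult:
    """Per-lipid result of one two-group comparison."""

    lipid: str
    class_code: str
    category: ClassCategory
    p_value: float
    fold_change: float
    log2_fc: float
    call: str  # "up" | "down" | "not_significant"

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value) if self.p_value > 0 else math.inf


def _check_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise DegenerateDataError(
            f"group {name!r} has {arr.size} finite value(s); need at least 2"
        )
    return arr


def student_t(values1, values2, variant: str = "student") -> tuple[float, float]:
    """Two-sample t test, two-sided.

    Parameters
    ----------
    values1, values2:
        Intensity values of the two groups; non-finite entries (missing
        values left unimputed) are dropped.
    variant:
        ``"student"`` — classical pooled-variance test, df = n1+n2-2;
        ``"welch"`` — unequal-variance test with Satterthwaite df.

    Returns
    -------
    (t_statistic, p_value)
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = _check_group(values1, "group1")
    b = _check_group(values2, "group2")
    n1, n2 = a.size, b.size
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)

    if variant == "student":
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    else:
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = math.sqrt(se2_1 + se2_2)
        if se > 0:
            df = (se2_1 + se2_2) ** 2 / (
                se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
            )
        else:
            df = n1 + n2 - 2

    if se == 0.0:
        if m1 == m2:
            return 0.0, 1.0  # constant, identical groups: no evidence either way
        raise DegenerateDataError(
            "zero within-group variance with unequal means; t test undefined"
        )
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def fold_change(values1, values2) -> float:
    """Ratio of arithmetic mean intensities, group1 over group2 (raw scale)."""
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("fold change needs at least one observed value per group")
    m2 = b.mean()
    if m2 <= 0:
        raise DegenerateDataError(f"non-positive denominator group mean ({m2}); fold change undefined")
    return float(a.mean() / m2)


def classify_volcano(
    p_value: float,
    fc: float,
    p_threshold: float = 0.05,
    log2_threshold: float = 1.0,
) -> str:
    """Volcano-plane call: ``up``, ``down``, or ``not_significant``.

    ``up`` iff p < p_threshold and log2(fc) > log2_threshold; ``down``
    iff p < p_threshold and log2(fc) < -log2_threshold. Lipids inside
    the exclusion band -log2_threshold..log2_threshold, or above the p
    threshold, are not significant.
    """
    if p_threshold <= 0 or log2_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if p_value >= p_threshold:
        return "not_significant"
    log2fc = math.log2(fc)
    if log2fc > log2_threshold:
        return "up"
    if log2fc < -log2_threshold:
        return "down"
    return "not_significant"


def run_comparison(
    table,
    spec: ComparisonSpec,
    *,
    variant: str = "student",
    log_scale: bool = False,
    p_threshold: float = 0.05,
    log2_threshold: float = 1.0,
) -> list[DiffResult]:
    """Compute per-lipid differential statistics for one comparison.

    Parameters
    ----------
    table:
        An :class:`~lipidiff.io_preprocess.IntensityTable`, normally
        already grade-filtered. Missing cells (NaN) are excluded from
        both the test and the fold change.
    log_scale:
        When True the t test runs on log10 intensities (a sensitivity
        option); the fold change is always the raw-scale mean ratio.

    Returns one :class:`DiffResult` per lipid, in table order.
    """
    idx1 = table.group_indices(spec.group1)
    idx2 = table.group_indices(spec.group2)
    if idx1.size < 2 or idx2.size < 2:
        raise DegenerateDataError(
            f"comparison {spec.tag} needs >= 2 samples per group "
            f"(got {idx1.size} and {idx2.size})"
        )
    results: list[DiffResult] = []
    for i, lipid in enumerate(table.lipids):
        row = table.intensities[i]
        a, b = row[idx1], row[idx2]
        try:
            fc = fold_change(a, b)
            ta, tb = (np.log10(a), np.log10(b)) if log_scale else (a, b)
            _, p = student_t(ta, tb, variant=variant)
        except DegenerateDataError as exc:
            raise DegenerateDataError(f"lipid {lipid!r} in {spec.tag}: {exc}") from exc
        parsed = parse_lipid_name(lipid)
        results.append(
            DiffResult(
                lipid=lipid,
                class_code=parsed.class_code,
                category=classify_category(parsed.class_code),
                p_value=p,
                fold_change=fc,
                log2_fc=math.log2(fc),
                call=classify_volcano(p, fc, p_threshold, log2_threshold),
            )
        )
    return results


def unique_significant_union(result_lists, alpha: float = 0.05) -> int:
    """Count distinct lipids with p < alpha in at least one comparison.

    This is the study-level headline count: how many lipids are
    differentially abundant in any of the pairwise group comparisons.
    """
    significant: set[str] = set()
    for results in result_lists:
        significant.update(r.lipid for r in results if r.p_value < alpha)
    return len(significant)
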