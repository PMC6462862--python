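"""Two-sample comparisons of smoking metrics by germline DNA-repair status.

The gene-by-environment question: do patients carrying at least one
filter-passing germline variant in smoking-damage repair genes show a larger
tobacco-signature fraction (or burden, or smoking variants per pack-year)
than wild-type patients?  Comparisons use Welch's t-test (unequal variances,
Welch–Satterthwaite degrees of freedom) or the pooled-variance unpaired
Student t-test, both two-tailed.  Statistic and df are computed from the
formulas; the two-tailed p comes from the t distribution's survival
function.  No multiple-testing correction is applied by default (the
comparisons are reported as single tests); a Benjamini–Hochberg helper is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .exceptions import InsufficientDataError

WELCH = "welch"
STUDENT = "student"


@dataclass
class TestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


@dataclass
class GroupComparison:
    metric: str
    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]
    means: tuple[float, float]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    test_kind: str
    n_excluded: int = 0


def _check_samples(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0:
        raise ValueError("each sample needs nonzero variance")


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's two-sample t-test, two-tailed.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b); df by the
    Welch–Satterthwaite approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_samples(a, b)
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    sa, sb = va / na, vb / nb
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)))


def student_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Unpaired pooled-variance Student t-test, two-tailed; df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_samples(a, b)
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    t = (np.mean(a) - np.mean(b)) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * t_dist.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)))


_TESTS = {WELCH: welch_t, STUDENT: student_t}


def compare_by_germline_status(
    patient_table: pd.DataFrame,
    metric: str,
    test_kind: str = WELCH,
    status_column: str = "germline_mutant",
) -> GroupComparison:
    """Compare a per-patient metric between germline-mutant and WT patients.

    ``patient_table`` needs one row per patient with a boolean
    ``status_column`` (>= 1 passing germline repair variant) and the metric
    column.  Patients with an undefined (NaN/None) metric are excluded and
    counted in ``n_excluded``.  Fewer than two patients in either group is
    an insufficient-data condition.
    """
    if metric not in patient_table.columns:
        raise ValueError(f"metric column {metric!r} not in patient table")
    if test_kind not in _TESTS:
        raise ValueError(f"test_kind must be one of {sorted(_TESTS)}")
    values = pd.to_numeric(patient_table[metric], errors="coerce")
    defined = values.notna()
    n_excluded = int((~defined).sum())
    mutant = values[defined & patient_table[status_column].astype(bool)]
    wildtype = values[defined & ~patient_table[status_column].astype(bool)]
    if len(mutant) < 2 or len(wildtype) < 2:
        raise InsufficientDataError(
            f"need >= 2 patients per group (mutant={len(mutant)}, wt={len(wildtype)})"
        )
    result = _TESTS[test_kind](mutant.to_numpy(), wildtype.to_numpy())
    return GroupComparison(
        metric=metric,
        group_labels=("mutant", "wildtype"),
        group_sizes=(len(mutant), len(wildtype)),
        means=(float(mutant.mean()), float(wildtype.mean())),
        t_statistic=result.t_statistic,
        degrees_of_freedom=result.degrees_of_freedom,
        p_value=result.p_value,
        test_kind=test_kind,
        n_excluded=n_excluded,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional; comparisons are reported unadjusted)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    cummin = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        rank = m - rank_from_last
        cummin = min(cummin, p[idx] * m / rank)
        adjusted[idx] = cummin
    return adjusted


def comparison_report(comparisons: Sequence[GroupComparison]) -> str:
    """Human-readable block summarizing group comparisons."""
    lines = []
    for c in comparisons:
        lines.append(
            f"{c.metric}: {c.group_labels[0]} (n={c.group_sizes[0]}, "
            f"mean={c.means[0]:.4g}) vs {c.group_labels[1]} (n={c.group_sizes[1]}, "
            f"mean={c.means[1]:.4g}); {c.test_kind} t={c.t_statistic:.4g}, "
            f"df={c.degrees_of_freedom:.3g}, two-tailed p={c.p_value:.4g}"
            + (f" [{c.n_excluded} excluded]" if c.n_excluded else "")
        )
    return "\n".join(lines)
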