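"""Between-group statistical comparisons: t-tests with Bonferroni correction.

Paired or unpaired two-sided t-tests compare a metric between library
methods or body fluids; families of tests are corrected by Bonferroni
(p multiplied by family size, capped at 1).  Significance labels follow the
conventional star binning (ns / * / ** / *** / ****).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError

__all__ = ["ComparisonResult", "compare_metric", "bonferroni", "significance_stars"]


@dataclass
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    test: str  # 'paired_t' or 'unpaired_t'
    t_statistic: float
    p_raw: float
    p_bonferroni: float | None = None
    n_comparisons: int | None = None

    @property
    def stars(self) -> str:
        p = self.p_bonferroni if self.p_bonferroni is not None else self.p_raw
        return significance_stars(p)


def compare_metric(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool,
    metric: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> ComparisonResult:
    """Two-sided t-test between two groups of per-sample metric values.

    Degenerate-input conventions (documented, not silent): identical inputs
    yield t = 0, p = 1; a paired comparison whose differences have zero
    variance but nonzero mean (or an unpaired comparison of two distinct
    constants) is an error, since the t statistic is unbounded there.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise DegenerateDataError("paired test requires equal-length groups")
        if len(a) < 2:
            raise DegenerateDataError("paired test requires at least 2 pairs")
        d = a - b
        if np.std(d, ddof=1) == 0:
            if np.all(d == 0):
                t, p = 0.0, 1.0
            else:
                raise DegenerateDataError(
                    "paired differences are constant and nonzero; t is unbounded"
                )
        else:
            t, p = sps.ttest_rel(a, b)
        test = "paired_t"
    else:
        if len(a) < 2 or len(b) < 2:
            raise DegenerateDataError("unpaired test requires >= 2 values per group")
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            if a[0] == b[0]:
                t, p = 0.0, 1.0
            else:
                raise DegenerateDataError(
                    "both groups are constant with different means; t is unbounded"
                )
        else:
            t, p = sps.ttest_ind(a, b)
        test = "unpaired_t"
    return ComparisonResult(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        test=test,
        t_statistic=float(t),
        p_raw=float(p),
    )


def bonferroni(results: Sequence[ComparisonResult]) -> list[ComparisonResult]:
    """Bonferroni-correct a family of comparisons.

    Each raw p-value is multiplied by the family size and capped at 1; the
    family size is recorded on every result.
    """
    if not results:
        raise DegenerateDataError("empty comparison family")
    k = len(results)
    return [
        replace(r, p_bonferroni=min(1.0, r.p_raw * k), n_comparisons=k) for r in results
    ]


def significance_stars(p: float) -> str:
    """Conventional significance label for a p-value.

    ns: p > 0.05; *: 0.01 < p <= 0.05; **: 0.001 < p <= 0.01;
    ***: 0.0001 < p <= 0.001; ****: p <= 0.0001.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
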