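"""Two-group statistical battery with FDR control.

Each variable is compared between groups with a Welch t-test when both
group samples pass Shapiro-Wilk normality (p >= 0.05 by default) and a
Mann-Whitney U test otherwise.  All p-values from one pipeline run form a
single Benjamini-Hochberg family, and the adjusted values are reported as
Q-values.  Associations between lung-function variables and computational
outputs use Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "CorrelationEntry",
    "StatReport",
    "compare_groups",
    "bh_adjust",
    "spearman_correlation",
    "build_report",
]


@dataclass
class ComparisonResult:
    variable: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    test: str  # "t_test" or "mann_whitney"
    p_value: float
    q_value: float | None = None


@dataclass
class CorrelationEntry:
    x: str
    y: str
    rho: float
    p_value: float
    significant: bool


@dataclass
class StatReport:
    comparisons: list[ComparisonResult]
    correlations: list[CorrelationEntry] = field(default_factory=list)

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])

    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.correlations])


def compare_groups(a, b, variable: str = "", alpha_normality: float = 0.05,
                   exact_below: int = 12) -> ComparisonResult:
    """Normality-gated two-group comparison (no Q-value yet).

    Welch's unequal-variance t-test when Shapiro-Wilk p >= alpha in both
    samples, otherwise a two-sided Mann-Whitney U (tie-corrected normal
    approximation without continuity correction; exact enumeration when
    both groups are smaller than ``exact_below`` and tie-free).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError(f"each group needs n >= 3 (got {a.size}, {b.size})")
    if np.ptp(np.concatenate([a, b])) == 0:
        # every observation tied across both groups: no evidence of a shift
        return ComparisonResult(
            variable=variable, mean_a=float(a.mean()), sd_a=0.0,
            mean_b=float(b.mean()), sd_b=0.0, n_a=int(a.size), n_b=int(b.size),
            test="mann_whitney", p_value=1.0)
    normal = (
        np.ptp(a) > 0 and np.ptp(b) > 0
        and sps.shapiro(a).pvalue >= alpha_normality
        and sps.shapiro(b).pvalue >= alpha_normality
    )
    if normal:
        test = "t_test"
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        test = "mann_whitney"
        pooled = np.concatenate([a, b])
        ties = np.unique(pooled).size < pooled.size
        method = "exact" if (max(a.size, b.size) < exact_below and not ties) else "asymptotic"
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                   use_continuity=False).pvalue)
    return ComparisonResult(
        variable=variable,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        n_a=int(a.size), n_b=int(b.size),
        test=test, p_value=p,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q-values), input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_correlation(x, y, alpha: float = 0.05,
                         x_name: str = "x", y_name: str = "y") -> CorrelationEntry:
    """Spearman rank correlation with two-sided p via the t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    res = sps.spearmanr(x, y)
    return CorrelationEntry(x=x_name, y=y_name, rho=float(res.statistic),
                            p_value=float(res.pvalue),
                            significant=bool(res.pvalue < alpha))


def build_report(
    comparisons: list[ComparisonResult],
    correlation_pairs: list[tuple[str, str, np.ndarray, np.ndarray]] | None = None,
    alpha: float = 0.05,
) -> StatReport:
    """Attach one global BH family across all comparisons; add correlations.

    The family spans every comparison passed in (demographics, QCT and
    pressure variables alike), mirroring a single pooled correction over
    the whole battery.  Q-values are written back onto the results.
    """
    if not comparisons:
        raise ValueError("empty comparison family")
    q = bh_adjust([c.p_value for c in comparisons])
    for c, qi in zip(comparisons, q):
        c.q_value = float(qi)
    correlations = [
        spearman_correlation(x, y, alpha=alpha, x_name=xn, y_name=yn)
        for xn, yn, x, y in (correlation_pairs or [])
    ]
    return StatReport(comparisons=comparisons, correlations=correlations)
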