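"""Group-comparison statistics: rank tests with effect sizes, t-tests,
Friedman test, and Benjamini-Hochberg FDR adjustment.

All tests return a :class:`TestResult`; a :class:`ComparisonReport` adjusts
every queued result jointly in one BH family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "BHResult",
    "ComparisonReport",
    "mann_whitney",
    "welch_t",
    "friedman",
    "bh_adjust",
]

#: Use exact U-test enumeration up to this combined sample size (no ties).
EXACT_U_MAX_N = 12


@dataclass
class TestResult:
    """One hypothesis test with effect size and (after adjustment) BH fields."""

    test_name: str
    label: str
    statistic: float
    p_raw: float
    effect_size: float
    n1: int
    n2: int
    p_adjusted: float | None = None
    rank: int | None = None
    significant: bool | None = None
    effect_size_signed: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError(f"p_raw {self.p_raw} outside [0, 1]")


@dataclass
class BHResult:
    p_adjusted: float
    rank: int
    significant: bool


def mann_whitney(x, y, label: str = "", exact: bool | None = None) -> TestResult:
    """Two-sided Mann-Whitney U test with rank-biserial effect size.

    Exact p by enumeration when n1 + n2 <= 12 and the data are tie-free;
    otherwise the normal approximation with continuity and tie correction.
    The reported effect size is ``|1 - 2U/(n1*n2)|``; the signed value is
    kept in ``effect_size_signed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if exact is None:
        exact = (x.size + y.size <= EXACT_U_MAX_N) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u = float(res.statistic)  # U of x: #pairs (x_i > y_j) + 0.5 ties
    r_signed = 1.0 - 2.0 * u / (x.size * y.size)
    return TestResult(
        test_name="mann_whitney_u",
        label=label,
        statistic=u,
        p_raw=float(min(res.pvalue, 1.0)),
        effect_size=abs(r_signed),
        effect_size_signed=float(r_signed),
        n1=int(x.size),
        n2=int(y.size),
    )


def welch_t(x, y, label: str = "", equal_var: bool = False) -> TestResult:
    """Two-sided t-test (Welch by default; Student via ``equal_var=True``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t-test requires n >= 2 per sample")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            # no variance, no difference: statistic 0, p 1 by convention
            return TestResult(
                test_name="welch_t" if not equal_var else "student_t",
                label=label, statistic=0.0, p_raw=1.0,
                effect_size=0.0, effect_size_signed=0.0,
                n1=int(x.size), n2=int(y.size),
            )
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    # Cohen's d (pooled SD) as a descriptive effect size
    pooled = np.sqrt(
        ((x.size - 1) * np.var(x, ddof=1) + (y.size - 1) * np.var(y, ddof=1))
        / (x.size + y.size - 2)
    )
    d = float((np.mean(x) - np.mean(y)) / pooled) if pooled > 0 else 0.0
    return TestResult(
        test_name="welch_t" if not equal_var else "student_t",
        label=label,
        statistic=float(res.statistic),
        p_raw=float(min(res.pvalue, 1.0)),
        effect_size=abs(d),
        effect_size_signed=d,
        n1=int(x.size),
        n2=int(y.size),
    )


def friedman(samples, label: str = "") -> TestResult:
    """Friedman test over k >= 3 matched samples (blocks along axis 0).

    ``samples`` is a sequence of k equal-length arrays, one per condition.
    Effect size is Kendall's-W-derived eta-squared: H / (n * (k - 1)).
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 3:
        raise ValueError("friedman requires k >= 3 matched samples")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("friedman requires equal block lengths")
    with np.errstate(invalid="ignore"):
        res = sps.friedmanchisquare(*arrays)
    h = float(res.statistic)
    pvalue = float(res.pvalue)
    if np.isnan(h):
        # fully tied ranks in every block: no evidence of any difference
        h, pvalue = 0.0, 1.0
    eta2 = h / (n * (len(arrays) - 1))
    return TestResult(
        test_name="friedman",
        label=label,
        statistic=h,
        p_raw=float(min(pvalue, 1.0)),
        effect_size=float(eta2),
        effect_size_signed=float(eta2),
        n1=int(n),
        n2=len(arrays),
    )


def bh_adjust(p_values, fdr: float = 0.10) -> list[BHResult]:
    """Benjamini-Hochberg step-up adjustment.

    Sort ascending, set adj_i = p_i * m / rank_i, enforce monotonicity by a
    cumulative minimum from the largest rank down, cap at 1.  Results are
    returned in the original input order; ``significant`` means
    adjusted p <= ``fdr``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks_sorted = np.arange(1, m + 1)
    adj_sorted = p[order] * m / ranks_sorted
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    # m/rank >= 1 guarantees adj >= p; clamp float noise to keep it exact
    adj_sorted = np.maximum(adj_sorted, p[order])
    adjusted = np.empty(m, dtype=float)
    ranks = np.empty(m, dtype=int)
    adjusted[order] = adj_sorted
    ranks[order] = ranks_sorted
    return [
        BHResult(p_adjusted=float(adjusted[i]), rank=int(ranks[i]),
                 significant=bool(adjusted[i] <= fdr))
        for i in range(m)
    ]


@dataclass
class ComparisonReport:
    """An ordered family of tests adjusted jointly at one FDR level."""

    results: list[TestResult] = field(default_factory=list)
    fdr: float = 0.10

    def __post_init__(self):
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must lie in (0, 1)")

    @property
    def m(self) -> int:
        return len(self.results)

    def add(self, result: TestResult) -> None:
        self.results.append(result)

    def extend(self, results) -> None:
        self.results.extend(results)

    def adjust(self) -> "ComparisonReport":
        """Fill p_adjusted / rank / significant across the whole family."""
        bh = bh_adjust([r.p_raw for r in self.results], fdr=self.fdr)
        for res, b in zip(self.results, bh):
            res.p_adjusted = b.p_adjusted
            res.rank = b.rank
            res.significant = b.significant
        return self

    def to_rows(self) -> list[dict]:
        return [
            {
                "label": r.label,
                "test": r.test_name,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "rank": r.rank,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "effect_size": r.effect_size,
                "n1": r.n1,
                "n2": r.n2,
            }
            for r in self.results
        ]
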