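"""Shared hypothesis-testing layer.

All tests are two-sided. Results carry a significance "star" annotation at
the conventional strict thresholds 0.05 / 0.01 / 0.001 / 0.0001 used
throughout the reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "TestResult",
    "hypothesis_test",
    "star_label",
    "proportions_ztest",
    "adjust_pvalues",
]

#: strict upper thresholds mapped to star labels, most stringent first
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def star_label(p: float) -> str:
    """Map a p-value to its star annotation ('' if p >= 0.05).

    Thresholds are strict: ``p == 0.05`` is not significant.
    """
    if not 0.0 <= p <= 1.0:
        raise InputError(f"p-value must lie in [0, 1], got {p}")
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return ""


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    sidedness: str = "two-sided"
    stars: str = field(default="")

    def __post_init__(self) -> None:
        if not self.stars:
            self.stars = star_label(self.p_value)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_per_group"] = list(self.n_per_group)
        return d


def proportions_ztest(
    x1: float,
    n1: int,
    x2: float,
    n2: int,
    continuity: bool = False,
) -> TestResult:
    """Two-proportion z-test with pooled variance.

    ``x1``/``x2`` are success counts (non-integral "effective" counts are
    accepted, e.g. summed per-cell intensity fractions). No continuity
    correction by default; ``continuity=True`` applies the Yates ±0.5
    adjustment to the difference.
    """
    if n1 <= 0 or n2 <= 0:
        raise InputError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise InputError("success counts must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    diff = p1 - p2
    if continuity:
        correction = 0.5 * (1.0 / n1 + 1.0 / n2)
        diff = np.sign(diff) * max(abs(diff) - correction, 0.0)
    if se == 0.0:
        z = 0.0
    else:
        z = diff / se
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("proportions", float(z), float(min(p, 1.0)), (int(n1), int(n2)))


def hypothesis_test(
    kind: str,
    a: Sequence[float],
    b: Sequence[float],
    *,
    equal_var: bool = True,
    continuity: bool = False,
) -> TestResult:
    """Run a two-sided, two-sample test of the given kind.

    Parameters
    ----------
    kind:
        ``"t"`` (Student by default, Welch with ``equal_var=False``),
        ``"proportions"`` (each sample is a ``(successes, n)`` pair),
        ``"ks"`` (two-sample Kolmogorov-Smirnov), or
        ``"wilcoxon_signed_rank"`` (paired; samples must have equal length).
    a, b:
        The two samples (or ``(successes, n)`` pairs for proportions).
    """
    if kind == "t":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise InputError("t-test requires at least 2 values per group")
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
        stat = 0.0 if np.isnan(res.statistic) else float(res.statistic)
        name = "t" if equal_var else "welch_t"
        return TestResult(name, stat, p, (a.size, b.size))
    if kind == "proportions":
        (x1, n1), (x2, n2) = a, b
        res = proportions_ztest(x1, n1, x2, n2, continuity=continuity)
        return res
    if kind == "ks":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise InputError("KS test requires non-empty samples")
        res = sps.ks_2samp(a, b, alternative="two-sided")
        return TestResult("ks", float(res.statistic), float(res.pvalue), (a.size, b.size))
    if kind == "wilcoxon_signed_rank":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size != b.size:
            raise InputError(
                f"Wilcoxon signed-rank test is paired: lengths {a.size} != {b.size}"
            )
        if np.allclose(a, b):
            # all-zero differences: no evidence against the null
            return TestResult("wilcoxon_signed_rank", 0.0, 1.0, (a.size, b.size))
        res = sps.wilcoxon(a, b, alternative="two-sided")
        return TestResult(
            "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), (a.size, b.size)
        )
    raise InputError(f"unknown test kind: {kind!r}")


def adjust_pvalues(p_values: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg (or other statsmodels) multiplicity adjustment.

    Off by default everywhere in the pipeline; provided for users who
    aggregate many comparisons.
    """
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method=method)[1]
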