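"""Comfort-index scoring and the study's comparison statistics.

The comfort questionnaire is seven bipolar 7-point scales. Lines 2, 4, 6
read left-to-right (mark m -> m); lines 1, 3, 5, 7 are reversed
(mark m -> 8 - m), so that after conversion larger always means more
comfortable. The comfort index is the sum of the seven converted values,
ranging from 7 (most uncomfortable) to 49 (most comfortable).

Statistical tests:

* noninferiority / nonsuperiority two-sample t-tests with a margin
  epsilon (by default one pooled standard deviation): noninferiority of A
  vs B tests H0: mu_A - mu_B <= -eps against H1: mu_A - mu_B > -eps with
  the one-sided statistic t = (xbar_A - xbar_B + eps) / SE; the
  nonsuperiority test mirrors it at +eps,
* the Friedman rank sum test for blocked (subjects x treatments) designs,
  with midrank tie correction,
* the classical unpaired two-sample t-test (pooled variance by default,
  Welch switchable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

REVERSED_LINES: frozenset[int] = frozenset({1, 3, 5, 7})
N_SCALES = 7


@dataclass
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class NoninferiorityConfig:
    """Margin and direction of the shifted two-sample t-test.

    margin_kind 'sigma' sets epsilon to margin_value pooled standard
    deviations of the two groups; 'absolute' uses margin_value directly
    in index units.
    """

    margin_kind: str = "sigma"
    margin_value: float = 1.0
    direction: str = "noninferiority"
    alpha: float = 0.05
    equal_var: bool = True

    def __post_init__(self) -> None:
        if self.margin_kind not in ("sigma", "absolute"):
            raise ValueError("margin_kind must be 'sigma' or 'absolute'")
        if self.direction not in ("noninferiority", "nonsuperiority"):
            raise ValueError("direction must be noninferiority or nonsuperiority")
        if self.margin_value < 0:
            raise ValueError("margin must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ComfortResponse:
    """One respondent's seven raw marks and their converted values."""

    raw_marks: tuple[int, ...]
    converted: tuple[int, ...]

    @classmethod
    def from_marks(cls, raw_marks: Sequence[int],
                   reversed_lines: frozenset[int] = REVERSED_LINES,
                   ) -> "ComfortResponse":
        conv = convert_comfort_scales(raw_marks, reversed_lines)
        return cls(tuple(int(m) for m in raw_marks), tuple(conv))

    @property
    def index(self) -> int:
        return comfort_index(self)


def convert_comfort_scales(raw_marks: Sequence[int],
                           reversed_lines: frozenset[int] = REVERSED_LINES,
                           ) -> list[int]:
    """Map raw 1-7 marks to comfort-oriented values (reversed lines: 8 - m)."""
    if len(raw_marks) != N_SCALES:
        raise ValueError(f"expected {N_SCALES} marks, got {len(raw_marks)}")
    out = []
    for line, m in enumerate(raw_marks, start=1):
        m = int(m)
        if not 1 <= m <= 7:
            raise ValueError(f"mark {m} on line {line} outside 1-7")
        out.append(8 - m if line in reversed_lines else m)
    return out


def comfort_index(response: ComfortResponse) -> int:
    """Sum of the seven converted scale values; integer in [7, 49]."""
    if len(response.converted) != N_SCALES:
        raise ValueError("response is missing scales")
    return int(sum(response.converted))


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    return float(np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                         / (na + nb - 2)))


def noninferiority_t_test(group_a: Sequence[float], group_b: Sequence[float],
                          cfg: NoninferiorityConfig | None = None) -> TestResult:
    """One-sided shifted two-sample t-test against a margin.

    direction 'noninferiority': H0: mu_a - mu_b <= -eps, rejected for large
    t = (xbar_a - xbar_b + eps)/SE. direction 'nonsuperiority':
    H0: mu_a - mu_b >= +eps, rejected for small t = (xbar_a - xbar_b - eps)/SE.
    """
    cfg = cfg or NoninferiorityConfig()
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    sp = _pooled_sd(a, b)
    eps = cfg.margin_value * sp if cfg.margin_kind == "sigma" else cfg.margin_value
    if sp == 0 and eps > 0:
        raise ValueError("zero pooled variance with a nonzero margin is degenerate")
    na, nb = len(a), len(b)
    if cfg.equal_var:
        se = sp * np.sqrt(1 / na + 1 / nb)
        df = na + nb - 2
    else:
        va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    if se == 0:
        raise ValueError("zero standard error: groups are degenerate")
    diff = a.mean() - b.mean()
    if cfg.direction == "noninferiority":
        t = (diff + eps) / se
        p = float(stats.t.sf(t, df))
    else:
        t = (diff - eps) / se
        p = float(stats.t.cdf(t, df))
    return TestResult(float(t), float(df), p,
                      f"two-sample t ({cfg.direction}, eps={eps:.4g})")


def friedman_test(block_matrix: np.ndarray) -> TestResult:
    """Friedman rank sum test on a subjects x treatments matrix.

    Within-subject midranks, tie-corrected chi-square with k-1 degrees of
    freedom.
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 treatments")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing treatment value in a subject row")
    n, k = m.shape
    ranks = stats.rankdata(m, axis=1)  # midranks within each subject
    ssbn = float((ranks.sum(axis=0) ** 2).sum())
    chisq = 12.0 / (n * k * (k + 1)) * ssbn - 3 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) over tie groups / (n k (k^2 - 1))
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts ** 3 - counts).sum())
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c == 0.0:  # every row fully tied: no evidence against H0
        return TestResult(0.0, float(k - 1), 1.0, "Friedman rank sum")
    chisq /= c
    p = float(stats.chi2.sf(chisq, k - 1))
    return TestResult(float(chisq), float(k - 1), p, "Friedman rank sum")


def unpaired_t_test(group_a: Sequence[float], group_b: Sequence[float],
                    equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t-test (pooled by default; Welch switchable)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    name = "unpaired t (pooled)" if equal_var else "unpaired t (Welch)"
    return TestResult(float(res.statistic), df, float(res.pvalue), name)
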