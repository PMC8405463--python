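"""Metabolite-to-parent ratio kinetics in exposed organisms.

Biotransformation of a parent compound shows up as a rising ratio of
metabolite to parent body burden over the exposure.  This module builds the
ratio time course from two body-burden series (replicate means per sampling
time, one ratio per time point) and assesses its monotone trend with the
Mann-Kendall test, using an exact small-sample null distribution — the
default designs have only four sampling times, where the normal
approximation is meaningless.

Exact p-values: with no ties the null distribution of the Mann-Kendall S
statistic over the n! orderings is computed by the inversion-count
recurrence (generating function prod_{i=1..n} (1 + x + ... + x^{i-1})).
With tied values and n <= 8 the distribution is enumerated over all
permutations of the observed multiset.  Larger tied samples fall back to
the tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from .series import ConcentrationSeries

__all__ = [
    "RatioSeries",
    "ratio_series",
    "TrendResult",
    "ratio_trend",
    "mann_kendall",
]


@dataclass
class RatioSeries:
    """Metabolite/parent body-burden ratio per sampling time.

    ``data`` columns: ``time_h``, ``parent_conc``, ``metabolite_conc``
    (replicate means, ng/g), ``ratio`` (NaN where undefined), ``defined``.
    A ratio is undefined at a time where the parent mean is not positive or
    the parent is entirely censored; a fully-censored metabolite counts as
    concentration 0 (ratio 0), matching a non-detect.
    """

    parent: str
    metabolite: str
    data: pd.DataFrame = field(repr=False)
    notes: list[str] = field(default_factory=list)

    @property
    def defined_ratios(self) -> pd.Series:
        """Defined ratios indexed by time, in time order."""
        d = self.data[self.data["defined"]]
        return d.set_index("time_h")["ratio"]


def ratio_series(parent: ConcentrationSeries, metabolite: ConcentrationSeries) -> RatioSeries:
    """Ratio time course from parent and metabolite body-burden series.

    Ratios are computed on replicate means per sampling time, one per time
    point common to both series; times present in only one series are
    omitted with a note.
    """
    p_means = parent.replicate_means()
    m_means = metabolite.replicate_means()
    # fully censored metabolite time points count as zero concentration
    for t in metabolite.times:
        if t not in m_means.index:
            m_means.loc[t] = 0.0
    m_means = m_means.sort_index()

    notes: list[str] = []
    p_times = set(np.round(parent.times, 9))
    m_times = set(np.round(metabolite.times, 9))
    only_one = sorted(p_times.symmetric_difference(m_times))
    if only_one:
        notes.append(f"times present in only one series omitted: {only_one}")

    rows = []
    for t in sorted(p_times & m_times):
        p_val = p_means.get(t)
        m_val = float(m_means.get(t, 0.0))
        if p_val is None or not (p_val > 0):
            rows.append((t, np.nan if p_val is None else float(p_val), m_val, np.nan, False))
            notes.append(f"ratio undefined at t={t} h: parent censored or non-positive")
        else:
            rows.append((t, float(p_val), m_val, m_val / float(p_val), True))
    data = pd.DataFrame(rows, columns=["time_h", "parent_conc", "metabolite_conc",
                                       "ratio", "defined"])
    return RatioSeries(parent=parent.analyte, metabolite=metabolite.analyte,
                       data=data, notes=notes)


# ---------------------------------------------------------------------------
# Mann-Kendall trend test
# ---------------------------------------------------------------------------

def _s_statistic(x: np.ndarray) -> int:
    """S = sum over i<j of sign(x[j] - x[i])."""
    diff = np.subtract.outer(x, x)          # diff[j, i] = x[j] - x[i]
    j_idx, i_idx = np.tril_indices(len(x), k=-1)
    return int(np.sum(np.sign(diff[j_idx, i_idx])))


def _tau_b(x: np.ndarray, s: int) -> float:
    n = len(x)
    n0 = n * (n - 1) // 2
    _, counts = np.unique(x, return_counts=True)
    n_tied = int(np.sum(counts * (counts - 1) // 2))
    denom = math.sqrt((n0 - n_tied) * n0)
    return s / denom if denom > 0 else 0.0


def _exact_s_counts_no_ties(n: int) -> dict[int, int]:
    """Null counts of S over the n! orderings of distinct values.

    S = n(n-1)/2 - 2 * inversions; inversion counts come from the classic
    polynomial product prod_{i=1}^{n} (1 + x + ... + x^{i-1}).
    """
    poly = np.array([1], dtype=object)
    for i in range(2, n + 1):
        poly = np.convolve(poly, np.ones(i, dtype=object))
    n0 = n * (n - 1) // 2
    return {n0 - 2 * inv: int(c) for inv, c in enumerate(poly)}


def _exact_tail_probs(x: np.ndarray, s: int) -> tuple[float, float, str]:
    """(one-sided p toward observed S, two-sided p, method label)."""
    n = len(x)
    has_ties = len(np.unique(x)) < n
    if not has_ties:
        counts = _exact_s_counts_no_ties(n)
        total = math.factorial(n)
        method = "exact"
    elif n <= 8:
        counts: dict[int, int] = {}
        total = 0
        for perm in permutations(x):
            sp = _s_statistic(np.asarray(perm))
            counts[sp] = counts.get(sp, 0) + 1
            total += 1
        method = "exact_ties"
    else:
        return _normal_tail_probs(x, s) + ("normal_approx",)
    if s >= 0:
        p_one = sum(c for v, c in counts.items() if v >= s) / total
    else:
        p_one = sum(c for v, c in counts.items() if v <= s) / total
    p_two = sum(c for v, c in counts.items() if abs(v) >= abs(s)) / total
    return p_one, p_two, method


def _normal_tail_probs(x: np.ndarray, s: int) -> tuple[float, float]:
    from scipy.stats import norm
    n = len(x)
    _, counts = np.unique(x, return_counts=True)
    var = (n * (n - 1) * (2 * n + 5)
           - np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
    if var <= 0:
        return 1.0, 1.0
    z = (s - np.sign(s)) / math.sqrt(var)  # continuity correction
    p_one = float(norm.sf(abs(z))) if s != 0 else 1.0
    return p_one, min(1.0, 2.0 * p_one)


@dataclass
class TrendResult:
    """Mann-Kendall trend assessment of a ratio time course."""

    direction: str      # "increasing" | "decreasing" | "none"
    s: int
    tau: float
    p_one_sided: float  # exact tail probability toward the observed S
    p_two_sided: float
    n: int
    method: str         # "exact" | "exact_ties" | "normal_approx" | "degenerate"


def mann_kendall(values, alpha: float = 0.05) -> TrendResult:
    """Mann-Kendall trend test on a sequence ordered by time.

    The direction call uses the exact one-sided p-value in the direction of
    the observed S at level ``alpha``: at n=4 a perfectly monotone sequence
    reaches p = 1/24 < 0.05 one-sided, while no n=4 sequence can reach
    p < 0.05 two-sided (minimum 1/12).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError(f"trend test needs >= 3 points, have {len(x)}")
    if not np.all(np.isfinite(x)):
        raise InsufficientDataError("trend test input contains non-finite values")
    s = _s_statistic(x)
    tau = _tau_b(x, s)
    if len(np.unique(x)) == 1:
        return TrendResult("none", 0, 0.0, 1.0, 1.0, len(x), "degenerate")
    p_one, p_two, method = _exact_tail_probs(x, s)
    if s > 0 and p_one <= alpha:
        direction = "increasing"
    elif s < 0 and p_one <= alpha:
        direction = "decreasing"
    else:
        direction = "none"
    return TrendResult(direction, s, tau, p_one, p_two, len(x), method)


def ratio_trend(series, alpha: float = 0.05) -> TrendResult:
    """Trend assessment of a :class:`RatioSeries` (or a plain ratio sequence).

    Requires at least three time points with defined ratios.
    """
    if isinstance(series, RatioSeries):
        values = series.defined_ratios.to_numpy()
    else:
        values = np.asarray(series, dtype=float)
    if len(values) < 3:
        raise InsufficientDataError(
            f"need >= 3 defined ratios for a trend test, have {len(values)}"
        )
    return mann_kendall(values, alpha=alpha)
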