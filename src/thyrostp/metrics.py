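"""Accuracy metrics for single-time-point TIA estimates against a reference.

Per patient j and method/time-point k the relative deviation is

    RD_kj = (sTIA_kj - rTIA_j) / rTIA_j

and per group the summary statistics are the mean RD, the population
standard deviation of RD (divide by n), the root-mean-square error

    RMSE_k = sqrt(SDRD_k^2 + MeanRD_k^2) = sqrt(mean(RD^2))

(the identity holds exactly because the population SD is used), the mean
absolute percentage error MAPE_k = mean(|RD_kj|), and the counts of
patients whose |RD| strictly exceeds 5% / 10% / 20%.

A paired Wilcoxon signed-rank test compares two methods on the same
patients: exact distribution (rank-sum convolution, mid-ranks for ties)
for n <= 25 non-zero differences, normal approximation with tie correction
otherwise.  Zero differences are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .stp import TIAEstimate

__all__ = [
    "AccuracyRow",
    "WilcoxonResult",
    "relative_deviation",
    "summarize",
    "wilcoxon_paired",
    "build_table",
    "METHOD_ORDER",
]

#: Row-block order of the report table.
METHOD_ORDER = ("s1TIA", "s2TIA", "hTIA", "nTIA")


@dataclass(frozen=True)
class AccuracyRow:
    """One report row: a method at one time point, summarized over patients."""

    method: str
    time_point_h: float | None
    mean_rd: float
    sd_rd: float
    rmse: float
    mape: float
    n: int
    n_rd5: int
    n_rd10: int
    n_rd20: int


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    median_of_differences: float
    n: int
    degenerate: bool = False


def relative_deviation(stia: float, rtia: float) -> float:
    """(stia - rtia) / rtia; requires a positive reference."""
    if not rtia > 0.0:
        raise ValueError(f"reference TIA must be > 0, got {rtia}")
    return (stia - rtia) / rtia


def summarize(
    rds: Sequence[float],
    method: str = "",
    time_point_h: float | None = None,
    sd_mode: str = "population",
) -> AccuracyRow:
    """Summarize a vector of relative deviations into one accuracy row.

    ``sd_mode="population"`` (default) divides by n so that
    ``rmse**2 == mean_rd**2 + sd_rd**2`` holds exactly; ``"sample"``
    divides by n-1 for sensitivity checks (the RMSE then still reports
    sqrt(mean(RD^2))).
    """
    rd = np.asarray(list(rds), dtype=float)
    if rd.size == 0:
        raise ValueError("need at least one relative deviation")
    if sd_mode not in ("population", "sample"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    ddof = 0 if sd_mode == "population" else 1
    mean_rd = float(np.mean(rd))
    sd_rd = float(np.std(rd, ddof=ddof)) if rd.size > ddof else 0.0
    rmse = float(np.sqrt(np.mean(rd**2)))
    mape = float(np.mean(np.abs(rd)))
    ar = np.abs(rd)
    return AccuracyRow(
        method=method,
        time_point_h=time_point_h,
        mean_rd=mean_rd,
        sd_rd=sd_rd,
        rmse=rmse,
        mape=mape,
        n=int(rd.size),
        n_rd5=int(np.sum(ar > 0.05)),
        n_rd10=int(np.sum(ar > 0.10)),
        n_rd20=int(np.sum(ar > 0.20)),
    )


def _signed_rank_exact_p(w_obs: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for the signed-rank statistic W+ = sum of positive
    ranks, by convolving the rank-sum distribution over all sign vectors.

    Mid-ranks are multiples of 1/2, so doubling makes them integers and the
    distribution of 2*W+ is a polynomial convolution.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2.0 * w_obs))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_paired(
    rds_a: Sequence[float], rds_b: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-rank test between two paired vectors.

    Returns the statistic ``W+`` (sum of ranks of positive differences
    a - b), a two-sided p-value, and the median of the paired differences.
    Zero differences are dropped; at least 3 non-zero pairs are required
    unless all differences are zero, in which case a degenerate result is
    returned.
    """
    a = np.asarray(list(rds_a), dtype=float)
    b = np.asarray(list(rds_b), dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-d and of equal length")
    d = a - b
    median_d = float(np.median(d)) if d.size else float("nan")
    nz = d[d != 0.0]
    if nz.size == 0:
        return WilcoxonResult(float("nan"), float("nan"), median_d, 0, degenerate=True)
    if nz.size < 3:
        raise ValueError(
            f"need >= 3 non-zero paired differences, got {nz.size}"
        )
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(nz))  # mid-ranks for ties
    w_plus = float(ranks[nz > 0].sum())
    n = nz.size
    if n <= exact_max_n:
        p = _signed_rank_exact_p(w_plus, ranks)
    else:
        mu = n * (n + 1) / 4.0
        # tie correction: subtract sum(t^3 - t)/48 from the null variance
        _, counts = np.unique(np.abs(nz), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            np.sum(counts**3 - counts)
        ) / 48.0
        from scipy.stats import norm

        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return WilcoxonResult(w_plus, p, median_d, n)


def build_table(
    estimates: Iterable[TIAEstimate],
    references: Iterable[TIAEstimate],
    sd_mode: str = "population",
) -> list[AccuracyRow]:
    """Group STP/NTP estimates by (method, time point) and summarize each
    group against the per-patient reference TIAs.

    Rows are ordered by method block (s1TIA, s2TIA, hTIA, nTIA) and
    ascending time within a block.
    """
    est = list(estimates)
    if not est:
        raise ValueError("no estimates given")
    ref = {r.patient_id: r.value for r in references}
    missing = sorted({e.patient_id for e in est if e.patient_id not in ref})
    if missing:
        raise ValueError(f"patients without a reference TIA: {missing}")
    groups: dict[tuple[str, float | None], list[float]] = {}
    for e in est:
        key = (e.method, e.time_point_h)
        groups.setdefault(key, []).append(
            relative_deviation(e.value, ref[e.patient_id])
        )

    def sort_key(key):
        method, tp = key
        mi = METHOD_ORDER.index(method) if method in METHOD_ORDER else len(METHOD_ORDER)
        return (mi, tp if tp is not None else float("inf"))

    return [
        summarize(groups[key], method=key[0], time_point_h=key[1], sd_mode=sd_mode)
        for key in sorted(groups, key=sort_key)
    ]
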