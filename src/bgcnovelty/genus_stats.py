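"""Genus-level comparison of best membership-distance distributions.

If one genus sits systematically further from the known gene-cluster
families than another, its strains are the better prospecting targets.
The comparison is rank-based: a two-sided Mann-Whitney U test on the
per-BGC best distances, with box-plot summaries (Tukey conventions) for
reporting.

The U statistic counts, over all cross-genus pairs, how often a value
from the first sample exceeds one from the second (ties count 1/2).
Small tie-free samples are handled exactly by enumerating the equally
likely rank splits; larger or tied samples use the normal approximation
with midranks, a tie-corrected variance and a continuity correction of
1/2 — the path that applies at the study's sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .novelty_scoring import NoveltyRecord

EXACT_MAX_N = 8  # largest sample size for the automatic exact path


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: rank-sum formulation with midranks (ties count 1/2)."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided p by exhaustive enumeration of rank assignments.

    Every way of labelling n1 of the pooled N observations as "x" is
    equally likely under the null; p is the fraction of labellings whose
    U deviates from the null mean n1*n2/2 at least as much as observed.
    Valid with ties (midranks are computed on the fixed pooled sample).
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total


def _approx_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Normal approximation with tie-corrected variance and continuity
    correction 1/2; two-sided."""
    n1, n2 = len(x), len(y)
    N = n1 + n2
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = (n1 * n2 / 12.0) * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    mu = n1 * n2 / 2.0
    dev = u_obs - mu
    if dev == 0:
        return 1.0
    z = (dev - math.copysign(0.5, dev)) / math.sqrt(var)
    return min(1.0, 2.0 * norm.sf(abs(z)))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test; returns (U_x, p, method_used).

    ``method`` is "auto" (exact for tie-free samples with
    max(n1, n2) <= 8, normal approximation otherwise), "exact" or
    "asymptotic".  Identical samples yield U = n1*n2/2 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    u = _u_statistic(x, y)
    if method == "auto":
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = (
            "exact" if max(len(x), len(y)) <= EXACT_MAX_N and not has_ties
            else "asymptotic"
        )
    if method == "exact":
        if math.comb(len(x) + len(y), len(x)) > 2_000_000:
            raise ValueError(
                "exact enumeration infeasible at these sample sizes"
            )
        p = _exact_p(x, y, u)
    else:
        p = _approx_p(x, y, u)
    return float(u), float(p), method


def summarize_distribution(values: Sequence[float]) -> tuple[int, float, float]:
    """(n, mean, median) of one genus's best-distance sample."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty sample")
    return len(values), float(values.mean()), float(np.median(values))


def boxplot_stats(values: Sequence[float]) -> dict[str, object]:
    """Tukey box-plot summary: quartiles, 1.5*IQR whiskers, outliers, mean."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "n": int(len(v)),
        "mean": float(v.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": [float(o) for o in v[(v < lo_fence) | (v > hi_fence)]],
    }


@dataclass(frozen=True)
class GenusComparison:
    genus_x: str
    genus_y: str
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    median_x: float
    median_y: float
    u_statistic: float  # U for genus_x
    p_value: float
    method: str
    alpha: float
    alternative: str = "two-sided"

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    @property
    def cles(self) -> float:
        """Common-language effect size P(X > Y) (ties halved)."""
        return self.u_statistic / (self.n_x * self.n_y)

    @property
    def stochastically_larger(self) -> str:
        """Which genus tends to larger distances, judged by U."""
        return self.genus_x if self.cles >= 0.5 else self.genus_y


def compare_distance_samples(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    method: str = "auto",
) -> tuple[list[GenusComparison], dict[str, dict[str, object]]]:
    """All pairwise genus comparisons plus per-genus box-plot data."""
    genera = list(samples)
    if len(genera) < 2:
        raise ValueError("need >=2 genera for a comparison")
    for g in genera:
        if len(samples[g]) == 0:
            raise ValueError(f"genus {g!r} has no BGCs")
    comparisons = []
    for gx, gy in combinations(genera, 2):
        x = np.asarray(samples[gx], dtype=float)
        y = np.asarray(samples[gy], dtype=float)
        u, p, used = mann_whitney_u(x, y, method=method)
        comparisons.append(
            GenusComparison(
                genus_x=gx, genus_y=gy, n_x=len(x), n_y=len(y),
                mean_x=float(x.mean()), mean_y=float(y.mean()),
                median_x=float(np.median(x)), median_y=float(np.median(y)),
                u_statistic=u, p_value=p, method=used, alpha=alpha,
            )
        )
    box = {g: boxplot_stats(samples[g]) for g in genera}
    return comparisons, box


def compare_genera(
    records: Iterable[NoveltyRecord],
    genus_of: Mapping[str, str],
    alpha: float = 0.05,
    method: str = "auto",
) -> tuple[list[GenusComparison], dict[str, dict[str, object]]]:
    """Compare best-distance distributions between genera.

    ``genus_of`` maps bgc_id -> genus; every BGC's best distance enters
    its genus's sample.
    """
    samples: dict[str, list[float]] = {}
    for rec in records:
        genus = genus_of.get(rec.bgc_id)
        if genus is None:
            raise ValueError(f"no genus label for BGC {rec.bgc_id!r}")
        samples.setdefault(genus, []).append(rec.best_distance)
    return compare_distance_samples(samples, alpha=alpha, method=method)
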