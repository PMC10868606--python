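"""Pairwise distances over membership profiles and metric MDS (SMACOF).

Each BGC's membership-score profile (its vector of distances to all GCFs
in the model) describes where it sits relative to the known gene-cluster
families.  A pairwise distance matrix over these profiles, embedded in
2-D by metric multidimensional scaling, places BGCs with similar
relationships to known chemistry near each other.  Stratifying by
product category before computing distances sharpens within-type
resolution; marker size/hue scaled by the top-k mean membership distance
highlights the most novel BGCs.

The SMACOF stress-majorization loop is implemented here directly:
iterated Guttman transforms minimize raw stress
``sigma(Z) = sum_{i<j} (d_ij(Z) - delta_ij)^2`` and the reported quality
is normalized stress-1, ``sqrt(sigma / sum delta^2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import BGCRecord, MembershipMatrix
from .novelty_scoring import NoveltyRecord

logger = logging.getLogger(__name__)

#: The eight supported pairwise metrics ("l2" is kept alongside
#: "euclidean" for interface fidelity; the two are identical).
METRICS: tuple[str, ...] = (
    "euclidean",
    "cosine",
    "cityblock",
    "chebyshev",
    "l2",
    "braycurtis",
    "canberra",
    "correlation",
)

_SCIPY_NAME = {m: m for m in METRICS}
_SCIPY_NAME["l2"] = "euclidean"


@dataclass(frozen=True)
class PairwiseMatrix:
    """Symmetric, zero-diagonal, non-negative BGC x BGC distance matrix."""

    ids: tuple[str, ...]
    M: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        n = len(self.ids)
        if M.shape != (n, n):
            raise ValueError(f"matrix shape {M.shape} does not match {n} ids")
        if not np.all(np.isfinite(M)):
            raise ValueError("pairwise distances must be finite")
        if np.any(M < 0):
            raise ValueError("pairwise distances must be non-negative")
        if not np.allclose(M, M.T, atol=1e-9):
            raise ValueError("pairwise matrix must be symmetric")
        if np.any(np.abs(np.diag(M)) > 1e-12):
            raise ValueError("pairwise matrix must have a zero diagonal")
        object.__setattr__(self, "M", M)


def pairwise_distances(
    profiles: np.ndarray,
    metric: str,
    ids: Sequence[str] | None = None,
) -> PairwiseMatrix:
    """Pairwise distance matrix over row-profiles under one of the 8 metrics.

    Degenerate inputs for cosine (zero vector) and correlation
    (zero-variance vector) get the bounded convention: both members of a
    pair degenerate -> distance 0; exactly one -> distance 1; a warning
    is logged.  Canberra terms with a 0/0 denominator contribute 0.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; supported: {METRICS}")
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValueError("profiles must be a 2-D array (BGCs x GCFs)")
    n = X.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]

    degenerate = None
    if metric == "cosine":
        degenerate = np.linalg.norm(X, axis=1) == 0
    elif metric == "correlation":
        degenerate = np.std(X, axis=1) == 0

    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(X, metric=_SCIPY_NAME[metric]))

    if degenerate is not None and degenerate.any():
        logger.warning(
            "%d degenerate profile(s) under %s distance; applying "
            "0/1 convention", int(degenerate.sum()), metric,
        )
        one = np.logical_xor.outer(degenerate, degenerate)
        both = np.logical_and.outer(degenerate, degenerate)
        D[one] = 1.0
        D[both] = 0.0
    np.fill_diagonal(D, 0.0)
    # guard tiny negative round-off from the cosine/correlation formulas
    np.clip(D, 0.0, None, out=D)
    return PairwiseMatrix(ids=tuple(ids), M=D, metric_name=metric)


def pairwise_from_membership(
    matrix: MembershipMatrix,
    metric: str,
    bgc_ids: Sequence[str] | None = None,
) -> PairwiseMatrix:
    """Pairwise distances over (a subset of) a membership matrix's rows.

    Profiles span ALL GCF columns, not just the top-X hits.
    """
    sub = matrix if bgc_ids is None else matrix.subset(bgc_ids)
    return pairwise_distances(sub.values, metric, ids=sub.bgc_ids)


# ---------------------------------------------------------------------------
# SMACOF


@dataclass
class Embedding:
    """2-D coordinates plus normalized stress for one stratum/metric."""

    ids: tuple[str, ...]
    coords: np.ndarray
    stress: float  # stress-1
    metric_name: str
    stratum: str = "all"
    seed: int = 0
    n_iter: int = 0
    stress_history: list[float] = field(default_factory=list)


def raw_stress(coords: np.ndarray, delta: np.ndarray) -> float:
    """sigma(Z) = sum_{i<j} (d_ij(Z) - delta_ij)^2."""
    d = pdist(coords)
    return float(np.sum((d - squareform(delta, checks=False)) ** 2))


def stress_1(coords: np.ndarray, delta: np.ndarray) -> float:
    denom = np.sum(squareform(delta, checks=False) ** 2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(raw_stress(coords, delta) / denom))


def _torgerson(delta: np.ndarray, dims: int) -> np.ndarray:
    """Classical scaling init: double-centre squared distances, top eigs."""
    n = delta.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (delta**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    w_top = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w_top)


def _guttman(coords: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """One majorization step: Z' = (1/n) B(Z) Z."""
    n = coords.shape[0]
    d = squareform(pdist(coords), checks=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, delta / np.where(d > 0, d, 1.0), 0.0)
    B = -ratio
    np.fill_diagonal(B, 0.0)
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ coords) / n


def mds_smacof(
    P: PairwiseMatrix,
    dims: int = 2,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_restarts: int = 4,
) -> Embedding:
    """Metric MDS by SMACOF stress majorization.

    The first initialization is the classical Torgerson solution of P
    (exact for inputs that are Euclidean-embeddable in ``dims``); further
    restarts use seeded random coordinates.  Iteration stops when the
    relative raw-stress decrease falls below ``tol`` or at ``max_iter``.
    Per-iteration raw stress is non-increasing (a property of the
    Guttman transform); the best restart by final raw stress is kept.
    """
    delta = P.M
    n = delta.shape[0]
    if n == 0:
        raise ValueError("cannot embed an empty matrix")
    if n == 1:
        return Embedding(
            ids=P.ids, coords=np.zeros((1, dims)), stress=0.0,
            metric_name=P.metric_name, seed=seed, n_iter=0,
        )
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    denom = np.sum(squareform(delta, checks=False) ** 2)
    scale = delta.max() if delta.max() > 0 else 1.0
    child_seeds = np.random.SeedSequence(seed).spawn(max(n_restarts - 1, 0))

    best: tuple[float, np.ndarray, int, list[float]] | None = None
    for restart in range(n_restarts):
        if restart == 0:
            Z = _torgerson(delta, dims)
        else:
            rng = np.random.default_rng(child_seeds[restart - 1])
            Z = rng.normal(scale=scale, size=(n, dims))
        sigma = raw_stress(Z, delta)
        history = [sigma]
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            Z = _guttman(Z, delta)
            sigma_new = raw_stress(Z, delta)
            history.append(sigma_new)
            if sigma == 0.0 or (sigma - sigma_new) / sigma < tol:
                sigma = sigma_new
                break
            sigma = sigma_new
        if best is None or sigma < best[0]:
            best = (sigma, Z, n_iter, history)

    sigma, Z, n_iter, history = best
    stress = float(np.sqrt(sigma / denom)) if denom > 0 else 0.0
    return Embedding(
        ids=P.ids, coords=Z, stress=stress, metric_name=P.metric_name,
        seed=seed, n_iter=n_iter, stress_history=history,
    )


# ---------------------------------------------------------------------------
# Stratification and plot-data export

MIN_STRATUM_SIZE = 3


def stratified_embeddings(
    records: Sequence[BGCRecord],
    matrix: MembershipMatrix,
    metrics: Sequence[str] = METRICS,
    categories: Sequence[str] | None = None,
    seed: int = 0,
    min_size: int = MIN_STRATUM_SIZE,
    **smacof_kwargs,
) -> list[Embedding]:
    """One embedding per (product category, metric) stratum.

    Strata with fewer than ``min_size`` BGCs are skipped with a logged
    notice (two points embed trivially with zero information).  Each
    stratum/metric pair gets its own deterministic child seed so results
    are reproducible and independent of evaluation order.
    """
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    by_cat: dict[str, list[str]] = {}
    for rec in records:
        if rec.category is None:
            raise ValueError(f"record {rec.bgc_id} has not been classified")
        by_cat.setdefault(rec.category, []).append(rec.bgc_id)
    if categories is None:
        categories = sorted(by_cat)

    jobs = [(c, m) for c in categories for m in metrics]
    seeds = np.random.SeedSequence(seed).spawn(len(jobs))
    out: list[Embedding] = []
    for (cat, metric), child in zip(jobs, seeds):
        ids = by_cat.get(cat, [])
        if len(ids) < min_size:
            logger.info(
                "skipping stratum %r under %s: only %d BGC(s) (< %d)",
                cat, metric, len(ids), min_size,
            )
            continue
        P = pairwise_from_membership(matrix, metric, bgc_ids=ids)
        emb = mds_smacof(
            P, seed=int(child.generate_state(1)[0] % (2**31)), **smacof_kwargs
        )
        emb.stratum = cat
        out.append(emb)
    return out


def export_plot_data(
    embedding: Embedding,
    novelty: Mapping[str, NoveltyRecord],
    s_min: float = 20.0,
    s_max: float = 200.0,
    norm_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Scatter-plot table with novelty-scaled marker size and hue.

    Marker size is a linear min-max map of the top-k mean distance onto
    [s_min, s_max]; hue is the same normalized scalar in [0, 1].  By
    default normalization is stratum-local (the embedded ids); pass
    ``norm_range`` to normalize against a global range instead.  If all
    scores are equal the size is the midpoint and the hue 0.5.
    """
    missing = [b for b in embedding.ids if b not in novelty]
    if missing:
        raise ValueError(
            f"missing novelty records for {len(missing)} BGC(s), "
            f"first 10: {missing[:10]}"
        )
    scores = np.array([novelty[b].topk_mean for b in embedding.ids])
    lo, hi = norm_range if norm_range is not None else (scores.min(), scores.max())
    if hi > lo:
        t = np.clip((scores - lo) / (hi - lo), 0.0, 1.0)
    else:
        t = np.full_like(scores, 0.5)
    return pd.DataFrame(
        {
            "bgc_id": embedding.ids,
            "x": embedding.coords[:, 0],
            "y": embedding.coords[:, 1],
            "category": embedding.stratum,
            "topk_mean": scores,
            "marker_size": s_min + t * (s_max - s_min),
            "hue_value": t,
        }
    )
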