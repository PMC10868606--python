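"""Rank GCF membership distances and categorize BGC novelty.

For each BGC the membership distances to all GCFs are ranked from lowest
to highest to give the top-X hits.  A BGC whose best (lowest) distance
exceeds the clustering threshold T failed to cluster into any known
gene-cluster family and is flagged novel ("unclustered"); a clustered
BGC is further split by whether its best GCF contains a MIBiG reference
BGC (likely known chemistry) or not.  The top-k mean distance is the
continuous novelty score used to scale markers in the embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .containers import BGCRecord, MembershipMatrix, strains_per_genus

#: Novelty categories, in reporting order.
NOVELTY_CATEGORIES = ("unclustered", "clustered_mibig", "clustered_novel")

DEFAULT_THRESHOLD = 900.0
DEFAULT_TOP_X = 10
DEFAULT_TOP_K = 3


@dataclass(frozen=True)
class NoveltyRecord:
    """Per-BGC ranked hits, best distance, top-k mean and category."""

    bgc_id: str
    top_hits: tuple[tuple[str, float], ...]
    topk_mean: float
    category: str | None = None

    @property
    def best_gcf(self) -> str:
        return self.top_hits[0][0]

    @property
    def best_distance(self) -> float:
        return self.top_hits[0][1]

    @property
    def strain_id(self) -> str:
        """Strain part of a `<strain>.<region>` bgc_id."""
        return self.bgc_id.rsplit(".", 1)[0]


def rank_hits(
    matrix: MembershipMatrix, bgc_id: str, top_x: int
) -> tuple[tuple[str, float], ...]:
    """Top-X (gcf_id, distance) hits, ascending by distance.

    Ties are broken by ascending gcf_id so the ranking is deterministic
    and independent of column order.
    """
    if top_x < 1:
        raise ValueError(f"top_x must be >= 1, got {top_x}")
    if top_x > len(matrix.gcf_ids):
        raise ValueError(
            f"top_x={top_x} exceeds number of GCFs ({len(matrix.gcf_ids)})"
        )
    row = matrix.row(bgc_id)
    order = sorted(range(len(row)), key=lambda j: (row[j], matrix.gcf_ids[j]))
    return tuple((matrix.gcf_ids[j], float(row[j])) for j in order[:top_x])


def novelty_score(hits: Sequence[tuple[str, float]], k: int) -> float:
    """Arithmetic mean of the k smallest membership distances."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(hits):
        raise ValueError(f"k={k} exceeds number of ranked hits ({len(hits)})")
    return float(np.mean([d for _, d in hits[:k]]))


def categorize(
    best_gcf: str,
    best_distance: float,
    catalog: Mapping[str, bool],
    threshold: float = DEFAULT_THRESHOLD,
) -> str:
    """Three-way novelty category against threshold and MIBiG flags.

    A BGC clusters iff its best distance is <= T (strictly above the
    threshold means it failed to cluster).
    """
    if best_distance > threshold:
        return "unclustered"
    if best_gcf not in catalog:
        raise ValueError(f"best GCF {best_gcf!r} missing from catalog")
    return "clustered_mibig" if catalog[best_gcf] else "clustered_novel"


def build_novelty_records(
    matrix: MembershipMatrix,
    catalog: Mapping[str, bool],
    threshold: float = DEFAULT_THRESHOLD,
    top_x: int = DEFAULT_TOP_X,
    top_k: int = DEFAULT_TOP_K,
) -> list[NoveltyRecord]:
    """Rank, score and categorize every BGC in the matrix."""
    if not 1 <= top_k <= top_x:
        raise ValueError(f"need 1 <= top_k <= top_x, got k={top_k}, X={top_x}")
    records = []
    for bgc_id in matrix.bgc_ids:
        hits = rank_hits(matrix, bgc_id, top_x)
        records.append(
            NoveltyRecord(
                bgc_id=bgc_id,
                top_hits=hits,
                topk_mean=novelty_score(hits, top_k),
                category=categorize(hits[0][0], hits[0][1], catalog, threshold),
            )
        )
    return records


def summarize_categories(records: Iterable[NoveltyRecord]) -> dict[str, int]:
    """Counts of the three-way partition; categories always sum to total."""
    counts = {"total": 0, "unclustered": 0, "clustered_mibig": 0,
              "clustered_novel": 0}
    for rec in records:
        if rec.category not in NOVELTY_CATEGORIES:
            raise ValueError(f"record {rec.bgc_id} is not categorized")
        counts["total"] += 1
        counts[rec.category] += 1
    return counts


def per_strain_unclustered(
    records: Iterable[NoveltyRecord],
    collection: Sequence[BGCRecord],
) -> dict[str, float]:
    """Mean number of unclustered BGCs per strain, by genus.

    Every strain of each genus counts in the denominator, including
    strains with zero unclustered BGCs.
    """
    strains = strains_per_genus(collection)
    if not strains:
        raise ValueError("empty collection")
    strain_genus = {r.strain_id: r.genus for r in collection}
    counts = {g: 0 for g in strains}
    for rec in records:
        if rec.category != "unclustered":
            continue
        genus = strain_genus.get(rec.strain_id)
        if genus is None:
            raise ValueError(
                f"novelty record {rec.bgc_id} has no strain in the collection"
            )
        counts[genus] += 1
    return {g: counts[g] / len(strains[g]) for g in strains}
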