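"""Core in-memory containers shared across the pipeline.

A :class:`BGCRecord` is one antiSMASH region (one candidate biosynthetic
gene cluster) with its raw product labels and, once classified, its product
category.  A :class:`MembershipMatrix` holds the BGC x GCF membership
distances produced by querying a collection against a gene-cluster-family
model: entry (i, j) is the non-negative distance from BGC i's feature
vector to the centroid of GCF j, lower meaning more similar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BGCRecord:
    """One antiSMASH region: identity, raw product labels, optional metadata."""

    strain_id: str
    region_id: str
    products: tuple[str, ...]
    genus: str = ""
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.strain_id or not self.region_id:
            raise ValueError("strain_id and region_id must be non-empty")
        if not self.products:
            raise ValueError(
                f"{self.strain_id}.{self.region_id}: product list must be non-empty"
            )
        object.__setattr__(self, "products", tuple(self.products))

    @property
    def bgc_id(self) -> str:
        return f"{self.strain_id}.{self.region_id}"

    def with_category(self, category: str) -> "BGCRecord":
        return replace(self, category=category)


class MembershipMatrix:
    """Complete rectangular BGC x GCF membership-distance matrix.

    Distances are finite, non-negative floats; row (bgc) and column (gcf)
    ids are unique.  The matrix is the object queried, ranked and embedded
    throughout the pipeline.
    """

    def __init__(
        self,
        bgc_ids: Sequence[str],
        gcf_ids: Sequence[str],
        values: np.ndarray,
    ) -> None:
        self.bgc_ids = list(bgc_ids)
        self.gcf_ids = list(gcf_ids)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.bgc_ids), len(self.gcf_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.bgc_ids)} BGCs x {len(self.gcf_ids)} GCFs"
            )
        if len(set(self.bgc_ids)) != len(self.bgc_ids):
            raise ValueError("duplicate bgc_id in membership matrix")
        if len(set(self.gcf_ids)) != len(self.gcf_ids):
            raise ValueError("duplicate gcf_id in membership matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("membership distances must be finite")
        if np.any(values < 0):
            raise ValueError("membership distances must be non-negative")
        self.values = values
        self._row_index = {b: i for i, b in enumerate(self.bgc_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, bgc_id: str) -> np.ndarray:
        try:
            return self.values[self._row_index[bgc_id]]
        except KeyError:
            raise KeyError(f"unknown bgc_id: {bgc_id!r}") from None

    def subset(self, bgc_ids: Sequence[str]) -> "MembershipMatrix":
        idx = [self._row_index[b] for b in bgc_ids]
        return MembershipMatrix(list(bgc_ids), self.gcf_ids, self.values[idx])

    def to_long(self) -> pd.DataFrame:
        """Long-form (bgc_id, gcf_id, distance) table, row-major order."""
        n_b, n_g = self.shape
        return pd.DataFrame(
            {
                "bgc_id": np.repeat(self.bgc_ids, n_g),
                "gcf_id": np.tile(self.gcf_ids, n_b),
                "distance": self.values.ravel(),
            }
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "MembershipMatrix":
        """Build from a long-form table, validating completeness.

        Every (bgc, gcf) pair must appear exactly once with a finite
        non-negative distance.
        """
        required = {"bgc_id", "gcf_id", "distance"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"membership table must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        dup = df.duplicated(subset=["bgc_id", "gcf_id"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate membership triple for ({first.bgc_id}, {first.gcf_id})"
            )
        dist = pd.to_numeric(df["distance"], errors="coerce")
        if dist.isna().any():
            bad = df.loc[dist.isna().idxmax()]
            raise ValueError(
                f"non-numeric/NaN distance for ({bad.bgc_id}, {bad.gcf_id})"
            )
        if (dist < 0).any():
            bad = df.loc[(dist < 0).idxmax()]
            raise ValueError(
                f"negative distance for ({bad.bgc_id}, {bad.gcf_id}): "
                f"{bad.distance}"
            )
        bgc_ids = list(pd.unique(df["bgc_id"]))
        gcf_ids = list(pd.unique(df["gcf_id"]))
        if len(df) != len(bgc_ids) * len(gcf_ids):
            present = set(zip(df["bgc_id"], df["gcf_id"]))
            for b in bgc_ids:
                for g in gcf_ids:
                    if (b, g) not in present:
                        raise ValueError(
                            f"incomplete membership table: missing ({b}, {g})"
                        )
        wide = df.assign(distance=dist).pivot(
            index="bgc_id", columns="gcf_id", values="distance"
        )
        wide = wide.reindex(index=bgc_ids, columns=gcf_ids)
        return cls(bgc_ids, gcf_ids, wide.to_numpy())


def records_by_id(records: Iterable[BGCRecord]) -> dict[str, BGCRecord]:
    out: dict[str, BGCRecord] = {}
    for rec in records:
        if rec.bgc_id in out:
            raise ValueError(f"duplicate (strain, region): {rec.bgc_id}")
        out[rec.bgc_id] = rec
    return out


def genus_of_bgc(records: Iterable[BGCRecord]) -> dict[str, str]:
    return {rec.bgc_id: rec.genus for rec in records}


def strains_per_genus(records: Iterable[BGCRecord]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for rec in records:
        out.setdefault(rec.genus, set()).add(rec.strain_id)
    return out
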