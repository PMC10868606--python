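"""Sequence-similarity-network family summaries and novelty cross-tabulation.

A family assignment maps every node of a BiG-SCAPE-style similarity
network (collection BGCs plus MIBiG reference BGCs) to a family id.
Singletons — families of exactly one collection BGC with no MIBiG
co-member — are candidate novel chemical classes; families that contain
an experimentally characterized MIBiG BGC likely encode known chemistry.
Cross-tabulating family structure with the GCF-membership novelty
categories identifies BGCs that are novel both within the collection and
relative to the public terrestrial record.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

#: MIBiG accessions look like BGC0000699 (seven digits).
MIBIG_PATTERN = re.compile(r"^BGC[0-9]{7}")


def is_mibig(node_id: str) -> bool:
    return bool(MIBIG_PATTERN.match(node_id))


class FamilyAssignment:
    """BGC -> family mapping with per-family rosters and MIBiG flags."""

    def __init__(self, pairs: Iterable[tuple[str, object]]) -> None:
        self.family_of: dict[str, object] = {}
        self.rosters: dict[object, list[str]] = {}
        for node, fam in pairs:
            if node in self.family_of:
                if self.family_of[node] != fam:
                    raise ValueError(
                        f"BGC {node!r} assigned to two families: "
                        f"{self.family_of[node]!r} and {fam!r}"
                    )
                continue
            self.family_of[node] = fam
            self.rosters.setdefault(fam, []).append(node)
        if not self.rosters:
            raise ValueError("empty family assignment")

    @property
    def families(self) -> list[object]:
        return list(self.rosters)

    def collection_members(self, fam) -> list[str]:
        return [n for n in self.rosters[fam] if not is_mibig(n)]

    def mibig_members(self, fam) -> list[str]:
        return [n for n in self.rosters[fam] if is_mibig(n)]

    def has_mibig(self, fam) -> bool:
        return any(is_mibig(n) for n in self.rosters[fam])

    def collection_bgcs(self) -> list[str]:
        return [n for n in self.family_of if not is_mibig(n)]

    def is_singleton(self, fam) -> bool:
        """One collection BGC, no MIBiG co-member."""
        roster = self.rosters[fam]
        return len(roster) == 1 and not is_mibig(roster[0])


@dataclass(frozen=True)
class FamilySummary:
    n_bgcs: int
    n_singletons: int
    n_families: int
    n_families_mibig: int
    n_bgcs_in_mibig_families: int

    @property
    def n_total(self) -> int:
        """Families plus singletons."""
        return self.n_singletons + self.n_families

    @property
    def singleton_fraction(self) -> float:
        return self.n_singletons / self.n_bgcs

    @property
    def singleton_percent(self) -> float:
        return round(100.0 * self.singleton_fraction, 1)


def summarize_families(assignment: FamilyAssignment) -> FamilySummary:
    """Singleton / family / MIBiG-family counts over the network.

    MIBiG reference nodes are excluded from collection-BGC counts but do
    count towards family size, so a collection BGC paired only with a
    MIBiG node forms a (known-chemistry) family, not a singleton.
    """
    n_bgcs = 0
    n_singletons = 0
    n_families = 0
    n_families_mibig = 0
    n_in_mibig = 0
    for fam in assignment.families:
        members = assignment.collection_members(fam)
        n_bgcs += len(members)
        if assignment.is_singleton(fam):
            n_singletons += 1
        else:
            n_families += 1
            if assignment.has_mibig(fam):
                n_families_mibig += 1
                n_in_mibig += len(members)
    if n_bgcs == 0:
        raise ValueError("family assignment contains no collection BGCs")
    return FamilySummary(
        n_bgcs=n_bgcs,
        n_singletons=n_singletons,
        n_families=n_families,
        n_families_mibig=n_families_mibig,
        n_bgcs_in_mibig_families=n_in_mibig,
    )


def unique_class_estimate(summary: FamilySummary) -> int:
    """Expected number of unique chemical classes if every BGC expressed.

    Singletons plus families without a MIBiG member: each is a candidate
    distinct chemical class not yet tied to characterized chemistry.
    """
    return summary.n_singletons + (summary.n_families - summary.n_families_mibig)


@dataclass(frozen=True)
class IntegrationReport:
    summary: FamilySummary
    unique_class_estimate: int
    n_singletons_unclustered: int
    n_families_with_unclustered: int
    crosstab: dict[tuple[bool, bool], int]
    per_family_unclustered: dict[object, int]
    per_strain: pd.DataFrame | None = None


def crosstab_novelty(
    assignment: FamilyAssignment,
    categories: Mapping[str, str],
    strain_of: Mapping[str, str] | None = None,
) -> IntegrationReport:
    """Cross-tabulate network families against GCF-novelty categories.

    ``categories`` maps bgc_id -> novelty category ("unclustered",
    "clustered_mibig", "clustered_novel"); its id space must match the
    family table exactly (normalize upstream).  Returns singleton /
    unclustered overlap counts, the number of multi-member families
    containing at least one unclustered BGC, the full 2x2 crosstab of
    (is singleton, is unclustered), and optionally a per-strain table of
    (n_singletons, n_unclustered, overlap).
    """
    collection = assignment.collection_bgcs()
    missing = [b for b in collection if b not in categories]
    if missing:
        raise ValueError(
            "no novelty record for "
            f"{len(missing)} BGCs, first 10: {missing[:10]}"
        )

    crosstab = {(s, u): 0 for s in (False, True) for u in (False, True)}
    per_family_unclustered: dict[object, int] = {}
    n_singletons_unclustered = 0
    n_families_with_unclustered = 0
    for fam in assignment.families:
        members = assignment.collection_members(fam)
        if not members:
            continue
        singleton = assignment.is_singleton(fam)
        n_uncl = sum(categories[b] == "unclustered" for b in members)
        for b in members:
            crosstab[(singleton, categories[b] == "unclustered")] += 1
        if singleton:
            n_singletons_unclustered += n_uncl
        else:
            per_family_unclustered[fam] = n_uncl
            if n_uncl > 0:
                n_families_with_unclustered += 1

    per_strain = None
    if strain_of is not None:
        rows: dict[str, dict[str, int]] = {}
        for b in collection:
            strain = strain_of.get(b)
            if strain is None:
                raise ValueError(f"no strain label for BGC {b!r}")
            row = rows.setdefault(
                strain, {"n_singletons": 0, "n_unclustered": 0, "overlap": 0}
            )
            singleton = assignment.is_singleton(assignment.family_of[b])
            uncl = categories[b] == "unclustered"
            row["n_singletons"] += singleton
            row["n_unclustered"] += uncl
            row["overlap"] += singleton and uncl
        per_strain = (
            pd.DataFrame.from_dict(rows, orient="index")
            .rename_axis("strain_id")
            .reset_index()
            .sort_values("strain_id", ignore_index=True)
        )

    summary = summarize_families(assignment)
    return IntegrationReport(
        summary=summary,
        unique_class_estimate=unique_class_estimate(summary),
        n_singletons_unclustered=n_singletons_unclustered,
        n_families_with_unclustered=n_families_with_unclustered,
        crosstab=crosstab,
        per_family_unclustered=per_family_unclustered,
        per_strain=per_strain,
    )
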