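"""Synthetic BGC collections with the statistical structure the pipeline assumes.

The generator emulates a genome-mining survey of a marine actinomycete
collection: a few genera of strains, 13-34 BGC regions per genome, a
realistic product-type mix, and a BGC x GCF membership-distance matrix
in which each BGC has one planted "home" family.  Best (home) distances
follow a genus-located log-normal — membership distances are
non-negative and right-skewed, and parameterizing the location by the
median makes genus shifts directly comparable to reported medians.
Distances to all other GCFs come from a far background distribution
truncated below at the home distance, so the planted home family is
always the top hit and ground truth is unambiguous for recovery tests.

``reference_fixture`` is a fully deterministic 779-BGC collection over
38 strains whose novelty partition, similarity-network family structure
and cross-tabulation reproduce a fixed set of benchmark marginal counts
exactly; only the counts are contractual, the individual distances are
arbitrary deterministic values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import BGCRecord, MembershipMatrix
from .network_integration import FamilyAssignment
from .product_typing import CATEGORIES

# Default product-category mix: terpenes, non-PKS/NRPS hybrids and RiPPs
# dominate (156/146/129 of 779 in the kind of collection emulated); the
# remainder is spread plausibly over the other seven categories.
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "Terpene": 156 / 779,
    "Hybrid-other": 146 / 779,
    "RiPP": 129 / 779,
    "Other": 80 / 779,
    "NRPS": 60 / 779,
    "PKS-I": 55 / 779,
    "PKS/NRPS-hybrid": 50 / 779,
    "PKS-other": 40 / 779,
    "Siderophore": 38 / 779,
    "Saccharide": 25 / 779,
}

# Representative antiSMASH v5 label sets per category; lists are cycled
# so repeated draws vary the raw labels (RiPP subclasses especially).
_LABEL_CHOICES: dict[str, list[tuple[str, ...]]] = {
    "Terpene": [("terpene",)],
    "RiPP": [
        ("bacteriocin",),
        ("lanthipeptide",),
        ("LAP",),
        ("thiopeptide",),
        ("TfuA-related",),
    ],
    "NRPS": [("NRPS",), ("NRPS-like",)],
    "PKS-I": [("T1PKS",)],
    "PKS-other": [("T2PKS",), ("T3PKS",), ("transAT-PKS",)],
    "PKS/NRPS-hybrid": [("T1PKS", "NRPS")],
    "Hybrid-other": [
        ("T2PKS", "lanthipeptide"),
        ("T1PKS", "NRPS", "terpene"),
        ("NRPS", "terpene"),
        ("siderophore", "lanthipeptide"),
        ("NRPS", "oligosaccharide", "terpene"),
    ],
    "Siderophore": [("siderophore",)],
    "Saccharide": [("oligosaccharide",), ("amglyccycl",)],
    "Other": [("butyrolactone",), ("ectoine",), ("arylpolyene",)],
}


def labels_for(category: str, idx: int) -> tuple[str, ...]:
    """Deterministic raw product labels for a category (cycled by idx)."""
    choices = _LABEL_CHOICES[category]
    return choices[idx % len(choices)]


@dataclass(frozen=True)
class GenusSpec:
    """One genus: strain count and median best (home) distance."""

    name: str
    n_strains: int
    median_best: float

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError(f"genus {self.name!r}: n_strains must be >= 1")
        if self.median_best <= 0:
            raise ValueError(f"genus {self.name!r}: median_best must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults emulate the surveyed collection: 29 + 6 strains in two
    genera with best-distance medians 908 and 1004, 13-34 BGCs per
    genome, log-normal home distances (log-sd ``home_sigma`` 0.5,
    matching the observed mean/median ratios), a far background
    (median 2500) for non-home families, and clustering threshold 900.
    """

    genera: tuple[GenusSpec, ...] = (
        GenusSpec("Micromonospora", 29, 908.0),
        GenusSpec("Micromonospora_E", 6, 1004.0),
    )
    bgc_range: tuple[int, int] = (13, 34)
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    n_gcfs: int = 60
    mibig_fraction: float = 0.12
    home_sigma: float = 0.5
    background_median: float = 2500.0
    background_sigma: float = 0.35
    type_coherence: float = 0.5
    threshold: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genera:
            raise ValueError("genera list must be non-empty")
        lo, hi = self.bgc_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid bgc_range {self.bgc_range}")
        total = sum(self.category_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category weights sum to {total}, not 1")
        unknown = set(self.category_weights) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in weights: {sorted(unknown)}")
        if self.home_sigma <= 0 or self.background_sigma <= 0:
            raise ValueError("spreads must be > 0")
        if self.n_gcfs < 2:
            raise ValueError("n_gcfs must be >= 2")
        if not 0.0 <= self.mibig_fraction <= 1.0:
            raise ValueError("mibig_fraction must be in [0, 1]")
        if not 0.0 <= self.type_coherence <= 1.0:
            raise ValueError("type_coherence must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth: home GCF, home distance and novelty flag."""

    home_gcf: dict[str, str]
    home_distance: dict[str, float]
    novel: dict[str, bool]
    genus_location: dict[str, float]


def draw_best_distances(
    median: float, sigma: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal best distances with the given median and log-sd."""
    return rng.lognormal(mean=np.log(median), sigma=sigma, size=size)


def generate_collection(
    config: SimulationConfig,
) -> tuple[list[BGCRecord], SyntheticTruth]:
    """Strains, regions, categories and planted truth (seeded, reproducible).

    Per-strain BGC counts are uniform over ``bgc_range``; categories are
    drawn by ``category_weights``; each BGC gets a home GCF (with
    probability ``type_coherence`` its category's anchor GCF, otherwise
    uniform) and a home distance from its genus's log-normal.  The
    novelty flag is home distance > threshold.
    """
    rng = np.random.default_rng(config.seed)
    cats = list(config.category_weights)
    weights = np.array([config.category_weights[c] for c in cats])
    weights = weights / weights.sum()
    gcf_ids = [f"GCF{i + 1:05d}" for i in range(config.n_gcfs)]
    # one anchor GCF per category, spread over the model
    anchors = {
        c: gcf_ids[(i * max(config.n_gcfs // len(cats), 1)) % config.n_gcfs]
        for i, c in enumerate(cats)
    }

    records: list[BGCRecord] = []
    truth = SyntheticTruth(
        home_gcf={}, home_distance={}, novel={},
        genus_location={g.name: g.median_best for g in config.genera},
    )
    lo, hi = config.bgc_range
    for genus in config.genera:
        for s in range(genus.n_strains):
            strain_id = f"{genus.name}-S{s + 1:03d}"
            n_bgc = int(rng.integers(lo, hi + 1))
            cat_draw = rng.choice(len(cats), size=n_bgc, p=weights)
            homes = draw_best_distances(
                genus.median_best, config.home_sigma, n_bgc, rng
            )
            for r in range(n_bgc):
                cat = cats[cat_draw[r]]
                rec = BGCRecord(
                    strain_id=strain_id,
                    region_id=f"region{r + 1:03d}",
                    products=labels_for(cat, int(rng.integers(0, 1000))),
                    genus=genus.name,
                    category=cat,
                )
                if rng.random() < config.type_coherence:
                    home = anchors[cat]
                else:
                    home = gcf_ids[int(rng.integers(0, config.n_gcfs))]
                records.append(rec)
                truth.home_gcf[rec.bgc_id] = home
                truth.home_distance[rec.bgc_id] = float(homes[r])
                truth.novel[rec.bgc_id] = bool(homes[r] > config.threshold)
    return records, truth


def generate_membership(
    collection: Sequence[BGCRecord],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[MembershipMatrix, dict[str, bool]]:
    """Membership matrix honouring the planted truth, plus a GCF catalog.

    The home column carries the planted home distance; all other columns
    draw i.i.d. from the background log-normal, truncated below so every
    non-home distance strictly exceeds the home distance.  A
    ``mibig_fraction`` of GCFs is flagged as containing a MIBiG member.
    """
    max_home_median = max(g.median_best for g in config.genera)
    if config.background_median <= max_home_median:
        raise ValueError(
            "background_median must exceed every genus median "
            f"({config.background_median} <= {max_home_median})"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(2)[1]
    )
    gcf_ids = [f"GCF{i + 1:05d}" for i in range(config.n_gcfs)]
    needed = set(truth.home_gcf.values())
    if not needed.issubset(gcf_ids):
        raise ValueError("n_gcfs smaller than the planted home GCFs require")
    col = {g: j for j, g in enumerate(gcf_ids)}
    n = len(collection)
    values = rng.lognormal(
        mean=np.log(config.background_median),
        sigma=config.background_sigma,
        size=(n, config.n_gcfs),
    )
    bgc_ids = [rec.bgc_id for rec in collection]
    for i, b in enumerate(bgc_ids):
        home = truth.home_distance[b]
        # truncate the background strictly above the home distance
        np.maximum(values[i], np.nextafter(home, np.inf), out=values[i])
        values[i, col[truth.home_gcf[b]]] = home
    matrix = MembershipMatrix(bgc_ids, gcf_ids, values)
    n_mibig = round(config.mibig_fraction * config.n_gcfs)
    mibig = set(rng.choice(config.n_gcfs, size=n_mibig, replace=False))
    catalog = {g: (j in mibig) for j, g in enumerate(gcf_ids)}
    return matrix, catalog


def generate_families(
    collection: Sequence[BGCRecord],
    truth: SyntheticTruth,
    catalog: Mapping[str, bool] | None = None,
) -> FamilyAssignment:
    """Similarity-network families implied by the planted home GCFs.

    BGCs sharing a home GCF form one family; unique homes become
    singletons.  Families whose home GCF is flagged as MIBiG-containing
    receive one synthetic MIBiG reference node.
    """
    by_home: dict[str, list[str]] = {}
    for rec in collection:
        by_home.setdefault(truth.home_gcf[rec.bgc_id], []).append(rec.bgc_id)
    pairs: list[tuple[str, str]] = []
    mibig_counter = 0
    for i, (home, members) in enumerate(sorted(by_home.items())):
        fam = f"FAM{i + 1:04d}"
        for b in members:
            pairs.append((b, fam))
        if catalog is not None and catalog.get(home, False) and len(members) >= 2:
            mibig_counter += 1
            pairs.append((f"BGC{mibig_counter:07d}", fam))
    return FamilyAssignment(pairs)


# ---------------------------------------------------------------------------
# Deterministic benchmark fixture
#
# 779 BGCs over 38 strains (29 + 6 + 3 across four genera); the novelty
# partition is 413 unclustered / 94 clustered-MIBiG / 272 clustered-novel;
# the network has 196 singletons and 132 multi-member families of which 16
# contain a MIBiG node (83 collection BGCs; the other 116 families hold
# 500); 148 of the singletons and 265 family members are unclustered,
# giving 108 families with at least one unclustered member.  Strain
# WMMD406 carries the 17-singletons / 21-unclustered / 16-overlap pattern.


def _fixture_strains() -> list[tuple[str, str, int, int]]:
    """(strain_id, genus, n_bgcs, n_unclustered) for the 38 strains."""
    strains = []
    for i in range(29):
        n = 20 if i < 19 else 19
        u = 11 if i == 0 else 10
        strains.append((f"MICRO{i + 1:03d}", "Micromonospora", n, u))
    strains += [
        ("WMMD406", "Micromonospora_E", 25, 21),
        ("MICROE01", "Micromonospora_E", 25, 14),
        ("MICROE02", "Micromonospora_E", 25, 14),
        ("MICROE03", "Micromonospora_E", 24, 14),
        ("MICROE04", "Micromonospora_E", 24, 13),
        ("MICROE05", "Micromonospora_E", 24, 13),
        ("ASANOA01", "Asanoa", 13, 11),
        ("PLANTA01", "Plantactinospora", 15, 11),
        ("MICROG01", "Micromonospora_G", 34, 11),
    ]
    return strains


def _fixture_categories(n: int) -> list[str]:
    """Exact category multiset scrambled by a stride coprime to n."""
    counts = [
        ("Terpene", 156), ("Hybrid-other", 146), ("RiPP", 129),
        ("Other", 80), ("NRPS", 60), ("PKS-I", 55),
        ("PKS/NRPS-hybrid", 50), ("PKS-other", 40),
        ("Siderophore", 38), ("Saccharide", 25),
    ]
    flat: list[str] = []
    for cat, c in counts:
        flat.extend([cat] * c)
    assert len(flat) == n
    return [flat[(i * 100) % n] for i in range(n)]  # gcd(100, 779) = 1


def reference_fixture() -> tuple[
    list[BGCRecord], MembershipMatrix, dict[str, bool], FamilyAssignment
]:
    """Deterministic 779-BGC benchmark collection (no RNG involved)."""
    strains = _fixture_strains()
    cats = _fixture_categories(779)

    records: list[BGCRecord] = []
    unclustered_flags: list[bool] = []
    i = 0
    for strain_id, genus, n_bgc, n_uncl in strains:
        for r in range(n_bgc):
            cat = cats[i]
            records.append(
                BGCRecord(
                    strain_id=strain_id,
                    region_id=f"region{r + 1:03d}",
                    products=labels_for(cat, i),
                    genus=genus,
                    category=cat,
                )
            )
            unclustered_flags.append(r < n_uncl)
            i += 1

    bgc_ids = [rec.bgc_id for rec in records]
    uncl = {b for b, f in zip(bgc_ids, unclustered_flags) if f}
    wmmd = [b for b in bgc_ids if b.startswith("WMMD406.")]
    wmmd_uncl = [b for b in wmmd if b in uncl]
    wmmd_clu = [b for b in wmmd if b not in uncl]

    # --- singleton / family allocation -----------------------------------
    singleton_uncl = wmmd_uncl[:16]
    fam_uncl_queue = wmmd_uncl[16:]  # 5 family-bound unclustered BGCs
    singleton_clu = wmmd_clu[:1]
    fam_clu_queue = wmmd_clu[1:]  # 3 family-bound clustered BGCs

    other_uncl = [b for b in bgc_ids if b in uncl and not b.startswith("WMMD406.")]
    other_clu = [b for b in bgc_ids if b not in uncl and not b.startswith("WMMD406.")]
    singleton_uncl += other_uncl[:132]  # 148 unclustered singletons total
    fam_uncl_queue += other_uncl[132:]  # 265 unclustered family members
    singleton_clu += other_clu[:47]  # 48 clustered singletons total
    fam_clu_queue += other_clu[47:]  # 318 clustered family members

    # family plan: (size, n_unclustered, has_mibig)
    plan = (
        [(5, 0, True)] * 13 + [(6, 0, True)] * 3   # 16 MIBiG families, 83 BGCs
        + [(4, 0, False)] * 8                       # families with no novelty
        + [(4, 2, False)] * 59 + [(4, 3, False)] * 13 + [(5, 3, False)] * 36
    )
    assert len(plan) == 132
    assert sum(size for size, _, _ in plan) == 583
    assert sum(nu for _, nu, _ in plan) == 265

    pairs: list[tuple[str, str]] = []
    ui = ci = 0
    mibig_n = 0
    for f, (size, n_u, has_mibig) in enumerate(plan):
        fam = f"FAM{f + 1:04d}"
        for b in fam_uncl_queue[ui:ui + n_u]:
            pairs.append((b, fam))
        ui += n_u
        for b in fam_clu_queue[ci:ci + (size - n_u)]:
            pairs.append((b, fam))
        ci += size - n_u
        if has_mibig:
            mibig_n += 1
            pairs.append((f"BGC{mibig_n:07d}", fam))
    assert ui == len(fam_uncl_queue) and ci == len(fam_clu_queue)
    for s, b in enumerate(singleton_uncl + singleton_clu):
        pairs.append((b, f"SING{s + 1:04d}"))
    families = FamilyAssignment(pairs)

    # --- membership matrix and GCF catalog -------------------------------
    # clustered-MIBiG BGCs: the 83 members of MIBiG families plus the
    # first 11 clustered singletons -> 94
    mibig_best = {
        b
        for f, (size, n_u, has_mibig) in enumerate(plan) if has_mibig
        for b in families.collection_members(f"FAM{f + 1:04d}")
    }
    mibig_best |= set(singleton_clu[:11])

    mibig_gcfs = [f"MGCF{i + 1:03d}" for i in range(4)]
    other_gcfs = [f"NGCF{i + 1:03d}" for i in range(20)]
    gcf_ids = mibig_gcfs + other_gcfs
    catalog = {g: g.startswith("MGCF") for g in gcf_ids}

    n = len(bgc_ids)
    values = np.zeros((n, len(gcf_ids)))
    col = {g: j for j, g in enumerate(gcf_ids)}
    for i, b in enumerate(bgc_ids):
        if b in uncl:
            best = 905.0 + (i * 37) % 600
            best_gcf = other_gcfs[i % len(other_gcfs)]
        else:
            best = 420.0 + (i * 23) % 480  # <= 899
            best_gcf = (
                mibig_gcfs[i % len(mibig_gcfs)] if b in mibig_best
                else other_gcfs[i % len(other_gcfs)]
            )
        for j in range(len(gcf_ids)):
            values[i, j] = best + 900.0 + (i * 7 + j * 13) % 400
        values[i, col[best_gcf]] = best

    matrix = MembershipMatrix(bgc_ids, gcf_ids, values)
    return records, matrix, catalog, families
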