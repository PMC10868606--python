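"""Product-type classification of antiSMASH regions.

Each region is assigned to exactly one of ten product categories.  Raw
antiSMASH product labels (``T1PKS``, ``lanthipeptide``, ...) are first
resolved to a base chemistry class; a region with a single distinct base
class takes that class's category, the exact pair {Type-1 PKS, NRPS}
becomes the classical PKS/NRPS hybrid, and any other combination of two
or more distinct base classes falls into the non-PKS/NRPS hybrid
super-category ("Hybrid-other") — a catch-all for chemically mixed
clusters that are traditionally underexplored.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

from .containers import BGCRecord

logger = logging.getLogger(__name__)

#: The ten product categories used for stratification.
CATEGORIES: tuple[str, ...] = (
    "Terpene",
    "RiPP",
    "NRPS",
    "PKS-I",
    "PKS-other",
    "PKS/NRPS-hybrid",
    "Hybrid-other",
    "Siderophore",
    "Saccharide",
    "Other",
)

#: Base chemistry classes a single product label can resolve to.
BASE_CLASSES: tuple[str, ...] = (
    "PKS-I",
    "PKS-other",
    "NRPS",
    "RiPP",
    "Terpene",
    "Siderophore",
    "Saccharide",
    "Other",
)

# Default antiSMASH v5 label -> base class map (keys matched
# case-insensitively).  Follows the BiG-SCAPE class scheme except that
# siderophores get their own class.
_DEFAULT_LABEL_MAP: dict[str, str] = {
    # modular type-1 polyketide synthases
    "t1pks": "PKS-I",
    # other PKS
    "t2pks": "PKS-other",
    "t3pks": "PKS-other",
    "transat-pks": "PKS-other",
    "transatpks": "PKS-other",
    "transat-pks-like": "PKS-other",
    "hgle-ks": "PKS-other",
    "ppys-ks": "PKS-other",
    "pks-like": "PKS-other",
    "otherks": "PKS-other",
    # non-ribosomal peptide synthetases
    "nrps": "NRPS",
    "nrps-like": "NRPS",
    "thioamide-nrp": "NRPS",
    "cdps": "NRPS",
    # RiPPs
    "bacteriocin": "RiPP",
    "lanthipeptide": "RiPP",
    "lantipeptide": "RiPP",
    "lap": "RiPP",
    "thiopeptide": "RiPP",
    "tfua-related": "RiPP",
    "lassopeptide": "RiPP",
    "linaridin": "RiPP",
    "cyanobactin": "RiPP",
    "glycocin": "RiPP",
    "sactipeptide": "RiPP",
    "bottromycin": "RiPP",
    "head_to_tail": "RiPP",
    "microviridin": "RiPP",
    "proteusin": "RiPP",
    "lipolanthine": "RiPP",
    "ranthipeptide": "RiPP",
    "ripp-like": "RiPP",
    "fungal-ripp": "RiPP",
    # terpenes
    "terpene": "Terpene",
    # siderophores
    "siderophore": "Siderophore",
    # saccharides
    "oligosaccharide": "Saccharide",
    "amglyccycl": "Saccharide",
    "saccharide": "Saccharide",
    "cf_saccharide": "Saccharide",
    # everything else antiSMASH v5 emits
    "arylpolyene": "Other",
    "ectoine": "Other",
    "butyrolactone": "Other",
    "melanin": "Other",
    "nucleoside": "Other",
    "phosphonate": "Other",
    "phenazine": "Other",
    "furan": "Other",
    "indole": "Other",
    "ladderane": "Other",
    "pufa": "Other",
    "resorcinol": "Other",
    "hserlactone": "Other",
    "betalactone": "Other",
    "blactam": "Other",
    "acyl_amino_acids": "Other",
    "fused": "Other",
    "other": "Other",
    "cf_putative": "Other",
    "cf_fatty_acid": "Other",
}


class BaseClassMap:
    """Case-insensitive map from raw product labels to base classes.

    Total by construction: unknown labels resolve to ``Other`` with a
    logged warning (once per label), never a crash.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        source = mapping if mapping is not None else _DEFAULT_LABEL_MAP
        self._map: dict[str, str] = {}
        for label, cls in source.items():
            if cls not in BASE_CLASSES:
                raise ValueError(f"unknown base class {cls!r} for label {label!r}")
            self._map[label.lower()] = cls
        self._warned: set[str] = set()

    def resolve(self, label: str) -> str:
        cls = self._map.get(label.lower())
        if cls is None:
            if label.lower() not in self._warned:
                logger.warning(
                    "unknown product label %r; mapping to 'Other'", label
                )
                self._warned.add(label.lower())
            return "Other"
        return cls

    @classmethod
    def from_tsv(cls, path) -> "BaseClassMap":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        if not {"label", "base_class"}.issubset(df.columns):
            raise ValueError(
                "base-class map TSV needs columns 'label' and 'base_class'"
            )
        return cls(dict(zip(df["label"], df["base_class"])))


_default_map = BaseClassMap()


def classify_region(
    products: Sequence[str], mapping: BaseClassMap | None = None
) -> str:
    """Assign a product category to one region from its raw product labels.

    Labels are collapsed to a set of distinct base classes first, so the
    result is invariant to label order and duplication.  The hybrid rule:
    a region whose distinct base classes are exactly {PKS-I, NRPS} is a
    PKS/NRPS hybrid; any other combination of two or more classes is a
    non-PKS/NRPS hybrid.
    """
    if not products:
        raise ValueError("cannot classify a region with no product labels")
    mapping = mapping or _default_map
    classes = {mapping.resolve(p) for p in products}
    if len(classes) == 1:
        return classes.pop()
    if classes == {"PKS-I", "NRPS"}:
        return "PKS/NRPS-hybrid"
    return "Hybrid-other"


def classify_records(
    records: Iterable[BGCRecord], mapping: BaseClassMap | None = None
) -> list[BGCRecord]:
    """Return records with their category field filled in."""
    return [r.with_category(classify_region(r.products, mapping)) for r in records]


def tally_categories(
    records: Iterable[BGCRecord],
) -> tuple[dict[str, int], dict[str, float]]:
    """Count records per category; returns (counts, fractions).

    All ten categories appear in the output, zero-filled.  Fractions sum
    to 1 (or are all zero for an empty input).
    """
    counts = {c: 0 for c in CATEGORIES}
    n = 0
    for rec in records:
        if rec.category is None:
            raise ValueError(f"record {rec.bgc_id} has not been classified")
        counts[rec.category] = counts.get(rec.category, 0) + 1
        n += 1
    fractions = {c: (counts[c] / n if n else 0.0) for c in counts}
    return counts, fractions


def tally_ripp_subclasses(
    records: Iterable[BGCRecord], mapping: BaseClassMap | None = None
) -> tuple[Counter, int]:
    """Count RiPP subclass labels across all RiPP-bearing regions.

    A region containing any label that resolves to the RiPP base class
    contributes each of its distinct RiPP labels once (verbatim, as
    emitted by antiSMASH).  Returns (per-label counts, number of
    RiPP-bearing regions).  Note the two counting universes differ: a
    hybrid region counts here but is not categorized "RiPP".
    """
    mapping = mapping or _default_map
    counts: Counter = Counter()
    n_regions = 0
    for rec in records:
        ripp_labels = {
            p for p in rec.products if mapping.resolve(p) == "RiPP"
        }
        if ripp_labels:
            n_regions += 1
            counts.update(sorted(ripp_labels))
    return counts, n_regions
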