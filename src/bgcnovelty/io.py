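"""Readers and writers for the file formats the pipeline touches.

GenBank region files (antiSMASH output), long-form membership-distance
TSVs (or the equivalent SQLite report), BiG-SCAPE-style family tables,
GCF catalogs, flat region tables, novelty tables, TOML run configs and
JSON run manifests.  All TSVs are tab-separated UTF-8 with a mandatory
header row and ``.`` decimals, so outputs are bit-exact interchange.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import sqlite3
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .containers import BGCRecord, MembershipMatrix
from .network_integration import FamilyAssignment
from .novelty_scoring import NoveltyRecord

logger = logging.getLogger(__name__)

#: antiSMASH names region files `<strain>.region<NNN>.gbk`
_FNAME_RE = re.compile(r"^(?P<strain>.+?)\.(?P<region>region\d+)(?:\.gbk)?$", re.I)

_SQLITE_MAGIC = b"SQLite format 3\x00"


@dataclass(frozen=True)
class RegionSource:
    """One antiSMASH region file: ids plus ordered raw product labels."""

    path: str
    strain_id: str
    region_id: str
    products: tuple[str, ...]

    def to_record(self, genus: str = "") -> BGCRecord:
        return BGCRecord(
            strain_id=self.strain_id,
            region_id=self.region_id,
            products=self.products,
            genus=genus,
        )


def read_antismash_regions(paths: Sequence[str | Path]) -> list[RegionSource]:
    """Parse antiSMASH region GenBank files into RegionSource objects.

    Product labels are taken verbatim and in order from the ``product``
    qualifiers of ``region`` (or legacy ``cluster``) features.  Strain
    and region ids come from the `<strain>.region<NNN>.gbk` filename
    convention, falling back to the record LOCUS plus a counter.
    """
    sources: list[RegionSource] = []
    seen: set[tuple[str, str]] = set()
    fallback_counter: dict[str, int] = {}
    for path in paths:
        path = Path(path)
        try:
            record = next(SeqIO.parse(str(path), "genbank"))
        except Exception as exc:
            raise ValueError(f"unparseable GenBank file {path}: {exc}") from exc
        products: list[str] = []
        for feat in record.features:
            if feat.type in ("region", "cluster"):
                products.extend(feat.qualifiers.get("product", []))
        if not products:
            raise ValueError(
                f"{path}: no region/cluster feature with a product qualifier"
            )
        m = _FNAME_RE.match(path.stem if path.suffix == ".gbk" else path.name)
        if m:
            strain, region = m.group("strain"), m.group("region").lower()
        else:
            strain = record.name or path.stem
            fallback_counter[strain] = fallback_counter.get(strain, 0) + 1
            region = f"region{fallback_counter[strain]:03d}"
        key = (strain, region)
        if key in seen:
            raise ValueError(f"duplicate (strain, region) {key} from {path}")
        seen.add(key)
        sources.append(
            RegionSource(
                path=str(path), strain_id=strain, region_id=region,
                products=tuple(products),
            )
        )
    return sources


# ---------------------------------------------------------------------------
# Membership matrix


def read_membership_long(path: str | Path) -> MembershipMatrix:
    """Read a long-form (bgc_id, gcf_id, distance) table; TSV or SQLite.

    The TSV is the canonical format.  SQLite support is read-only: the
    first table exposing bgc_id/gcf_id/distance columns is used.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(16)
    if head == _SQLITE_MAGIC:
        df = _membership_from_sqlite(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"bgc_id": str, "gcf_id": str})
    return MembershipMatrix.from_long(df)


def _membership_from_sqlite(path: Path) -> pd.DataFrame:
    with sqlite3.connect(path) as con:
        tables = [
            r[0]
            for r in con.execute(
                "SELECT name FROM sqlite_master WHERE type='table'"
            )
        ]
        for table in tables:
            cols = {r[1] for r in con.execute(f"PRAGMA table_info({table})")}
            if {"bgc_id", "gcf_id", "distance"}.issubset(cols):
                return pd.read_sql_query(
                    f"SELECT bgc_id, gcf_id, distance FROM {table}", con
                ).astype({"bgc_id": str, "gcf_id": str})
    raise ValueError(
        f"{path}: no table with columns bgc_id, gcf_id, distance"
    )


def write_membership_long(matrix: MembershipMatrix, path: str | Path) -> None:
    matrix.to_long().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Family table and GCF catalog


def read_family_table(
    path: str | Path, strip_gbk: bool = True
) -> FamilyAssignment:
    """BiG-SCAPE-style clustering table: bgc_id -> family_id.

    MIBiG reference nodes are recognized by the ``BGC<7 digits>``
    accession prefix.  Node names ending in ``.gbk`` are normalized by
    stripping the suffix (BiG-SCAPE decorates names with it).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty family table")
    if not {"bgc_id", "family_id"}.issubset(df.columns):
        raise ValueError(
            f"{path}: family table needs columns bgc_id, family_id"
        )
    names = df["bgc_id"]
    if strip_gbk:
        names = names.str.replace(r"\.gbk$", "", regex=True)
    return FamilyAssignment(zip(names, df["family_id"]))


def write_family_table(
    assignment: FamilyAssignment, path: str | Path
) -> None:
    rows = [(n, f) for n, f in assignment.family_of.items()]
    pd.DataFrame(rows, columns=["bgc_id", "family_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gcf_catalog(path: str | Path) -> dict[str, bool]:
    """GCF catalog TSV: gcf_id, has_mibig (0/1 or true/false)."""
    df = pd.read_csv(path, sep="\t", dtype={"gcf_id": str})
    if not {"gcf_id", "has_mibig"}.issubset(df.columns):
        raise ValueError(f"{path}: catalog needs columns gcf_id, has_mibig")
    flags = (
        df["has_mibig"]
        .astype(str)
        .str.lower()
        .map({"1": True, "true": True, "0": False, "false": False})
    )
    if flags.isna().any():
        bad = df.loc[flags.isna().idxmax()]
        raise ValueError(f"unrecognized has_mibig value: {bad.has_mibig!r}")
    return dict(zip(df["gcf_id"], flags))


def write_gcf_catalog(catalog: Mapping[str, bool], path: str | Path) -> None:
    pd.DataFrame(
        {"gcf_id": list(catalog), "has_mibig": [int(v) for v in catalog.values()]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Flat region table (strain, region, genus, products) and novelty table


def write_regions_table(
    records: Iterable[BGCRecord], path: str | Path
) -> None:
    rows = [
        {
            "bgc_id": r.bgc_id,
            "strain_id": r.strain_id,
            "region_id": r.region_id,
            "genus": r.genus,
            "products": ";".join(r.products),
            "category": r.category or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_regions_table(path: str | Path) -> list[BGCRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"strain_id", "region_id", "products"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: region table needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            BGCRecord(
                strain_id=row.strain_id,
                region_id=row.region_id,
                products=tuple(row.products.split(";")),
                genus=getattr(row, "genus", ""),
                category=(getattr(row, "category", "") or None),
            )
        )
    if len({r.bgc_id for r in records}) != len(records):
        raise ValueError(f"{path}: duplicate (strain, region) ids")
    return records


def write_novelty_table(
    records: Iterable[NoveltyRecord], path: str | Path
) -> None:
    rows = [
        {
            "bgc_id": r.bgc_id,
            "best_gcf": r.best_gcf,
            "best_distance": r.best_distance,
            "topk_mean": r.topk_mean,
            "category": r.category,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_novelty_table(path: str | Path) -> list[NoveltyRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"bgc_id": str, "best_gcf": str})
    required = {"bgc_id", "best_gcf", "best_distance", "topk_mean", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: novelty table needs columns {sorted(required)}")
    return [
        NoveltyRecord(
            bgc_id=row.bgc_id,
            top_hits=((row.best_gcf, float(row.best_distance)),),
            topk_mean=float(row.topk_mean),
            category=row.category,
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Run configuration and manifest


@dataclass
class RunConfig:
    """Pipeline-wide knobs; flags override TOML-supplied defaults."""

    threshold: float = 900.0
    top_x: int = 10
    top_k: int = 3
    metrics: tuple[str, ...] = ()
    seed: int = 0
    mds_max_iter: int = 300
    mds_tol: float = 1e-6
    mds_restarts: int = 4
    membership: str | None = None
    catalog: str | None = None
    regions: str | None = None
    families: str | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not 1 <= self.top_k <= self.top_x:
            raise ValueError("need 1 <= top_k <= top_x")


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    section = data.get("run", data)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "metrics" in section:
        section["metrics"] = tuple(section["metrics"])
    return RunConfig(**section)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: Mapping[str, object],
    inputs: Sequence[str | Path] = (),
) -> None:
    """JSON run manifest: config, seed, input checksums, RNG identity."""
    manifest = {
        "config": {k: v for k, v in config.items()},
        "inputs": {str(p): sha256_of(p) for p in inputs},
        "rng": "numpy.random.default_rng (PCG64)",
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
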