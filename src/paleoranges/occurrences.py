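"""Occurrence tables: parsing, filtering, epoch binning, midpoints.

Occurrence records are fossil/extant locality records with present-day and
palaeorotated coordinates, an age interval in Ma, and a habitat flag.  The
table is a thin wrapper around a pandas DataFrame with a fixed schema,
accepting Paleobiology-Database-flavoured headers (lat/lng/paleolat/
paleolng/min_ma/max_ma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeoPoint, geographic_midpoint, normalize_lon

logger = logging.getLogger(__name__)

#: tokens marking open-nomenclature identifications ("Crocodylus sp." etc.)
OPEN_NOMENCLATURE_TOKENS = (" sp.", " cf.", " aff.", " indet.")

COLUMNS = ["taxon", "lat", "lng", "paleolat", "paleolng", "min_ma", "max_ma", "habitat"]

_HEADER_ALIASES = {
    "taxon": ["taxon", "accepted_name", "species", "name"],
    "lat": ["lat", "latitude"],
    "lng": ["lng", "lon", "longitude"],
    "paleolat": ["paleolat", "palaeolat", "paleolatitude"],
    "paleolng": ["paleolng", "paleolon", "palaeolng", "paleolongitude"],
    "min_ma": ["min_ma", "minma", "min_age"],
    "max_ma": ["max_ma", "maxma", "max_age"],
    "habitat": ["habitat", "taxon_environment", "environment"],
}


@dataclass(frozen=True)
class EpochBin:
    """A coarse time bin used to pool occurrences before clustering."""

    label: str
    start_ma: float  # older bound
    end_ma: float    # younger bound

    def contains(self, age_ma: float) -> bool:
        return self.end_ma <= age_ma <= self.start_ma


#: ICS epoch-level bins tiling 145–0 Ma (older records are unbinnable).
EPOCH_BINS = (
    EpochBin("EarlyCretaceous", 145.0, 100.5),
    EpochBin("LateCretaceous", 100.5, 66.0),
    EpochBin("Palaeogene", 66.0, 23.03),
    EpochBin("NeogeneQuaternary", 23.03, 0.0),
)


def assign_epoch(min_ma: float, max_ma: float):
    """Bin an age interval by its midpoint into one of the epoch-level bins.

    Returns the EpochBin, or None for records whose midpoint predates the
    oldest bin (too sparse a record for meaningful clustering there).
    """
    if min_ma < 0 or max_ma < min_ma:
        raise ValueError(f"invalid age interval ({min_ma}, {max_ma})")
    mid = 0.5 * (min_ma + max_ma)
    if mid > EPOCH_BINS[0].start_ma:
        return None
    for b in EPOCH_BINS:
        if b.end_ma < mid <= b.start_ma or (b.end_ma == 0.0 and mid == 0.0):
            return b
    return None


@dataclass
class OccurrenceTable:
    """A validated table of occurrence records."""

    df: pd.DataFrame
    provenance: str = ""
    n_dropped: int = 0
    removed_taxa: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"occurrence table missing column(s): {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def taxa(self) -> list:
        return sorted(self.df["taxon"].unique())

    def paleo_points(self) -> list:
        return [GeoPoint(r.paleolat, r.paleolng) for r in self.df.itertuples()]

    def taxon_midpoint(self, taxon: str, paleo: bool = True) -> GeoPoint:
        """Geographic midpoint over a taxon's occurrences (Cartesian mean)."""
        sub = self.df[self.df["taxon"] == taxon]
        if sub.empty:
            raise KeyError(f"taxon {taxon!r} not in table")
        cols = ("paleolat", "paleolng") if paleo else ("lat", "lng")
        pts = [GeoPoint(row[cols[0]], row[cols[1]]) for _, row in sub.iterrows()]
        return geographic_midpoint(pts)

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False, columns=COLUMNS)


def _canonical_columns(df: pd.DataFrame) -> pd.DataFrame:
    rename = {}
    lower = {c.lower().strip(): c for c in df.columns}
    for canon, aliases in _HEADER_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canon
                break
    return df.rename(columns=rename)


def read_occurrences(path, provenance: str = "") -> OccurrenceTable:
    """Read an occurrence CSV, normalizing coordinates and dropping bad rows.

    Mandatory columns (after header aliasing): taxon plus at least one
    coordinate pair.  Rows with unparseable coordinates or ages are dropped
    with a logged count; longitudes are wrapped into (-180, 180].
    """
    raw = pd.read_csv(path)
    raw = _canonical_columns(raw)
    if "taxon" not in raw.columns:
        raise ValueError("missing mandatory column: taxon")
    if "lat" not in raw.columns and "paleolat" not in raw.columns:
        raise ValueError("missing mandatory column: lat (or paleolat)")
    # mirror missing coordinate system from the other one
    for a, b in (("lat", "paleolat"), ("lng", "paleolng")):
        if a not in raw.columns and b in raw.columns:
            raw[a] = raw[b]
        if b not in raw.columns and a in raw.columns:
            raw[b] = raw[a]
    for col, default in (("min_ma", 0.0), ("max_ma", 0.0), ("habitat", "unknown")):
        if col not in raw.columns:
            raw[col] = default

    n_before = len(raw)
    for col in ("lat", "lng", "paleolat", "paleolng", "min_ma", "max_ma"):
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
    raw = raw.dropna(subset=["taxon", "lat", "lng", "paleolat", "paleolng"])
    raw = raw[(raw["lat"].abs() <= 90) & (raw["paleolat"].abs() <= 90)]
    raw["min_ma"] = raw["min_ma"].fillna(0.0)
    raw["max_ma"] = raw["max_ma"].fillna(raw["min_ma"])
    raw = raw[(raw["min_ma"] >= 0) & (raw["max_ma"] >= raw["min_ma"])]
    raw["lng"] = raw["lng"].map(normalize_lon)
    raw["paleolng"] = raw["paleolng"].map(normalize_lon)
    raw["habitat"] = raw["habitat"].fillna("unknown").astype(str).str.lower()
    raw["taxon"] = raw["taxon"].astype(str).str.strip()
    raw = raw[raw["taxon"] != ""]
    raw = raw.drop_duplicates(subset=["taxon", "lat", "lng", "min_ma", "max_ma"])
    n_dropped = n_before - len(raw)
    if n_dropped:
        logger.info("read_occurrences: dropped %d unparseable/duplicate rows", n_dropped)
    return OccurrenceTable(raw[COLUMNS].copy(), provenance=provenance, n_dropped=n_dropped)


def is_open_nomenclature(taxon: str) -> bool:
    """Heuristic open-nomenclature detector based on rank-qualifier tokens."""
    padded = taxon.strip() + " "
    return any(tok in padded or padded.rstrip().endswith(tok.rstrip())
               for tok in OPEN_NOMENCLATURE_TOKENS)


def filter_occurrences(
    table: OccurrenceTable,
    exclude_marine: bool = True,
    exclude_open_nomenclature: bool = True,
    marine_taxa: set | None = None,
) -> OccurrenceTable:
    """Drop primarily marine taxa and open-nomenclature identifications.

    Marine status comes from the habitat column, optionally augmented by an
    explicit `marine_taxa` exclusion list.  Returns a filtered copy; the
    removed taxa are recorded on the result.  Idempotent.
    """
    df = table.df
    keep = pd.Series(True, index=df.index)
    if exclude_marine:
        marine = df["habitat"].str.lower().eq("marine")
        if marine_taxa:
            marine |= df["taxon"].isin(set(marine_taxa))
        keep &= ~marine
    if exclude_open_nomenclature:
        keep &= ~df["taxon"].map(is_open_nomenclature)
    removed = sorted(set(df.loc[~keep, "taxon"]) - set(df.loc[keep, "taxon"]))
    return OccurrenceTable(
        df[keep].copy(), provenance=table.provenance, removed_taxa=removed
    )


def write_filter_report(table: OccurrenceTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("removed_taxon\n")
        for t in table.removed_taxa:
            fh.write(f"{t}\n")
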