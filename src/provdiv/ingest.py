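"""Occurrence ingestion: record filtering, 0.5-degree gridding, cell filters.

The pipeline consumes point occurrence records (taxon name + decimal
coordinates, Darwin-Core-like column names) and an environmental table keyed
by the lower corner of each 0.5-degree grid cell.  Records are filtered for
taxonomic and coordinate quality, pooled into half-degree cells, and cells
with inadequate sampling are excluded before any diversity or
bioregionalization step.

Filtering semantics
-------------------
* a record must carry a full two-word binomial accepted by a pluggable name
  validator (default: a regex binomial check standing in for a registry
  lookup);
* both coordinates must be stated to at least two decimal places — judged on
  the *textual* field, since precision is a property of the recorded string
  (trailing zeros count; a bare float falls back to its shortest repr);
* cells with fewer than 10 species or fewer than 150 records are excluded.

Cells are the half-open squares ``[floor2(lat), floor2(lat)+0.5) x
[floor2(lon), floor2(lon)+0.5)`` with ``floor2(x) = floor(2x)/2``, anchored
at integer degrees; centers sit at 0.25-degree offsets.
"""

from __future__ import annotations

import logging
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceRecord",
    "CellAssemblage",
    "CellId",
    "default_name_validator",
    "read_occurrences",
    "read_env_table",
    "filter_records",
    "grid_records",
    "filter_cells",
    "build_matrix",
    "cell_id_of",
    "cell_lower_corner",
    "cell_center",
    "cell_key",
    "parse_cell_key",
    "NoCellsError",
    "IngestError",
    "ENV_VARIABLES",
    "DEFAULT_COLUMN_MAP",
]

CellId = Tuple[int, int]

#: the eight gridded ocean-climatology variables used downstream
ENV_VARIABLES = (
    "sst_mean",       # mean annual sea surface temperature, degC
    "sst_sd",         # yearly temperature standard deviation, degC
    "salinity_mean",  # mean annual salinity, PSU
    "salinity_sd",    # yearly salinity standard deviation, PSU
    "oxygen",         # mean annual dissolved oxygen, ml/l
    "nitrate",        # umol/l
    "silicate",       # umol/l
    "phosphate",      # umol/l
)

DEFAULT_COLUMN_MAP = {
    "taxon_name": "scientificName",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "source_id": "id",
}


class IngestError(ValueError):
    pass


class NoCellsError(IngestError):
    """No grid cell survives the species/record thresholds."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One specimen/observation record.

    ``lat_text``/``lon_text`` keep the textual coordinate fields for the
    decimal-precision test; when absent the shortest repr of the float is
    used instead.
    """

    taxon_name: str
    latitude: float
    longitude: float
    source_id: str = ""
    lat_text: Optional[str] = None
    lon_text: Optional[str] = None


@dataclass
class CellAssemblage:
    """Per-cell species -> record-count map with its summary statistics."""

    cell_id: CellId
    incidence: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(self.incidence.values())

    @property
    def S(self) -> int:
        return len(self.incidence)

    @property
    def s1(self) -> int:
        return sum(1 for v in self.incidence.values() if v == 1)

    @property
    def s2(self) -> int:
        return sum(1 for v in self.incidence.values() if v == 2)

    def add(self, species: str) -> None:
        self.incidence[species] = self.incidence.get(species, 0) + 1


# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------

def cell_id_of(lat: float, lon: float) -> CellId:
    """Half-open 0.5-degree cell index: ``(floor(2*lat), floor(2*lon))``."""
    return (int(np.floor(2.0 * lat)), int(np.floor(2.0 * lon)))


def cell_lower_corner(cell_id: CellId) -> Tuple[float, float]:
    return (cell_id[0] / 2.0, cell_id[1] / 2.0)


def cell_center(cell_id: CellId) -> Tuple[float, float]:
    return (cell_id[0] / 2.0 + 0.25, cell_id[1] / 2.0 + 0.25)


def cell_key(cell_id: CellId) -> str:
    """Canonical string form of a cell id, used as a DataFrame index."""
    return f"{cell_id[0]}|{cell_id[1]}"


def parse_cell_key(key: str) -> CellId:
    a, b = key.split("|")
    return (int(a), int(b))


# ---------------------------------------------------------------------------
# Reading inputs
# ---------------------------------------------------------------------------

def read_occurrences(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    sep: str = ",",
) -> list[OccurrenceRecord]:
    """Read delimited occurrence records, keeping coordinates as text."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for role in ("taxon_name", "latitude", "longitude"):
        if cmap[role] not in df.columns:
            raise IngestError(f"missing column {cmap[role]!r} for {role}")
    has_id = cmap["source_id"] in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        lat_text = d[cmap["latitude"]].strip()
        lon_text = d[cmap["longitude"]].strip()
        records.append(
            OccurrenceRecord(
                taxon_name=d[cmap["taxon_name"]].strip(),
                latitude=_try_float(lat_text),
                longitude=_try_float(lon_text),
                source_id=d[cmap["source_id"]] if has_id else str(i),
                lat_text=lat_text,
                lon_text=lon_text,
            )
        )
    return records


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Environmental table CSV keyed by cell lower-corner ``lat``/``lon``.

    Returns a DataFrame of the eight variables indexed by canonical cell key.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("lat", "lon", *ENV_VARIABLES) if c not in df.columns]
    if missing:
        raise IngestError(f"env table missing columns: {missing}")
    keys = [
        cell_key((int(round(2 * la)), int(round(2 * lo))))
        for la, lo in zip(df["lat"], df["lon"])
    ]
    out = df[list(ENV_VARIABLES)].copy()
    out.index = pd.Index(keys, name="cell_id")
    if out.index.has_duplicates:
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise IngestError(f"duplicate cell ids in env table: {dups}")
    if out.isna().any().any():
        raise IngestError("env table contains missing values")
    return out


def _try_float(text: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        return float("nan")


# ---------------------------------------------------------------------------
# Record filtering
# ---------------------------------------------------------------------------

_BINOMIAL_RE = re.compile(r"^[A-Z][a-z\-]+ [a-z][a-z\-]+$")
_DECIMAL_RE = re.compile(r"^[+-]?\d+\.(\d+)$")
_INT_RE = re.compile(r"^[+-]?\d+$")


def default_name_validator(name: str) -> bool:
    """Accept any two-word binomial (capitalized genus + lowercase epithet)."""
    return bool(_BINOMIAL_RE.match(name.strip()))


def _decimal_places(text: Optional[str], value: float) -> Optional[int]:
    """Digits after the decimal separator, or None if unparseable.

    Trailing zeros count.  When no textual field is available the shortest
    repr of the float stands in for the recorded string.
    """
    if text is None:
        if not np.isfinite(value):
            return None
        text = repr(float(value))
    text = text.strip()
    m = _DECIMAL_RE.match(text)
    if m:
        return len(m.group(1))
    if _INT_RE.match(text):
        return 0
    return None


def filter_records(
    records: Iterable[OccurrenceRecord],
    name_validator: Callable[[str], bool] = default_name_validator,
    log: Optional[Counter] = None,
) -> list[OccurrenceRecord]:
    """Apply the record-quality filters, preserving order.

    A record is retained iff its name passes ``name_validator`` and both
    coordinates parse, lie in range, and are stated to >= 2 decimal places.
    Rejection reasons ("no_species_name", "malformed", "out_of_range",
    "low_precision") are counted into ``log`` (if given) and logged.
    """
    counts: Counter = Counter() if log is None else log
    kept = []
    for rec in records:
        if not name_validator(rec.taxon_name):
            counts["no_species_name"] += 1
            continue
        lat_dp = _decimal_places(rec.lat_text, rec.latitude)
        lon_dp = _decimal_places(rec.lon_text, rec.longitude)
        if (
            lat_dp is None
            or lon_dp is None
            or not np.isfinite(rec.latitude)
            or not np.isfinite(rec.longitude)
        ):
            counts["malformed"] += 1
            continue
        if not (-90.0 <= rec.latitude <= 90.0 and -180.0 <= rec.longitude <= 180.0):
            counts["out_of_range"] += 1
            continue
        if lat_dp < 2 or lon_dp < 2:
            counts["low_precision"] += 1
            continue
        kept.append(rec)
    if counts:
        logger.info("filter_records rejections: %s", dict(counts))
    logger.info("filter_records retained %d records", len(kept))
    return kept


# ---------------------------------------------------------------------------
# Gridding and cell-level filters
# ---------------------------------------------------------------------------

def grid_records(records: Iterable[OccurrenceRecord]) -> dict[CellId, CellAssemblage]:
    """Pool filtered records into half-degree cells (half-open intervals)."""
    cells: dict[CellId, CellAssemblage] = {}
    for rec in records:
        cid = cell_id_of(rec.latitude, rec.longitude)
        if cid not in cells:
            cells[cid] = CellAssemblage(cell_id=cid)
        cells[cid].add(rec.taxon_name)
    return cells


def filter_cells(
    assemblages: Mapping[CellId, CellAssemblage],
    min_species: int = 10,
    min_records: int = 150,
) -> tuple[dict[CellId, CellAssemblage], list[tuple[CellId, str]]]:
    """Exclude cells with fewer than ``min_species`` species or
    ``min_records`` records; thresholds themselves are retained.

    Returns (retained assemblages, exclusion log of (cell_id, reason)).
    """
    kept: dict[CellId, CellAssemblage] = {}
    excluded: list[tuple[CellId, str]] = []
    for cid, asm in assemblages.items():
        if asm.S < min_species:
            excluded.append((cid, f"S={asm.S} < {min_species}"))
        elif asm.n < min_records:
            excluded.append((cid, f"n={asm.n} < {min_records}"))
        else:
            kept[cid] = asm
    if not kept:
        raise NoCellsError(
            f"no cells survive filters (min_species={min_species}, "
            f"min_records={min_records}); {len(excluded)} excluded"
        )
    logger.info("filter_cells retained %d / %d cells", len(kept), len(assemblages))
    return kept, excluded


def build_matrix(
    assemblages: Mapping[CellId, CellAssemblage],
    env_table: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Cell x species incidence-count matrix, aligned with the env table.

    Rows are canonical cell keys (sorted by cell id), columns the sorted
    union of species; absences are 0 and row sums equal each cell's n.  When
    an env table is supplied, cells without environmental data are dropped
    with a warning and the returned env frame is row-aligned to the matrix.
    """
    cids = sorted(assemblages)
    species = sorted({sp for cid in cids for sp in assemblages[cid].incidence})
    mat = np.zeros((len(cids), len(species)), dtype=np.int64)
    col = {sp: j for j, sp in enumerate(species)}
    for i, cid in enumerate(cids):
        for sp, cnt in assemblages[cid].incidence.items():
            mat[i, col[sp]] = cnt
    matrix = pd.DataFrame(
        mat, index=pd.Index([cell_key(c) for c in cids], name="cell_id"),
        columns=species,
    )
    if env_table is None:
        return matrix, None
    if env_table.index.has_duplicates:
        raise IngestError("duplicate cell ids in env table")
    have = matrix.index.intersection(env_table.index)
    missing = matrix.index.difference(env_table.index)
    if len(missing):
        warnings.warn(
            f"{len(missing)} retained cell(s) lack environmental data and "
            f"were dropped: {list(missing[:5])}...",
            stacklevel=2,
        )
        matrix = matrix.loc[have]
        # drop species that no longer occur anywhere
        matrix = matrix.loc[:, matrix.sum(axis=0) > 0]
    env = env_table.loc[matrix.index, list(ENV_VARIABLES)]
    return matrix, env


def cell_metadata(assemblages: Mapping[CellId, CellAssemblage]) -> pd.DataFrame:
    """Per-cell metadata table (indices, centers, n, S) for export/joins."""
    rows = []
    for cid in sorted(assemblages):
        asm = assemblages[cid]
        clat, clon = cell_center(cid)
        rows.append(
            {
                "cell_id": cell_key(cid),
                "lat_index": cid[0],
                "lon_index": cid[1],
                "center_lat": clat,
                "center_lon": clon,
                "n_records": asm.n,
                "n_species": asm.S,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")
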