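"""Occurrence-table IO, taxonomic cleaning and matrix construction.

Turns PBDB/MIOMAP-style occurrence CSVs into binary taxon-by-locality
matrices, applying the standard preparation rules for this kind of
analysis:

* open-nomenclature occurrences ("Equus cf. simplicidens") are accepted as
  valid identifications of the named species;
* indeterminate occurrences ("Equus sp.") are dropped unless they are the
  only record of their genus within the time bin;
* Homo sapiens is excluded;
* taxa and localities with fewer than two occurrences are removed, applied
  iteratively to a fixed point (dropping a locality can strand a taxon and
  vice versa).

Time bins are North American Land Mammal Age (NALMA) subdivisions; the
standard subdivision table (name, epoch, age bounds in Ma) ships with the
package.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .ranges import EARTH_RADIUS_KM

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceRecord",
    "NalmaBin",
    "OccurrenceMatrix",
    "BinCovariates",
    "EmptyMatrixError",
    "parse_occurrences",
    "clean_taxa",
    "build_matrix",
    "filter_min_occurrences",
    "compute_bin_covariates",
    "spherical_convex_hull_area_km2",
    "load_nalma_bins",
]

OPEN_NOMENCLATURE = {"cf.", "aff.", "?"}


class EmptyMatrixError(ValueError):
    """Raised when filtering empties an occurrence matrix completely."""


@dataclass(frozen=True)
class OccurrenceRecord:
    genus: str
    epithet: str            # empty for indeterminate ("sp.") records
    qualifier: str          # "", "sp.", or an open-nomenclature marker
    locality_id: str
    latitude: float
    longitude: float
    bin_label: str

    @property
    def taxon(self) -> str:
        if self.qualifier == "sp.":
            return f"{self.genus} sp."
        return f"{self.genus} {self.epithet}"


@dataclass(frozen=True)
class NalmaBin:
    name: str
    epoch: str
    older_ma: float
    younger_ma: float

    def __post_init__(self) -> None:
        if not self.older_ma > self.younger_ma:
            raise ValueError(f"{self.name}: older bound must exceed younger bound")

    @property
    def midpoint_ma(self) -> float:
        return (self.older_ma + self.younger_ma) / 2.0

    @property
    def length_ma(self) -> float:
        return self.older_ma - self.younger_ma


def load_nalma_bins() -> list[NalmaBin]:
    """The sampled NALMA subdivisions (oldest last, as a youngest-first table)."""
    with resources.files("paleobeta.data").joinpath("nalma_bins.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        NalmaBin(r["name"], r["epoch"], float(r["older_ma"]), float(r["younger_ma"]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Parsing

DEFAULT_COLUMNS = {
    "taxon": "taxon",
    "genus": "genus",
    "species_epithet": "species_epithet",
    "identification_qualifier": "identification_qualifier",
    "locality_id": "locality_id",
    "latitude": "latitude",
    "longitude": "longitude",
    "bin_label": "bin_label",
}


def _split_taxon(name: str) -> tuple[str, str, str]:
    """Parse 'Genus epithet', 'Genus sp.' or 'Genus cf. epithet' style names."""
    parts = str(name).strip().split()
    if not parts:
        return "", "", ""
    genus = parts[0]
    if len(parts) == 1:
        return genus, "", "sp."
    if parts[1] in ("sp.", "sp", "indet.", "indet"):
        return genus, "", "sp."
    if parts[1] in OPEN_NOMENCLATURE and len(parts) >= 3:
        return genus, parts[2], parts[1]
    return genus, parts[1], ""


def parse_occurrences(source, columns: dict | None = None) -> list[OccurrenceRecord]:
    """Parse an occurrence CSV into records.

    ``source`` is a path, file object or DataFrame. ``columns`` maps the
    logical fields of :data:`DEFAULT_COLUMNS` to the file's column names
    (only ``locality_id``, ``latitude``, ``longitude``, ``bin_label`` and
    either ``taxon`` or genus/epithet are required). Rows with malformed or
    out-of-range coordinates are skipped with a logged count.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif isinstance(source, (str, bytes)) and "\n" in str(source):
        df = pd.read_csv(io.StringIO(str(source)))
    else:
        df = pd.read_csv(source)

    required = ["locality_id", "latitude", "longitude", "bin_label"]
    for key in required:
        if colmap[key] not in df.columns:
            raise ValueError(f"missing required column {colmap[key]!r}")
    has_taxon = colmap["taxon"] in df.columns
    has_parts = colmap["genus"] in df.columns and colmap["species_epithet"] in df.columns
    if not (has_taxon or has_parts):
        raise ValueError("need either a taxon column or genus + species_epithet columns")

    records: list[OccurrenceRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            lat = float(row[colmap["latitude"]])
            lon = float(row[colmap["longitude"]])
        except (TypeError, ValueError):
            skipped += 1
            continue
        if not (np.isfinite(lat) and np.isfinite(lon) and -90 <= lat <= 90 and -180 <= lon <= 180):
            skipped += 1
            continue
        if has_parts and not pd.isna(row[colmap["genus"]]):
            genus = str(row[colmap["genus"]]).strip()
            epithet = row[colmap["species_epithet"]]
            epithet = "" if pd.isna(epithet) else str(epithet).strip()
            qual = ""
            if colmap["identification_qualifier"] in df.columns:
                q = row[colmap["identification_qualifier"]]
                qual = "" if pd.isna(q) else str(q).strip()
            if not epithet and not qual:
                qual = "sp."
        else:
            genus, epithet, qual = _split_taxon(row[colmap["taxon"]])
        if not genus:
            skipped += 1
            continue
        records.append(
            OccurrenceRecord(
                genus=genus,
                epithet=epithet,
                qualifier=qual,
                locality_id=str(row[colmap["locality_id"]]),
                latitude=lat,
                longitude=lon,
                bin_label=str(row[colmap["bin_label"]]),
            )
        )
    if skipped:
        logger.warning("parse_occurrences: skipped %d malformed rows", skipped)
    return records


# ---------------------------------------------------------------------------
# Cleaning

def clean_taxa(records: list[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Apply the taxonomic preparation rules (idempotent).

    Open-nomenclature qualifiers (cf., aff.) are stripped: the occurrence
    is treated as a correct identification of the named species.
    Indeterminate "sp." records are dropped unless their genus has no other
    record in the same bin (genus uniqueness is judged per bin, because
    matrices are built per bin). Homo sapiens is removed.
    """
    # genera with at least one species-level record, per bin
    identified: set[tuple[str, str]] = set()
    for r in records:
        if r.qualifier != "sp." and r.epithet:
            identified.add((r.bin_label, r.genus))

    out: list[OccurrenceRecord] = []
    for r in records:
        if r.genus == "Homo" and r.epithet == "sapiens":
            continue
        if r.qualifier == "sp." or not r.epithet:
            if (r.bin_label, r.genus) in identified:
                continue
            out.append(
                OccurrenceRecord(r.genus, "", "sp.", r.locality_id, r.latitude, r.longitude, r.bin_label)
            )
            continue
        if r.qualifier in OPEN_NOMENCLATURE:
            r = OccurrenceRecord(
                r.genus, r.epithet, "", r.locality_id, r.latitude, r.longitude, r.bin_label
            )
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# Matrices

@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary locality-by-taxon matrix with locality coordinates.

    ``data`` has locality ids as index and taxa as columns, entries 0/1.
    ``coords`` is indexed by locality id with columns latitude/longitude.
    """

    data: pd.DataFrame
    coords: pd.DataFrame
    bin_label: str | None = None

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("occurrence matrix must be binary")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate locality or taxon labels")
        if not self.data.index.isin(self.coords.index).all():
            raise ValueError("every locality needs coordinates")

    @property
    def n_localities(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    @property
    def localities(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def latitudes(self) -> np.ndarray:
        return self.coords.loc[self.data.index, "latitude"].to_numpy(dtype=float)

    @property
    def longitudes(self) -> np.ndarray:
        return self.coords.loc[self.data.index, "longitude"].to_numpy(dtype=float)

    def refiltered(self, min_occurrences: int = 2) -> "OccurrenceMatrix":
        """Re-apply the minimum-occurrence fixed-point filter."""
        df = filter_min_occurrences(self.data, min_occurrences)
        if df.empty:
            raise EmptyMatrixError(f"matrix for bin {self.bin_label!r} emptied by filtering")
        return OccurrenceMatrix(df, self.coords.loc[df.index], self.bin_label)

    def subset_localities(self, localities) -> "OccurrenceMatrix":
        df = self.data.loc[list(localities)]
        return OccurrenceMatrix(df, self.coords.loc[df.index], self.bin_label).refiltered()

    def drop_taxa(self, taxa) -> "OccurrenceMatrix":
        df = self.data.drop(columns=list(taxa))
        if df.empty or df.shape[1] == 0:
            raise EmptyMatrixError(f"matrix for bin {self.bin_label!r} emptied by taxon removal")
        return OccurrenceMatrix(df, self.coords.loc[df.index], self.bin_label).refiltered()


def write_matrix_csv(matrix: OccurrenceMatrix, triplets_path, localities_path) -> None:
    """Write a matrix as sparse triplets (locality_id, taxon, present) plus
    a locality metadata CSV (locality_id, latitude, longitude, bin_label)."""
    stacked = matrix.data.stack()
    trip = stacked[stacked > 0].reset_index()
    trip.columns = ["locality_id", "taxon", "present"]
    trip.to_csv(triplets_path, index=False)
    meta = matrix.coords.loc[matrix.data.index].reset_index()
    meta.columns = ["locality_id", "latitude", "longitude"]
    meta["bin_label"] = matrix.bin_label
    meta.to_csv(localities_path, index=False)


def read_matrix_csv(triplets_path, localities_path) -> OccurrenceMatrix:
    """Inverse of :func:`write_matrix_csv`."""
    trip = pd.read_csv(triplets_path)
    meta = pd.read_csv(localities_path)
    mat = (
        trip.pivot_table(index="locality_id", columns="taxon", values="present",
                         aggfunc="max", fill_value=0)
        .astype(np.int8)
    )
    coords = meta.set_index("locality_id")[["latitude", "longitude"]]
    bin_label = meta["bin_label"].iloc[0] if "bin_label" in meta.columns else None
    return OccurrenceMatrix(mat, coords.loc[mat.index],
                            None if pd.isna(bin_label) else str(bin_label))


def filter_min_occurrences(df: pd.DataFrame, min_count: int = 2) -> pd.DataFrame:
    """Drop localities (rows) and taxa (columns) with fewer than
    ``min_count`` occurrences, iterating to a fixed point."""
    df = df.copy()
    while True:
        rows = df.sum(axis=1) >= min_count
        cols = df.sum(axis=0) >= min_count
        if rows.all() and cols.all():
            return df
        df = df.loc[rows, cols]
        if df.empty:
            return df


def build_matrix(
    records: list[OccurrenceRecord], bin_label: str | None = None, min_occurrences: int = 2
) -> OccurrenceMatrix:
    """Build the binary taxon-by-locality matrix for one bin."""
    if bin_label is not None:
        records = [r for r in records if r.bin_label == bin_label]
    else:
        labels = {r.bin_label for r in records}
        if len(labels) > 1:
            raise ValueError(f"records span multiple bins {sorted(labels)}; pass bin_label")
        bin_label = labels.pop() if labels else None
    if not records:
        raise EmptyMatrixError(f"no records for bin {bin_label!r}")

    df = pd.DataFrame(
        [(r.locality_id, r.taxon) for r in records], columns=["locality_id", "taxon"]
    )
    mat = (
        df.assign(present=1)
        .pivot_table(index="locality_id", columns="taxon", values="present", aggfunc="max", fill_value=0)
        .astype(np.int8)
    )
    mat = filter_min_occurrences(mat, min_occurrences)
    if mat.empty:
        raise EmptyMatrixError(f"matrix for bin {bin_label!r} emptied by the <{min_occurrences} filter")
    coords = (
        pd.DataFrame(
            [(r.locality_id, r.latitude, r.longitude) for r in records],
            columns=["locality_id", "latitude", "longitude"],
        )
        .groupby("locality_id")
        .mean()
    )
    return OccurrenceMatrix(mat, coords.loc[mat.index], bin_label)


# ---------------------------------------------------------------------------
# Per-bin covariates

@dataclass(frozen=True)
class BinCovariates:
    n_localities: int
    n_taxa: int
    area_km2: float
    lat_range_deg: float
    bin_length_ma: float

    def __post_init__(self) -> None:
        if min(self.n_localities, self.n_taxa) < 0 or self.area_km2 < 0:
            raise ValueError("covariates must be non-negative")
        if not 0 <= self.lat_range_deg <= 180:
            raise ValueError("latitudinal range must lie in [0, 180]")


def _spherical_triangle_area(p1, p2, p3) -> float:
    """Spherical excess of a triangle given unit vectors (l'Huilier)."""

    def angle(u, v):
        return float(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v)))

    a, b, c = angle(p2, p3), angle(p1, p3), angle(p1, p2)
    s = (a + b + c) / 2.0
    inner = np.tan(s / 2) * np.tan((s - a) / 2) * np.tan((s - b) / 2) * np.tan((s - c) / 2)
    return 4.0 * float(np.arctan(np.sqrt(max(inner, 0.0))))


def _unit_vectors(lats, lons) -> np.ndarray:
    la, lo = np.radians(lats), np.radians(lons)
    return np.column_stack([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])


def spherical_convex_hull_area_km2(lats, lons, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Area (km^2) of the spherical convex hull of locality points.

    The hull is taken in (lon, lat) and its area computed as the summed
    spherical excess of a fan triangulation. Fewer than 3 distinct
    non-collinear points give area 0 with a warning.
    """
    pts = np.unique(np.column_stack([np.asarray(lons, float), np.asarray(lats, float)]), axis=0)
    if len(pts) < 3:
        logger.warning("area: fewer than 3 distinct points, reporting 0")
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        logger.warning("area: degenerate (collinear) points, reporting 0")
        return 0.0
    verts = pts[hull.vertices]  # counter-clockwise order
    uv = _unit_vectors(verts[:, 1], verts[:, 0])
    excess = sum(_spherical_triangle_area(uv[0], uv[i], uv[i + 1]) for i in range(1, len(uv) - 1))
    return excess * radius_km**2


def compute_bin_covariates(matrix: OccurrenceMatrix, nalma: NalmaBin | None = None) -> BinCovariates:
    """Sampling covariates for one bin's matrix (Table-1-style summary)."""
    lats = matrix.latitudes
    return BinCovariates(
        n_localities=matrix.n_localities,
        n_taxa=matrix.n_taxa,
        area_km2=spherical_convex_hull_area_km2(lats, matrix.longitudes),
        lat_range_deg=float(lats.max() - lats.min()) if len(lats) else 0.0,
        bin_length_ma=nalma.length_ma if nalma is not None else float("nan"),
    )
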