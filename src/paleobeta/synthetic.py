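"""Synthetic fossil-record generator.

Real analyses of deep-time mammal communities start from occurrence
downloads (PBDB/MIOMAP-style tables), continental climate proxy series and
digitised species range maps. This module generates statistically analogous
inputs so that the whole pipeline is testable offline:

* a species pool with right-skewed range sizes, lognormal body masses and
  per-variable Gaussian climate tolerances;
* AR(1) driver series standing in for paleosol-derived mean annual
  precipitation (MAP, mm/yr) and a benthic-foraminiferal d18O-like proxy;
* per-bin fossil localities drawn from clustered spatial distributions,
  with mass-biased detection and climate-dependent occupancy.

Occupancy is constructed so that community structure responds unimodally to
MAP (Gaussian suitability with an interior optimum) and sorts along
latitude through a temperature gradient — the two signals the downstream
statistics are designed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeding import derive_seed
from .ranges import GeoBounds, GeodesicDisk, Range

__all__ = [
    "Species",
    "SpeciesPool",
    "DriverSeries",
    "TaphonomyParams",
    "generate_species_pool",
    "generate_driver_series",
    "generate_fossil_record",
    "write_occurrences_csv",
    "write_drivers_csv",
    "temperature_at",
    "DEFAULT_BOUNDS",
    "REFERENCE_LAT_GRADIENT",
]

# North-America-like study window
DEFAULT_BOUNDS = GeoBounds(lat_min=25.0, lat_max=55.0, lon_min=-125.0, lon_max=-70.0)

# Reference latitudinal temperature field, centred on the middle of the
# study window so that flattening the gradient removes latitudinal sorting
# without moving every species off its optimum:
#   T(lat) = T_ref - g * (lat - lat_ref)
# g ~ 0.6 degC per degree latitude is a realistic continental lapse.
REFERENCE_LAT_GRADIENT = 0.6
REFERENCE_LAT = 40.0
TEMP_AT_REFERENCE = 12.0


def temperature_at(
    lat,
    gradient: float = REFERENCE_LAT_GRADIENT,
    t_ref: float = TEMP_AT_REFERENCE,
    lat_ref: float = REFERENCE_LAT,
):
    """Mean annual temperature (degC) of the synthetic climate field."""
    return t_ref - gradient * (np.asarray(lat, dtype=float) - lat_ref)


@dataclass(frozen=True)
class Species:
    """One species: identity, geographic range, body mass and climate tolerance."""

    species_id: str
    genus: str
    epithet: str
    range: Range
    mass_kg: float
    map_optimum: float      # mm/yr
    map_breadth: float      # mm/yr (Gaussian sd)
    temp_optimum: float     # degC
    temp_breadth: float     # degC (Gaussian sd)

    @property
    def taxon(self) -> str:
        return f"{self.genus} {self.epithet}"

    def map_suitability(self, map_mm) -> np.ndarray:
        z = (np.asarray(map_mm, dtype=float) - self.map_optimum) / self.map_breadth
        return np.exp(-0.5 * z**2)

    def temp_suitability(self, temp_c) -> np.ndarray:
        z = (np.asarray(temp_c, dtype=float) - self.temp_optimum) / self.temp_breadth
        return np.exp(-0.5 * z**2)


@dataclass(frozen=True)
class SpeciesPool:
    species: tuple[Species, ...]
    bounds: GeoBounds = DEFAULT_BOUNDS
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.species]
        if len(ids) != len(set(ids)):
            raise ValueError("species ids must be unique")
        if any(s.mass_kg <= 0 for s in self.species):
            raise ValueError("body masses must be positive")

    def __len__(self) -> int:
        return len(self.species)

    @property
    def masses(self) -> dict[str, float]:
        return {s.taxon: s.mass_kg for s in self.species}

    @property
    def ranges(self) -> dict[str, Range]:
        return {s.taxon: s.range for s in self.species}


@dataclass(frozen=True)
class DriverSeries:
    """Per-bin covariate series: MAP and a d18O-like proxy with AR(1) noise."""

    bin_ids: tuple[str, ...]
    age_midpoints: tuple[float, ...]   # Ma, oldest first
    map_mm: tuple[float, ...]
    d18o: tuple[float, ...]
    phi: float
    seed: int

    def __post_init__(self) -> None:
        n = len(self.bin_ids)
        if not (len(self.age_midpoints) == len(self.map_mm) == len(self.d18o) == n):
            raise ValueError("driver series fields must all have one value per bin")

    def __len__(self) -> int:
        return len(self.bin_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bin_ids,
                "age_midpoint": self.age_midpoints,
                "map_mm": self.map_mm,
                "d18o": self.d18o,
            }
        )


@dataclass(frozen=True)
class TaphonomyParams:
    """How the record samples the living community.

    Detection is a monotone step in body mass: species at or above
    ``mass_threshold_kg`` are always detectable, smaller ones only with
    probability ``small_detection``. Localities cluster around a few
    Gaussian kernels per bin, mimicking the strong spatial clustering of
    real fossil localities.
    """

    n_localities: int = 40
    n_clusters: int = 4
    cluster_sd: float = 2.0           # degrees
    small_detection: float = 0.35
    mass_threshold_kg: float = 5.0
    bounds: GeoBounds = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        if self.n_localities < 2:
            raise ValueError("need at least 2 localities per bin")
        if not 0.0 <= self.small_detection <= 1.0:
            raise ValueError("detection probability must lie in [0, 1]")
        if self.n_clusters < 1 or self.cluster_sd <= 0:
            raise ValueError("invalid spatial clustering parameters")

    def detection(self, mass_kg) -> np.ndarray:
        mass_kg = np.asarray(mass_kg, dtype=float)
        return np.where(mass_kg >= self.mass_threshold_kg, 1.0, self.small_detection)


def generate_species_pool(
    n_species: int,
    bounds: GeoBounds = DEFAULT_BOUNDS,
    seed: int = 0,
    *,
    mass_meanlog: float = 0.0,
    mass_sdlog: float = 2.0,
    radius_medlog: float = 5.0,
    radius_sdlog: float = 0.6,
    map_optimum_center: float = 450.0,
    map_optimum_sd: float = 150.0,
    map_breadth: float = 120.0,
    temp_breadth: float = 3.0,
    lat_gradient: float = REFERENCE_LAT_GRADIENT,
) -> SpeciesPool:
    """Draw a synthetic species pool.

    Range radii are lognormal (median ``radius_medlog`` degrees), giving the
    right-skewed range-size distribution seen in real faunas: many small
    ranges, few continental ones. Body masses are lognormal in kg. Each
    species gets a Gaussian MAP tolerance centred near
    ``map_optimum_center`` (the community optimum the generator plants) and
    a temperature optimum matching the reference climate at its range
    centre, so communities sort along latitude when the gradient is active.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(derive_seed(seed, "species_pool"))
    lats = rng.uniform(bounds.lat_min, bounds.lat_max, n_species)
    lons = rng.uniform(bounds.lon_min, bounds.lon_max, n_species)
    radii = np.exp(rng.normal(np.log(radius_medlog), radius_sdlog, n_species))
    masses = np.exp(rng.normal(mass_meanlog, mass_sdlog, n_species))
    map_opts = rng.normal(map_optimum_center, map_optimum_sd, n_species)
    species = tuple(
        Species(
            species_id=f"sp{i:04d}",
            genus=f"Genus{i:04d}",
            epithet=f"species{i:04d}",
            range=GeodesicDisk(float(lats[i]), float(lons[i]), float(radii[i])),
            mass_kg=float(masses[i]),
            map_optimum=float(map_opts[i]),
            map_breadth=float(map_breadth),
            temp_optimum=float(temperature_at(lats[i], lat_gradient)),
            temp_breadth=float(temp_breadth),
        )
        for i in range(n_species)
    )
    return SpeciesPool(species=species, bounds=bounds, seed=seed)


def _ar1_noise(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with coefficient phi and innovation sd."""
    x = np.empty(n)
    if sd == 0:
        return np.zeros(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0.0, sd)
    return x


def generate_driver_series(
    n_bins: int,
    phi: float = 0.5,
    innovation_sd: float = 60.0,
    trend=450.0,
    seed: int = 0,
    *,
    d18o_trend=None,
    d18o_innovation_sd: float = 0.3,
    ages=None,
    bin_ids=None,
) -> DriverSeries:
    """Generate per-bin MAP and d18O-like series with AR(1) noise.

    ``trend`` (for MAP) may be a scalar, an array of length ``n_bins`` or a
    callable of the bin index. The d18O proxy defaults to a linear rise
    toward the present (global cooling signal) with its own AR(1) noise at
    the same phi.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if not abs(phi) < 1:
        raise ValueError("|phi| must be < 1 for a stationary AR(1) process")
    rng = np.random.default_rng(derive_seed(seed, "drivers"))

    def _resolve(tr, default):
        if tr is None:
            return default
        if callable(tr):
            return np.asarray([tr(i) for i in range(n_bins)], dtype=float)
        tr = np.asarray(tr, dtype=float)
        if tr.ndim == 0:
            return np.full(n_bins, float(tr))
        if tr.shape != (n_bins,):
            raise ValueError("trend array must have one value per bin")
        return tr

    map_trend = _resolve(trend, np.full(n_bins, 450.0))
    d18o_base = _resolve(d18o_trend, np.linspace(1.0, 4.0, n_bins))
    map_mm = map_trend + _ar1_noise(n_bins, phi, innovation_sd, rng)
    d18o = d18o_base + _ar1_noise(n_bins, phi, d18o_innovation_sd, rng)
    if ages is None:
        ages = np.linspace(35.0, 0.1, n_bins)
    if bin_ids is None:
        bin_ids = [f"bin{i:02d}" for i in range(n_bins)]
    return DriverSeries(
        bin_ids=tuple(bin_ids),
        age_midpoints=tuple(float(a) for a in ages),
        map_mm=tuple(map_mm),
        d18o=tuple(d18o),
        phi=float(phi),
        seed=int(seed),
    )


def _sample_clustered_localities(
    n: int, n_clusters: int, cluster_sd: float, bounds: GeoBounds, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Localities around Gaussian cluster kernels, rejected back into bounds."""
    # keep kernels away from the edges so clusters stay mostly inside
    pad_lat = min(cluster_sd, (bounds.lat_max - bounds.lat_min) / 4)
    pad_lon = min(cluster_sd, (bounds.lon_max - bounds.lon_min) / 4)
    c_lat = rng.uniform(bounds.lat_min + pad_lat, bounds.lat_max - pad_lat, n_clusters)
    c_lon = rng.uniform(bounds.lon_min + pad_lon, bounds.lon_max - pad_lon, n_clusters)
    lats = np.empty(n)
    lons = np.empty(n)
    for i in range(n):
        k = rng.integers(n_clusters)
        for _ in range(100):
            la = c_lat[k] + rng.normal(0.0, cluster_sd)
            lo = c_lon[k] + rng.normal(0.0, cluster_sd)
            if bounds.contains(la, lo):
                break
        else:
            la = float(np.clip(la, bounds.lat_min, bounds.lat_max))
            lo = float(np.clip(lo, bounds.lon_min, bounds.lon_max))
        lats[i], lons[i] = la, lo
    return lats, lons


def generate_fossil_record(
    pool: SpeciesPool,
    drivers: DriverSeries,
    taphonomy: TaphonomyParams | None = None,
    seed: int = 0,
    *,
    lat_gradient: float = REFERENCE_LAT_GRADIENT,
) -> pd.DataFrame:
    """Simulate occurrence records for every bin of ``drivers``.

    A species is recorded at a locality with marginal probability

        P = [locality in range] * detection(mass) * suit_MAP(bin MAP) * suit_T(T(lat))

    The MAP-suitability factor acts at the bin level (the species joins the
    bin's regional pool with probability suit_MAP, a metacommunity
    persistence draw), while detection and temperature suitability act per
    locality. Bin-level inclusion means that away from the community MAP
    optimum whole species drop out rather than thinning evenly, so bin
    richness — and with it among-locality turnover (beta diversity) —
    peaks where bin MAP sits at the planted optimum. Communities sort
    along latitude in proportion to ``lat_gradient``; setting
    ``lat_gradient=0`` flattens the climate gradient (all latitudes
    equally suitable).

    Returns a tidy occurrence table with columns taxon, genus,
    species_epithet, identification_qualifier, locality_id, latitude,
    longitude, bin_label.
    """
    if len(pool) == 0:
        raise ValueError("species pool is empty")
    if len(drivers) == 0:
        raise ValueError("driver series has no bins")
    taphonomy = taphonomy or TaphonomyParams(bounds=pool.bounds)

    rows: list[dict] = []
    detect = taphonomy.detection(np.array([s.mass_kg for s in pool.species]))
    for b, bin_id in enumerate(drivers.bin_ids):
        rng = np.random.default_rng(derive_seed(seed, "record", bin_id))
        lats, lons = _sample_clustered_localities(
            taphonomy.n_localities, taphonomy.n_clusters, taphonomy.cluster_sd, taphonomy.bounds, rng
        )
        temp = temperature_at(lats, lat_gradient)
        map_b = drivers.map_mm[b]
        for j, sp in enumerate(pool.species):
            # bin-level persistence draw (MAP suitability), then
            # per-locality occupancy (range, detection, temperature)
            if rng.random() >= float(sp.map_suitability(map_b)):
                continue
            in_range = np.asarray(sp.range.contains(lats, lons), dtype=float)
            p = in_range * detect[j] * sp.temp_suitability(temp)
            hits = rng.random(taphonomy.n_localities) < p
            for i in np.flatnonzero(hits):
                rows.append(
                    {
                        "taxon": sp.taxon,
                        "genus": sp.genus,
                        "species_epithet": sp.epithet,
                        "identification_qualifier": "",
                        "locality_id": f"{bin_id}_L{i:03d}",
                        "latitude": float(lats[i]),
                        "longitude": float(lons[i]),
                        "bin_label": bin_id,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "taxon",
            "genus",
            "species_epithet",
            "identification_qualifier",
            "locality_id",
            "latitude",
            "longitude",
            "bin_label",
        ],
    )


def write_occurrences_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_drivers_csv(drivers: DriverSeries, path) -> None:
    drivers.to_frame().to_csv(path, index=False)
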