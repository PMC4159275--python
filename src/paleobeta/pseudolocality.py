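"""Pseudo-locality generation and bias-injection trials.

To compare extant (or projected) faunas with the fossil record on equal
footing, sampling points ("pseudo localities") are drawn from frequency
distributions fitted to real fossil-locality coordinates, matched in
number, and intersected with species ranges to build occurrence matrices.
Latitude and longitude are fitted and sampled as independent marginals
with the classic normal / gamma / beta families, the family per axis
chosen by AIC; gamma and beta use an affine support transform estimated
from the data span.

Bias trials remove a fraction of taxa — uniformly at random (taxonomic
bias) or only among species below a body-mass threshold (taphonomic
small-mammal bias) — and re-apply the minimum-occurrence filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seeding import derive_seed
from .occio import EmptyMatrixError, OccurrenceMatrix, filter_min_occurrences
from .ranges import GeoBounds, Range

__all__ = [
    "AxisFit",
    "FittedSpatialDistribution",
    "BiasSpec",
    "ReplicateEnsemble",
    "fit_spatial_distribution",
    "sample_pseudo_localities",
    "project_ranges_to_matrix",
    "apply_bias",
    "replicate_ensemble",
]

_FAMILIES = ("normal", "gamma", "beta")
_MIN_POINTS = 10


@dataclass(frozen=True)
class AxisFit:
    """Maximum-likelihood marginal fit for one coordinate axis."""

    family: str                 # 'normal' | 'gamma' | 'beta'
    params: tuple[float, ...]   # family shape parameters
    loc: float                  # affine support transform: x = loc + scale * u
    scale: float
    loglik: float
    aic: float

    def frozen(self):
        if self.family == "normal":
            return stats.norm(*self.params)
        if self.family == "gamma":
            return stats.gamma(self.params[0], loc=self.loc, scale=self.params[1])
        if self.family == "beta":
            return stats.beta(*self.params, loc=self.loc, scale=self.scale)
        raise ValueError(self.family)

    @property
    def mean(self) -> float:
        return float(self.frozen().mean())


@dataclass(frozen=True)
class FittedSpatialDistribution:
    lat: AxisFit
    lon: AxisFit
    n_points: int


def _fit_axis(x: np.ndarray) -> AxisFit:
    """Fit normal, gamma and beta marginals by ML; keep the AIC-best.

    Two free parameters per family; the gamma offset and beta interval are
    set from the data span (epsilon-padded so all points are interior).
    """
    span = float(x.max() - x.min())
    if span == 0:
        raise ValueError("degenerate (constant) coordinate axis")
    eps = 0.005 * span
    fits: list[AxisFit] = []

    mu, sd = stats.norm.fit(x)
    ll = float(stats.norm.logpdf(x, mu, sd).sum())
    fits.append(AxisFit("normal", (mu, sd), 0.0, 1.0, ll, 2 * 2 - 2 * ll))

    loc_g = float(x.min()) - eps
    try:
        a, _, scale_g = stats.gamma.fit(x, floc=loc_g)
        ll = float(stats.gamma.logpdf(x, a, loc=loc_g, scale=scale_g).sum())
        fits.append(AxisFit("gamma", (a, scale_g), loc_g, scale_g, ll, 2 * 2 - 2 * ll))
    except (ValueError, RuntimeError):
        pass

    loc_b = float(x.min()) - eps
    scale_b = float(x.max()) + eps - loc_b
    try:
        a, b, _, _ = stats.beta.fit(x, floc=loc_b, fscale=scale_b)
        ll = float(stats.beta.logpdf(x, a, b, loc=loc_b, scale=scale_b).sum())
        fits.append(AxisFit("beta", (a, b), loc_b, scale_b, ll, 2 * 2 - 2 * ll))
    except (ValueError, RuntimeError):
        pass

    return min(fits, key=lambda f: f.aic)


def fit_spatial_distribution(coordinates) -> FittedSpatialDistribution:
    """Fit per-axis frequency distributions to locality coordinates.

    ``coordinates`` is a DataFrame with latitude/longitude columns, an
    OccurrenceMatrix, or an (n, 2) array of (lat, lon). Requires at least
    10 localities; a constant axis is an error.
    """
    if isinstance(coordinates, OccurrenceMatrix):
        lats, lons = coordinates.latitudes, coordinates.longitudes
    elif isinstance(coordinates, pd.DataFrame):
        lats = coordinates["latitude"].to_numpy(dtype=float)
        lons = coordinates["longitude"].to_numpy(dtype=float)
    else:
        arr = np.asarray(coordinates, dtype=float)
        lats, lons = arr[:, 0], arr[:, 1]
    if len(lats) < _MIN_POINTS:
        raise ValueError(f"need at least {_MIN_POINTS} localities to fit spatial distributions")
    return FittedSpatialDistribution(lat=_fit_axis(lats), lon=_fit_axis(lons), n_points=len(lats))


def sample_pseudo_localities(
    fit: FittedSpatialDistribution,
    n: int,
    bounds: GeoBounds | None = None,
    seed: int = 0,
    *,
    max_attempt_factor: int = 1000,
) -> np.ndarray:
    """Draw exactly ``n`` (lat, lon) points from the fitted marginals.

    Points outside ``bounds`` are rejected and redrawn. If fewer than 1%
    of candidate draws are accepted the fit is deemed incompatible with
    the bounds and an error is raised.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(derive_seed(seed, "pseudo_localities"))
    lat_rv, lon_rv = fit.lat.frozen(), fit.lon.frozen()
    out = np.empty((n, 2))
    got = 0
    drawn = 0
    limit = max(n * max_attempt_factor, 10000)
    while got < n:
        m = max(n - got, 256)
        lats = lat_rv.rvs(size=m, random_state=rng)
        lons = lon_rv.rvs(size=m, random_state=rng)
        ok = np.ones(m, dtype=bool) if bounds is None else bounds.contains(lats, lons)
        drawn += m
        take = min(int(ok.sum()), n - got)
        idx = np.flatnonzero(ok)[:take]
        out[got : got + take, 0] = lats[idx]
        out[got : got + take, 1] = lons[idx]
        got += take
        if drawn >= limit and got / drawn < 0.01:
            raise ValueError("rejection rate exceeds 99%: fitted distribution incompatible with bounds")
    return out


def project_ranges_to_matrix(
    ranges: dict[str, Range],
    points: np.ndarray,
    bin_label: str | None = None,
    min_occurrences: int = 2,
) -> OccurrenceMatrix:
    """Intersect species ranges with pseudo-locality points.

    Presence is the closed point-in-range test; the minimum-occurrence
    fixed-point filter is then applied exactly as for fossil matrices.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if not ranges:
        raise ValueError("no species ranges supplied")
    lats, lons = points[:, 0], points[:, 1]
    loc_ids = [f"P{i:04d}" for i in range(len(points))]
    cols = {}
    for taxon, rng_ in ranges.items():
        cols[taxon] = np.asarray(rng_.contains(lats, lons), dtype=np.int8)
    df = pd.DataFrame(cols, index=loc_ids)
    if df.to_numpy().sum() == 0:
        raise ValueError("no species overlaps any pseudo-locality point")
    df = filter_min_occurrences(df, min_occurrences)
    if df.empty:
        raise EmptyMatrixError(f"pseudo-locality matrix for bin {bin_label!r} emptied by filtering")
    coords = pd.DataFrame({"latitude": lats, "longitude": lons}, index=loc_ids)
    return OccurrenceMatrix(df, coords.loc[df.index], bin_label)


@dataclass(frozen=True)
class BiasSpec:
    """A bias-injection trial: remove a fraction of taxa.

    kind 'taxonomic' removes uniformly at random; kind 'body-mass' removes
    only among taxa with mass below ``mass_threshold_kg`` (default 5 kg,
    the classic small-mammal taphonomic cutoff).
    """

    kind: str                       # 'taxonomic' | 'body-mass'
    fraction: float                 # in (0, 1); study levels are 0.25/0.50/0.75
    mass_threshold_kg: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("taxonomic", "body-mass"):
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("removal fraction must lie in (0, 1)")
        if self.kind == "body-mass" and self.mass_threshold_kg <= 0:
            raise ValueError("mass threshold must be positive")


def apply_bias(
    matrix: OccurrenceMatrix,
    masses: dict[str, float] | None,
    spec: BiasSpec,
    seed: int = 0,
) -> OccurrenceMatrix:
    """Remove floor(fraction * pool size) taxa per ``spec`` and re-filter."""
    rng = np.random.default_rng(derive_seed(seed, "bias", spec.kind, spec.fraction))
    taxa = list(matrix.taxa)
    if spec.kind == "taxonomic":
        pool = taxa
    else:
        if masses is None or any(t not in masses for t in taxa):
            raise ValueError("body-mass bias requires a mass for every taxon")
        pool = [t for t in taxa if masses[t] < spec.mass_threshold_kg]
    n_remove = math.floor(spec.fraction * len(pool))
    if n_remove >= len(taxa):
        raise ValueError("bias would remove all taxa")
    if n_remove == 0:
        return matrix
    removed = rng.choice(pool, size=n_remove, replace=False)
    return matrix.drop_taxa(removed)


@dataclass
class ReplicateEnsemble:
    """A set of replicate matrices with per-replicate seeds."""

    replicates: list
    seeds: list[int]

    def __len__(self) -> int:
        return len(self.replicates)

    def summarize(self, metric: Callable) -> tuple[float, float]:
        """Mean and standard error (sd/sqrt(n); nan when n = 1) of a metric."""
        vals = np.asarray([metric(r) for r in self.replicates], dtype=float)
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        return mean, se


def replicate_ensemble(
    generator: Callable[[int], object],
    n_reps: int = 100,
    base_seed: int = 0,
    keys: Sequence[object] = (),
) -> ReplicateEnsemble:
    """Run ``generator(seed)`` for ``n_reps`` derived seeds.

    Seeds are derived from ``base_seed`` (and optional extra ``keys``, e.g.
    the bin name) by counter hashing, so replicate r is reproducible in
    isolation. Generator failures propagate with the replicate index.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    reps, seeds = [], []
    for r in range(n_reps):
        s = derive_seed(base_seed, "replicate", *keys, r)
        try:
            reps.append(generator(s))
        except Exception as err:
            raise RuntimeError(f"replicate {r} (seed {s}) failed: {err}") from err
        seeds.append(s)
    return ReplicateEnsemble(replicates=reps, seeds=seeds)
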