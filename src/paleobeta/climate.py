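"""Simplified climate-space (climate-envelope) modelling.

Species ranges are sampled on a regular 1-degree grid carrying three
climate variables — mean annual temperature (mat, degC), winter
temperature (wintert, degC) and mean annual precipitation (map, mm/yr) —
and each species' climate space is modelled by a two-member consensus:

* a **surface range envelope**: per-variable [2.5th, 97.5th] percentile
  bounds of climate at presence cells (presence when all variables fall
  inside);
* a **logistic regression** of presence/absence on the three variables.

The consensus probability is the mean of member outputs; it is binarized
at the threshold maximizing the true skill statistic (TSS) on training
cells. Performance is scored by AUC, TSS and proportion correct
classification (PCC). Projected presences under a warming scenario form a
cell-set range that feeds back into the pseudo-locality pipeline.

This deliberately keeps only the behaviour class of climate-tracking
models — species rigidly follow their fitted climate space, with no
dispersal limits, evolution or biotic interactions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from ._seeding import derive_seed
from .ranges import CellSetRange, GeoBounds, Range
from .synthetic import REFERENCE_LAT_GRADIENT, Species, temperature_at

logger = logging.getLogger(__name__)

__all__ = [
    "ClimateGrid",
    "EvaluationMetrics",
    "ClimateEnvelopeEnsemble",
    "make_climate_grid",
    "apply_scenario",
    "sample_presences",
    "filter_rare",
    "fit_envelope",
    "evaluate",
    "project",
    "presences_to_range",
]

CLIMATE_VARS = ("mat", "wintert", "map")


@dataclass(frozen=True)
class ClimateGrid:
    """Regular lat/lon grid of cell centres with climate covariates."""

    cells: pd.DataFrame                 # cell_id, lat, lon, mat, wintert, map
    resolution_deg: float = 1.0
    scenario: str = "current"

    def __post_init__(self) -> None:
        required = {"cell_id", "lat", "lon", *CLIMATE_VARS}
        if not required <= set(self.cells.columns):
            raise ValueError(f"grid must have columns {sorted(required)}")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("duplicate grid cells")
        if not np.isfinite(self.cells[list(CLIMATE_VARS)].to_numpy()).all():
            raise ValueError("non-finite climate values")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def X(self) -> pd.DataFrame:
        return self.cells[list(CLIMATE_VARS)]

    def to_csv(self, path) -> None:
        out = self.cells.copy()
        out["scenario"] = self.scenario
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, resolution_deg: float = 1.0) -> "ClimateGrid":
        df = pd.read_csv(path)
        scenario = str(df["scenario"].iloc[0]) if "scenario" in df.columns else "current"
        return cls(cells=df.drop(columns=["scenario"], errors="ignore"),
                   resolution_deg=resolution_deg, scenario=scenario)


def make_climate_grid(
    bounds: GeoBounds,
    resolution_deg: float = 1.0,
    seed: int = 0,
    *,
    lat_gradient: float = REFERENCE_LAT_GRADIENT,
    winter_offset: float = 8.0,
    map_west: float = 250.0,
    map_east: float = 900.0,
    noise_sd: float = 0.5,
) -> ClimateGrid:
    """Synthetic current-climate surface on a regular grid.

    Mean annual temperature follows the reference latitudinal gradient;
    winter temperature is a colder offset of it with independent noise (the
    same latitudinal slope, so a uniform warming delta translates both
    temperature fields coherently); precipitation increases west to east
    (continental-interior dryness) with mild noise.
    """
    lats = np.arange(bounds.lat_min + resolution_deg / 2, bounds.lat_max, resolution_deg)
    lons = np.arange(bounds.lon_min + resolution_deg / 2, bounds.lon_max, resolution_deg)
    glon, glat = np.meshgrid(lons, lats)
    glat, glon = glat.ravel(), glon.ravel()
    rng = np.random.default_rng(derive_seed(seed, "climate_grid"))
    mat = temperature_at(glat, lat_gradient) + rng.normal(0, noise_sd, glat.size)
    wintert = mat - winter_offset + rng.normal(0, noise_sd, glat.size)
    frac_east = (glon - glon.min()) / max(glon.max() - glon.min(), 1e-9)
    map_mm = map_west + (map_east - map_west) * frac_east + rng.normal(0, 20 * noise_sd, glat.size)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(glat.size)],
            "lat": glat,
            "lon": glon,
            "mat": mat,
            "wintert": wintert,
            "map": np.clip(map_mm, 10.0, None),
        }
    )
    return ClimateGrid(cells=cells, resolution_deg=resolution_deg, scenario="current")


def apply_scenario(grid: ClimateGrid, deltas: dict[str, float], label: str) -> ClimateGrid:
    """Shift climate variables by scenario deltas (uniform offsets)."""
    unknown = set(deltas) - set(CLIMATE_VARS)
    if unknown:
        raise ValueError(f"unknown climate variables {sorted(unknown)}")
    cells = grid.cells.copy()
    for var, d in deltas.items():
        cells[var] = cells[var] + d
    return ClimateGrid(cells=cells, resolution_deg=grid.resolution_deg, scenario=label)


def sample_presences(species_range: Range, grid: ClimateGrid) -> np.ndarray:
    """Presence/absence of a range at every grid cell centre (closed test)."""
    if len(grid) == 0:
        raise ValueError("empty climate grid")
    return np.asarray(
        species_range.contains(grid.cells["lat"].to_numpy(), grid.cells["lon"].to_numpy()),
        dtype=bool,
    )


def filter_rare(presence_counts: dict[str, int], min_cells: int = 20) -> tuple[list[str], list[str]]:
    """Drop species present in fewer than ``min_cells`` cells.

    Returns (retained, removed); the boundary count min_cells is retained.
    """
    retained = [s for s, c in presence_counts.items() if c >= min_cells]
    removed = [s for s, c in presence_counts.items() if c < min_cells]
    return retained, removed


@dataclass(frozen=True)
class EvaluationMetrics:
    auc: float      # nan when one class absent
    tss: float
    pcc: float


def evaluate(predicted, observed, threshold: float = 0.5) -> EvaluationMetrics:
    """AUC (rank formulation), TSS and PCC of presence predictions.

    ``predicted`` are probabilities/scores; TSS and PCC binarize at
    ``threshold`` (closed above). With only one observed class AUC and TSS
    are undefined and reported as nan.
    """
    p = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=bool)
    if p.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    pred = p >= threshold
    pcc = float((pred == obs).mean())
    if obs.all() or (~obs).all():
        return EvaluationMetrics(auc=float("nan"), tss=float("nan"), pcc=pcc)
    auc = float(roc_auc_score(obs, p))
    sens = float((pred & obs).sum() / obs.sum())
    spec_ = float((~pred & ~obs).sum() / (~obs).sum())
    return EvaluationMetrics(auc=auc, tss=sens + spec_ - 1.0, pcc=pcc)


class ClimateEnvelopeEnsemble(BaseEstimator, ClassifierMixin):
    """Two-member consensus climate-space model (envelope + logistic).

    Parameters
    ----------
    percentiles : envelope trim, default (2.5, 97.5).
    variables : climate columns used, default ('mat', 'wintert', 'map').

    Attributes (after fit)
    ----------------------
    bounds_ : {variable: (lower, upper)} envelope percentile bounds.
    logit_params_ : logistic coefficients (None when the member was dropped
        for complete separation).
    threshold_ : consensus binarization threshold (max training TSS).
    train_metrics_ : EvaluationMetrics on the training cells.
    """

    def __init__(self, percentiles: tuple[float, float] = (2.5, 97.5),
                 variables: tuple[str, ...] = CLIMATE_VARS):
        self.percentiles = percentiles
        self.variables = variables

    def _envelope_member(self, X: pd.DataFrame) -> np.ndarray:
        ok = np.ones(len(X), dtype=bool)
        for v in self.variables:
            lo, hi = self.bounds_[v]
            ok &= (X[v].to_numpy() >= lo) & (X[v].to_numpy() <= hi)
        return ok.astype(float)

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        """Logistic design: linear + quadratic terms of each climate variable
        (z-scored by the training moments), as in GLM-based distribution
        models — a linear-only predictor cannot express an interior optimum."""
        cols = []
        for v in self.variables:
            z = (X[v].to_numpy(dtype=float) - self._center[v]) / self._scale[v]
            cols += [z, z**2]
        return sm.add_constant(np.column_stack(cols), has_constant="add")

    def _logistic_member(self, X: pd.DataFrame) -> np.ndarray | None:
        if self.logit_params_ is None:
            return None
        eta = np.clip(self._design(X) @ self.logit_params_, -500, 500)
        return 1.0 / (1.0 + np.exp(-eta))

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=bool)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        if y.sum() == 0:
            raise ValueError("no presences to fit")
        lo, hi = self.percentiles
        self.bounds_ = {}
        for v in self.variables:
            vals = X.loc[y, v].to_numpy(dtype=float)
            b_lo, b_hi = np.percentile(vals, [lo, hi])
            if b_lo >= b_hi:          # degenerate variable at presences
                b_lo, b_hi = float(vals.min()), float(vals.max() + 1e-9)
            self.bounds_[v] = (float(b_lo), float(b_hi))

        self._center = {v: float(X[v].mean()) for v in self.variables}
        self._scale = {v: float(X[v].std(ddof=0)) or 1.0 for v in self.variables}
        self.logit_params_ = None
        if 0 < y.sum() < len(y):
            Z = self._design(X)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error", category=RuntimeWarning)
                    res = sm.Logit(y.astype(float), Z).fit(disp=0, maxiter=200)
                if np.isfinite(res.params).all() and np.abs(res.params).max() < 1e4:
                    self.logit_params_ = np.asarray(res.params)
            except Exception:
                pass
            if self.logit_params_ is None:
                warnings.warn("complete separation in logistic member; "
                              "falling back to envelope-only consensus", stacklevel=2)

        proba = self.predict_proba(X)
        self.threshold_ = self._max_tss_threshold(proba, y)
        self.train_metrics_ = evaluate(proba, y, self.threshold_)
        return self

    @staticmethod
    def _max_tss_threshold(proba: np.ndarray, y: np.ndarray) -> float:
        cands = np.unique(proba)
        best_t, best_tss = 0.5, -np.inf
        pos, neg = y.sum(), (~y).sum()
        for t in cands:
            pred = proba >= t
            tss = (pred & y).sum() / pos + ((~pred) & ~y).sum() / neg - 1.0
            if tss > best_tss + 1e-12:
                best_t, best_tss = float(t), float(tss)
        return best_t

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        members = [self._envelope_member(X)]
        logit = self._logistic_member(X)
        if logit is not None:
            members.append(logit)
        return np.mean(members, axis=0)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_proba(X) >= self.threshold_


def fit_envelope(presences, grid: ClimateGrid, **kwargs) -> ClimateEnvelopeEnsemble:
    """Fit the consensus model for one species' grid presences."""
    y = np.asarray(presences, dtype=bool)
    return ClimateEnvelopeEnsemble(**kwargs).fit(grid.X, y)


def project(model: ClimateEnvelopeEnsemble, scenario_grid: ClimateGrid) -> np.ndarray:
    """Binary presence per cell under a scenario grid."""
    missing = set(model.variables) - set(scenario_grid.cells.columns)
    if missing:
        raise ValueError(f"scenario grid lacks variables {sorted(missing)}")
    return model.predict(scenario_grid.X)


def presences_to_range(grid: ClimateGrid, presence) -> CellSetRange:
    """Treat a projected cell set as a species range for pseudo-locality sampling."""
    presence = np.asarray(presence, dtype=bool)
    centers = grid.cells.loc[presence, ["lat", "lon"]].to_numpy(dtype=float)
    return CellSetRange(centers, resolution_deg=grid.resolution_deg)


def species_presence_on_grid(species: Species, grid: ClimateGrid, level: float = 0.5) -> np.ndarray:
    """Climate-determined 'true' presence of a synthetic species: combined
    Gaussian suitability over (mat, map) at or above ``level``."""
    suit = species.temp_suitability(grid.cells["mat"].to_numpy()) * species.map_suitability(
        grid.cells["map"].to_numpy()
    )
    return suit >= level
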