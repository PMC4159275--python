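"""End-to-end orchestration of the fossil and projection analyses.

`run_fossil_analysis` walks synthetic (or user-supplied) occurrence data
through the full chain: parse/clean/bin -> beta diversity and LTG strength
per bin -> standardized resampling -> AR(1)-GLS model selection over
climate and sampling covariates -> residual detrending, and writes tidy
CSVs plus trend and metric-vs-MAP figures.

`run_projection_analysis` fits climate-envelope consensus models to a
species pool on a climate grid, projects presences under warming
scenarios, samples pseudo-locality ensembles against the projected cell
sets, and reports beta diversity and LTG strength per scenario.

A single master seed is fanned out per stage/bin/replicate by stable
hashing; every output CSV carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeding import derive_seed
from .biascontrol import MetricSeries, ResamplingSpec, detrend, standardized_resample
from .climate import (
    apply_scenario,
    fit_envelope,
    filter_rare,
    make_climate_grid,
    presences_to_range,
    project,
)
from .gls import ModelSelectionTable, model_select
from .metrics import beta_diversity, ltg
from .occio import (
    EmptyMatrixError,
    NalmaBin,
    build_matrix,
    clean_taxa,
    compute_bin_covariates,
    load_nalma_bins,
    parse_occurrences,
)
from .pseudolocality import fit_spatial_distribution, project_ranges_to_matrix, sample_pseudo_localities
from .ranges import GeoBounds
from .synthetic import (
    DEFAULT_BOUNDS,
    TaphonomyParams,
    generate_driver_series,
    generate_fossil_record,
    generate_species_pool,
    write_drivers_csv,
    write_occurrences_csv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "FossilAnalysisResult", "ProjectionResult",
           "run_fossil_analysis", "run_projection_analysis"]

CLIMATE_TERMS = ("map", "map^2", "d18o")
SAMPLING_TERMS = ("n_localities", "area_km2", "n_taxa", "lat_range_deg", "bin_length_ma",
                  "area_km2:n_taxa")

# SRES-style warming scenarios: uniform mean-annual-temperature deltas (degC)
# spanning the 1.49-6.78 degC envelope of ensemble projections.
DEFAULT_SCENARIOS: dict[str, float] = {
    "current": 0.0,
    "B1 2050s low": 1.49,
    "B1 2050s": 2.0,
    "A1b 2050s": 2.5,
    "A2 2050s": 2.9,
    "A1b 2080s": 3.7,
    "A2 2080s": 4.8,
    "A2 2080s high": 6.78,
}


def _default_map_trend(n_bins: int) -> np.ndarray:
    """Cyclical continental MAP trend spanning both flanks of the planted
    community optimum (~450 mm/yr)."""
    i = np.arange(n_bins)
    return 450.0 + 230.0 * np.sin(2.0 * np.pi * i / 8.0)


@dataclass
class RunConfig:
    """Configuration for a synthetic end-to-end run."""

    seed: int = 0
    out_dir: str | None = None
    # synthetic generation
    n_species: int = 150
    n_localities: int = 80
    phi: float = 0.4
    map_innovation_sd: float = 40.0
    lat_gradient: float = 0.6
    small_detection: float = 0.35
    occurrences_csv: str | None = None      # use real data instead of generating
    drivers_csv: str | None = None
    # resampling
    resample_n_localities: int = 30
    resample_lat_min: float = 30.0
    resample_lat_max: float = 50.0
    resample_reps: int = 100
    # ordination: raw CA axis-1 scores by default; the segment-based
    # nonlinear rescaling is available but adds score-deformation noise
    # that inflates the replicate variance of R^2 on small matrices
    ca_rescale: bool = False
    # projection stage
    scenarios: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCENARIOS))
    projection_n_species: int = 300
    projection_reps: int = 30
    projection_temp_breadth: float = 2.5
    pseudo_n_localities: int = 40
    grid_resolution: float = 1.0
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class FossilAnalysisResult:
    bins: list[NalmaBin]
    series: list[MetricSeries]
    covariates: pd.DataFrame
    selection: dict[str, ModelSelectionTable]           # metric -> table
    quadratic_fit: dict[str, np.ndarray]                # metric -> poly coeffs (deg 2)
    detrend_predictors: dict[str, list[str]]
    provenance: dict

    def series_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.series], ignore_index=True)


def _significant_sampling_predictors(table: ModelSelectionTable, alpha: float = 0.05) -> list[str]:
    """Sampling covariates in the AIC-best model with p < alpha."""
    fit = table.best_fit
    out = []
    for term in fit.terms:
        base_terms = term.split(":") if ":" in term else [term[:-2] if term.endswith("^2") else term]
        if any(t in ("map", "d18o") for t in base_terms):
            continue
        if fit.pvalues.get(term, 1.0) < alpha:
            out.append(term)
    return out


def run_fossil_analysis(config: RunConfig) -> FossilAnalysisResult:
    """Occurrences -> metrics -> bias control -> GLS model selection."""
    nalmas = list(reversed(load_nalma_bins()))      # oldest first
    n_bins = len(nalmas)
    seed = config.seed

    drivers = generate_driver_series(
        n_bins,
        phi=config.phi,
        innovation_sd=config.map_innovation_sd,
        trend=_default_map_trend(n_bins),
        seed=derive_seed(seed, "drivers"),
        ages=[b.midpoint_ma for b in nalmas],
        bin_ids=[b.name for b in nalmas],
    )
    if config.occurrences_csv:
        raw_records = parse_occurrences(config.occurrences_csv)
    else:
        pool = generate_species_pool(
            config.n_species, seed=derive_seed(seed, "pool"), lat_gradient=config.lat_gradient
        )
        taph = TaphonomyParams(n_localities=config.n_localities,
                               small_detection=config.small_detection)
        record = generate_fossil_record(
            pool, drivers, taph, seed=derive_seed(seed, "record"), lat_gradient=config.lat_gradient
        )
        raw_records = parse_occurrences(record)
    records = clean_taxa(raw_records)

    resample_spec = ResamplingSpec(
        n_localities=config.resample_n_localities,
        lat_min=config.resample_lat_min,
        lat_max=config.resample_lat_max,
        n_reps=config.resample_reps,
        seed=derive_seed(seed, "resample"),
    )
    metric_fns = {
        "beta_diversity": beta_diversity,
        "ltg_strength": lambda m: ltg(m, rescale=config.ca_rescale).r_squared,
    }

    raw_vals: dict[str, list[float]] = {m: [] for m in metric_fns}
    res_vals: dict[str, list[float]] = {m: [] for m in metric_fns}
    res_ses: dict[str, list[float]] = {m: [] for m in metric_fns}
    cov_rows = []
    kept_bins: list[NalmaBin] = []
    excluded: dict[str, str] = {}
    for nalma in nalmas:
        # bins whose matrices collapse under the occurrence filters are
        # excluded as too poorly sampled (with the reason recorded), the
        # same treatment real compilations give under-sampled subdivisions
        try:
            matrix = build_matrix(records, bin_label=nalma.name)
            bin_raw = {m: float(fn(matrix)) for m, fn in metric_fns.items()}
        except (EmptyMatrixError, ValueError) as err:
            logger.warning("bin %s excluded (insufficient sampling): %s", nalma.name, err)
            excluded[nalma.name] = str(err)
            continue
        kept_bins.append(nalma)
        cov = compute_bin_covariates(matrix, nalma)
        cov_rows.append({"bin": nalma.name, "n_localities": cov.n_localities,
                         "n_taxa": cov.n_taxa, "area_km2": cov.area_km2,
                         "lat_range_deg": cov.lat_range_deg, "bin_length_ma": cov.bin_length_ma})
        for m, fn in metric_fns.items():
            raw_vals[m].append(bin_raw[m])
            rs = standardized_resample(matrix, resample_spec, fn)
            res_vals[m].append(rs.mean)
            res_ses[m].append(rs.se)
    if len(kept_bins) < 5:
        raise RuntimeError(
            f"stage build_matrix: only {len(kept_bins)} usable bins (excluded: {excluded})"
        )

    bin_names = tuple(b.name for b in kept_bins)
    idx = [drivers.bin_ids.index(b) for b in bin_names]
    covariates = pd.DataFrame(cov_rows).set_index("bin")
    covariates["map"] = [drivers.map_mm[i] for i in idx]
    covariates["d18o"] = [drivers.d18o[i] for i in idx]

    series: list[MetricSeries] = []
    selection: dict[str, ModelSelectionTable] = {}
    quad: dict[str, np.ndarray] = {}
    detrend_preds: dict[str, list[str]] = {}
    terms = list(CLIMATE_TERMS + SAMPLING_TERMS)
    for m in metric_fns:
        raw = MetricSeries(bin_names, tuple(raw_vals[m]), "raw", metric=m)
        resampled = MetricSeries(bin_names, tuple(res_vals[m]), "resampled", metric=m,
                                 se=tuple(res_ses[m]))
        table = model_select(raw.values, covariates, terms=terms)
        preds = _significant_sampling_predictors(table)
        detrend_preds[m] = preds
        residual, _ = detrend(raw, _with_derived(covariates, preds), preds)
        series += [raw, resampled, residual]
        selection[m] = table
        quad[m] = np.polyfit(covariates["map"].to_numpy(), np.asarray(raw.values), 2)

    provenance = {
        "seed": seed,
        "config_hash": config.hash,
        "n_bins": n_bins,
        "bins_used": list(bin_names),
        "bins_excluded": excluded,
        "n_records_raw": len(raw_records),
        "n_records_clean": len(records),
    }
    result = FossilAnalysisResult(kept_bins, series, covariates, selection, quad,
                                  detrend_preds, provenance)
    if config.out_dir:
        _write_fossil_outputs(result, config)
    return result


def _with_derived(covariates: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    """Materialize derived terms (quadratics, interactions) as columns."""
    out = covariates.copy()
    for p in predictors:
        if p in out.columns:
            continue
        if ":" in p:
            a, b = p.split(":")
            out[p] = out[a] * out[b]
        elif p.endswith("^2"):
            out[p] = out[p[:-2]] ** 2
    return out


def _write_fossil_outputs(result: FossilAnalysisResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sf = result.series_frame()
    sf["config_hash"] = config.hash
    sf.to_csv(out / "metric_series.csv", index=False)
    cov = result.covariates.copy()
    cov["config_hash"] = config.hash
    cov.to_csv(out / "bin_covariates.csv")
    for m, table in result.selection.items():
        tab = table.table.copy()
        tab["model"] = tab["model"].map(lambda t: "+".join(t) if t else "(intercept)")
        tab["config_hash"] = config.hash
        tab.to_csv(out / f"model_selection_{m}.csv", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2)
    if config.make_figures:
        _fossil_figures(result, out)


def _fossil_figures(result: FossilAnalysisResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ages = [b.midpoint_ma for b in result.bins]
    styles = {"raw": dict(color="black"), "residual": dict(color="gray"),
              "resampled": dict(color="gray", linestyle="--")}
    metrics = sorted({s.metric for s in result.series})
    fig, axes = plt.subplots(len(metrics), 1, figsize=(7, 3 * len(metrics)), sharex=True)
    for ax, m in zip(np.atleast_1d(axes), metrics):
        for s in result.series:
            if s.metric == m:
                ax.plot(ages, s.values, label=s.variant, **styles[s.variant])
        ax.set_ylabel(m)
        ax.legend(fontsize=7)
    np.atleast_1d(axes)[-1].set_xlabel("age (Ma)")
    np.atleast_1d(axes)[-1].invert_xaxis()
    fig.tight_layout()
    fig.savefig(out / "fig_trends.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(metrics), figsize=(5 * len(metrics), 4))
    mapvals = result.covariates["map"].to_numpy()
    grid = np.linspace(mapvals.min(), mapvals.max(), 200)
    for ax, m in zip(np.atleast_1d(axes), metrics):
        raw = next(s for s in result.series if s.metric == m and s.variant == "raw")
        ax.scatter(mapvals, raw.values, color="black", s=18)
        ax.plot(grid, np.polyval(result.quadratic_fit[m], grid), color="gray")
        ax.set_xlabel("MAP (mm/yr)")
        ax.set_ylabel(m)
    fig.tight_layout()
    fig.savefig(out / "fig_map_response.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Projection stage

@dataclass
class ProjectionResult:
    metrics: pd.DataFrame          # scenario, metric, mean, se
    n_matrices: int
    model_quality: pd.DataFrame    # species, auc, tss, pcc
    provenance: dict


def run_projection_analysis(config: RunConfig) -> ProjectionResult:
    """Envelope models -> scenario projections -> pseudo-locality metrics."""
    seed = config.seed
    # the grid reaches well into tropical latitudes so that warm-adapted
    # species exist to occupy the sampling window under every warming
    # scenario (the study design includes equator-crossing faunas for the
    # same reason)
    grid_bounds = GeoBounds(-10.0, 70.0, DEFAULT_BOUNDS.lon_min, DEFAULT_BOUNDS.lon_max)
    grid = make_climate_grid(grid_bounds, resolution_deg=config.grid_resolution,
                             seed=derive_seed(seed, "grid"))
    # the pool spans the whole grid (not just the sampling window) so that
    # poleward-shifted ranges keep the window occupied under warming
    pool = generate_species_pool(config.projection_n_species, bounds=grid_bounds,
                                 seed=derive_seed(seed, "proj_pool"),
                                 temp_breadth=config.projection_temp_breadth)

    # 'observed' ranges are climate bands: each species occupies the cells
    # inside its temperature tolerance (abiotic filtering sets range edges,
    # so communities sort latitudinally — the structure the LTG measures,
    # and the structure climate-tracking projections translate poleward)
    mat = grid.cells["mat"].to_numpy()
    presences = {s.taxon: s.temp_suitability(mat) >= 0.5 for s in pool.species}
    counts = {t: int(p.sum()) for t, p in presences.items()}
    retained, removed = filter_rare(counts, min_cells=20)
    if not retained:
        raise RuntimeError("stage fit_envelope: no species retained after the rare filter")
    logger.info("projection: %d species retained, %d rare removed", len(retained), len(removed))

    models, quality = {}, []
    from .climate import evaluate  # local alias for clarity
    for t in retained:
        models[t] = fit_envelope(presences[t], grid)
        mt = models[t].train_metrics_
        quality.append({"species": t, "auc": mt.auc, "tss": mt.tss, "pcc": mt.pcc})

    # spatial distribution of sampling points: fit to a synthetic 'modern'
    # clustered locality set inside the study window, shared by all scenarios
    from .synthetic import _sample_clustered_localities
    rng = np.random.default_rng(derive_seed(seed, "proj_localities"))
    lats, lons = _sample_clustered_localities(300, 10, 4.0, DEFAULT_BOUNDS, rng)
    spatial_fit = fit_spatial_distribution(np.column_stack([lats, lons]))

    rows = []
    n_matrices = 0
    for label, delta in config.scenarios.items():
        sgrid = apply_scenario(grid, {"mat": delta, "wintert": delta}, label)
        ranges = {}
        for t in retained:
            pres = project(models[t], sgrid)
            if pres.sum() >= 2:
                ranges[t] = presences_to_range(sgrid, pres)
        vals = {"beta_diversity": [], "ltg_strength": []}
        for r in range(config.projection_reps):
            pts = sample_pseudo_localities(
                spatial_fit, config.pseudo_n_localities, bounds=grid_bounds,
                seed=derive_seed(seed, "proj_points", label, r),
            )
            try:
                matrix = project_ranges_to_matrix(ranges, pts, bin_label=label)
            except Exception as err:
                logger.warning("scenario %s replicate %d unusable: %s", label, r, err)
                continue
            n_matrices += 1
            vals["beta_diversity"].append(beta_diversity(matrix))
            vals["ltg_strength"].append(ltg(matrix, rescale=config.ca_rescale).r_squared)
        for m, v in vals.items():
            arr = np.asarray(v, dtype=float)
            se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
            rows.append({"scenario": label, "metric": m, "mean": float(arr.mean()),
                         "se": se, "n_reps": len(arr)})

    provenance = {"seed": seed, "config_hash": config.hash,
                  "n_species_retained": len(retained), "n_matrices": n_matrices}
    result = ProjectionResult(pd.DataFrame(rows), n_matrices, pd.DataFrame(quality), provenance)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dfm = result.metrics.copy()
        dfm["config_hash"] = config.hash
        dfm.to_csv(out / "projection_metrics.csv", index=False)
        result.model_quality.to_csv(out / "projection_model_quality.csv", index=False)
        with open(out / "projection_provenance.json", "w") as fh:
            json.dump(result.provenance, fh, indent=2)
    return result


def simulate_to_csv(config: RunConfig, out_dir) -> dict[str, str]:
    """Generate and write synthetic occurrences and drivers (CLI helper)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nalmas = list(reversed(load_nalma_bins()))
    drivers = generate_driver_series(
        len(nalmas), phi=config.phi, innovation_sd=config.map_innovation_sd,
        trend=_default_map_trend(len(nalmas)), seed=derive_seed(config.seed, "drivers"),
        ages=[b.midpoint_ma for b in nalmas], bin_ids=[b.name for b in nalmas],
    )
    pool = generate_species_pool(config.n_species, seed=derive_seed(config.seed, "pool"),
                                 lat_gradient=config.lat_gradient)
    record = generate_fossil_record(
        pool, drivers, TaphonomyParams(n_localities=config.n_localities,
                                       small_detection=config.small_detection),
        seed=derive_seed(config.seed, "record"), lat_gradient=config.lat_gradient,
    )
    occ_path = out / "occurrences.csv"
    drv_path = out / "drivers.csv"
    write_occurrences_csv(record, occ_path)
    write_drivers_csv(drivers, drv_path)
    return {"occurrences": str(occ_path), "drivers": str(drv_path)}
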