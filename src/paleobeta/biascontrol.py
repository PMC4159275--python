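"""Sampling-bias control: standardized resampling and residual detrending.

Fossil sampling intensity varies wildly between time bins, so two
standardizations separate sampling artifacts from biological signal:

* **standardized resampling** — each bin is subsampled (without
  replacement) to a fixed number of localities (default 30) drawn from a
  fixed latitude window (default 30-50 degrees N), the minimum-occurrence
  filter is re-applied, and the metric recomputed; the mean and standard
  error over replicates give the resampled series.
* **detrending** — the metric series is regressed (AR(1)-GLS) on the
  statistically significant sampling covariates and the residuals carried
  forward as the bias-corrected series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from ._seeding import derive_seed
from .gls import GlsFit, fit_gls_ar1
from .occio import EmptyMatrixError, OccurrenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ResamplingSpec",
    "MetricSeries",
    "ResampleResult",
    "standardized_resample",
    "detrend",
]

SAMPLING_COVARIATES = ("n_localities", "area_km2", "n_taxa", "lat_range_deg", "bin_length_ma")


@dataclass(frozen=True)
class ResamplingSpec:
    n_localities: int = 30
    lat_min: float = 30.0
    lat_max: float = 50.0
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_localities < 3:
            raise ValueError("need at least 3 localities per draw")
        if not self.lat_min < self.lat_max:
            raise ValueError("latitude window must have min < max")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass(frozen=True)
class MetricSeries:
    """A metric (beta diversity or LTG strength) over ordered bins."""

    bins: tuple[str, ...]
    values: tuple[float, ...]
    variant: str                       # 'raw' | 'resampled' | 'residual'
    metric: str = ""
    se: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.values):
            raise ValueError("one value per bin required")
        if self.variant not in ("raw", "resampled", "residual"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin": self.bins, "variant": self.variant,
                           "metric": self.metric, "value": self.values})
        if self.se is not None:
            df["se"] = self.se
        return df


@dataclass(frozen=True)
class ResampleResult:
    mean: float
    se: float
    values: tuple[float, ...]
    skipped: bool = False
    reason: str = ""


def standardized_resample(
    matrix: OccurrenceMatrix,
    spec: ResamplingSpec,
    metric: Callable[[OccurrenceMatrix], float],
) -> ResampleResult:
    """Subsample a bin to a standardized locality count inside the window.

    Each replicate draws exactly ``spec.n_localities`` in-window localities
    without replacement, re-applies the minimum-occurrence filter, and
    evaluates ``metric``. Bins with too few in-window localities are
    flagged and skipped, not imputed.
    """
    lats = matrix.latitudes
    in_window = (lats >= spec.lat_min) & (lats <= spec.lat_max)
    pool = [loc for loc, ok in zip(matrix.localities, in_window) if ok]
    if len(pool) < spec.n_localities:
        logger.warning(
            "bin %s: only %d in-window localities (< %d); skipped",
            matrix.bin_label, len(pool), spec.n_localities,
        )
        return ResampleResult(float("nan"), float("nan"), (), skipped=True,
                              reason=f"{len(pool)} in-window localities < {spec.n_localities}")
    vals = []
    for r in range(spec.n_reps):
        rng = np.random.default_rng(derive_seed(spec.seed, "resample", matrix.bin_label, r))
        draw = rng.choice(pool, size=spec.n_localities, replace=False)
        try:
            sub = matrix.subset_localities(draw)
            vals.append(float(metric(sub)))
        except (EmptyMatrixError, ValueError) as err:
            logger.warning("bin %s replicate %d unusable after filtering: %s",
                           matrix.bin_label, r, err)
    if not vals:
        return ResampleResult(float("nan"), float("nan"), (), skipped=True,
                              reason="all replicates emptied by filtering")
    arr = np.asarray(vals)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    return ResampleResult(float(arr.mean()), se, tuple(vals))


def detrend(
    series: MetricSeries,
    covariates: pd.DataFrame,
    predictors: list[str],
) -> tuple[MetricSeries, GlsFit]:
    """Regress a metric series on sampling predictors; return residuals.

    The regression is AR(1)-GLS over bin order (intercept included), so
    residuals are centred and their variance cannot exceed the original.
    A rank-deficient design is rejected with the collinear columns named.
    """
    missing = [p for p in predictors if p not in covariates.columns]
    if missing:
        raise ValueError(f"predictors not in covariate table: {missing}")
    if len(covariates) != len(series.bins):
        raise ValueError("covariate table must align with the metric series bins")
    X = covariates[list(predictors)].astype(float)
    full = np.column_stack([np.ones(len(X)), X.to_numpy()])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        collinear = _find_collinear(X)
        raise ValueError(f"singular design; collinear columns: {collinear}")
    y = np.asarray(series.values, dtype=float)
    fit = fit_gls_ar1(y, X)
    residual = replace(series, values=tuple(fit.residuals), variant="residual", se=None)
    return residual, fit


def _find_collinear(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (greedy)."""
    cols = list(X.columns)
    bad = []
    for c in cols:
        others = [o for o in cols if o != c and o not in bad]
        design = np.column_stack([np.ones(len(X))] + [X[o].to_numpy(dtype=float) for o in others])
        if np.linalg.matrix_rank(design) == design.shape[1]:
            bad.append(c)
    return bad or cols
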