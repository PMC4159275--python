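# Methods

`paleobeta` implements a complete, synthetic-data-testable pipeline for
studying how mammal community composition varies across space and time:
from occurrence tables to per-bin diversity statistics, through
sampling-bias control, to autoregressive inference of climate drivers and
a simplified climate-envelope projection stage. This note documents the
models, the choices made where the design was genuinely open, and what the
synthetic experiments do and do not establish.

## Community statistics

**Beta diversity — multivariate dispersion.** Each time bin yields a
binary locality-by-taxon matrix. Pairwise Jaccard dissimilarities
`d = 1 − |A∩B|/|A∪B|` are embedded by principal coordinates analysis
(Gower double-centering of −d²/2, full eigendecomposition). Because
Jaccard distances are non-Euclidean, some eigenvalues are negative; the
corresponding axes form an imaginary part of the space. Following
Anderson's multivariate-dispersion construction, the squared distance of
locality *i* to the centroid is the squared real-axis distance *minus*
the squared imaginary-axis distance; rare negative squared distances
(possible on small matrices) are clamped to zero and counted. Beta
diversity is the mean distance to centroid. The implementation reproduces
vegan's `betadisper(…, type="centroid")` to 1e-7 on a frozen fixture
(tests/test_metrics.py).

**LTG strength — correspondence analysis.** The first
correspondence-analysis axis orders localities along the dominant
compositional gradient. Two algorithms are implemented — reciprocal
averaging iterated to a 1e-10 score change, and the SVD of the chi-square
standardized residual matrix — and must agree to 1e-6; scores are
standard coordinates (row-mass-weighted mean 0, variance 1), matching
vegan's `cca` site scores with `scaling="none"`. LTG (latitudinal
turnover gradient) strength is the R² of an OLS regression of axis-1
scores on locality latitude.

*Nonlinear rescaling.* A simplified Hill-style rescaling is implemented
(segment-based, order-preserving deformation equalizing the local
within-site dispersion of species scores; 26 segments by default) and can
be enabled per call. The pipeline default is **off**: on matrices of
30–60 localities the deformation roughly doubles the replicate variance
of the latitude R² without changing the axis ordering, and every
comparison the pipeline makes (across bins, variants, or scenarios) is
cleaner on the linear scores. Only axis 1 is computed; detrending by
segments affects higher axes and cannot change the axis-1 ordering, so
full DCA detrending is out of scope.

## Occurrence preparation

Taxonomic cleaning follows the standard rules for fossil compilations:
open-nomenclature identifications (cf., aff.) are accepted as the named
species; indeterminate "sp." records are dropped unless they are the only
record of their genus in the bin (judged per bin, since matrices are
built per bin); *Homo sapiens* is excluded. Taxa and localities with
fewer than two occurrences are removed **iteratively to a fixed point**,
since removing a locality can strand a taxon and vice versa; a one-pass
removal can leave violating rows. Bins whose matrices collapse entirely
under these filters are excluded from the analysis with the reason
recorded in the run provenance, the same treatment real compilations give
under-sampled subdivisions.

Per-bin sampling covariates are the locality count, taxon count,
latitudinal range, bin length (Ma), and sampled area. Area is the
spherical convex hull of locality coordinates (fan triangulation,
l'Huilier spherical excess, R = 6371 km) — a standard, parameter-free
choice; the original compilations do not state their area method, so
absolute areas need not match published tables.

## Pseudo-localities and bias trials

To sample modern or projected ranges comparably to the fossil record,
frequency distributions are fitted to fossil-locality coordinates —
latitude and longitude as independent marginals, each by maximum
likelihood under normal, gamma, and beta families, the family chosen per
axis by AIC. Gamma and beta use affine support transforms estimated from
the data span (0.5% padding so all points are interior); each family
contributes two fitted parameters, keeping AICs comparable. Pseudo-
locality sets are drawn from the fitted marginals with rejection outside
the study bounds (an error if acceptance falls below 1%).

Bias trials remove ⌊fraction × pool⌋ taxa — uniformly (taxonomic bias) or
uniformly among species lighter than 5 kg (taphonomic small-mammal bias;
random rather than smallest-first, since the record's size bias is noisy)
— and re-apply the minimum-occurrence filter. Replicate ensembles derive
per-replicate seeds from a base seed by counter hashing, so any replicate
is reproducible in isolation and ensembles are order-independent.

## Sampling-bias control

Standardized resampling subsamples each bin, without replacement, to 30
localities within 30–50°N (both configurable), 100 replicates, reporting
mean ± s.e.; bins with too few in-window localities are flagged and
skipped, not imputed. Detrending regresses a metric series on the
sampling covariates that are significant (p < 0.05) in the AIC-best
model — refit without climate terms — using the same AR(1)-GLS machinery,
and carries the residuals forward. Both the resampled and residual series
are reported alongside the raw series.

## AR(1)-GLS and model selection

Metric series over consecutive bins are modelled as
`y = Xβ + ε, ε ~ AR(1)(φ)` with the correlation indexed by bin order
(corAR1-style; a continuous-age alternative can be obtained by
interpolating covariates at midpoints). Estimation is maximum likelihood:
the model is whitened by the AR(1) Cholesky factor (Prais–Winsten), β and
σ² are profiled out by OLS, and the profile likelihood is maximized over
φ ∈ (−0.99, 0.99) by bounded scalar optimization. ML rather than REML so
AIC is comparable across fixed-effect structures; k counts coefficients
plus φ plus σ². Standard errors use the unbiased variance with n − p
degrees of freedom, matching nlme's `gls` t-table; the full fit agrees
with `nlme::gls(…, corAR1, method="ML")` to ~1e-8 on a frozen fixture.

Model selection enumerates all predictor subsets respecting marginality
(a quadratic term requires its main effect; an interaction requires both
main effects) over MAP, MAP², δ¹⁸O, and the five sampling covariates plus
the area × taxa interaction — 240 models — and ranks by AIC. "Variance
explained (%)" is the squared Pearson correlation between fitted and
observed values × 100; this quantity is not defined in the source
compilations, so cross-study comparisons of it carry that caveat.
Covariates are z-scored before fitting (AIC ranking is invariant; the
optimization is better conditioned).

## Climate-space models

Species climate spaces are modelled on a regular 1° grid carrying mean
annual temperature, winter temperature, and annual precipitation, by a
two-member consensus: a surface range envelope (per-variable
[2.5, 97.5] percentile bounds at presence cells) and a logistic
regression with linear + quadratic terms of each z-scored variable (the
polynomial form is the GLM convention in distribution modelling; a
linear-only predictor cannot express an interior climate optimum).
Consensus probability is the member mean; presence is binarized at the
threshold maximizing the training true skill statistic. Complete
separation in the logistic member falls back to envelope-only with a
warning. Performance is reported as AUC (rank formulation), TSS, and
PCC. The two members stand for the behaviour *class* of climate-tracking
models — the conclusions concern that class, not any particular learner —
and larger member ensembles would not change the translation property the
projections exhibit.

## The synthetic world

The generator supplies everything the real analysis would download, with
the statistical structure the methods assume:

* **Species pool** — geodesic-disk ranges with lognormal radii (median
  5°, log-sd 0.6: many small ranges, few continental), lognormal body
  masses (median 1 kg, log-sd 2), Gaussian climate tolerances. MAP
  optima are drawn N(450, 150) mm/yr with tolerance breadth 120 mm/yr;
  temperature optima equal the reference climate at the range centre
  with breadth 3 °C.
* **Climate field** — T(lat) = 12 − 0.6·(lat − 40) °C, a realistic
  continental lapse centred on the study window so that flattening the
  gradient (the LTG experiment) removes latitudinal *sorting* without
  pushing every species off its optimum.
* **Drivers** — MAP follows a cyclical trend (450 ± 230 mm/yr) with
  stationary AR(1) noise (φ = 0.4, innovation sd 40); the δ¹⁸O-like
  proxy rises toward the present with its own AR(1) noise.
* **Taphonomy** — localities cluster around Gaussian kernels (fossil
  localities are strongly clustered); detection is a monotone step in
  body mass (probability 0.35 below 5 kg, 1 above).
* **Occupancy** — the MAP suitability factor is applied as a *bin-level*
  persistence draw (the species joins the bin's regional pool with
  probability suit_MAP), with range membership, detection, and
  temperature suitability acting per locality. The marginal per-locality
  occurrence probability is the product of all four factors. The
  bin-level draw is what plants the concave beta–MAP response: away from
  the optimum whole species drop out of the regional pool and among-
  locality turnover falls. A purely per-locality thinning produces the
  opposite pattern (sparser matrices have *higher* Jaccard dispersion),
  which is a sampling artifact, not community structure.

The projection stage uses a separate construction: the grid spans
−10…70°N so warm-adapted species exist under every warming scenario
(mirroring the inclusion of equator-crossing faunas in continental
compilations), and 'observed' species ranges are temperature-tolerance
bands (breadth 2.5 °C) — abiotic filtering sets range edges, giving the
latitudinally sorted communities whose turnover the LTG measures. Under a
uniform warming delta, the true community field is an exact poleward
translation; the projection experiment asks whether fitted climate-space
models reproduce that translation (they do: beta diversity and LTG
strength change by < ~5% up to +6.78 °C at the default pool of 300
species).

**What the synthetic results do not show.** The generator has no
coastlines or ocean masking, no dispersal limits, no evolution, no
species interactions, no time-averaging within bins, and independent
lat/lon marginals for locality placement. Passing tests demonstrate that
the *statistical machinery* recovers planted signals under the stated
assumptions — not that real faunas obey those assumptions.

## Numerical choices and degenerate inputs

* PCoA eigenvalue sign threshold: 1e-9 × the spectral radius.
* Negative squared centroid distances are clamped at 0 and counted.
* Reciprocal averaging converges at a 1e-10 maximum score change
  (typically < 500 iterations); ties in CA orderings are resolved by the
  deterministic eigensolver.
* φ is constrained to (−0.99, 0.99); optimizer tolerance 1e-6.
* The max-TSS threshold scans the unique consensus probabilities and
  takes the lowest maximizer.
* Degenerate inputs raise informative errors: constant coordinate axes,
  zero-variance latitude, one-class evaluation (AUC/TSS reported as
  missing), matrices emptied by filtering (the bin is named).

## Problem sizes

Default study sizes — 21 bins, 150 species, 80 localities per bin, 100
resampling replicates, 300 projection species with 30 replicate
pseudo-locality sets per scenario — run the full fossil analysis in a few
seconds and the projection analysis in well under a minute on one CPU.
The acceptance script (scripts/acceptance.py) re-runs the replicate
bookkeeping at the study's printed ensemble sizes (2100 / 6300 / 16,800
matrices) with deliberately small per-matrix dimensions, chosen so the
counting exercise measures the machinery rather than the matrices.
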