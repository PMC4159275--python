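# paleobeta

Statistics and simulation tools for studying **spatiotemporal mammal
community composition**: how much communities differ across a landscape
(β diversity), how strongly that compositional turnover is organized by
latitude (latitudinal turnover gradients, LTGs), which climate and
sampling variables drive those quantities through deep time, and what
climate-envelope models project for them under future warming.

The package is aimed at paleoecologists and macroecologists working with
occurrence compilations (PBDB/MIOMAP-style tables binned into North
American Land Mammal Age subdivisions) and at anyone who wants a tested,
fully synthetic-data-exercisable implementation of this analysis chain.

## The statistics

For each time bin's binary locality × taxon matrix **X**:

* **β diversity** is Anderson's multivariate dispersion: with Jaccard
  dissimilarities d(i,j) = 1 − |A∩B|/|A∪B| embedded by principal
  coordinates analysis, β is the mean Euclidean distance of localities to
  their centroid, `β = (1/n) Σᵢ zᵢ`, where `zᵢ² = Δ²ᵢ(real) − Δ²ᵢ(imag)`
  accounts for the negative eigenvalues of the non-Euclidean embedding.
* **LTG strength** is the R² of ordinary least squares of
  correspondence-analysis axis-1 site scores on locality latitude.
* **Drivers** are inferred by generalized least squares with AR(1) errors
  over bin order (`y = Xβ + ε`, `εₜ = φεₜ₋₁ + ηₜ`), fitted by profile
  maximum likelihood and compared by ΔAIC across all predictor subsets
  respecting marginality (MAP² requires MAP; area : taxa requires both).
* **Projections** use a two-member climate-envelope consensus (surface
  range envelope + polynomial logistic regression) on a 1° climate grid,
  binarized at the max-TSS threshold and evaluated by AUC/TSS/PCC.

Sampling-bias control includes standardized resampling (30 localities,
30–50°N, 100 replicates per bin), taxonomic and body-mass (< 5 kg)
removal trials, and residual detrending against significant sampling
covariates. A synthetic-data module generates species pools, AR(1)
driver series, and clustered, detection-biased fossil records with
planted climate responses, so the whole chain runs and is tested without
any external downloads.

## Worked example

```python
from paleobeta.pipeline import RunConfig, run_fossil_analysis

cfg = RunConfig(seed=1, resample_reps=20, make_figures=False)
res = run_fossil_analysis(cfg)

raw_beta = next(s for s in res.series
                if s.metric == "beta_diversity" and s.variant == "raw")
print(f"bins analysed: {len(res.bins)}")
print(f"beta diversity range: {min(raw_beta.values):.3f}-{max(raw_beta.values):.3f}")
a, b, c = res.quadratic_fit["beta_diversity"]
print(f"beta~MAP quadratic coefficient: {a:.2e} (peak at {-b/(2*a):.0f} mm/yr)")
table = res.selection["beta_diversity"]
print(f"AIC-best beta model: {' + '.join(table.best_terms)}")
print(f"variance explained: {table.table.iloc[0]['var_explained']:.1f}%")
```

prints

```
bins analysed: 21
beta diversity range: 0.444-0.640
beta~MAP quadratic coefficient: -1.09e-06 (peak at 465 mm/yr)
AIC-best beta model: map + d18o + lat_range_deg + bin_length_ma
variance explained: 75.8%
```

The generator plants a community MAP optimum at 450 mm/yr; the negative
quadratic coefficient with an interior peak near 465 mm/yr is that signal
recovered through the full pipeline (occurrence cleaning, the ≥2-
occurrence filter, Jaccard/PCoA dispersion, and the per-bin covariates).
The AIC-best model is reported with its variance explained (squared
correlation of fitted and observed, ×100); which sampling covariates
join MAP in the best model varies with the seed, as it does across real
compilations.

A command-line interface wraps the same calls:

```bash
paleobeta simulate   --seed 1 --out runs/sim        # synthetic occurrence + driver CSVs
paleobeta fossil-run --seed 1 --out runs/fossil     # metrics, model selection, figures
paleobeta project-run --seed 1 --out runs/proj      # climate-envelope projections
paleobeta report runs/fossil
```

## Layout

```
src/paleobeta/
  synthetic.py       species pools, driver series, fossil-record generator
  occio.py           occurrence parsing, cleaning, matrices, NALMA bins
  pseudolocality.py  spatial-distribution fitting, pseudo-localities, bias trials
  metrics.py         Jaccard, PCoA, multivariate dispersion, CA, LTG strength
  biascontrol.py     standardized resampling, residual detrending
  gls.py             AR(1)-GLS, model enumeration, delta-AIC selection
  climate.py         climate grids, envelope-consensus models, projections
  pipeline.py / cli.py  orchestration and command-line verbs
docs/methods.md      model and design documentation
```
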