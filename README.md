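# rsfpipe

Seasonal resource-selection analysis for GPS-collared animals in
agricultural landscapes — telemetry cleaning, used/available design
construction, random-intercept logistic habitat-selection models with AIC
competition over land-cover aggregation hypotheses, selection-probability
curves and landscape prediction maps, and a raster similarity metric for
comparing seasonal maps.  Everything runs end to end on a synthetic study
with known ground truth, so the whole pipeline is testable without any
data download.

The package is aimed at movement ecologists analyzing collar data against
a categorical land-cover raster (CDL-style, 30 m cells) and mapped
flowlines, and at anyone who wants a tested, self-contained reference
implementation of this analysis pattern.

## The model

For each animal *i* and season, used GPS fixes (y = 1) are paired 1:1
with available points (y = 0) drawn uniformly from the individual's
seasonal 100% minimum convex polygon, and fit with a binomial GLMM:

    logit P(y_ij = 1) = β₀ + Σ_c β_c x_c,ij + β_f,l x_f,ij + β_f,q x²_f,ij + b_i
    b_i ~ N(0, σ_b²)

where x_c is proportional coverage by land-cover category c within a
100 m buffer, and x_f is the standardized distance to the nearest
flowline (quadratic term centered before squaring).  The marginal
likelihood is maximized with adaptive Gauss–Hermite quadrature (15
nodes).  Four a-priori code-to-category aggregation hypotheses (H1–H4)
are competed by AIC per season; the winner feeds:

- **selection curves** p(l) = logistic(β₀ + β_c P + β_w (1−P) + flowline
  terms) along the crop/wetland proportionality gradient P, and
- **prediction maps** of relative selection probability per raster cell,

and seasonal maps are compared with the similarity metric

    S = 1 − Σ d²ᵢⱼ / Σ Δ²ᵢⱼ,   Δᵢⱼ = max(Bᵢⱼ, 1 − Bᵢⱼ),

which scores 1 for identical maps and 0 for a map as different from the
target B as any binary raster can be.

## Worked example

The analysis is organised as numbered scripts over the library; each
stage writes under `results/` and prints what it found.  A full run
(13 collared animals, 300 × 300-cell landscape):

```bash
python analysis/01_simulate_study.py   # synthetic landscape, flowlines, tracks
python analysis/02_qc_tracks.py        # speed filter, trimming, binning, screen
python analysis/03_build_design.py     # seasons, MCPs, used/available tables
python analysis/04_fit_models.py       # AIC competition + seasonal GLMM fits
python analysis/05_selection_curves.py # crop/wetland gradient curves
python analysis/06_prediction_maps.py  # landscape projection per season
python analysis/07_compare_maps.py     # pairwise map similarity
```

Output from a full run, abridged (`--small` gives a 6-animal quick look):

```
=== 01_simulate_study ===
simulated 14 collared animals, 52464 raw fixes
injected 1032 speed spikes; one dependent pair (pig00_dep duplicates pig00)
=== 02_qc_tracks ===
14 tracks in, 13 retained after the dependence screen; 52464 fixes in, 46976 after cleaning
  speed_filter: removed 1032 fixes
  removed pig00_dep (pair ('pig00', 'pig00_dep'), r_x=0.998, r_y=0.998)
=== 03_build_design ===
early_growing: n = 10 individuals, mean 894 fixes/individual, range 889-898
scheme H1: 93340 used+available rows, 9 predictors
=== 04_fit_models ===
early_growing: winner H1 (runner-up dAIC 36.7, decisive=True); sigma_b=0.02, max VIF 12.29
  significant terms at alpha=0.05: prop_Corn, prop_Wetland, dist_flow_std, dist_flow_quad_std
=== 07_compare_maps ===
	early_growing	fallow	harvest	late_growing
early_growing	1.0000000
fallow	0.9791965	1.0000000
harvest	0.9590468	0.9774705	1.0000000
late_growing	0.9672736	0.9952370	0.9886070	1.0000000
```

Reading the output: the speed filter removed exactly the 1,032 injected
spike fixes; the dependence screen caught the injected companion animal
(coordinate correlations 0.998 on both axes) and removed one member of
the pair; the AIC competition recovered the generating aggregation
hypothesis (H1 — individual crops with wetland distinct from other
natural cover) decisively in all four seasons; and the similarity
matrix's diagonal is exactly 1.0000000, with off-diagonal entries
quantifying how the seasonal space-use predictions differ.  Coefficients,
Wald tables, curves, and prediction grids land under `results/derived/`.

The same pipeline runs from a single config via the library:

```python
from rsfpipe import PipelineConfig, run_full
art = run_full(PipelineConfig(master_seed=42), outdir="results/run42")
art.rankings["harvest"].winner     # AIC-winning aggregation, e.g. 'H1'
art.similarity.lower_triangle()    # Table-style similarity rendering
```

Real data drop in by pointing `PipelineConfig` at a relocation table
(`id,timestamp,x,y` CSV, projected meters), an ESRI ASCII land-cover grid,
and a WKT flowline file, with a code-to-category scheme matching your
raster.

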