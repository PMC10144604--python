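# Methods

## Problem setting

National immunization programmes want to know whether the districts
holding the most zero-dose children (no-DTP: no dose of any
diphtheria–tetanus–pertussis-containing vaccine, the standard operational
proxy for zero-dose status) also carry the highest burden of other health
indicators. `zdoverlap` quantifies that geographic overlap from gridded
prevalence surfaces or pre-aggregated district tables. It works on point
(mean) estimates only; no uncertainty intervals are propagated, and no
geostatistical estimation of the surfaces themselves is performed — they
are consumed as given.

## Fractional aggregation

Pixel estimates are aggregated to districts by exact polygon–pixel area
intersection. For pixel *p* and district *d*, the weight `w_pd` is the
fraction of the pixel's area inside the district, computed by shapely
polygon clipping (never centroid assignment, which would break
conservation at boundaries). District prevalence is the
population-weighted mean over contributing pixels, the district target
population is `Σ_p pop_p · w_pd`, and counts are prevalence × population.
Consequences tested as invariants:

* when districts tile the raster, total population and total counts are
  conserved to 1e-9 relative tolerance;
* district prevalence lies within the range of contributing pixel values;
* scaling the population surface leaves prevalence unchanged and scales
  counts linearly.

Nodata pixels are excluded from numerator and denominator alike; treating
them as zero would bias district means. Districts with zero aggregated
population (or all-nodata coverage) carry missing prevalence, are logged,
and are excluded from classification. Area fractions are applied to both
indicator and population grids. All areas are computed in the input
coordinate system; nothing is reprojected implicitly, and a CRS label
mismatch between raster and polygons is an error, because silent
reprojection changes area weights. Counts remain real numbers — both
inputs are modelled, continuous quantities — and are never rounded to
whole persons.

The reference burden is derived from a coverage surface as
`no-DTP = 1 − DTP1`, applied elementwise to tables or rasters with range
validation.

## Population-weighted quantile classification

Within a scope unit (one country, or the pooled multi-country set),
districts are sorted ascending by burden value, ties broken by district id
so results are deterministic. With total target population `T` and
cumulative population accumulated in that order, a district whose
cumulative span has midpoint `m` is assigned to bin `k` iff
`m ∈ ((k−1)·T/n_bins, k·T/n_bins]`; a midpoint exactly on a boundary falls
in the lower bin. This midpoint rule keeps each district in exactly one
bin (no splitting, even for districts larger than `T/n_bins`) and bounds
every bin's population deviation from `T/n_bins` by the largest single
district population — the precise sense in which bins hold "roughly
equal" population. Equal district weights reduce the rule to ordinary
rank quantiles, and any strictly increasing transform of the burden
values leaves assignments unchanged.

Districts missing a value for one indicator are excluded from that
indicator's classification only, with `T` recomputed over the remainder.
A scope unit with fewer districts than bins is an error naming the unit.

The rule is implemented as `PopulationWeightedDiscretizer`, an
sklearn-compatible transformer (fit learns the weighted bin structure and
value thresholds; transform bins unseen values against those thresholds).
Alternative prioritization schemes beyond a configurable `n_bins` are out
of scope.

## Overlap summaries

Cross-tabulations are computed over districts classified for both
indicators; the exact-match proportion is the diagonal share. Highest-bin
overlap is reported under both denominators that appear in practice —
districts high for the reference, and districts high for either
indicator — with the choice explicit in every call. Empty denominators
yield NaN with a warning rather than an error. Multi-indicator counts
(`n_high` per district, plus whether the reference is among the top-bin
indicators) require all assignments to share bin count, scope and basis.
No inferential statistics are attached to any of these; they are
descriptive point summaries.

## Serial-targeting AUC

Districts are ordered by descending reference counts (ties by ascending
district id), and the curve of cumulative comparator proportion (y)
against cumulative reference proportion (x) is anchored at the origin.
The AUC is the trapezoidal integral over these points. The trapezoid rule
is the one choice that makes the proportional-comparator anchor exact for
any number of districts: if comparator counts are district-wise
proportional to reference counts the curve is the diagonal and AUC = 0.5
identically (verified to 1e-12). A step-function integral would only
approach 0.5 as districts grow many; step plots are treated as a
visualization style, not the metric. AUC is invariant to rescaling either
count vector and always lies in [0, 1]. Districts missing either count are
dropped from both vectors (complete-case alignment, logged). The AUC panel
computes curves within country (and per year when a `year` column is
present), skipping country–indicator cells with no counts.

## Synthetic data

The generator emulates the statistical structure of the real inputs at
desk scale; defaults (chosen once):

| parameter | default | rationale |
|---|---|---|
| `n_countries` | 5 | mirrors a five-country multi-country study |
| `districts_per_country` | 64 | a few hundred districts total, admin-2 order of magnitude |
| population | log-normal, median 1e4, `sigma = population_dispersion = 1.0` | district birth-cohort sizes are strongly right-skewed; the heavy tail is what makes prevalence- and count-based classification diverge |
| `prevalence_range` | (0.02, 0.6) | spans low- to high-burden districts without saturating either bound |
| `rank_correlation` | 0.5 | moderate spatial concordance between indicators |

Reference prevalence is uniform over the range via a Gaussian latent
variable; the comparator couples to it through a Gaussian copula with
Pearson parameter `ρ_g = 2 sin(π ρ_s / 6)` so the *Spearman* correlation
matches the requested value in expectation — association is targeted on
ranks because every downstream classification is rank-based. At ±1 the
coupling is exactly comonotone/antitone. Coupling, like classification, is
per country. Everything is driven by one `numpy` Generator seed; identical
specs give byte-identical CSV output.

Rasterization lays districts out as rectangular pixel blocks (countries as
block rows), with uniform within-district pixel populations summing to the
district total, so aggregation round-trips the table to 1e-9. Optional
within-district prevalence noise is exactly mean-centred per block and off
by default so the round trip stays exact; noise large enough to push
pixels outside [0, 1] is rejected rather than clipped (clipping would
break mean preservation silently).

What the generator does **not** emulate: realistic district geometries
(blocks, not GADM-style polygons), spatial autocorrelation between
neighbouring districts, posterior uncertainty of modelled surfaces, or
survey microdata structure. Passing tests therefore demonstrate the
correctness of the aggregation/classification/overlap arithmetic, not the
field realism of any particular overlap value.

## Numerical and I/O choices

* Bin assignment uses `ceil(m·n_bins/T − 1e-12)` so floating-point drift
  at exact boundaries resolves to the lower bin, matching the half-open
  interval definition.
* GeoTIFF I/O supports single-band, north-up rasters with
  ModelPixelScale/ModelTiepoint georeferencing, the GDAL nodata tag, and
  a minimal GeoKeyDirectory carrying an EPSG code. Polygons are GeoJSON
  with configurable district/country attribute names (defaults
  `ADM2_CODE` / `ADM0_NAME`).
* The pipeline writes every figure's plotted values as a CSV sidecar and
  a provenance JSON (config echo + package version); a stage failure
  removes the partial outputs of that run and re-raises with the stage
  name.

## Problem sizes used in the test suite

Property suites run at deliberately small scale: aggregation oracles on
grids ≤ 10×10 with rectangular districts, classification oracles on ≤ 8
districts, AUC oracles on 1–6 districts × 100 random count vectors,
population balance on 200 tables of 4–1000 districts, and the stochastic
monotonicity check on 200 replicates of 48 districts per rank-correlation
level (mean AUC rises strictly across ρ_s ∈ {−0.9, 0, 0.9}). These sizes
keep the full suite to a few seconds while exercising every boundary case
the rules define.

## Known limitations

* Only axis-aligned, north-up rasters are supported; rotated or sheared
  transforms are rejected.
* No shapefile reader; district polygons must be GeoJSON.
* CRS handling is label-matching only — the package never reprojects, it
  just refuses mismatched labels.
* Overlapping district polygons are not detected; pixel fractions are
  computed per district independently and may then sum above 1.
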