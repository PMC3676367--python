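# Methods

## Problem and model

A replicated field trial is imaged with a thermal camera whose footprint
covers only a small patch of the field (up to 9 plots across and 3–4 rows),
so a survey is a sequence of dozens of images taken minutes apart. Between
images, cloud cover, wind and irradiance move whole-image temperatures by
several °C, while the genotypic signal of interest is on the order of
0.5 °C. The package's working model for an observed plot temperature is
additive on the Celsius scale:

    T(p, i) = b_i + g(G(p)) + d(G(p)) + u_p + e_{p,i}

with `b_i` an image-level environmental baseline, `g` a stable genotype
effect, `d` an optional genotype-by-day perturbation, `u_p` a per-plot
(replicate) deviation constant across images, and `e_{p,i}` independent
observation noise. Everything downstream rests on the assumption that the
environmental disturbance is an additive per-image shift; the image-mean
differencing chain (IINPT → NPT → genotype means) removes exactly that term,
identically in the data, not just in expectation. The synthetic generator
realises the same model, so simulations probe estimator variance, not model
misspecification; a multiplicative genotype × irradiance interaction switch
(`interaction_scale`) exists, off by default, to probe what happens when the
additivity assumption fails.

## Estimators

**Differencing.** IINPT = IPT − image mean (over QC-passing plots only, so a
soil-contaminated plot cannot bias the normaliser); NPT = unweighted mean of
a plot's IINPTs; genotype mean = unweighted mean over replicate plots. All
means average plot values, never pixels. Per image, IINPTs sum to zero by
construction; adding any constant to one image's observations changes no
downstream quantity beyond 1e-9 °C.

**Additive fixed-effects model.** OLS on `T = mu + g + h` with genotype and
image indicator blocks, solved by minimum-norm least squares and centred to
the sum-to-zero parameterisation. This is a deliberate fixed-effects
stand-in for a REML mixed-model adjustment; variance components are out of
scope. Identifiability requires the genotype–image incidence graph to be
connected — note genotypes, not plots: a genotype's replicates bridge images
even when no plot appears twice. On a disconnected graph the fit warns and
lists image components, and only within-component contrasts are meaningful.

The two estimators coincide exactly only when images are equal-sized, cover
each plot once, and each contains every genotype equally often (then the
OLS adjustment of image means for genotype composition vanishes). On
overlapping acquisitions they differ but agree to Pearson r > 0.95 under the
default scenario; the comparison reports r, mean difference and the
major-axis slope so systematic bias would show as slope ≠ 1.

## Synthetic data: what it emulates and what it does not

Defaults (chosen once to match the study's qualitative features):

| parameter | default | meaning |
|---|---|---|
| sigma_g | 0.4 °C | genotype-effect SD; gives a ~2 °C genotype range |
| drift_sd | 0.2 °C/image | baseline random-walk step SD |
| cloud_step_prob / size | 0.05 / 4 °C | sky-state toggle; arrival subtracts, clearing restores |
| sigma_plot | 0.3 °C | per-plot replicate deviation, constant within an occasion |
| sigma_obs | 0.15 °C | per-observation measurement noise |
| sigma_day | 0 (pipeline: 0.1 °C) | genotype-by-day perturbation |
| footprint / advance / jitter | 8×3 / 4×2 / 1 | overlap plan, mean coverage ≈ 2 images/plot |
| soil_temp | 35 °C | background for rendered frames (sunlit soil runs hotter) |

The scenario field list carries `sigma_obs` explicitly because the
generative model needs both a per-plot and a per-observation noise term.
Plot deviations are redrawn independently between occasions — transient
micro-environment rather than persistent soil differences — which is why
averaging days recovers estimation accuracy; a persistent plot effect would
not average out. Perspective distortion of the oblique camera view, canopy
segmentation, wind/boundary-layer physics and radiometric calibration are
not modelled: rendered frames are axis-aligned canopy rectangles (cells
eroded 22 % per side, emulating polygons drawn well inside the canopy) on a
uniform hot-soil background. Passing tests therefore demonstrate that the
chain recovers known inputs under the stated noise structure, not that the
camera-side assumptions hold in a real field.

The trial layout generator produces a resolvable randomised incomplete-block
design (contiguous replicate superblocks; within each replicate, genotypes
shuffled into blocks of 8 whose order is shuffled again). It reproduces the
randomisation structure of an alpha design but makes no alpha-optimality
claim; only the randomisation structure matters to the analyses here.
Harvest traits are linear in the genotype temperature effect (yield
−2 kg/°C around 10 kg per 5-plant plot, height −15 cm/°C, maturity +1
score/°C on the 1–9 scale with 9 = least mature, rounded and clipped), with
noise SDs set so trait–temperature correlations land in the weak-to-moderate
range a field trial shows.

## Statistics

ANOVA sums of squares are accumulated explicitly from the mean decomposition
so every entry is checkable against brute-force summation; t and F tail
areas come from scipy. Balanced genotype × day × replicate tables use the
exact orthogonal decomposition; unbalanced tables fall back to sequential
(Type I) SS in the order Genotype, Days, Interaction, with a logged note —
no attempt is made to reproduce any particular package's missing-plot
adjustment. The LSD uses the standard t form
`t(1 − α/2, df_e) · sqrt(2·MS_e/n)`.

The randomisation test permutes genotype labels independently within each
day (each day's column of the means table shuffled separately), preserving
per-day multisets while destroying genotypic structure. It reports the
add-one permutation p-value `(b + 1)/(m + 1)` for the observed one-way F
(m = 1000 by default) and the *apparent LSD*: the mean over permutations of
the LSD computed from the null within-genotype mean square. Permuting the
derived means table (rather than re-running the normalisation per
permutation) treats genotype means as exchangeable under the null; the
image-mean constraint induces weak negative dependence between plots sharing
an image, which simulation shows leaves the type-I error within Monte-Carlo
error of nominal.

Spearman correlation is the Pearson correlation of average (midrank) ranks.
The extremes analysis ranks genotypes by mean rank across occasions (ties
broken by identifier), takes the k coolest and k hottest (k = 20 by
default), and computes pairwise occasion correlations on that subset.
Occasion correlation matrices get appended `day<d>_mean` columns — averages
of a day's occasions — whose mutual correlations exceed typical
single-occasion ones, quantifying the replication gain. No multiple-testing
correction is applied to correlation matrices; consumers should treat the
matrix as descriptive.

Forward-stepwise regression adds, per step, the predictor maximising r²,
admitting it if its partial-F p-value is below 0.05; collinear candidates
are skipped with a warning; maturity is treated as a numeric covariate.
Cumulative r² is non-decreasing and bounded by the full-model r².

## Numerical choices and degenerate inputs

- Pixel-in-polygon membership: even-odd rule at pixel centres
  `(col + 0.5, row + 0.5)`, 0-based; unambiguous and brute-force verifiable.
- The plot mean is computed anchored at the first pixel
  (`v0 + fsum(v − v0)/n`), making noiseless recovery bit-exact.
- QC trim: symmetric median ± k (default 3 °C), observation flagged above
  20 % exclusion; flagged observations are dropped entirely. For an even
  pixel count whose central pair straddles the interpolated median by more
  than k the band can be empty; that raises a QC error rather than returning
  an empty mean.
- A genotype with one surviving replicate reports its mean with SE = NaN and
  `n_plots = 1`; zero error mean square yields F = ∞ (or NaN when the source
  SS is also zero); an all-constant estimate set makes comparison
  correlations undefined and errors.
- Acquisition plans clamp jittered anchors to the field and append patch
  images for any plot a jittered sweep missed, so full coverage is
  guaranteed without biasing the overlap structure.
- Internal coordinates are 0-based; all CSV interfaces are 1-based in
  row/col, matching field-book convention, and round-trip losslessly.

## Problem sizes

The shipped test-suite and acceptance computations use the full 192 × 2
trial where the df structure matters (ANOVA, method agreement) and a
48-genotype version of the same design for replicated calibration studies
(500-run type-I error, 200-run parameter recovery), which leaves the
statistical questions unchanged while keeping runs small. The
method-agreement statistic is evaluated over 100 simulated occasions.

## Known limitations

- The additive-model route is OLS, not REML: image effects are fixed, and
  no variance-component inference is offered.
- No spatial (row/column trend) adjustment within the field.
- The simulator's plot noise has no spatial autocorrelation and no
  persistence across days; both exist in real fields.
- The rank-extremes and correlation analyses assume complete genotype × 
  occasion tables; missing occasions must be handled upstream.
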