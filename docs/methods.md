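# Methods

This note documents the models, conventions and numerical choices behind
`paleodent`, in the spirit of a package methods appendix: what each
pipeline assumes, which knobs matter, and what the synthetic-data tests
do and do not demonstrate about real material.

## Specimen data model

Every proxy record points to a tooth (`specimen_id`), optionally grouped
into individuals (`individual_id`; an isolated tooth is its own
individual — the conservative reading for museum collections of loose
teeth). Localities carry a biozone from the ordered European land-mammal
chronology MP28 < MP29 < MP30 < MN1 < MN2 < MN3; a locality dated across
the Palaeogene/Neogene boundary is stored as a two-zone interval and,
wherever a single group is required (epoch contrasts), assigned to its
own "transitional" group by default — the assignment is a policy
argument, not a hard-coded choice. Tooth loci are coded `i, c, p1–p4,
m1–m3` with case encoding the jaw (`M2` = upper second molar). Unknown
wear stage or side is an explicit `unknown` token, never an empty
string, so inclusion filters can distinguish "missing" from "failing".

CSV/TSV readers auto-detect the delimiter from the header line (museum
exports vary), validate biozones and key uniqueness eagerly, and report
rejected rows instead of dropping them silently. Summary writers round
the way the field reports: isotope and climate means to 1 decimal,
prevalences to 2, body masses to the nearest 10 kg.

## Body mass

Eight published molar-dimension regressions are implemented exactly as
printed, with "log" = log₁₀ and "ln" natural (the convention of the
allometry literature). Equations native in grams are divided by 1000 so
every per-equation entry is in kg before any aggregation. Aggregation
follows a two-stage rule: within each (species, locality), one tooth per
individual per locus is selected with a seeded RNG (bilateral pairs and
duplicates collapse); per-equation means are taken over individuals; the
reported mass is the **median of the pooled per-equation means** (up to
8 values). A locus-level grouping switch exists for sensitivity checks.

The equations disagree with one another structurally — at a 50 mm upper
M2 the three regressions span roughly 1500–2060 kg — so a median over
equations carries a spread of up to ~10–15% that no sample size
removes. The recovery tests reflect this: a controlled single-species
simulation (n = 20 individuals, 5% lognormal length noise, seeded)
recovers a 1000 kg design mass within 5%, while the full unbalanced
multi-species design is checked at 15%.

## Enamel hypoplasia

The unit of prevalence is the tooth (affected iff at least one defect),
matching how such data are printed; an individual-level mode would
require associating isolated teeth, which the data model deliberately
does not guess. The Pearson χ² statistic uses expected counts from the
margins and no continuity correction at any table size. Pairwise group
contrasts apply the rank-sum test to per-tooth 0/1 outcomes (for binary
data this is a proportions contrast by ranks); raw p-values are the
default and Holm-adjusted values are reported alongside.

## Stable isotopes

The per-specimen chain is a composition of printed transfer functions
(all ‰ quantities):

1. ε\*_diet−bioapatite = exp(2.42 + 0.032·ln mass_kg) — body-mass
   dependent carbon enrichment for a hindgut-fermenting megaherbivore;
2. δ¹³C_diet = δ¹³C_CO₃ − ε\* − corr, with corr = past − modern
   atmospheric δ¹³C_CO₂. Defaults: past −6.1‰, modern −8‰, hence
   corr = +1.9‰ subtracted. This sign/reference convention was fixed by
   requiring the downstream precipitation estimates to land on the
   published reconstructions; it is exposed as `AtmosphereContext` so
   other conventions are one argument away.
3. MAP, latitude/altitude form:
   MAP = 10^[(−δ¹³C_diet − 10.29 − 0.0124·|lat| + 1.9·10⁻⁴·alt)/5.61] − 300.
   This is the source regression δ¹³C = −10.29 + 1.9·10⁻⁴·alt −
   5.61·log₁₀(MAP+300) − 0.0124·|lat| solved for MAP (the inline form
   circulating in print is typographically garbled). It can be negative
   for enriched C3 diets; locality aggregation excludes negative
   per-specimen values ("without negative values" rule) and reports the
   exclusion count; if every specimen is excluded the estimate is
   absent, not zero. Latitude defaults to present-day site coordinates
   and altitude to 0 — palaeo-altitude is not estimable for these sites.
4. MAP, leaf-discrimination form: Δ¹³C_leaf = (δ¹³C_atm − δ¹³C_diet)/
   (1 + δ¹³C_diet/1000); MAP = 10^(0.092·Δ¹³C_leaf + 1.148) − 300.
5. δ¹⁸O scale conversion: δV-SMOW = 1.03091·δV-PDB + 30.91.
6. δ¹⁸O_precip = 1.02·δ¹⁸O_CO₃,SMOW − 33.3 — the rounded composition of
   the phosphate–precipitation (0.94x + 23.3) and phosphate–carbonate
   (0.96x − 8.05) relations. The rounded coefficients are the default
   (they reproduce the published tables); the unrounded composition is a
   flag and agrees within 0.06‰ over the observed range.
7. MAT = (δ¹⁸O_precip + 14.178)/0.442 or MAT = 1.41·δ¹⁸O_precip + 23.63.

Locality aggregation computes the full chain per specimen and averages;
the default is specimen-weighted (each sampled tooth counts once), with
an unweighted species-mean policy as the alternative. Classification
thresholds: C3 feeding below −22‰ δ¹³C_diet; woodland-mesic vs
open-xeric C3 biomes split at −25‰; the empirically observed shift
cut-off (−25.6‰) is reported as a flag.

Analytical precision (±0.2‰ δ¹³C, ±0.3‰ δ¹⁸O, 1σ) propagates through
the affine oxygen chain to ≈ ±0.7 °C on the steeper MAT calibration;
`mat_uncertainty` computes this bound as |slope product| × σ.

Serial (along-crown) series are summarised by per-isotope ranges, a
least-squares sinusoid a·sin(2πx/T + φ) + c (the period is
grid-searched over ⅓–3× the sampled span, then refined by bounded
scalar minimisation; amplitude/phase/offset are linear sub-problems),
and the rank correlation between the two isotopes. Fewer than 4 points
yield ranges only.

## Mesowear

Scores are integers 0–6 (the physical ruler has seven templates);
medians may be half-integers. The validity gate — paracone only, upper
molar only, wear stage within 4–7 — is hard: rejected observations are
returned with the first failed rule named, and never enter aggregation.
Diet categories are literature ranges that overlap by construction, so
classification returns the *set* of compatible categories rather than
forcing a single label.

## Dental microwear texture analysis

Pre-treatment runs in acquisition order: inversion (scans are negative
silicone replicas; disable for surfaces already in positive relief),
replacement of non-measured points, aberrant-peak removal, plane
levelling, removal of form by a bivariate polynomial of total degree 8,
and selection of the centred 200 × 200 μm window. Numerical choices:

* Non-measured points (< 1% required, configurable) are filled by the
  mean of their 8-neighbours, relaxed to convergence with a linearly
  extrapolated one-pixel border pad; the stencil then reproduces affine
  surfaces exactly, so a masked tilted plane pre-treats to zero.
* Aberrant peaks: pixels deviating from their 5 × 5 local median by more
  than k × global RMS roughness (k = 10 default) are masked and
  refilled. The upstream acquisition software's exact procedure is
  unpublished; k is configurable and logged.
* Form removal uses a Chebyshev tensor basis restricted to total degree
  ≤ 8; on a full grid the Gram matrix separates into 1-D Grams, so the
  fit is O(grid) and exact — degree-8 surfaces are annihilated to
  machine precision even at the nominal 1551 × 1551 resolution.

Parameters:

* **Relative-area curve / Asfc.** At each observation scale the surface
  is tiled by triangles (square cells of side k pixels split along the
  diagonal); scale = projected triangle area (k·spacing)²/2; relative
  area = 3-D area / projected area, averaged over up to 4 × 4 mesh
  origins per scale to de-noise the coarse end. Asfc = −1000 × the
  steepest slope of log₁₀(relative area) vs log₁₀(scale) over sliding
  5-point windows, restricted to scales below 100 μm² (the fine-scale
  regime). A flat curve gives 0. Asfc is deliberately *not*
  height-scale invariant: doubling relief amplitude increases it.
* **epLsar.** Transect profiles are sampled by bilinear interpolation
  along orientations 0°–175° in 5° steps at a fine scale of 1.8 μm; the
  per-orientation relative lengths are normalised to shares and combined
  as the mean resultant vector on the doubled-angle circle (all
  orientations weighted equally — the corrected normalisation). The
  relief is first normalised to unit RMS, making the parameter a pure
  shape statistic, exactly invariant under height rescaling. No
  numerical equality with commercial implementations is claimed.
* **Str.** The normalised autocorrelation is computed by zero-padded
  FFT (the biased estimator, whose taper guarantees decay towards the
  field edge); decay lengths to s = 0.5 are interpolated along rays at
  1° steps; Str = Rmin/Rmax ∈ (0, 1]. Directions that never reach s are
  capped at the field radius and counted in the diagnostics; if no
  direction decays the surface is rejected.
* **HAsfc.** Asfc per cell of a 3 × 3 or 9 × 9 partition (remainders
  truncated) on the RMS-normalised relief; the summary is the relative
  median absolute deviation median(|Asfc_i − med|)/med. Being
  median-based, it is robust to a minority of deviant cells — a single
  rough quadrant among nine cells cannot push it above 1 by
  construction; the (max − min)/median variant (behind a flag) is the
  sensitive alternative for such contrasts.

Interpretation thresholds from extant comparisons: Str < 0.2 marks
tough/abrasive (grass-like or folivorous) textures, Str > 0.3 low
anisotropy, Asfc > 2 hard-object inclusion; the classifier returns the
triggered rules with the combined tendency, and grinding and shearing
facets are never pooled.

## Statistics toolbox

* Rank-sum: midrank ties; the permutation distribution of the rank sum
  is enumerated exactly when the number of group assignments is ≤ 2·10⁵
  (all two-sided p-values), otherwise the normal approximation with tie
  correction applies.
* Spearman: ρ is the product-moment correlation of midranks; S is
  reported via S = (1 − ρ)·n(n² − 1)/6 — the convention under which
  published (ρ, S) pairs are mutually consistent — and
  `spearman_n_from_s` inverts it for the implied sample size.
* Box-Cox: λ maximises the profile log-likelihood on a grid [−5, 5] in
  0.01 steps; a configurable shift accommodates zero-inflated texture
  variables.
* ANOVA: sequential (type-I) sums of squares in the stated factor
  order, via statsmodels OLS. MANOVA: Wilks' Λ with its F approximation
  per term (statsmodels); a single response collapses to the univariate
  F. LSD post hoc: pairwise t-tests sharing the pooled residual mean
  square, unadjusted p by convention, Holm column alongside.

## Synthetic data: what it does and does not show

The default `StudyDesign` embeds the study structure — 15 localities
(MP28–MN3), 10 species, per-proxy sample sizes, species-at-locality
body masses, hypoplasia prevalences, enamel-carbonate isotope means and
mesowear medians — so generated datasets have realistic shapes and
unbalanced group sizes. Generator conventions: tooth lengths invert a
randomly chosen allometric equation at the true mass with 5%
multiplicative lognormal noise and a 0.6 width/length ratio; hypoplasia
outcomes are Bernoulli at the design prevalence (an exact mode realises
round(p·n) affected teeth deterministically for integer-ratio checks);
bulk isotope values scatter normally (σ = 0.5‰) around species means;
serial series follow shared-phase sinusoids (δ¹³C amplitude 0.25‰, δ¹⁸O
0.5‰, 30 mm period, 12 points, σ = 0.1‰) matching observed intra-tooth
ranges; surfaces come from closed-form archetypes (flat, tilted plane,
sinusoidal grooves, isotropic Gaussian, spectral fractal, rough
quadrant) at 256² for the routine suite, with one test at the nominal
1551² resolution. The spectral-fractal recovery check uses a 20 μm RMS
amplitude: in the small-slope regime log(relative area) is not a power
law (relative area − 1 is), so only a steep surface has the near-linear
log-log curve against which the windowed slope estimator can be
meaningfully compared to an independent global regression.

Every generator is a pure function of (design, seed). What passing
recovery tests show is that the estimators invert the generative
assumptions at the stated noise levels; they do not show robustness to
taphonomy, preservation bias, intra-tooth sampling geometry, or real
enamel microstructure, none of which the generators attempt to model.

## Known limitations

* The two MAP transfer functions disagree strongly at the arid end;
  both are reported, and the latitude/altitude form additionally depends
  on unknowable palaeo-coordinates.
* Commercial DMTA software's exact epLsar/HAsfc formulas are
  unpublished; this package documents its operationalisations and their
  invariants instead of claiming numerical equality.
* The exact-enumeration rank-sum branch is combinatorial; very unequal
  large groups silently fall back to the normal approximation.
* De-duplication of bilaterally matched teeth across proxies other than
  body mass is exposed as a policy, not guessed.
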