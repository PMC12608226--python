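# Methods

## Problem setting

A two-band vegetation index (VI) compresses a leaf reflectance spectrum
R(λ) into one number through the band reflectances of two spectral
channels.  A calibration curve maps that number to a pigment
concentration.  The package quantifies how the quality of this chain
depends on the three design choices a sensor embeds: the channels'
central wavelengths λ, their bandwidths Δλ (FWHM), and the index
formula.  Everything operates on the 450–950 nm range sampled at 1 nm,
which matches common VNIR spectrometers and brackets the pigment
absorption region (450–740 nm) and the insensitive NIR plateau.

## Synthetic leaf data

No per-sample spectra are publicly available for the kind of
lettuce/cucumber calibration study this package targets, so the
`synthetic` module generates them.  It is first-class, tested code, not
a fixture.

**Pigments.**  Chlorophyll and carotenoid concentrations (mg/L of
extract) are drawn from a bivariate normal with preset means/SDs,
truncated at zero by rejection.  Four presets carry published group
statistics (two lettuce cultivars: 3.94±0.83 / 1.13±0.17 and
8.24±0.85 / 1.92±0.18 mg/L; two cucumber stages: 7.88±2.77 / 1.86±0.31
and 7.53±3.14 / 1.70±0.46 mg/L), with aliases `cucumber-like` (the
young-stage cucumber group, the most variable) and `lettuce-like` (the
low-pigment cultivar).  The Chl–Car correlation defaults to 0.8: the
two pigments co-vary strongly in healthy leaves, which is also why
informative wavelengths for both lie close together.  Rejection
sampling makes moments slightly approximate when a mean sits within
~2 SD of zero; the shipped presets are far from that regime.

**Spectra.**  Reflectance follows a Beer–Lambert-style attenuation of a
smooth envelope:

    R(λ) = clip( B(λ) · exp(−[Chl·A_Chl(λ) + Car·A_Car(λ)]) · (1+ε_m) + ε_a , 0, 1 )

* B(λ): NIR plateau 0.50 with a +8% Gaussian bump at 550 nm (width
  50 nm).  The plateau level is typical of fresh dicot leaves; the bump
  keeps a green maximum even at zero pigment.
* A_Chl: Gaussian components at 430 nm (Soret, σ=25 nm, 0.060 /(mg/L)),
  662 nm (σ=28, 0.250), 649 nm (σ=25, 0.180) and a red-edge shoulder at
  700 nm (σ=14, 0.100).  A_Car: 450 nm (σ=22, 0.300) and 478 nm (σ=20,
  0.350).  The red strengths put the red-minimum reflectance near 0.03
  at the cucumber-like mean and near 0.11 at the lettuce-like mean —
  the qualitative species contrast (sharper 550/700 nm peaks at lower
  pigment load) that motivates index-based estimation.
* Noise: multiplicative Gaussian (sensor gain) plus additive Gaussian
  (dark noise), per wavelength.  Named levels: none (0, 0), low
  (0.01, 0.002), medium (0.03, 0.005), high (0.08, 0.01).  "Low"
  corresponds to a well-averaged laboratory measurement and is the
  default for calibration-set generation.

The construction guarantees the features downstream stages exploit:
red reflectance decreases monotonically in Chl; the wavelength at which
the red edge crosses the midpoint between its shoulders moves longward
monotonically as Chl grows (the Gaussian tail of the 700 nm component
needs a longer wavelength to decay to a fixed attenuation as Chl
increases); and the NIR plateau beyond 780 nm varies < 0.1% across the
physiological pigment range, so NIR channels act as pure references.

What the generator does **not** emulate: radiative transfer in the
mesophyll (no PROSPECT-style plate model), water absorption beyond
950 nm, specular/surface effects, venation heterogeneity, and
between-sample baseline variability beyond the noise terms.  Passing
tests therefore demonstrate the correctness and internal consistency of
the analysis machinery under a controlled spectral model — not that any
particular wavelength pair is optimal for real crops.

**Extract ODs.**  For round-trip testing of the reference equations,
optical densities are constructed by algebraic inversion:
S = Chl/(6.1φ + 20.04(1−φ)), D₆₆₅ = φS, D₆₄₉ = (1−φ)S,
D₄₄₀.₅ = (Car + 0.268·Chl)/4.695.  φ (default 0.7) apportions the red
absorbance between the Chl a and Chl b bands — any value in (0,1)
yields an exact round trip; 0.7 reflects the usual a:b dominance.

## Reference equations

Total chlorophyll and carotenoids of an ethanol extract:
Chl = 6.1·D₆₆₅ + 20.04·D₆₄₉ and Car = 4.695·D₄₄₀.₅ − 0.268·Chl.
Negative carotenoid outputs (possible for inconsistent inputs) are
returned unclipped with a `NonPhysicalCarotenoidWarning`, so that
consistency checks see the formula's raw behavior.  Units stay mg/L of
extract throughout; no per-leaf-mass conversion is applied.

## Preprocessing

Reflectance is the elementwise ratio of leaf to reference-panel
radiance on a shared grid.  Denoising convolves with a normalized
Gaussian (default σ = 20 nm — heavy relative to the 1 nm grid, but kept
as the pipeline default and exposed as a parameter), truncated at ±4σ,
with reflective boundary handling so the 450/950 nm ends are not
attenuated — the optimizer does select channels at the edges.
Resampling is linear interpolation; spectra are smooth after the σ=20
filter, so higher-order interpolation would change nothing material.

## Channel model

A channel (λc, Δλ) has Gaussian weights with σ = Δλ/(2√(2 ln 2)) (the
exact FWHM relation), truncated at ±4σ, clipped to the grid, normalized
to sum 1; band reflectance is the weighted mean (a convex combination,
hence bounded by the spectrum's range).  Discrete summation on the 1 nm
grid replaces continuous quadrature deliberately: it matches the data's
sampling, and for σ ≥ 0.4 nm the trapezoid correction is far below the
other error terms.  Channels clipped by the grid boundary are
**renormalized over the visible part**, not rejected — edge optima
(e.g. 451 nm with Δλ = 50 nm) are legitimate configurations.  A channel
whose ±4σ window misses the grid entirely degrades to the renormalized
Gaussian tail (dominated by the nearest edge); this is what makes the
445 nm auxiliary band usable with narrow bandwidths on a 450 nm grid.
Only a channel with no numerical support at all raises an error.

## Index formulas

Seven two-band forms, with ρ1, ρ2 the searched band reflectances:
SR = ρ1/ρ2, DI = ρ1−ρ2, NDVI = (ρ1−ρ2)/(ρ1+ρ2),
SAVI = (1+L)(ρ1−ρ2)/(ρ1+ρ2+L) with L = 0.5,
mSR = (ρ1−ρA)/(ρ2−ρA), mNDI = (ρ1−ρ2)/(ρ1+ρ2−2ρA) with ρA a fixed
445 nm blue band, and TVI = 0.5[120(ρ2−ρG) − 200(ρ1−ρG)] with ρG a
fixed 550 nm green band.  mSR/mNDI/TVI exist in several algebraic
variants in the literature; the two-searched-band forms above, with the
third band fixed, are the ones consistent with an optimizer that
searches exactly two wavelengths per index.  The auxiliary band
inherits Δλ of the first searched channel by default (configurable).
The search runs over *ordered* pairs and never hard-codes which slot is
"red" or "NIR": orientation is absorbed by the search.  Denominators
below 1e−9 in magnitude yield NaN, the invalid marker, so map cells can
be masked instead of carrying infinities.

## Calibration and metrics

The calibration model is y = a·exp(b·x) (a > 0 in mg/L, b
dimensionless), chosen for the empirically observed saturation of index
response at high pigment content.  The primary fit is OLS of ln y on x —
closed-form, which is what makes ~250k fits per map affordable — with
optional Levenberg–Marquardt refinement in the original space
(`refine=True`, off by default; the log fit is exact on noiseless data
and within a fraction of a percent under realistic noise).  No offset
term: it would destroy the closed form and is unidentifiable from
saturating index data.  Fitting is in-sample (a calibration, not a
prediction benchmark); no train/test machinery is included.

Metrics, computed in the original concentration space:
R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)², RMSE = √(Σ(ŷᵢ−yᵢ)²/n) in mg/L, and
RE = mean(|ŷᵢ−yᵢ|)·100/ȳ in percent (the only aggregation of a
per-sample relative error that both yields a single percentage and uses
the mean-concentration denominator).  Typeset variants of R² and RMSE
that omit the squares / substitute ȳ circulate in print; they are
implemented behind `literal=True` for auditability and never used for
selection.

## Exhaustive search

For each formula and bandwidth pair (Δλ1, Δλ2) the optimizer evaluates
all ordered distinct wavelength pairs on the search grid — 501·500 =
250,500 per bandwidth setting at 1 nm step.  The diagonal λ1 = λ2 is
excluded as degenerate for every ratio/difference form.  Bandwidth
pairing supports both the full Δλ1 × Δλ2 product (unequal pairs do win
in practice) and an equal-pairs restriction.  Cells with fewer than
three valid samples, zero VI variance, zero pigment variance, or an
overflowed exponential are masked.

The map computation is vectorized: band-reflectance matrices per
bandwidth (k channels × n samples), VI broadcast over all k² pairs, and
closed-form log-linear fits from centered sums, processed in row blocks
(~32 MB peak per block).  A scalar per-cell path assembled from the
single-channel, single-index, single-fit primitives exists alongside it
and agrees with the vectorized maps to ~1e−14; both use identical
masking rules so the maps are bit-comparable across runs.

Selection maximizes R²; ties break by minimal RMSE, then by the
lexicographically smallest (λ1, λ2, Δλ1, Δλ2) so results are
deterministic.  A minimal-RMSE criterion is available, and
`compare_criteria` reports the wavelength displacement between the two
criteria's optima — the standard robustness check on whether the R²
surface is peaked or plateaued.  The winning cell is re-fitted through
the scalar path, so every sensitivity profile embeds its reference
point bitwise (no vectorized-vs-scalar drift at offset zero).

## Sensitivity analyses

All three analyses are pure functions of (samples, reference, config)
and re-fit the calibration at every perturbed configuration by default —
the comparison is between calibrated instruments, not between a frozen
model and shifted inputs.  A frozen-model mode (`refit=False`)
simulates drift of a device calibrated once.

* **Wavelength shift**: joint equal displacement of both centers
  (default; per-channel 2-D offset grids optional), offsets that push a
  center off the sampled range are dropped and recorded.  Reported per
  offset: R², RMSE, and the max/mean per-sample prediction deviation as
  % of ȳ — max because a buyer of a mis-specified sensor cares about
  the worst sample; mean because the literature often reports it.  When
  the reference came from an exhaustive search over the same grid,
  on-grid offsets can never beat the reference (argmax dominance) —
  this is asserted in tests with shift step equal to the search step.
* **Bandwidth sweep**: re-fit at each Δλ at fixed centers (joint by
  default, product optional; the exact reference pair is always
  included).  Each setting carries a stability score: the worst |ΔR²|
  under a ±5 nm joint center shift.  Wide channels average over the
  feature and are less sensitive to center error; narrow channels are
  sharper but fragile — the trade-off the score quantifies.
* **Formula substitution**: all seven formulas on identical band
  reflectances, each with its own exponential fit, plus per-sample
  relative errors and an R² ranking.

## Problem sizes

The shipped tests and the acceptance script use a 5 nm search grid
(10,100 pairs per setting), 8×8 toy grids for oracle comparisons, and
50-sample calibration sets — the per-group sample count of the study
design this package models.  One full 250,500-cell map at 1 nm step
runs in roughly a second per formula/bandwidth setting on one CPU
core with the vectorized path, so full-resolution searches are entirely
practical outside the test suite.

## Known limitations

* The synthetic spectral model is phenomenological; optimal wavelengths
  found on it reflect the model's absorption placement, not crop truth.
* Exactly two searched bands per index; three-band and derivative
  (red-edge-position) indices are out of scope.
* The exponential calibration has no offset and is fitted in log space;
  data with additive zero-mean noise at very low concentrations would
  bias it (use `refine=True` there).
* mg/L extract units throughout; conversion to per-area or per-mass
  pigment content is the caller's responsibility.
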