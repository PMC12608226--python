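# vibands

Vegetation-index band optimization for non-destructive leaf pigment
estimation.

`vibands` is for researchers and sensor designers who estimate leaf
chlorophyll (*Chl*) and carotenoid (*Car*) content from reflectance
spectroscopy and need to know how much the answer depends on the
instrument.  Two-band vegetation indices (VIs) — NDVI, SR, DI, SAVI,
mSR, mNDI, TVI — reduce a reflectance spectrum R(λ) to one number via
the band reflectances of two spectral channels, each modeled as a
Gaussian transmission function with central wavelength λ and bandwidth
Δλ (FWHM).  A calibration curve then maps the index to a concentration.
The package provides the full workflow:

1. **Synthetic leaf data** — a Beer–Lambert-style reflectance generator
   (smooth baseline × exp(−[Chl·A_Chl(λ) + Car·A_Car(λ)]) with Gaussian
   absorption components) plus correlated pigment sampling from crop
   presets, and extract optical densities consistent with the
   spectrophotometric reference equations
   Chl = 6.1·D₆₆₅ + 20.04·D₆₄₉ and Car = 4.695·D₄₄₀.₅ − 0.268·Chl.
2. **Preprocessing** — reflectance ratio R = I_obj/I_ref, Gaussian
   denoising (σ = 20 nm), resampling to the 450–950 nm, 1 nm grid.
3. **Channel model** — normalized Gaussian weights (truncated at ±4σ,
   boundary-renormalized), band reflectance ρ = Σ wᵢ R(λᵢ).
4. **Calibration** — exponential regression y = a·exp(b·VI) fitted by
   closed-form least squares on ln y, scored by R², RMSE (mg/L) and the
   mean relative error RE (%).
5. **Exhaustive search** — every ordered pair of distinct wavelengths
   (250,500 pairs per bandwidth setting at 1 nm step) for every formula
   and bandwidth pair, producing R²/RMSE/RE maps and optimal
   configurations (max R², ties by min RMSE).
6. **Sensitivity analysis** — degradation under central-wavelength
   shifts (±20 nm), bandwidth changes, and index-formula substitution
   at fixed channels.

## Worked example

```python
import vibands as vb

samples = vb.generate_sample_set(n=50, preset="cucumber-like",
                                 seed=7, noise="low")
grid = vb.GridConfig(step=5, bandwidths=(10,))
maps = [vb.evaluate_map(samples, "chl", f, 10, 10, grid)
        for f in grid.formulas]
per_formula, best = vb.select_optimal(maps, samples, "chl")
print(best.formula, best.lambda1, best.lambda2,
      round(best.metrics.r2, 3), round(best.metrics.rmse, 3))
```

prints

```
SR 705.0 845.0 0.997 0.144
```

the optimal configuration over all seven formulas on a 5 nm search
grid: a Simple Ratio of the 705 nm red-edge channel against an 845 nm
NIR reference channel (both Δλ = 10 nm) calibrates chlorophyll with
R² = 0.997 and RMSE = 0.144 mg/L on this 50-sample synthetic cucumber
set.  The red-edge channel falls inside the pigment-sensitive 600–740 nm
region that the generator encodes, which is exactly what the exhaustive
search should rediscover.

Perturbing that optimum shows why channel specifications matter:

```python
prof = vb.shift_profile(samples, "chl", best, max_shift=20, step=5)
print(prof.r2.round(3))
print(prof.max_deviation_percent.round(1))
```

```
[0.953 0.968 0.981 0.991 0.997 0.991 0.975 0.946 0.911]
[22.8 19.2 15.2  9.5  3.9  6.8 15.3 25.8 34.2]
```

A joint ±20 nm displacement of both channel centers degrades R² from
0.997 to 0.91 and drives the worst per-sample prediction deviation from
4% to 34% of the mean concentration.  Swapping only the formula at the
same fixed channels (`vb.formula_comparison`) spreads R² from 0.997
(SR) down to 0.67 (mNDI) — the index formula is part of the calibration,
not a cosmetic choice.

The same workflow is available from the shell:

```sh
vibands simulate --preset cucumber-like --n 50 --seed 7 --noise low --out data/
vibands optimize --spectra data/spectra.csv --pigments data/pigments.csv \
    --pigment chl --step 5 --bandwidths 10 --out results/
vibands sensitivity --spectra data/spectra.csv --pigments data/pigments.csv \
    --pigment chl --reference results/best.json --mode shift --out results/
```

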