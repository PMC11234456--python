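# Methods

This note documents the models implemented in `msiox`, the default
parameter values and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that matter
for reproducing results.

## Spectral conventions

All spectra live on an integer wavelength grid, 400–700 nm inclusive at
1 nm spacing (301 samples). Raw tabulations are smoothed with a 1 nm
boxcar (average of samples within ±0.5 nm; data already at ≥1 nm spacing
pass through bit-exactly) and linearly interpolated onto the grid.
Lengths are millimetres, absorption/scattering coefficients mm⁻¹.

### Hemoglobin reference spectra

The bundled tabulations (`src/msiox/data/hb_*_extinction_synthetic.csv`)
are **synthetic stand-ins** for the standard public molar-extinction
compilations: monotone PCHIP-in-log interpolations through anchor points
reproducing the canonical features of oxy- and deoxyhemoglobin in the
visible range (Soret bands near 415/430 nm, oxy Q-bands at 542/577 nm, a
single broad deoxy band at 555 nm, isosbestic crossings near
500/529/545/570/585 nm). Molar extinction ε (cm⁻¹/M) is converted to a
whole-blood absorption coefficient as
`μa = ln(10)·ε·c/M/10` with c = 145 g/l blood and M = 64 500 g/mol.
The tissue model also records hematocrit 43% and MCHC 345 g/l RBC; note
these constants are mutually inconsistent at the percent level
(145/0.43 ≈ 337 ≠ 345) — the conversion deliberately uses the
whole-blood concentration of 145 g/l and nothing else.

Internal consistency, not literal agreement with any one published
table, is what the test suite verifies (positivity, isosbestic
crossings, linearity in concentration). Absolute SO2 accuracy against
real instruments would require the real compilations.

## Two-layer skin model

Parameters and defaults of `TissueParams`:

| parameter | meaning | validated range |
|---|---|---|
| `t_epi` | epidermis thickness, mm | 0.0025–0.49 |
| `f_mel` | melanin volume fraction of epidermis | 0–1 |
| `f_blood` | blood volume fraction of dermis | 0–1 |
| `s` | blood oxygen saturation fraction | −0.2–1.2 during fitting |
| `d_vessel` | mean vessel diameter D, mm | > 0 |
| `alpha` | μs′ at 600 nm, mm⁻¹ | μs′(λ) ∈ 1.0–90.5 over the grid |
| `beta` | scattering power | (via the μs′ constraint) |

The melanin power law is `f_mel·39.0·(λ/550)⁻³` mm⁻¹. The vessel
packaging factor is implemented as
`c_VD = (1 − exp(−D·μa,blood))/(D·μa,blood)` — the standard correction
for blood confined to discrete vessels, bounded by 1, evaluated by series
expansion for `D·μa,blood < 10⁻⁶`. Anisotropy is fixed at g = 0.8, so
the transport engine uses `μs = μs′/(1−g) = 5 μs′`.

## White Monte Carlo and the reflectance LUT

Photons are launched as a pencil beam normally into a two-layer
semi-infinite slab with zero absorption; Henyey–Greenstein scattering;
tissue refractive index 1.4 against air with unpolarized Fresnel
reflection at the top surface only (both layers share one index, so the
internal boundary neither refracts nor reflects). Every photon exiting
the top surface is collected regardless of exit position or angle
(spatially integrated reflectance — to first order the reciprocal of
wide-field illumination with pixel-wise detection; no camera-aperture
weighting is applied). Per-photon pathlengths in each layer are recorded;
absorption is applied afterwards as
`T = ⟨w·exp(−μa,epi·ℓ_epi − μa,derm·ℓ_derm)⟩`.

Photons are terminated at a total pathlength of 400 mm (configurable);
the terminated fraction is stored in the LUT metadata (≤ ~15% at the
lowest scattering node and zero absorption; under realistic absorption
those long paths carry negligible weight, and the identical truncation
enters both the training data and the fitter, so it cancels in
estimator comparisons).

The LUT axes are log-spaced: full-range
(t_epi 9 nodes over 0.0025–0.49 mm, μs′ 9 nodes over 1.0–90.5 mm⁻¹, 24
absorption nodes over 10⁻⁴–10² mm⁻¹ plus an exact zero node) or the
*compact* layout used by the reference studies (t_epi 7 × μs′ 7 over the
default sampling ranges, 20 + 1 absorption nodes up to 50 mm⁻¹).
Interpolation is multilinear in `(log t_epi, log μs′, log(μa + a₀))`
where a₀ is the smallest positive absorption node; μs′ is wavelength
dependent, so each wavelength queries the LUT with its own μs′(λ).
Out-of-range queries raise by default; the inverse fitter opts into
clamping (`clip=True`) because box bounds on (α, β) cannot exactly
express the wavelength-dependent μs′ hull.

Default photon budgets are 10⁵ per node for the full axes and 4×10⁴ for
the compact reference-study LUT (the full-scale simulation budget would be 5×10⁷ detected photons;
the reduced budget adds Monte-Carlo noise to the LUT nodes that is shared
by both estimators and therefore largely cancels in their comparison).

## Camera model and hardware variation

`I_T[n] = k_n Σ_λ r_n(λ) F(λ) L(λ) T(λ)`; the white reference is the
same with T ≡ 1. The two-step normalization (band-wise division by the
white intensities, then by the 16-band mean) cancels `k_n` and any
global scalar exactly; both invariances are tested.

Default synthetic hardware:

- **Sensor response**: 16 bands with peaks evenly spread over 472–648 nm,
  Gaussian main lobes of FWHM ≈ 9.5–15 nm (typical of mosaic snapshot
  sensors), a small broadband leakage floor, and a displaced secondary
  peak on a few bands (the dual-peak character such sensors exhibit).
- **Optics**: a 470 nm long-pass edge times a flat polarizer
  transmission.
- **Lamp**: white-LED shape (blue die peak at 450 nm, suppressed by the
  long-pass; broad phosphor band near 560 nm), bundled as CSV.
- **Lamp variation**: smooth drift (`δt,max`) and emission-angle
  (`δθ,max`) envelopes with magnitudes ≤ ~5%, scaled by q ∈ [0, 1].
- **Detector noise**: per-band Gaussian factors with variance
  `a_n + I[n]/b_n`, a ≈ 2×10⁻⁷ and a slope giving ~0.25% relative std at
  half scale. These magnitudes were calibrated so that inverse-MC fits of
  synthetic spectra show a time-averaged spectral misfit (mape) of
  ~0.23%, matching the residual level the modeled instrument class
  exhibits on real skin after 8-frame averaging; they are the study
  conditions, not free dials.

## Synthetic training spectra

One training sample: draw tissue parameters (the melanin *amount*
`f_mel·t_epi` is drawn and divided by the drawn thickness); compute T(λ)
from the LUT; perturb the lamp with q_t, q_θ ~ U[0,1]; draw a mean level
`R_I ~ N(I_max/2, 0.2 I_max)` truncated to (0.05 I_max, I_max]; scale;
draw per-band noise at the scaled intensities; apply. A synthetic white
spectrum is generated the same way with T ≡ 1 and *independent* q's,
level and noise (white calibration happens at a different time and angle
than the measurement — the conservative reading), and the pair is
normalized to band mean exactly 1.

Default sampling laws (log-uniform unless noted): t_epi 0.025–0.3 mm;
melanin amount 2.5×10⁻⁵–0.01 mm (f_mel up to ~0.4); f_blood 0.001–0.1;
s uniform 0–1; D 0.005–0.3 mm; α 1–6 mm⁻¹ with β uniform 0.5–2.5,
rejection-sampled so μs′(λ) stays within 1.0–90.5 mm⁻¹. These are
declared approximations of realistic skin variability, chosen once.

What the generator does *not* emulate: chromophores beyond melanin and
hemoglobin (no water, bilirubin or carotenoids), spatial variation of the
sensor response across the die, specular/cross-polarization leakage,
subject-level population structure, or any systematic model error between
the instrument and the forward model. Passing tests therefore demonstrate
internal consistency of the method under realistic noise — not clinical
accuracy on real skin.

## Estimators

**Inverse MC** minimizes the per-band relative difference
`(N_model − N_meas)/N_meas` over all seven parameters, bounded
(s ∈ [−0.2, 1.2]; estimates are never clipped). The spread-magnitude
parameters (t_epi, f_blood, D, α) are optimized in log space. Because the
multilinear LUT makes the objective piecewise-smooth with shallow local
minima, a cold start screens a 1024-point Latin-hypercube cloud with the
cheap forward model, polishes the best 8 candidates with trust-region
least squares, and then runs a few perturbation restarts around the
incumbent. In time series the first frame uses this multi-start and later
frames warm-start from the previous solution (single fit). Noise-free
spectra can contain near-degenerate parameter twins separated by only
~0.04% per band; resolving them requires the thorough-search settings
(screening cloud 8192, 16 starts, 8 polish restarts) rather than the
defaults, which are sized for realistically noisy data.

**ANN**: 16 → H → 1, tanh hidden layer (H ∈ {5, 10, 15, 20}), linear
output in percent. Training is a Levenberg–Marquardt loop with the exact
Jacobian from backpropagation, damping μ (start 10⁻³, ×10 on rejection,
×0.1 on acceptance), inputs standardized internally (folded back into the
first-layer weights afterwards, so saved models consume raw normalized
spectra), Nguyen–Widrow-style initialization, and early stopping on a
validation split (defaults: patience 50 after at least 150 iterations,
max 500; the reference studies use 800/80 because validation error on
default synthetic sets improves intermittently out to ~700 iterations).
The returned weights are those of the best validation error. Training
sets are split 70/15/15 into train/validation/test.

A caution on reproducibility: LM training of these small networks is
chaotically sensitive — perturbing the training spectra at the 10⁻¹⁴
level can move the final validation RMSE by ~2% and a trace-level
agreement statistic by several tenths of a %-unit. Results are
bit-reproducible for a fixed code state and seed, and all stochastic
study components fan out deterministically from one master seed.

## Reference studies and problem sizes

- **Agreement study**: 100-frame occlusion-release trajectory (baseline
  60% for the first tenth, exponential desaturation to a sustained ~0%
  plateau through 60% of the frames, rapid reperfusion overshoot to 85%,
  slow recovery — the 1 min / 5 min / 4 min protocol mapped to frame
  fractions), all other tissue parameters fixed at the geometric
  mid-range of the sampling laws. The network is the best-validation
  H = 15 member of 10 trainings on a 20 000-spectrum set (the full-scale
  study size would be 50 000; LM cost scales with the training split).
  Statistics: mean absolute ANN-vs-inverse-MC difference and Pearson R.
- **Repeat-stability study**: 10 networks (H = 15, distinct
  initializations, one shared 10 000-spectrum set); average per-sample
  prediction std over a common 1 000-spectrum held-out set.
- Both run on the compact 4×10⁴-photon LUT.

## Calibration

The sweep estimator recovers each band response from 301 narrowband
(7 nm FWHM) filter settings by penalized nonlinear least squares: the
intensity residuals are normalized by the grand mean over all bands and
settings (making the fit insensitive to lamp level, exposure and gain),
and an amplitude-normalized first-difference penalty with weight 0.2
suppresses noise-driven structure; the denominator mixes the local
amplitude with the λ-averaged response, which stabilizes zero-response
regions. Bands are solved independently with analytic Jacobians,
nonnegativity bounds, a ridge-regularized linear warm start, and
tolerance 10⁻⁸ / 400 iterations per band. Noise-free synthetic sweeps
are recovered to ≲0.1% max-normalized MAE; at 1% measurement noise
recovery stays within ~1%.

Important subtlety encoded in the fixture generator: the reference
spectrometer does **not** look through the camera-side optics, so the
long-pass edge lives in the *response being estimated*, not in the
reference spectra. Folding it into the references leaves the sub-470 nm
response unconstrained, and the penalty's mean-normalization then rewards
dumping mass there.

The detector-noise fit regresses the relative temporal variance of
repeated white measurements on mean intensity per band. The intercept is
only identifiable when the variance-of-variance is small: at a few
hundred repeats the sampling error of a variance estimate is ~10% by
itself, so coefficient-recovery tests use 4000 repeats and an
exposure-balanced stack.

## Image pipeline

Hypercubes use 0-based indices, band axis first; band b of the 4×4 mosaic
sits at row offset `b // 4`, column offset `b % 4`; ROI rectangles are
half-open. Preprocessing: nearest-in-time dark subtraction (ties toward
the earlier frame; negative values clipped at zero), per-band bilinear
demosaicing on each band's own lattice with linear border extrapolation
(exact on affine images everywhere), white normalization with a white
cube processed the same way (non-positive white pixels are masked), and
per-pixel division by the 16-band mean. The pipeline is invariant to a
common rescaling of measurement and white frames.

## Known limitations

- The chromophore tables are synthetic stand-ins (above); absolute SO2
  values are internally consistent but not traceable to a measured
  instrument.
- The LUT's multilinear interpolation leaves percent-level systematic
  interpolation error between nodes; it is shared by synthesis and
  fitting and so cancels in estimator comparisons, but not against an
  independent simulation.
- Detected-photon statistics at desk-scale budgets add node noise ~0.5%;
  energy accounting at zero absorption is limited by the pathlength cap.
- SO2 is weakly identifiable at the low end of the blood-fraction range;
  both estimators degrade there, and network ensembles disagree most on
  such samples.
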