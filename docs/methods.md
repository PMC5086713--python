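# Methods

## Model

The estimator is a per-day geographically weighted regression of
humidity-revised PM2.5 on five regressors plus an intercept:

```
Revised_PM2.5(l,d) = β₀(l,d) + β₁(l,d)·Revised_AOD(l,d) + β₂(l,d)·Last_Prec(l,d)
                   + β₃(l,d)·ST(l,d) + β₄(l,d)·PS(l,d) + β₅(l,d)·WS(l,d) + ε
```

with `Revised_AOD = AOD/PBLH` (PBLH in km; a per-km extinction proxy for
the surface layer) and `Revised_PM2.5 = PM2.5·(1 − RH/100)⁻¹` (hygroscopic
growth of dry-measured mass to ambient optical conditions). `Last_Prec` is
the previous local calendar day's total precipitation (mm), `ST` surface
temperature (K), `PS` surface pressure (Pa), `WS = √(u² + v²)` wind speed
(m/s). Coefficients carry both a location and a day index: aerosol–PM
relationships drift with airmass and season, so one GWR is calibrated per
day and seasonal products aggregate daily fits.

Assumptions worth stating plainly: the response is linear in the corrected
regressors with coefficients that vary smoothly in space; residual noise is
additive on the *revised* (humidity-corrected) scale; the vertical
correction treats the boundary layer as well mixed; the hygroscopic
correction uses a single growth law for all particle compositions, and
diverges as RH → 100 % — hence the `rh_cap` (default 95 %): rows wetter
than the cap are excluded rather than extrapolated.

## Local fitting

At target location *l* the coefficients solve
`min Σᵢ wᵢ(l)·(yᵢ − xᵢβ)²` with bisquare weights
`wᵢ = (1 − (dᵢ/b)²)²` for `dᵢ < b`, else 0. Distances are great-circle km
(R = 6371 km) — the domain spans tens of degrees of latitude, so Euclidean
degrees would distort kernels anisotropically. The bandwidth is adaptive:
`b(l)` is the distance to the k-th nearest calibration station, which
tightens kernels in dense urban clusters and widens them in sparse
regions. A Gaussian kernel and a uniform (OLS-limit) kernel are available
by configuration.

The neighbour count k is selected per day by minimising the leave-one-out
CV residual sum of squares, searched by golden section on the integers
with an exhaustive sweep of the final bracket (width ≤ 10); ties resolve
to the smallest k (locality preferred). The search floor is
`k_min = 40`: a bisquare kernel roughly halves the effective sample, so
40 neighbours keep ~6–7 effective observations per parameter; below that
the local design is too ill-conditioned to be worth scoring. Local R² is
the weighted 1 − RSS/TSS about the weighted mean.

Numerical choices in the solver: regressor columns are rescaled to unit
RMS before the QR solve (pressure in Pa sits five orders above AOD;
without scaling the normal-equations conditioning is squared into the
solution), and coefficients are returned on the original scales. A
regressor that is identically zero over the positive-weight rows — the
normal state of previous-day precipitation in a locally dry neighbourhood
— has its coefficient pinned to 0 and the reduced system is solved;
genuine rank deficiency (duplicated or collinear columns) raises a
singular-fit error naming the location. Singular fits at prediction
points yield missing values by default, or the global OLS prediction when
configured.

## Integration rules

Deliberately different access rules by variable, matching how the source
products resolve space: AOD from the containing fine pixel (half-open
cell membership [west, east) × [south, north)); meteorology by bilinear
interpolation from cell centers (missing if any of the four neighbours is
masked); precipitation from the previous *local* calendar date resolved
at the 13:00-local overpass instant. Station records are averaged over
the two local overpass hours; if exactly one is present it is used alone
(a permissive reading, logged per row). Rows missing any ingredient are
excluded and counted — the model is strictly complete-case.

Time zones are nominal 15° solar bands edged at 67.5…142.5 °E
(offsets UTC+5…+9), not political zones: only the band arithmetic matters
for aligning a UTC+8-stamped network to local overpass time.

## Cross-validation

Records are pooled by meteorological season and partitioned into 10
random record-level folds (sizes differ by ≤ 1, reproducible from the
seed). Each fold is predicted from per-day models refitted on the other
nine; predictions are back-transformed to the dry scale with the row's RH
before computing metrics, because stations report dry mass. R² is the
squared Pearson correlation of estimated vs measured (the scatter-plot
convention); a sum-of-squares R² about the 1:1 line is carried as a
secondary column. The fitted line of estimated on measured diagnoses
attenuation: with noise in the response, local smoothing pulls the slope
below 1 and the intercept above 0 — overestimation of low and
underestimation of high concentrations is an expected signature, not a
bug.

The adaptive k is selected once per day on that day's full row set and
reused across folds (`cv_bandwidth_policy = "per-day"`). Bandwidth is a
smoothing hyperparameter, not a fitted coefficient; the held-out rows are
still absent from every calibration set, which is the leakage that
matters. Per-fold reselection is available (`"per-fold"`) at ~10× the
search cost.

## Synthetic scenes

The generator emulates the study's data constellation on a 10° × 10°
domain: truth coefficient surfaces, 400 stations (70 % drawn around six
cluster centers, emulating dense-urban/sparse-rural coverage), 30 days
spread over the four seasons, 0.03°/0.1° AOD grids (preserving the
3 km : 10 km resolution ratio without projection machinery), 0.5°
meteorology, and noise of sd 10 μg/m³ on the revised scale plus
3 μg/m³ hour-to-hour jitter on the dry scale.

Smooth fields are superpositions of 32 random-phase sinusoids with
wavelengths of 2–6 correlation lengths — exactly reproducible from
(config, seed), cheap to evaluate, and each realisation carries its
component list so discrete-smoothness bounds are closed-form. Because
sampled wavelengths can exceed the domain, the coefficient-surface
perturbation is rescaled after evaluation so its realised in-domain RMS
equals the stated amplitude (otherwise the realised variance is a lottery
over phase draws). Marginal shapes are imposed by rank-mapping the smooth
field through the target quantile function (a monotone transform, so
smoothness survives): log-normal PBLH (median 0.9 km), Weibull RH
(shape 4, scale 55 %) and temperature, Gaussian wind components (their
magnitude is then Weibull-like), and precipitation as a thresholded
latent field that is zero over most of the domain. Pressure comes from a
day-invariant plateau/lowland elevation surface through the barometric
formula, giving the bimodal marginal a high-relief domain shows.
Temperature takes a seasonal offset (−12/0/+8/−2 K for DJF/MAM/JJA/SON).

Coefficient means (30, 80, −1.5, 0.3, −4·10⁻⁴, −2.0) give revised
concentrations around 110–120 μg/m³ (≈ 50–70 μg/m³ dry at typical RH);
amplitudes (10, 30, 0.5, 0.03, 5·10⁻⁵, 0.5) are scaled so each term's
coefficient variation contributes a comparable few μg/m³ of spatial
response variance. The revised-AOD field has a 0.5° correlation length:
aerosol structure (plumes, urban sources) is genuinely finer-grained than
1° meteorology, and sub-kernel variation is also what makes the AOD slope
locally identifiable — when every regressor varies only at kernel scale,
the local design degenerates toward a shared planar gradient and
coefficients become unstable even though predictions stay accurate (the
familiar GWR local-collinearity caveat; it applies to real data too).

Observations invert the model's own corrections: regressors at stations
are computed with the pipeline's access rules (fused pixel / bilinear),
the revised response is the linear predictor with truth coefficients plus
Gaussian noise, and the recorded dry value is the revised response times
(1 − RH/100), split into the two local overpass hours with jitter. A
noise-free constant-coefficient scene therefore closes the loop exactly
(recovery to ~10⁻¹⁴), which pins down that generator and estimator share
one model — the closure test is a correctness proof for the plumbing, not
evidence about real-data skill.

What the generator does **not** emulate: cloud contamination and
spatially contiguous bright-surface regions (the DT-missing mask is iid
per cell, so coverage gaps are salt-and-pepper rather than desert-shaped);
multi-overpass days; instrument error structure beyond white noise;
terrain-coupled meteorology (the plateau affects pressure only); and any
AOD–meteorology dependence beyond the PBLH factor. Passing tests
demonstrate the estimator recovers the model it assumes under realistic
magnitudes and missingness — not that the linear six-term model is true
of any particular atmosphere.

## Reference-scene results

On the reference scene the pipeline recovers the β₁ (AOD-slope) surface
at r ≈ 0.96 across stations (per-station mean of 30 daily estimates) and
seasonal 10-fold CV reaches R² ≈ 0.90–0.94, RMSE ≈ 6–7 μg/m³ with slopes
0.92–0.95 and intercepts 3.7–5.0 μg/m³ — the attenuation signature. These
are the quantities `scripts/acceptance.py` recomputes; problem sizes
(400 stations × 30 days ≈ 11 000 rows) were chosen so a full run takes a
few minutes on one CPU.

## Known limitations

Per-day GWR ignores temporal coherence (no spatiotemporal kernel);
record-level CV folds share stations between training and validation, so
reported skill reflects interpolation at monitored locations rather than
transfer to unmonitored ones (leave-station-out CV is a noted extension);
the DB regrid is containment-based and will alias DB-scale gradients at
fine-cell boundaries; and the bandwidth search assumes a reasonably
unimodal LOO score — the exhaustive final bracket protects the optimum
locally, not globally.
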