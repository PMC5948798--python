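# Methods

## Problem and approach

`wheatlai` estimates winter-wheat leaf area index (LAI, m² leaf per m²
ground) from 4-band surface reflectance (Blue/Green/Red/NIR, the GaoFen-1
WFV band set) by look-up-table (LUT) inversion of a physically based canopy
reflectance model.  The pipeline is:

1. **Forward model.**  PROSPECT-5 simulates leaf directional-hemispherical
   reflectance and transmittance from the leaf structure parameter Ni,
   chlorophyll a+b content Cab (µg cm⁻²), equivalent water thickness Cw
   (cm), dry matter content Cm (g cm⁻²) and brown-pigment content Cbp,
   treating the leaf as Ni absorbing plates (Stern/Allen interface
   transmissivities, Stokes doubling for the plate stack).  4SAIL
   propagates the leaf optics through a turbid canopy layer of depth LAI
   with an ellipsoidal (Campbell) leaf-angle distribution of mean
   inclination ALIA, a hot-spot correlation correction of size parameter
   `hspot`, and a Lambertian soil background, for sun zenith `tts`, view
   zenith `tto`, relative azimuth `psi`.  The observed reflectance factor
   mixes the bidirectional and hemispherical-directional terms with the
   diffuse sky fraction: R = (1 − skyl)·rso + skyl·rdo.
2. **Band convolution.**  Fine-resolution spectra (400–2500 nm, 1 nm) are
   reduced to the four broadbands as spectral-response-weighted means;
   response weights are normalized internally.
3. **LUT inversion.**  100,000 parameter sets drawn from the priors are
   forward-simulated once per scene geometry.  An observation is inverted
   by ranking entries with a relative-RMSE cost — over a band subset,
   RRMSE = √[(1/m)·Σ((R_obs−R_sim)/R_obs)²]; for one vegetation index,
   |VI_obs−VI_sim|/|VI_obs| — and averaging the parameter vectors of the
   smallest ceil(0.10·N) entries (the multiple-solution rule that combats
   the ill-posedness of a 9-parameter model observed through 4 bands).
4. **Strategy screening.**  Twenty-five retrieval strategies — all 15
   non-empty band subsets and 10 vegetation indices (RVI, MSR, GRVI, NDVI,
   GNDVI, SAVI, OSAVI, TVI, ARVI, EVI) — are scored against validation
   plots with R² (squared Pearson correlation) and RMSE, and ranked
   RMSE-first with R² breaking ties.

## Priors and fixed parameters

| variable | unit | prior | default |
|---|---|---|---|
| Ni | – | Gaussian(1.5, 0.3) on [1.2, 1.8] | |
| Cab | µg cm⁻² | Gaussian(50, 7.5) on [25, 75] | |
| Cw | cm | Uniform[0.60, 0.85] | see note below |
| Cm | g cm⁻² | Gaussian(0.007, 0.002) on [0.003, 0.011] | |
| Cbp | µg cm⁻² | Gaussian(0, 0.3) on [0, 0.2] | |
| LAI | – | Uniform[0, 8] | |
| ALIA | deg | Gaussian(60, 4) on [30, 80] | |
| hspot | – | Gaussian(0.3, 0.2) on [0.1, 0.5] | |
| psoil | – | Gaussian(1.2, 2.0) on [0.5, 3.5] | |
| skyl | fraction | fixed | 0.1 |
| tts, tto, psi | deg | fixed per scene | 46, 32, 90 |

Gaussian priors are truncated to their ranges by rejection sampling
(redraw until inside); this reproduces the exact truncated-normal marginal,
verified against the analytic truncated-normal mean and a KS test.
Carotenoid content, a PROSPECT-5 input the retrieval does not vary, is held
at 8 µg cm⁻² (configurable).  The SAVI soil factor L, unstated in the index
table, is the canonical 0.5.

**The Cw range** (0.60–0.85 cm) is one to two orders of magnitude above
typical equivalent water thickness; it is implemented as printed because it
is what the study design states.  With realistic water absorption this
range is nearly harmless in the four VIS/NIR bands (water absorbs weakly
below 900 nm).  A `physical_cw` preset (0.006–0.035 cm) is available
without asserting the original intent.

**Geometry.**  The two acquisition dates' sensor zenith is tabulated as
≈63.4°, which is hard to reconcile with the fixed prior mode tto = 32°; the
package defaults every scene to the prior modes (46/32/90) and lets any
scene metadata file override them, so a user who trusts the per-date values
can supply them.

**ARVI** is computed exactly as printed — (B4−B3−(B1−B3))/(B4+B3−(B1−B3)),
whose numerator reduces to B4−B1 — which differs from the standard γ = 1
ARVI.  The standard form is available behind `arvi_standard=True`.  The
two-band strategy printed as "B4, B5" is implemented as (B3, B4): no band 5
exists and (B3, B4) is the unique missing pair.

## Synthetic spectral libraries

The measured PROSPECT optical-constant tables and instrument spectral
response files are not redistributable, so the package vendors *synthetic*
stand-ins generated from smooth analytic recipes (`wheatlai.synthspec`,
files suffixed `_synthetic`): Gaussian absorption features at the canonical
pigment and water band positions, a dry-matter coefficient that is nearly
transparent through the VIS/NIR plateau and rises steeply in the SWIR
(fresh leaves absorb almost nothing at 750–1100 nm, giving the high NIR
single-scattering albedo that makes canopy NIR sensitive to LAI up to
LAI ≈ 6), a declining refractive index, a bright dry-soil continuum peaking
near 0.40, and Gaussian-lobe band responses centred on the nominal
450–520/520–590/630–690/770–890 nm band edges.  Soil reflectance is
`psoil × dry-reference`, clipped to [0, 1]; the brightness range up to 3.5
is incompatible with the common dry/wet convex mixture, which is still
available as `mode="drywet"`.

Consequences for interpretation: simulated spectra are *qualitatively*
wheat-like (green bump, red trough, NIR plateau, soil line) but not
quantitatively comparable to spectra built from the measured coefficient
tables, and none of the original study's numerical R²/RMSE values can be
reproduced here — those depended on the authors' imagery and field data in
any case.  Forward-model correctness is instead established against an
independent scalar transcription of the published PROSPECT-5/4SAIL
algorithms (`tests/reference_rtm.py`), fed the same synthetic constants so
the comparison isolates the model equations; agreement is ≤1e-4 (leaf) and
≤1e-3 (canopy) absolute reflectance on a fixed 20-point design, and in
practice is at machine precision.

## Synthetic scenes and plots

`generate_scene` draws each free parameter as a Gaussian random field
smoothed with a configurable kernel (default 3 px), then maps it through
the parameter's generating distribution by probability-integral transform —
marginals are exact, spatial autocorrelation is plausible but arbitrary
(no spatial statistics were available to emulate).  Stage profiles:
*elongation* (LAI ~ truncated-Gaussian(3.5, 1.0) on [0.5, 5], Cbp = 0) and
*grain-filling* (LAI ~ tG(4.5, 1.0) on [3, 6], Cbp ~ U[0.05, 0.2]); all
other parameters follow the retrieval priors.  Observation noise defaults
to 3% multiplicative plus 0.005 additive reflectance noise per band.
Validation plots (default 44, matching the field campaign) are placed by
rejection sampling with a minimum spacing (default 6 px ≈ 100 m at 16 m
pixels); measured LAI adds Gaussian noise (σ = 0.3, truncated at 0) to the
pixel truth, and SPAD readings invert the chlorophyll transfer
Cab = 5.6351·exp(0.0287·SPAD + 0.8095) applied to the true Cab, plus
reading noise (σ = 1.5).

What passing tests show: the full pipeline is internally consistent,
deterministic under seeding, and reproduces the study's *qualitative*
conclusion — strategies built on the green band dominate (B2 ranks first on
every tested noisy elongation scene, with GNDVI/GRVI leading the index
family).  What they do not show: performance on real imagery, where
atmospheric residuals, mixed pixels, registration error and canopy
structure beyond the turbid-medium assumption all matter.

## Numerical choices

- Thin-canopy limit: LAI ≤ 1e-9 short-circuits to the exact bare-soil
  solution, so the LAI → 0 limit is bit-exact.
- The observed mixing is computed as rso + skyl·(rdo − rso) so that the
  bare-soil identity survives floating point.
- Conservative scattering (r + t ≥ 1) falls back to the standard linear
  plate-stack limit; the m² term of the SAIL eigenvalue is clipped at 0.
- Hot-spot bidirectional gap integral: 20-step exponential quadrature with
  an L'Hôpital fallback where the integrand increment vanishes.
- Division guards: observed reflectance/VI below ε = 1e-6 makes the cost
  undefined — scalar calls raise, raster calls flag the pixel as nodata.
- Tie handling in inversion: entries sort by (cost, insertion index) with a
  stable sort, so results are deterministic and invariant to permuting the
  LUT (verified by test).
- LUT builds simulate only the wavelength slice covering the band-response
  support (400–1000 nm), cutting the spectral workload ~3.5× with values
  identical to the full-grid computation (per-wavelength models).
- Seeds: every stochastic routine takes an explicit seed; a given seed
  yields bit-identical LUTs, scenes, plots and scores.

## Problem sizes

Default study scale is retained where it defines the method: LUT size
100,000 and the 10% solution rule.  The recovery experiment uses a 50×50
zero-noise elongation scene; strategy screening uses 200×200 noisy scenes
with 44 plots over five seeds; the noise-degradation property uses a
20,000-entry LUT with 40×40 scenes and 30 plots.  These sizes are the
package's own choices balancing statistical stability against test
turnaround.

## Measured retrieval behaviour and limitations

Numbers below are computed by `scripts/acceptance.py` and the test suite,
not asserted from elsewhere.

- The multiple-solution average over ceil(0.10·N) = 10,000 entries
  regularizes strongly: estimates attenuate toward the prior mean, so even
  noise-free all-band inversion of an elongation scene recovers LAI with
  RMSE ≈ 1.6 (and ≈ 1.05 over LAI ≤ 5 for observations drawn from the
  priors themselves).  This mirrors the ill-posedness the multiple-solution
  rule is designed to damp — nine parameters seen through four bands, with
  a wide soil-brightness prior creating strong soil/vegetation confusion —
  and is consistent with the original study's field-data finding that
  all-band strategies perform poorly while the single green band attains
  the lowest RMSE.  A tighter tolerance (RMSE ≤ 0.5) is asserted in the
  acceptance suite and currently fails; the package reports the honest
  number rather than weakening the estimator contract.
- Median per-strategy RMSE degrades monotonically as band noise grows
  (pooled over seeds; per-seed medians at 30 plots fluctuate by about one
  noise step).
- No atmosphere, sensor PSF, mixed pixels, row structure or multi-date
  dynamics are modelled; DN→radiance calibration is provided for
  completeness but the pipeline contract input is surface reflectance.
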