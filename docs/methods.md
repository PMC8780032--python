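# Methods

`aquakiwi` implements an aquaphotomics analysis chain for short-wave NIR
interactance spectra of kiwifruit measured in four configurations —
Unpeeled/Peeled fruit crossed with Unpolarized/Polarized (co-polarized)
detection — together with a synthetic forward model of the measurement that
makes the whole chain testable at desk scale.  This note records the models,
conventions and numerical choices, and what the synthetic tests do and do
not demonstrate.

## Analysis chain

1. **Absorbance.**  Raw interactance intensity is normalized by the
   per-configuration reference scan and converted with
   `A(λ) = log10(I_ref(λ)/I(λ))`.  This sign convention makes water
   absorption bands positive peaks.  Nonpositive intensities are rejected
   (they indicate saturated or dark pixels).
2. **SNV.**  Per-spectrum standard normal variate, `(x − mean)/sd`, with the
   **sample (n−1) standard deviation**.  SNV is invariant to positive affine
   rescaling of a spectrum and removes multiplicative scatter and additive
   offset differences between fruit.
3. **SNV + 2D.**  Savitzky–Golay second derivative, default 7-point window
   and 2nd-order polynomial.  The window is a *point count* (the filter is
   defined on samples; with the default 3 nm grid it spans about 21 nm); an
   alternative window can be configured.  The derivative is reported per
   (grid step)²; a `per_nm` flag divides by `step_nm²`.  Edge points are the
   second derivative of the boundary window's least-squares polynomial
   (`mode="interp"`), so output length equals input length and polynomials
   up to the fit order are reproduced exactly everywhere — the basis of the
   exactness tests (`y = x² → 2`, lines `→ 0`).
4. **PCA.**  SVD of the internally centered SNV+2D matrix
   (scikit-learn, full solver).  Loadings are unit-norm; explained variance
   is a percentage of total.  Because PCA is sign-ambiguous, the largest
   |element| of each loading is made positive, fixing signs
   deterministically across runs.  Local extrema of PC1–PC3 loadings in the
   900–1020 nm window are wavelength candidates.
5. **WAMACS and activated wavelengths.**  The 12 second-overtone water
   matrix coordinates C1–C12 with their published nm ranges and water-
   species assignments are shipped as constants; C1–C5 relate to free and
   C6–C12 to bound water species.  `assign_band` treats ranges as closed
   intervals scanned C1→C12, so the shared 998 nm endpoint of C10/C11
   resolves to C10.  SSC groups close the small gaps in the published
   ranges at Low < 12, Medium [12, 15), High ≥ 15 °Brix.  Candidate
   wavelengths are pooled from three sources — PCA loading extrema, extrema
   of each configuration's mean SNV+2D spectrum, and extrema of the SSC
   difference spectra (`mean_Low − mean_group`, per configuration).  Each
   source curve is standardized to unit maximum absolute value inside the
   selection window before candidates compete, so selection is invariant to
   the ordering of the sources and to positive rescaling of any single
   curve; within a band the largest standardized |extremum| wins, ties going
   to the lower wavelength.  A local extremum is strictly greater/less than
   its neighbouring distinct values; plateaus count once at their leftmost
   point.  Bands without candidates are omitted with a warning.  The
   package also ships the study's published activated wavelengths
   (903, 916, 926, 933, 946, 962, 965, 975, 988, 994, 1007, 1014 nm) as a
   ready-made selection.
6. **Aquagram.**  At the activated wavelengths, the preprocessed absorbance
   (SNV+2D by default; SNV-only is configurable) is standardized per
   wavelength with the mean and sample sd pooled over *all samples of all
   configurations* — individual samples, not configuration means.  The
   pooled population also backs the per-SSC-group aquagrams, so panels are
   comparable across configurations.  Because SNV+2D is negative at band
   centres, a display flag `negate_2d` (default on, recorded in the output
   tables) flips the standardized values so greater absorbance plots
   outward.  Profiles are group means; with equal group sizes the four
   configuration profiles cancel band-wise by construction.

## Synthetic forward model

The study's spectra are not publicly deposited, so a generator stands in
for them with known injected effects.

* **Fruit phantoms.**  SSC uniform on 7–20.5 °Brix (the study's range),
  recorded as the mean of simulated stem/blossom readings; DMC (dry/wet
  weight) loosely correlated with SSC around 14%; per-fruit band-amplitude
  jitter of 5%; a skin-scatter absorbance baseline ~0.05 AU on unpeeled
  configurations.
* **Line shapes.**  Each WAMACS band is a Gaussian at its range midpoint on
  a broad 970 nm water envelope (sd 35 nm, amplitude 0.8 AU).  Line widths
  are per-band: 4 nm for C1–C8, 5 nm for C9–C10, 3 nm for C11 and 6 nm for
  C12.  Widths much above ~5 nm merge the closely spaced C1–C4 lines
  (~7 nm apart), in which case the second derivative at a band centre is
  dominated by the neighbours' positive flanks and band-level effects
  become invisible to the analysis; C12 is broad because its activated
  wavelength (1014 nm) lies at the band's lower edge and must fall inside
  the line's curvature-negative zone.  Base amplitudes
  (0.10, 0.18, 0.15, 0.15, 0.50, 0.30, 0.45, 0.30, 0.30, 0.20, 0.15, 0.20
  for C1..C12) make the free-water S0 band (C5) dominant, as in fruit
  tissue near the 970 nm water peak.
* **SSC effect.**  Rising SSC transfers amplitude from the free bands
  C1–C5 to the bound bands C6–C10 exponentially at 0.02 per °Brix about the
  range midpoint, giving strictly monotone free/bound totals in SSC.
* **Polarization and depth.**  Detected light is a surface component (few
  scattering events, polarization-retaining, weight `depol_surface_weight`,
  default 0.6) plus a deep component (multiply scattered beyond the ~1 mm
  depolarization depth, fully depolarized, configuration-independent).
  Only the surface component feels the per-configuration effect matrix.  In
  polarized configurations the analyzer passes the surface component fully
  and a fraction `copol_fraction` (default 0.5, "half of the depolarized
  light") of the deep component: `I_detected = I_par + copol · I_perp`.
  A per-configuration reference is simulated, so the analyzer's overall
  transmission cancels in absorbance.  Setting the surface weight to zero
  therefore erases the polarization contrast exactly — the depolarization
  limit the tests assert to 1e−12.
* **Effect matrix (UU, UP, PU, PP × C1..C12).**  Polarized rows multiply the
  free bands by 1.35, C6–C10 by 0.88 and C11–C12 by 1.25; peeled rows
  multiply all bands by 1.70 (longer effective path in wet tissue once the
  highly scattering skin is removed — enough to dominate the unpeeled skin
  baseline in mean absorbance) and the bound bands by a further 1.15.
  These defaults are calibrated so that the end-to-end analysis reproduces
  the qualitative orderings reported on real fruit: mean raw absorbance
  peeled > unpeeled and polarized > unpolarized; configuration aquagrams
  with polarized > unpolarized on C1–C5 and C11–C12 and the reverse on
  C6–C10; SSC aquagrams with free-band alignment falling and bound-band
  alignment rising with SSC in every configuration.
* **Noise.**  Multiplicative i.i.d. Gaussian noise, sd 0.5% per scan, five
  scans averaged per sample.  All randomness flows from a single seeded
  generator; identical design + seed gives bit-identical outputs (asserted
  byte-wise on serialized CSV).

**What the generator does not emulate:** radiative-transfer physics, real
skin optics beyond a scalar baseline, temperature effects, instrument
bandpass, starch birefringence, or realistic band line shapes.  Passing
pattern tests on this generator demonstrates that the *analysis chain*
propagates band-level effects of the stated kind to the right read-outs
with the right signs — not that real kiwifruit produce effects of the
simulated magnitudes.  In particular, PCA explained-variance splits and
exact activated-wavelength attributions are dataset-dependent and are not
reproduction targets.

## Sizes and tolerances

The test suite and the reproduction script use the study scale — 200 fruit
× 4 configurations × 5 scans on an 84-point grid — which runs in seconds;
smaller populations (40–48 fruit) back unit fixtures.  Exactness checks use
1e−12 (SNV moments, depolarization limit, Eq.-style pooled standardization
at 1e−10), SG polynomial reproduction 1e−9, PCA-vs-eigendecomposition
agreement 1e−8 up to sign.  Grid uniformity tolerates 1e−9 nm of jitter.
Qualitative pattern tests require the polarization ordering on ≥ 10 of 12
bands per seed (it holds on 12/12 for the default calibration) and the SSC
ordering on all of C1–C10 in all four configurations.

## Known limitations

* The wavelength grid is configurable but uniform; the real instrument's
  pixel grid is not uniform in general.
* The activated-wavelength selector reconciles competing sources by
  standardized magnitude, one choice among several defensible rules; on
  sparse simulated data it may leave bands without candidates (it warns and
  omits them), in which case aquagrams cover fewer than 12 axes.
* `PolarizedSignalModel` components are exposed per scan only for polarized
  configurations; unpolarized scans carry no decomposition.
* Aquagram confidence bands and first-overtone (1450 nm) WAMACS are out of
  scope.
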