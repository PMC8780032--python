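# aquakiwi

Aquaphotomics analysis of polarized and unpolarized near-infrared
interactance spectra of kiwifruit.

NIR spectroscopy in the 800–1050 nm second overtone region of the OH
stretch is a standard non-destructive probe of fruit internal quality.
Aquaphotomics reads this region through twelve water matrix coordinates
(WAMACS, bands C1–C12): narrow wavebands whose absorbance tracks distinct
water species, from free water (S0, band C5) to molecules with one to four
hydrogen bonds (S1–S4) and strongly bonded water.  Because linearly
polarized light is depolarized within ~1 mm of fruit tissue, comparing
co-polarized with unpolarized detection separates near-surface from deep
water interactions.  `aquakiwi` implements the full analysis chain for a
study design of four measurement configurations — Unpeeled/Peeled fruit ×
Unpolarized/Polarized detection (UU, UP, PU, PP) — and a seeded synthetic
spectral simulator with known injected effects, so every step is verifiable
end to end.

The chain:

* absorbance `A(λ) = log10(I_ref/I)` from per-configuration reference scans;
* preprocessing: scan averaging, mean centering, SNV
  (`(x − x̄)/s`, sample sd), and Savitzky–Golay second derivative
  (window 7 points, polynomial order 2) — "SNV + 2D";
* PCA (first three components, deterministic loading signs) with loading
  extrema in the 900–1020 nm window;
* activated-wavelength selection per WAMACS band from three sources (PCA
  loadings, mean SNV+2D spectra per configuration, SSC-group difference
  spectra), plus the published twelve activated wavelengths as constants;
* aquagrams: the relative-SNV standardization
  `A′(λ) = (A(λ) − μ_λ)/σ_λ`, with `μ_λ, σ_λ` pooled over all samples of
  all configurations, displayed as radar charts by configuration and by
  SSC group (Low < 12, Medium 12–15, High ≥ 15 °Brix).

It is intended for chemometrics practitioners who want a tested, scriptable
reference implementation of this analysis, and for anyone needing a
controllable generator of polarization/peel/SSC effects in water-band
spectra.

## Worked example

```python
from aquakiwi import (SimulationDesign, simulate_population,
                      to_absorbance_set, PreprocessPlan, run_plan,
                      aquagram_input, relative_snv,
                      aquagram_by_configuration, published_activated_set)

result = simulate_population(SimulationDesign(n_fruit=200, seed=1))
absorb = to_absorbance_set(result.spectra, result.references)
snv2d = run_plan(absorb, PreprocessPlan(steps=("snv", "savgol2d")))
inp = aquagram_input(snv2d, published_activated_set())
profiles = aquagram_by_configuration(relative_snv(inp),
                                     inp.sample_table, inp.band_ids)
```

Running `python examples/01_simulate_population.py` prints

```
simulated 800 sample spectra (200 fruit x 4 configurations), grid 800-1049 nm

mean absorbance (AU) per configuration:
configuration
UU    0.4522
UP    0.4603
PU    0.4586
PP    0.4884
```

— peeling and the polarizer both raise mean absorbance (PU > UU, PP > UP,
UP > UU), the ordering seen on real fruit.  `examples/04_aquagrams.py`
prints the per-band polarized-minus-unpolarized aquagram differences

```
C1     1.199
C2     0.955
C3     1.071
C4     0.369
C5     1.354
C6    -1.318
C7    -0.941
C8    -0.240
C9    -0.897
C10   -1.321
C11    0.197
C12    0.146
```

— positive at the free-water bands C1–C5 and the strongly bonded C11–C12,
negative at the bound-water bands C6–C10: polarized detection relatively
favours free-water states and unpolarized detection bound-water states.
The other examples cover preprocessing + PCA (`02`) and data-driven
activated-wavelength selection (`03`).

A complete configured run (all stage CSVs, PCA outputs, aquagram tables and
charts, manifest and summary) is available through the pipeline, from
Python (`aquakiwi.run(RunConfig(output_dir="runs/demo", seed=1))`) or the
CLI:

```sh
aquakiwi run --output-dir runs/demo --seed 1
aquakiwi report runs/demo
```

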