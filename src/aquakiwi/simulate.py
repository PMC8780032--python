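"""Synthetic kiwifruit phantoms and instrument-like interactance spectra.

No spectra are publicly deposited for the polarized-kiwifruit study, so this
module generates a stand-in population with *known injected effects* so the
whole analysis chain (absorbance -> SNV -> SG 2nd derivative -> PCA ->
activated-wavelength selection -> aquagrams) can be verified end to end.

Forward model
-------------
Each fruit carries nonnegative absorption amplitudes for the 12 WAMACS
bands C1-C12 (Gaussian lines at the band midpoints, per-band widths of
3-6 nm, on a broad 970 nm water envelope, sd 35 nm).  Soluble solids
content moves amplitude
from the free-water bands C1-C5 to the bound-water bands C6-C10 at a fixed
exponential rate per degree Brix.

Detected light is split into a *surface* component (few scattering events,
retains polarization, samples the near-surface tissue where the measurement
configuration modifies band weights via the effect matrix) and a *deep*
component (multiply scattered beyond the ~1 mm depolarization depth, fully
depolarized, configuration-independent).  Through the analyzer of a
polarized configuration the surface component passes fully while only a
fraction ``copol_fraction`` (default one half) of the depolarized deep light
passes:

    I_detected = I_parallel + copol_fraction * I_perp

A per-configuration reference scan is simulated, so the analyzer's overall
transmission cancels in absorbance; residual polarized-vs-unpolarized
differences are carried entirely by the surface-weighted effect matrix.
Unpeeled configurations additionally carry a small skin-scatter absorbance
baseline; peeled configurations compensate with larger band amplitudes
(longer effective path in wet tissue), so mean absorbance is ordered
peeled > unpeeled and polarized > unpolarized as observed on real fruit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import (
    CONFIGURATIONS,
    POLARIZED_CONFIGURATIONS,
    UNPEELED_CONFIGURATIONS,
    SpectralGrid,
    SpectraSet,
    Spectrum,
)
from .wamacs import BAND_IDS, band_midpoints

#: Gaussian line widths (sd, nm) per WAMACS band.  The narrow WAMACS bands
#: C1-C4 sit only ~7 nm apart; a width above ~5 nm merges them so the second
#: derivative at each centre is dominated by the neighbours' positive flanks
#: rather than the band's own curvature, destroying the band-level structure
#: the analysis reads out.  4 nm keeps every band resolvable.  C11 (the
#: narrow S4 line) is kept at 3 nm and C12 (strongly bonded water, whose
#: activated wavelength 1014 nm lies at the band's lower edge) at 6 nm so
#: that the read-out point falls inside each band's own curvature-negative
#: zone rather than in the C11-C12 valley.
DEFAULT_BAND_SD_NM = np.array([4.0] * 8 + [5.0, 5.0, 3.0, 6.0])
#: Broad underlying water envelope: centre and sd in nm.
ENVELOPE_CENTER_NM = 970.0
ENVELOPE_SD_NM = 35.0

#: Base per-band absorption amplitudes of a typical fruit (C1..C12); the
#: free-water S0 band (C5) and the S1 band (C7) near the 970 nm water peak
#: dominate.  C2 and C12 are kept strong enough that their own curvature,
#: not a neighbour's flank, sets the sign of the 2nd derivative at their
#: activated wavelengths.
DEFAULT_BAND_AMPLITUDES = np.array(
    [0.10, 0.18, 0.15, 0.15, 0.50, 0.30, 0.45, 0.30, 0.30, 0.20, 0.15, 0.20]
)

_FREE = slice(0, 5)       # C1-C5
_SHIFT_BOUND = slice(5, 10)  # C6-C10 (receive amplitude as SSC rises)
_BOUND_ALL = slice(5, 12)  # C6-C12

#: Default multiplicative band-amplitude modifiers per configuration
#: (rows UU, UP, PU, PP x columns C1..C12).  Polarization favours the free
#: bands C1-C5 and the strongly bonded C11-C12 in relative terms and
#: suppresses C6-C10; peeling lengthens the effective path in wet tissue
#: (x1.70 overall, enough to dominate the unpeeled skin baseline) and
#: additionally boosts the bound bands (x1.15).
def _default_effect_matrix() -> np.ndarray:
    pol = np.ones(12)
    pol[_FREE] = 1.35
    pol[_SHIFT_BOUND] = 0.88
    pol[10:12] = 1.25
    peel = np.full(12, 1.70)
    peel[_BOUND_ALL] *= 1.15
    return np.vstack([np.ones(12), pol, peel, peel * pol])


DEFAULT_EFFECT_MATRIX = _default_effect_matrix()


@dataclass
class PhantomFruit:
    """Ground-truth description of one simulated fruit."""

    fruit_id: str
    ssc_stem: float
    ssc_blossom: float
    wet_weight: float
    dry_weight: float
    band_amplitudes: np.ndarray
    skin_scatter: float

    def __post_init__(self) -> None:
        self.band_amplitudes = np.asarray(self.band_amplitudes, dtype=float)
        if self.band_amplitudes.shape != (12,):
            raise ValueError("band_amplitudes must be a 12-vector")
        if np.any(self.band_amplitudes < 0):
            raise ValueError("band_amplitudes must be nonnegative")
        if self.skin_scatter < 0:
            raise ValueError("skin_scatter must be nonnegative")
        if self.wet_weight <= 0:
            raise ValueError("wet_weight must be positive")
        if self.dry_weight < 0 or self.dry_weight > self.wet_weight:
            raise ValueError("dry_weight must lie in [0, wet_weight]")

    @property
    def ssc(self) -> float:
        """Fruit SSC: average of the stem- and blossom-end readings."""
        return 0.5 * (self.ssc_stem + self.ssc_blossom)

    @property
    def dmc(self) -> float:
        """Dry matter content as a fraction of fresh weight."""
        return self.dry_weight / self.wet_weight


@dataclass
class PolarizedSignalModel:
    """Co-polarized detection: the analyzer passes polarization-retaining
    light fully and a fraction of the depolarized light."""

    i_parallel: np.ndarray
    i_perp: np.ndarray
    copol_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.i_parallel = np.asarray(self.i_parallel, dtype=float)
        self.i_perp = np.asarray(self.i_perp, dtype=float)
        if self.i_parallel.shape != self.i_perp.shape:
            raise ValueError("component shapes differ")
        if not 0.0 <= self.copol_fraction <= 1.0:
            raise ValueError("copol_fraction must lie in [0, 1]")

    @property
    def detected(self) -> np.ndarray:
        out = self.i_parallel + self.copol_fraction * self.i_perp
        if np.any(out < 0):
            raise ValueError("detected intensity must be nonnegative")
        return out


@dataclass
class SimulationDesign:
    """Study-scale defaults: 200 fruit x 4 configurations, 800-1050 nm grid
    (3 nm step), SSC uniform on 7-20.5 degrees Brix, five replicate scans
    with 0.5% multiplicative noise."""

    n_fruit: int = 200
    grid: SpectralGrid = field(default_factory=SpectralGrid)
    ssc_low: float = 7.0
    ssc_high: float = 20.5
    noise_sd: float = 0.005
    n_scans: int = 5
    depol_surface_weight: float = 0.6
    effect_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_EFFECT_MATRIX.copy())
    ssc_shift_rate: float = 0.02
    skin_scatter_mean: float = 0.05
    copol_fraction: float = 0.5
    reference_level: float = 1.0
    envelope_amplitude: float = 0.8
    amplitude_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        if self.n_fruit < 1 or self.n_scans < 1:
            raise ValueError("n_fruit and n_scans must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effect_matrix.shape != (4, 12):
            raise ValueError("effect_matrix must be 4 x 12 (UU, UP, PU, PP x C1..C12)")
        if np.any(self.effect_matrix <= 0):
            raise ValueError("effect_matrix entries must be > 0")
        if not 0.0 <= self.depol_surface_weight <= 1.0:
            raise ValueError("depol_surface_weight must lie in [0, 1]")
        if not 0.0 <= self.copol_fraction <= 1.0:
            raise ValueError("copol_fraction must lie in [0, 1]")
        if self.ssc_high < self.ssc_low or self.ssc_low < 0:
            raise ValueError("need 0 <= ssc_low <= ssc_high")
        if not self.grid.covers(800.0, 1020.0):
            raise ValueError("grid must cover at least 800-1020 nm (the WAMACS region)")

    def effect_row(self, configuration: str) -> np.ndarray:
        return self.effect_matrix[CONFIGURATIONS.index(configuration)]

    @property
    def ssc_mid(self) -> float:
        return 0.5 * (self.ssc_low + self.ssc_high)


def make_band_profile(band_amplitudes: np.ndarray, grid: SpectralGrid,
                      envelope_amplitude: float = 0.0,
                      band_sd_nm: float | np.ndarray | None = None,
                      envelope_sd_nm: float = ENVELOPE_SD_NM) -> Spectrum:
    """Absorbance-like profile: 12 Gaussians at the WAMACS band midpoints
    plus a broad 970 nm water envelope.  Linear in the amplitudes.
    ``band_sd_nm`` may be a scalar or a per-band 12-vector (default
    :data:`DEFAULT_BAND_SD_NM`)."""
    amps = np.asarray(band_amplitudes, dtype=float)
    if amps.shape != (12,):
        raise ValueError("band_amplitudes must be a 12-vector")
    if np.any(amps < 0) or envelope_amplitude < 0:
        raise ValueError("amplitudes must be nonnegative")
    sds = DEFAULT_BAND_SD_NM if band_sd_nm is None else band_sd_nm * np.ones(12)
    wl = grid.wavelengths  # SpectralGrid is uniform by construction
    centers = band_midpoints()
    gauss = np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / sds[:, None]) ** 2)
    values = amps @ gauss
    values = values + envelope_amplitude * np.exp(
        -0.5 * ((wl - ENVELOPE_CENTER_NM) / envelope_sd_nm) ** 2
    )
    return Spectrum(grid=grid, values=values, kind="absorbance",
                    meta={"role": "band_profile"})


def ssc_shift_factors(ssc: float, design: SimulationDesign) -> np.ndarray:
    """Per-band multiplicative SSC factors: free bands C1-C5 decay and bound
    bands C6-C10 grow exponentially with SSC about the range midpoint."""
    f = np.ones(12)
    delta = design.ssc_shift_rate * (ssc - design.ssc_mid)
    f[_FREE] = np.exp(-delta)
    f[_SHIFT_BOUND] = np.exp(delta)
    return f


def _clean_components(fruit: PhantomFruit, configuration: str,
                      design: SimulationDesign) -> tuple[np.ndarray, np.ndarray, float]:
    """Noise-free (surface, deep) intensity components (already reference-
    normalized) and the skin baseline transmission factor."""
    shift = ssc_shift_factors(fruit.ssc, design)
    amps_deep = fruit.band_amplitudes * shift
    amps_surf = amps_deep * design.effect_row(configuration)
    a_deep = make_band_profile(amps_deep, design.grid, design.envelope_amplitude).values
    a_surf = make_band_profile(amps_surf, design.grid, design.envelope_amplitude).values
    w = design.depol_surface_weight
    g_deep = design.copol_fraction if configuration in POLARIZED_CONFIGURATIONS else 1.0
    norm = w + g_deep * (1.0 - w)
    skin = fruit.skin_scatter if configuration in UNPEELED_CONFIGURATIONS else 0.0
    t_skin = 10.0 ** (-skin)
    level = design.reference_level
    surf = level * w * 10.0 ** (-a_surf) / norm * t_skin
    deep = level * (1.0 - w) * 10.0 ** (-a_deep) / norm * t_skin
    return surf, deep, t_skin


def simulate_measurement(fruit: PhantomFruit, configuration: str,
                         design: SimulationDesign, rng: np.random.Generator
                         ) -> tuple[list[Spectrum], Spectrum]:
    """Simulate the replicate scans of one fruit in one configuration.

    Returns ``(scans, reference)``: ``n_scans`` raw-intensity spectra with
    i.i.d. multiplicative noise, and the flat per-configuration reference
    scan (analyzer transmission cancels by construction).  For polarized
    configurations each scan's meta carries the ``i_parallel``/``i_perp``
    decomposition satisfying the co-polarized detection identity.
    """
    if configuration not in CONFIGURATIONS:
        raise ValueError(
            f"unknown configuration {configuration!r}; expected one of {CONFIGURATIONS}")
    surf, deep, _ = _clean_components(fruit, configuration, design)
    polarized = configuration in POLARIZED_CONFIGURATIONS
    g_deep = design.copol_fraction if polarized else 1.0
    scans: list[Spectrum] = []
    for k in range(design.n_scans):
        noise = 1.0 + rng.normal(0.0, design.noise_sd, size=len(design.grid)) \
            if design.noise_sd > 0 else np.ones(len(design.grid))
        i_par = surf * noise
        i_perp = deep * noise
        detected = i_par + g_deep * i_perp
        meta = {"fruit_id": fruit.fruit_id, "configuration": configuration, "scan": k}
        if polarized:
            meta["i_parallel"] = i_par
            meta["i_perp"] = i_perp
            meta["copol_fraction"] = design.copol_fraction
        scans.append(Spectrum(grid=design.grid, values=detected, kind="intensity",
                              meta=meta))
    reference = Spectrum(
        grid=design.grid,
        values=np.full(len(design.grid), design.reference_level),
        kind="intensity",
        meta={"configuration": configuration, "role": "reference"},
    )
    return scans, reference


def reference_values(fruit: PhantomFruit) -> tuple[float, float]:
    """Destructive reference values: (DMC in percent of fresh weight, SSC in
    degrees Brix as the mean of the two end readings)."""
    if fruit.wet_weight <= 0:
        raise ValueError("wet_weight must be positive")
    if fruit.dry_weight > fruit.wet_weight:
        raise ValueError("dry_weight cannot exceed wet_weight")
    return 100.0 * fruit.dry_weight / fruit.wet_weight, fruit.ssc


def make_phantoms(design: SimulationDesign, rng: np.random.Generator
                  ) -> list[PhantomFruit]:
    """Draw the fruit population: SSC uniform on [ssc_low, ssc_high], DMC
    loosely correlated with SSC, mild per-fruit band-amplitude jitter."""
    fruits = []
    width = max(design.n_fruit - 1, 1)
    digits = len(str(design.n_fruit))
    for i in range(design.n_fruit):
        ssc = rng.uniform(design.ssc_low, design.ssc_high)
        end_split = rng.normal(0.0, 0.3)
        dmc = np.clip(0.14 + 0.004 * (ssc - design.ssc_mid) + rng.normal(0.0, 0.005),
                      0.02, 0.60)
        wet = rng.normal(12.5, 1.0)
        wet = float(np.clip(wet, 5.0, 25.0))
        amps = DEFAULT_BAND_AMPLITUDES * (
            1.0 + design.amplitude_jitter * rng.normal(size=12))
        amps = np.clip(amps, 0.0, None)
        skin = max(0.0, rng.normal(design.skin_scatter_mean,
                                   0.2 * design.skin_scatter_mean))
        fruits.append(PhantomFruit(
            fruit_id=f"F{i + 1:0{digits}d}",
            ssc_stem=ssc + end_split,
            ssc_blossom=ssc - end_split,
            wet_weight=wet,
            dry_weight=float(dmc * wet),
            band_amplitudes=amps,
            skin_scatter=skin,
        ))
    return fruits


@dataclass
class SimulationResult:
    """Averaged intensity spectra, per-configuration reference scans and the
    ground-truth table of every injected parameter."""

    spectra: SpectraSet
    references: dict[str, Spectrum]
    truth: pd.DataFrame


def simulate_population(design: SimulationDesign) -> SimulationResult:
    """Simulate the full study: every fruit measured in all four
    configurations, replicate scans averaged per sample.

    Deterministic for a fixed design (including its seed): identical inputs
    give bit-identical outputs.
    """
    from .preprocess import average_scans
    from .wamacs import ssc_group

    rng = np.random.default_rng(design.seed)
    fruits = make_phantoms(design, rng)

    rows, meta_rows, truth_rows = [], [], []
    references: dict[str, Spectrum] = {}
    for fruit in fruits:
        dmc_pct, ssc = reference_values(fruit)
        for cfg in CONFIGURATIONS:
            scans, reference = simulate_measurement(fruit, cfg, design, rng)
            references[cfg] = reference
            avg = average_scans(scans)
            rows.append(avg.values)
            meta_rows.append({
                "fruit_id": fruit.fruit_id,
                "configuration": cfg,
                "ssc": ssc,
                "dmc": dmc_pct,
                "ssc_group": ssc_group(ssc),
            })
        truth_rows.append({
            "fruit_id": fruit.fruit_id,
            "ssc": ssc,
            "ssc_stem": fruit.ssc_stem,
            "ssc_blossom": fruit.ssc_blossom,
            "dmc_pct": dmc_pct,
            "wet_weight_g": fruit.wet_weight,
            "dry_weight_g": fruit.dry_weight,
            "skin_scatter": fruit.skin_scatter,
            "ssc_group": ssc_group(ssc),
            **{f"amp_{b}": a for b, a in zip(BAND_IDS, fruit.band_amplitudes)},
        })

    spectra = SpectraSet(
        matrix=np.asarray(rows),
        sample_table=pd.DataFrame(meta_rows),
        grid=design.grid,
        kind="intensity",
        history=("simulate", "average_scans"),
    )
    return SimulationResult(spectra=spectra, references=references,
                            truth=pd.DataFrame(truth_rows))
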