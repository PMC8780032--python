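"""Water matrix coordinates (WAMACS) for the second overtone of water,
soluble-solids grouping, SSC difference spectra and activated-wavelength
selection.

The twelve WAMACS wavebands C1-C12 in the 900-1021 nm region are published
constants derived from the anharmonic oscillator model of the OH stretch.
Each band corresponds to a water species or vibrational combination; C1-C5
relate to free water (S0: no hydrogen bonds) and C6-C12 to bound water
(S1-S4: one to four hydrogen bonds, plus strongly bonded combinations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometrics import PcaModel, curve_extrema, loading_extrema
from .spectra import SpectraSet, Spectrum

SSC_GROUPS = ("Low", "Medium", "High")

#: Published SSC-group summary for the 200-fruit study population:
#: group -> (n, range lo, range hi, mean degrees Brix).
SSC_GROUP_REFERENCE = {
    "Low": {"n": 61, "lo": 7.0, "hi": 11.9, "mean": 10.4},
    "Medium": {"n": 69, "lo": 12.1, "hi": 14.9, "mean": 13.5},
    "High": {"n": 70, "lo": 15.0, "hi": 20.5, "mean": 16.9},
    "All": {"n": 200, "lo": 7.0, "hi": 20.5, "mean": 13.7},
}


@dataclass(frozen=True)
class WamacsBand:
    band_id: str
    lo_nm: float
    hi_nm: float
    assignment: str
    species_class: str  # "free" or "bound"

    def __post_init__(self) -> None:
        if self.lo_nm >= self.hi_nm:
            raise ValueError(f"{self.band_id}: lo_nm must be < hi_nm")

    @property
    def center_nm(self) -> float:
        return 0.5 * (self.lo_nm + self.hi_nm)

    def contains(self, wavelength_nm: float) -> bool:
        return self.lo_nm <= wavelength_nm <= self.hi_nm


_TABLE = (
    ("C1", 900.0, 908.0, "v3 - asymmetric stretching vibration", "free"),
    ("C2", 916.0, 920.0, "OH stretch (water solvation shell)", "free"),
    ("C3", 923.0, 927.0, "v1+v3 - symmetric + asymmetric stretching vibration", "free"),
    ("C4", 930.0, 935.0, "OH stretch (water solvation shell)", "free"),
    ("C5", 942.0, 955.0, "S0 (free water)", "free"),
    ("C6", 957.0, 963.0, "Water hydration, H5O2+", "bound"),
    ("C7", 965.0, 973.0, "S1 - water molecules with one hydrogen bond", "bound"),
    ("C8", 975.0, 979.0, "v2+v3 - bending + asymmetric stretching vibration", "bound"),
    ("C9", 982.0, 989.0, "S2 - water molecules with 2 hydrogen bonds", "bound"),
    ("C10", 992.0, 998.0, "S3 - water molecules with 3 hydrogen bonds", "bound"),
    ("C11", 998.0, 1007.0, "S4 - water molecules with 4 hydrogen bonds", "bound"),
    ("C12", 1014.0, 1021.0, "strongly bonded water (v1, v2)", "bound"),
)

WAMACS_BANDS: tuple[WamacsBand, ...] = tuple(WamacsBand(*row) for row in _TABLE)

BAND_IDS: tuple[str, ...] = tuple(b.band_id for b in WAMACS_BANDS)

#: Bands dominated by free vs bound water species.
FREE_BANDS = tuple(b.band_id for b in WAMACS_BANDS if b.species_class == "free")
BOUND_BANDS = tuple(b.band_id for b in WAMACS_BANDS if b.species_class == "bound")

#: Activated wavelengths reported for the kiwifruit study, with the analysis
#: source that identified each one.
PUBLISHED_ACTIVATED = {
    "C1": (903.0, "ssc_diff"),
    "C2": (916.0, "pca"),
    "C3": (926.0, "snv2d"),
    "C4": (933.0, "snv2d"),
    "C5": (946.0, "pca"),
    "C6": (962.0, "snv2d"),
    "C7": (965.0, "pca"),
    "C8": (975.0, "ssc_diff"),
    "C9": (988.0, "pca"),
    "C10": (994.0, "ssc_diff"),
    "C11": (1007.0, "pca"),
    "C12": (1014.0, "pca"),
}

SOURCES = ("pca", "snv2d", "ssc_diff")


def wamacs_table() -> list[WamacsBand]:
    """The 12 second-overtone WAMACS bands, ordered C1 -> C12."""
    return list(WAMACS_BANDS)


def band_midpoints() -> np.ndarray:
    """Band centre wavelengths (midpoint of each band's nm range)."""
    return np.array([b.center_nm for b in WAMACS_BANDS])


def assign_band(wavelength_nm: float) -> str | None:
    """The band whose closed [lo, hi] range contains the wavelength, or None.

    The shared 998 nm endpoint of C10/C11 resolves to the lower band (C10):
    bands are scanned C1 -> C12 and the first containing band wins.
    """
    for band in WAMACS_BANDS:
        if band.contains(wavelength_nm):
            return band.band_id
    return None


def ssc_group(ssc: float) -> str:
    """SSC group label: Low < 12, Medium in [12, 15), High >= 15 degrees Brix.

    The published group ranges (7-11.9 / 12.1-14.9 / 15-20.5) leave small
    gaps; boundaries here close them at 12 and 15.
    """
    if ssc < 0:
        raise ValueError(f"SSC must be nonnegative, got {ssc}")
    if ssc < 12.0:
        return "Low"
    if ssc < 15.0:
        return "Medium"
    return "High"


def ssc_group_labels(ssc: pd.Series | np.ndarray) -> pd.Series:
    ssc = pd.Series(ssc)
    if (ssc < 0).any():
        raise ValueError("SSC must be nonnegative")
    return pd.Series(
        np.where(ssc < 12.0, "Low", np.where(ssc < 15.0, "Medium", "High")),
        index=ssc.index,
    )


@dataclass
class ActivatedWavelengthSet:
    """Selected activated wavelength per band: band_id -> (nm, source)."""

    entries: dict[str, tuple[float, str]]

    def __post_init__(self) -> None:
        by_band = {b.band_id: b for b in WAMACS_BANDS}
        for band_id, (wl, source) in self.entries.items():
            if band_id not in by_band:
                raise ValueError(f"unknown band {band_id!r}")
            if not by_band[band_id].contains(wl):
                raise ValueError(
                    f"wavelength {wl} nm lies outside band {band_id} "
                    f"[{by_band[band_id].lo_nm}, {by_band[band_id].hi_nm}]"
                )
            if source not in SOURCES:
                raise ValueError(f"unknown source {source!r}")
        # keep C1 -> C12 order
        self.entries = {b: self.entries[b] for b in BAND_IDS if b in self.entries}

    @property
    def band_ids(self) -> list[str]:
        return list(self.entries)

    @property
    def wavelengths(self) -> list[float]:
        return [wl for wl, _ in self.entries.values()]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b, wl, src) for b, (wl, src) in self.entries.items()],
            columns=["band_id", "wavelength_nm", "source"],
        )


def published_activated_set() -> ActivatedWavelengthSet:
    """The study's reported activated wavelengths as a ready-made selection."""
    return ActivatedWavelengthSet(dict(PUBLISHED_ACTIVATED))


def ssc_difference_spectra(sset: SpectraSet, configuration: str) -> dict[str, Spectrum]:
    """Per-group difference spectra for one configuration.

    For each SSC group g: diff_g(lambda) = mean_Low(lambda) - mean_g(lambda),
    computed on the (typically SNV+2D) spectra of that configuration only.
    diff_Low is identically zero by construction.
    """
    sub = sset.select((sset.sample_table["configuration"] == configuration).to_numpy())
    if sub.n_samples == 0:
        raise ValueError(f"no samples for configuration {configuration!r}")
    if "ssc_group" in sub.sample_table.columns:
        groups = sub.sample_table["ssc_group"]
    elif "ssc" in sub.sample_table.columns:
        groups = ssc_group_labels(sub.sample_table["ssc"])
    else:
        raise ValueError("sample table has neither 'ssc_group' nor 'ssc'")
    means: dict[str, np.ndarray] = {}
    for g in SSC_GROUPS:
        mask = (groups == g).to_numpy()
        if not mask.any():
            raise ValueError(f"SSC group {g!r} is empty for configuration {configuration!r}")
        means[g] = sub.matrix[mask].mean(axis=0)
    return {
        g: Spectrum(
            grid=sub.grid,
            values=means["Low"] - means[g],
            kind="difference",
            meta={"configuration": configuration, "ssc_group": g},
        )
        for g in SSC_GROUPS
    }


def _standardized_extrema(grid, values, window_nm, source):
    """Candidate extrema of one source curve, with magnitudes standardized to
    the curve's unit maximum absolute value inside the window."""
    wl = grid.wavelengths
    mask = (wl >= window_nm[0]) & (wl <= window_nm[1])
    scale = float(np.max(np.abs(np.asarray(values, dtype=float)[mask])))
    if scale == 0:
        return []
    return [(w, v / scale, s, source) for w, v, s in curve_extrema(grid, values, window_nm)]


def select_activated(
    pca_model: PcaModel,
    mean_snv2d_per_config: dict[str, Spectrum],
    diff_spectra: dict[str, Spectrum],
    bands: list[WamacsBand] | None = None,
    window_nm: tuple[float, float] = (900.0, 1020.0),
) -> ActivatedWavelengthSet:
    """Three-source activated-wavelength selection.

    Candidates are local extrema inside ``window_nm`` pooled from (a) PC1-PCn
    loadings, (b) the mean SNV+2D spectrum of each configuration and (c) the
    SSC difference spectra.  Each source curve is standardized to unit
    maximum absolute value so no source dominates by scale; within each band
    the candidate of largest standardized |value| wins, ties going to the
    lower wavelength.  Bands with no candidate are omitted with a warning.
    """
    bands = list(WAMACS_BANDS) if bands is None else bands
    candidates: list[tuple[float, float, int, str]] = []
    for k in range(1, pca_model.n_components + 1):
        candidates += _standardized_extrema(
            pca_model.grid, pca_model.loadings[k - 1], window_nm, "pca")
    for spec in mean_snv2d_per_config.values():
        candidates += _standardized_extrema(spec.grid, spec.values, window_nm, "snv2d")
    for spec in diff_spectra.values():
        candidates += _standardized_extrema(spec.grid, spec.values, window_nm, "ssc_diff")
    if not candidates:
        raise ValueError("no candidate extrema found in any source (degenerate input)")

    entries: dict[str, tuple[float, str]] = {}
    for band in bands:
        in_band = [c for c in candidates if band.contains(c[0])]
        if not in_band:
            warnings.warn(f"no activated-wavelength candidate in band {band.band_id}",
                          stacklevel=2)
            continue
        best = min(in_band, key=lambda c: (-abs(c[1]), c[0]))
        entries[band.band_id] = (best[0], best[3])
    if not entries:
        raise ValueError("no band received a candidate wavelength")
    return ActivatedWavelengthSet(entries)
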