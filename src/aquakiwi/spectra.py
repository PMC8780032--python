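"""Core spectral containers and the intensity -> absorbance transform.

The package works on interactance spectra sampled on a uniform wavelength
grid in the short-wave NIR (by default 800-1050 nm, the second overtone
region of the OH stretch of water).  A :class:`Spectrum` is a single
wavelength-indexed vector with a processing-stage tag; a :class:`SpectraSet`
is a sample x wavelength matrix joined to a per-sample metadata table.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Valid processing-stage tags, in the order they normally occur.
KINDS = ("intensity", "absorbance", "snv", "snv2d", "difference")

#: The four measurement configurations: Unpeeled/Peeled x Unpolarized/Polarized.
CONFIGURATIONS = ("UU", "UP", "PU", "PP")

#: Configurations measured through the linear polarizer (co-polarized detection).
POLARIZED_CONFIGURATIONS = ("UP", "PP")

#: Configurations measured on intact (skin-on) fruit.
UNPEELED_CONFIGURATIONS = ("UU", "UP")

#: Maximum tolerated deviation from uniform grid spacing, in nm.
GRID_TOL = 1e-9


@dataclass(frozen=True)
class SpectralGrid:
    """A uniform wavelength grid [start_nm, start_nm + step_nm, ...].

    The default grid spans 800-1050 nm in 3 nm steps (84 points); the last
    grid point is the largest start + k*step not exceeding stop_nm.
    """

    start_nm: float = 800.0
    stop_nm: float = 1050.0
    step_nm: float = 3.0

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be > 0, got {self.step_nm}")
        if self.stop_nm <= self.start_nm:
            raise ValueError("stop_nm must exceed start_nm")

    def __len__(self) -> int:
        return int(math.floor((self.stop_nm - self.start_nm) / self.step_nm + GRID_TOL)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(len(self), dtype=float)

    def index_nearest(self, wavelength_nm: float) -> int:
        """Index of the grid point nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def covers(self, lo_nm: float, hi_nm: float) -> bool:
        return self.start_nm <= lo_nm and self.wavelengths[-1] >= hi_nm

    @classmethod
    def from_wavelengths(cls, wavelengths: np.ndarray) -> "SpectralGrid":
        """Build a grid from an explicit wavelength vector, rejecting
        non-uniform spacing (any |step deviation| > 1 pm)."""
        wl = np.asarray(wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("need at least two wavelengths")
        steps = np.diff(wl)
        step = float(steps[0])
        if step <= 0 or np.any(np.abs(steps - step) > GRID_TOL):
            raise ValueError("wavelength grid is not uniformly increasing")
        return cls(start_nm=float(wl[0]), stop_nm=float(wl[-1]), step_nm=step)


def _check_kind(kind: str) -> str:
    if kind not in KINDS:
        raise ValueError(f"unknown spectrum kind {kind!r}; expected one of {KINDS}")
    return kind


@dataclass
class Spectrum:
    """One spectrum on a grid, with a processing-stage tag and metadata."""

    grid: SpectralGrid
    values: np.ndarray
    kind: str = "intensity"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.grid):
            raise ValueError(
                f"values length {self.values.size} does not match grid length {len(self.grid)}"
            )
        _check_kind(self.kind)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths


#: Metadata columns required in every sample table.
REQUIRED_SAMPLE_COLUMNS = ("fruit_id", "configuration")


@dataclass
class SpectraSet:
    """A samples x wavelengths matrix joined to a sample metadata table.

    ``sample_table`` has one row per matrix row and at minimum the columns
    ``fruit_id`` and ``configuration``; population-level sets also carry
    ``ssc`` (degrees Brix), ``dmc`` (percent of fresh weight) and
    ``ssc_group``.  ``history`` records the processing steps applied.
    """

    matrix: np.ndarray
    sample_table: pd.DataFrame
    grid: SpectralGrid
    kind: str = "intensity"
    history: tuple = ()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x wavelengths)")
        if self.matrix.shape[1] != len(self.grid):
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but grid has {len(self.grid)} points"
            )
        if len(self.sample_table) != self.matrix.shape[0]:
            raise ValueError(
                f"sample_table has {len(self.sample_table)} rows but matrix has "
                f"{self.matrix.shape[0]}"
            )
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.sample_table.columns:
                raise ValueError(f"sample_table missing required column {col!r}")
        bad = ~self.sample_table["configuration"].isin(CONFIGURATIONS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid configuration {self.sample_table['configuration'].iloc[row]!r} "
                f"in sample_table row {row}; expected one of {CONFIGURATIONS}"
            )
        _check_kind(self.kind)
        self.sample_table = self.sample_table.reset_index(drop=True)
        self.history = tuple(self.history)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def with_matrix(self, matrix: np.ndarray, kind: str | None = None,
                    step: str | None = None) -> "SpectraSet":
        """Copy with a new matrix (and optionally kind), appending ``step``
        to the processing history."""
        history = self.history + ((step,) if step else ())
        return SpectraSet(
            matrix=matrix,
            sample_table=self.sample_table.copy(),
            grid=self.grid,
            kind=self.kind if kind is None else kind,
            history=history,
        )

    def select(self, mask) -> "SpectraSet":
        """Row subset by boolean mask or index array."""
        mask = np.asarray(mask)
        return SpectraSet(
            matrix=self.matrix[mask],
            sample_table=self.sample_table.loc[mask].reset_index(drop=True),
            grid=self.grid,
            kind=self.kind,
            history=self.history,
        )

    def row(self, i: int) -> Spectrum:
        meta = self.sample_table.iloc[i].to_dict()
        return Spectrum(grid=self.grid, values=self.matrix[i].copy(), kind=self.kind, meta=meta)


def grids_equal(a: SpectralGrid, b: SpectralGrid, tol: float = GRID_TOL) -> bool:
    return (
        abs(a.start_nm - b.start_nm) <= tol
        and abs(a.step_nm - b.step_nm) <= tol
        and len(a) == len(b)
    )


def to_absorbance(sample: Spectrum, reference: Spectrum) -> Spectrum:
    """Convert raw interactance intensity to absorbance A = log10(ref/sample).

    Both spectra must share a grid and be strictly positive; this sign
    convention makes water absorption bands positive peaks.
    """
    if not grids_equal(sample.grid, reference.grid):
        raise ValueError("sample and reference grids differ")
    if np.any(sample.values <= 0):
        raise ValueError("sample intensity has nonpositive values (saturated/dark pixel?)")
    if np.any(reference.values <= 0):
        raise ValueError("reference intensity has nonpositive values")
    values = np.log10(reference.values / sample.values)
    return Spectrum(grid=sample.grid, values=values, kind="absorbance", meta=dict(sample.meta))


def to_absorbance_set(sset: SpectraSet, references: Mapping[str, Spectrum]) -> SpectraSet:
    """Row-wise absorbance using the per-configuration reference scans."""
    if sset.kind != "intensity":
        raise ValueError(f"expected an intensity set, got kind {sset.kind!r}")
    out = np.empty_like(sset.matrix)
    for cfg in sset.sample_table["configuration"].unique():
        if cfg not in references:
            raise ValueError(f"no reference scan for configuration {cfg!r}")
        ref = references[cfg]
        if not grids_equal(ref.grid, sset.grid):
            raise ValueError(f"reference grid for {cfg!r} does not match the set grid")
        if np.any(ref.values <= 0):
            raise ValueError(f"reference for {cfg!r} has nonpositive values")
        rows = (sset.sample_table["configuration"] == cfg).to_numpy()
        if np.any(sset.matrix[rows] <= 0):
            raise ValueError(f"nonpositive sample intensity in configuration {cfg!r}")
        out[rows] = np.log10(ref.values[None, :] / sset.matrix[rows])
    return sset.with_matrix(out, kind="absorbance", step="to_absorbance")
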