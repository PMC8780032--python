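"""Spectral preprocessing: scan averaging, SNV, Savitzky-Golay 2nd derivative.

The standard chain for this analysis is absorbance -> SNV -> SG second
derivative ("SNV + 2D").  SNV removes per-spectrum multiplicative scatter and
additive offset; the second derivative sharpens overlapping water bands and
turns each absorption peak into a negative extremum at the band centre.

Conventions (fixed here so downstream standardization agrees):

* SNV divides by the sample (n-1) standard deviation.
* The SG derivative is reported per (grid step)^2; pass ``per_nm=True`` to
  divide by step_nm^2.  Edge points come from evaluating the boundary
  window's least-squares polynomial at the edge (``mode="interp"``), so
  output length equals input length and polynomials up to the fit order are
  reproduced exactly everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra import SpectraSet, Spectrum, grids_equal, to_absorbance_set

STEPS = ("average_scans", "to_absorbance", "mean_center", "snv", "savgol2d")

#: Input kinds each step accepts.
_STEP_INPUT_KINDS = {
    "average_scans": {"intensity"},
    "to_absorbance": {"intensity"},
    "mean_center": {"absorbance", "snv", "snv2d"},
    "snv": {"absorbance"},
    "savgol2d": {"absorbance", "snv"},
}


@dataclass
class PreprocessPlan:
    """An ordered preprocessing recipe.

    The default SG filter uses a 7-point window with a 2nd-order polynomial.
    The window is a point count: with the default 3 nm grid the window spans
    about 21 nm; narrow windows are preferred because wide ones wash out
    band-level features.
    """

    steps: tuple = ("to_absorbance", "snv", "savgol2d")
    savgol_window_points: int = 7
    savgol_polyorder: int = 2
    derivative_per_nm: bool = False

    def __post_init__(self) -> None:
        self.steps = tuple(self.steps)
        for step in self.steps:
            if step not in STEPS:
                raise ValueError(f"unknown preprocessing step {step!r}")
        if self.savgol_window_points % 2 == 0:
            raise ValueError("savgol_window_points must be odd")
        if self.savgol_window_points < self.savgol_polyorder + 2:
            raise ValueError("savgol_window_points must be >= polyorder + 2")


def average_scans(scans: list[Spectrum]) -> Spectrum:
    """Elementwise mean of replicate scans of one sample (the instrument's
    reported spectrum is the average of five scans)."""
    if not scans:
        raise ValueError("need at least one scan")
    first = scans[0]
    for s in scans[1:]:
        if not grids_equal(s.grid, first.grid):
            raise ValueError("scans have mismatched grids")
        if s.kind != first.kind:
            raise ValueError("scans have mismatched kinds")
    values = np.mean([s.values for s in scans], axis=0)
    meta = {k: v for k, v in first.meta.items() if k != "scan"}
    meta["n_scans_averaged"] = len(scans)
    return Spectrum(grid=first.grid, values=values, kind=first.kind, meta=meta)


def _snv_rows(matrix: np.ndarray) -> np.ndarray:
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        row = int(np.flatnonzero(sd.ravel() == 0)[0])
        raise ValueError(f"constant spectrum (zero spread) at row {row}; cannot SNV")
    return (matrix - mean) / sd


def snv(spectrum: Spectrum) -> Spectrum:
    """Standard Normal Variate: per-spectrum (x - mean) / sd with sample
    (n-1) sd.  Output has mean 0 and sd 1 and is invariant to positive
    affine rescaling of the input."""
    if spectrum.values.size < 2:
        raise ValueError("SNV needs at least 2 points")
    values = _snv_rows(spectrum.values[None, :])[0]
    return Spectrum(grid=spectrum.grid, values=values, kind="snv", meta=dict(spectrum.meta))


def _savgol_rows(matrix: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window >= matrix.shape[1]:
        raise ValueError(
            f"window ({window}) must be smaller than the spectrum length ({matrix.shape[1]})"
        )
    return savgol_filter(matrix, window_length=window, polyorder=polyorder,
                         deriv=2, delta=1.0, axis=1, mode="interp")


def savgol2d(spectrum: Spectrum, window_points: int = 7, polyorder: int = 2,
             per_nm: bool = False) -> Spectrum:
    """Savitzky-Golay second derivative.

    Units are value per (grid step)^2 by default; ``per_nm=True`` divides by
    step_nm^2.  Input kind ``snv`` yields kind ``snv2d``.
    """
    values = _savgol_rows(spectrum.values[None, :], window_points, polyorder)[0]
    if per_nm:
        values = values / spectrum.grid.step_nm**2
    kind = "snv2d" if spectrum.kind == "snv" else spectrum.kind
    return Spectrum(grid=spectrum.grid, values=values, kind=kind, meta=dict(spectrum.meta))


def mean_center(sset: SpectraSet) -> SpectraSet:
    """Subtract the column (wavelength-wise) mean across samples."""
    if sset.n_samples < 2:
        raise ValueError("mean centering needs at least 2 samples")
    return sset.with_matrix(sset.matrix - sset.matrix.mean(axis=0, keepdims=True),
                            step="mean_center")


def average_scan_set(sset: SpectraSet) -> SpectraSet:
    """Collapse replicate-scan rows to one row per (fruit, configuration)."""
    if "scan" not in sset.sample_table.columns:
        raise ValueError("set has no 'scan' column; nothing to average")
    table = sset.sample_table
    keys = ["fruit_id", "configuration"]
    order = table[keys].drop_duplicates().reset_index(drop=True)
    rows = []
    metas = []
    for _, key in order.iterrows():
        mask = ((table["fruit_id"] == key["fruit_id"])
                & (table["configuration"] == key["configuration"])).to_numpy()
        rows.append(sset.matrix[mask].mean(axis=0))
        meta = table.loc[mask].iloc[0].drop(labels=["scan"]).to_dict()
        meta["n_scans_averaged"] = int(mask.sum())
        metas.append(meta)
    return SpectraSet(
        matrix=np.asarray(rows),
        sample_table=pd.DataFrame(metas),
        grid=sset.grid,
        kind=sset.kind,
        history=sset.history + ("average_scans",),
    )


def run_plan(sset: SpectraSet, plan: PreprocessPlan, references=None) -> SpectraSet:
    """Apply the plan's steps in order, validating kind transitions.

    ``references`` (configuration -> reference Spectrum) is required when the
    plan contains ``to_absorbance``.  An empty plan returns the input
    unchanged.  Each applied step is recorded in the set's history.
    """
    out = sset
    for step in plan.steps:
        allowed = _STEP_INPUT_KINDS[step]
        if out.kind not in allowed:
            raise ValueError(
                f"step {step!r} cannot follow kind {out.kind!r} "
                f"(expects one of {sorted(allowed)})"
            )
        if step == "average_scans":
            out = average_scan_set(out)
        elif step == "to_absorbance":
            if references is None:
                raise ValueError("to_absorbance requires per-configuration references")
            out = to_absorbance_set(out, references)
        elif step == "mean_center":
            out = mean_center(out)
        elif step == "snv":
            out = out.with_matrix(_snv_rows(out.matrix), kind="snv", step="snv")
        elif step == "savgol2d":
            values = _savgol_rows(out.matrix, plan.savgol_window_points, plan.savgol_polyorder)
            if plan.derivative_per_nm:
                values = values / out.grid.step_nm**2
            kind = "snv2d" if out.kind == "snv" else out.kind
            out = out.with_matrix(values, kind=kind, step="savgol2d")
    return out
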