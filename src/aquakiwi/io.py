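"""CSV readers/writers for spectra sets and reference scans.

Layout is a "wide" CSV: metadata columns first, then one column per
wavelength named ``wl_<zero-padded nm with one decimal>`` (e.g. ``wl_0800.0``).
Values are written at full repr precision so a write -> read round trip is
lossless and byte-deterministic for a fixed input.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .spectra import CONFIGURATIONS, SpectralGrid, SpectraSet, Spectrum

WL_PREFIX = "wl_"


def wavelength_column(nm: float) -> str:
    return f"{WL_PREFIX}{nm:06.1f}"


def _wl_columns(grid: SpectralGrid) -> list[str]:
    return [wavelength_column(w) for w in grid.wavelengths]


def write_spectra_csv(sset: SpectraSet, path: str | Path) -> Path:
    """Write a SpectraSet as wide CSV (all metadata columns, then a ``kind``
    column, then wavelength columns)."""
    path = Path(path)
    frame = sset.sample_table.copy()
    frame["kind"] = sset.kind
    wide = pd.DataFrame(sset.matrix, columns=_wl_columns(sset.grid))
    pd.concat([frame, wide], axis=1).to_csv(path, index=False)
    return path


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read a wide spectra CSV, validating the wavelength grid and metadata.

    Rejects unsorted or non-uniform wavelength columns, invalid configuration
    labels (naming the offending row) and duplicate (fruit, configuration,
    scan) rows.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    wl_cols = [c for c in frame.columns if c.startswith(WL_PREFIX)]
    if not wl_cols:
        raise ValueError(f"{path}: no wavelength columns (prefix {WL_PREFIX!r}) found")
    try:
        wls = np.array([float(c[len(WL_PREFIX):]) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed wavelength column name") from exc
    if np.any(np.diff(wls) <= 0):
        raise ValueError(f"{path}: wavelength columns are not sorted strictly increasing")
    grid = SpectralGrid.from_wavelengths(wls)

    meta_cols = [c for c in frame.columns if not c.startswith(WL_PREFIX)]
    meta = frame[meta_cols].copy()
    kind = "intensity"
    if "kind" in meta.columns:
        kinds = meta.pop("kind").unique()
        if len(kinds) != 1:
            raise ValueError(f"{path}: mixed spectrum kinds {sorted(kinds)} in one file")
        kind = str(kinds[0])

    if "configuration" in meta.columns:
        bad = ~meta["configuration"].isin(CONFIGURATIONS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: row {row} has invalid configuration "
                f"{meta['configuration'].iloc[row]!r}"
            )
    key_cols = [c for c in ("fruit_id", "configuration", "scan") if c in meta.columns]
    if key_cols and meta.duplicated(subset=key_cols).any():
        dup = meta[meta.duplicated(subset=key_cols)].iloc[0]
        raise ValueError(
            f"{path}: duplicate sample key {tuple(dup[k] for k in key_cols)}"
        )

    return SpectraSet(
        matrix=frame[wl_cols].to_numpy(dtype=float),
        sample_table=meta,
        grid=grid,
        kind=kind,
    )


def write_references_csv(references: Mapping[str, Spectrum], path: str | Path) -> Path:
    """One row per configuration reference scan, same wide layout."""
    path = Path(path)
    rows = []
    grid = None
    for cfg in CONFIGURATIONS:
        if cfg not in references:
            continue
        ref = references[cfg]
        grid = ref.grid
        rows.append({"configuration": cfg, **dict(zip(_wl_columns(grid), ref.values))})
    if grid is None:
        raise ValueError("no reference scans to write")
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_references_csv(path: str | Path) -> dict[str, Spectrum]:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    wl_cols = [c for c in frame.columns if c.startswith(WL_PREFIX)]
    grid = SpectralGrid.from_wavelengths(
        np.array([float(c[len(WL_PREFIX):]) for c in wl_cols])
    )
    refs: dict[str, Spectrum] = {}
    for _, row in frame.iterrows():
        cfg = str(row["configuration"])
        if cfg not in CONFIGURATIONS:
            raise ValueError(f"{path}: unknown configuration {cfg!r}")
        refs[cfg] = Spectrum(
            grid=grid,
            values=row[wl_cols].to_numpy(dtype=float),
            kind="intensity",
            meta={"configuration": cfg, "role": "reference"},
        )
    return refs
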