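"""PCA of preprocessed spectra, with deterministic sign handling and
loading-extremum extraction for wavelength identification.

PCA here serves two purposes: score plots separate the measurement
configurations (polarized vs unpolarized detection cluster apart on PC1),
and loading extrema in the 900-1020 nm water-band window are candidate
activated wavelengths for the aquaphotomics analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .spectra import SpectralGrid, SpectraSet


@dataclass
class PcaModel:
    """Fitted PCA: unit-norm loadings (components x wavelengths), scores
    (samples x components), explained variance in percent of total."""

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_pct: np.ndarray
    mean: np.ndarray
    grid: SpectralGrid
    n_components: int

    def reconstruct(self) -> np.ndarray:
        """Back-project scores through the loadings (adds the mean back)."""
        return self.scores @ self.loadings + self.mean[None, :]


def fit_pca(data: SpectraSet | np.ndarray, n_components: int = 3,
            grid: SpectralGrid | None = None) -> PcaModel:
    """Fit PCA on a (preprocessed) spectra set via SVD of the centered matrix.

    Centering happens inside the fit.  The sign of each component is fixed
    deterministically: the largest-|value| element of each loading is made
    positive (PCA is otherwise sign-ambiguous between runs/libraries).
    """
    if isinstance(data, SpectraSet):
        matrix = data.matrix
        grid = data.grid
    else:
        matrix = np.asarray(data, dtype=float)
        if grid is None:
            grid = SpectralGrid.from_wavelengths(np.arange(matrix.shape[1], dtype=float) + 1.0)
    n, p = matrix.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, wavelengths)="
            f"{min(n - 1, p)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    loadings = pca.components_.copy()
    # deterministic sign: largest-magnitude loading element positive
    for k in range(loadings.shape[0]):
        idx = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, idx] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    return PcaModel(
        loadings=loadings,
        scores=scores,
        explained_variance_pct=pca.explained_variance_ratio_ * 100.0,
        mean=pca.mean_,
        grid=grid,
        n_components=n_components,
    )


def find_local_extrema(values: np.ndarray) -> list[tuple[int, float, int]]:
    """Strict interior local extrema of a 1-D array.

    Returns (index, value, sign) with sign +1 for maxima, -1 for minima.
    Plateaus count once, at their leftmost point, and must be strictly above
    (below) both neighbouring distinct values; runs touching the array ends
    are not extrema.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        return []
    # compress equal-value runs
    starts = [0]
    for i in range(1, y.size):
        if y[i] != y[starts[-1]]:
            starts.append(i)
    out: list[tuple[int, float, int]] = []
    for j in range(1, len(starts) - 1):
        i = starts[j]
        prev_v = y[starts[j - 1]]
        next_v = y[starts[j + 1]]
        if y[i] > prev_v and y[i] > next_v:
            out.append((i, float(y[i]), +1))
        elif y[i] < prev_v and y[i] < next_v:
            out.append((i, float(y[i]), -1))
    return out


def curve_extrema(grid: SpectralGrid, values: np.ndarray,
                  window_nm: tuple[float, float]) -> list[tuple[float, float, int]]:
    """Local extrema of a spectrum-like curve restricted to a wavelength
    window, as (wavelength, value, sign) sorted by |value| descending
    (ties: lower wavelength first)."""
    lo, hi = window_nm
    wl = grid.wavelengths
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(f"window {window_nm} lies outside the grid [{wl[0]}, {wl[-1]}]")
    mask = (wl >= lo) & (wl <= hi)
    idx = np.flatnonzero(mask)
    sub = np.asarray(values, dtype=float)[idx]
    ext = find_local_extrema(sub)
    res = [(float(wl[idx[i]]), v, s) for i, v, s in ext]
    res.sort(key=lambda t: (-abs(t[1]), t[0]))
    return res


def loading_extrema(model: PcaModel, component: int,
                    window_nm: tuple[float, float] = (900.0, 1020.0)
                    ) -> list[tuple[float, float, int]]:
    """Extrema of a PC loading (``component`` is 1-based: 1 = PC1) inside the
    window, sorted by absolute magnitude descending."""
    if not 1 <= component <= model.n_components:
        raise ValueError(f"component must be in 1..{model.n_components}")
    return curve_extrema(model.grid, model.loadings[component - 1], window_nm)
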