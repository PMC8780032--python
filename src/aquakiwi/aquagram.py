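"""Aquagram computation and radar-chart rendering.

An aquagram displays, per WAMACS band, the group-mean of a relative SNV
standardization of preprocessed absorbance at the activated wavelengths:

    A'(lambda) = (A(lambda) - mu_lambda) / sigma_lambda

where mu and sigma are the mean and sample (n-1) standard deviation of the
preprocessed absorbance over ALL samples of ALL configurations at that
wavelength.  Because the pooled standardization is shared, profiles for
different configurations (and SSC groups within configurations) are directly
comparable on one chart.

Sign convention: SNV+2D absorbance is negative at band centres (second
derivative of a peak), so with the default ``negate_2d=True`` the
standardized values are negated before display so that greater absorbance
plots outward on the radar chart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import CONFIGURATIONS, SpectraSet
from .wamacs import SSC_GROUPS, ActivatedWavelengthSet, ssc_group_labels


@dataclass
class AquagramInput:
    """Samples x selected-wavelengths matrix plus the sample table.

    Columns are ordered by band index C1 -> C12.  ``negate`` records whether
    standardized values will be sign-flipped for display (appropriate when
    the input matrix holds second-derivative absorbance).
    """

    matrix: np.ndarray
    sample_table: pd.DataFrame
    band_ids: list[str]
    wavelengths: list[float]
    negate: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.band_ids):
            raise ValueError("matrix must be samples x len(band_ids)")
        if len(self.wavelengths) != len(self.band_ids):
            raise ValueError("wavelengths and band_ids must align")
        if len(self.sample_table) != self.matrix.shape[0]:
            raise ValueError("sample_table rows must match matrix rows")


@dataclass
class AquagramProfile:
    """Ordered standardized band values for one display group."""

    group_label: str
    band_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.band_ids):
            raise ValueError("values must align with band_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")


def aquagram_input(sset: SpectraSet, activated: ActivatedWavelengthSet,
                   negate_2d: bool = True) -> AquagramInput:
    """Extract the activated-wavelength columns (nearest grid point per
    band) from a preprocessed spectra set."""
    idx = [sset.grid.index_nearest(wl) for wl in activated.wavelengths]
    negate = negate_2d and sset.kind == "snv2d"
    return AquagramInput(
        matrix=sset.matrix[:, idx],
        sample_table=sset.sample_table.copy(),
        band_ids=activated.band_ids,
        wavelengths=[float(sset.grid.wavelengths[i]) for i in idx],
        negate=negate,
    )


def relative_snv(inp: AquagramInput) -> np.ndarray:
    """Column-wise pooled standardization (mean 0, sample sd 1 over all
    samples of all configurations); sign-flipped when ``inp.negate``."""
    if inp.matrix.shape[0] < 2:
        raise ValueError("relative SNV needs at least 2 samples")
    mu = inp.matrix.mean(axis=0)
    sigma = inp.matrix.std(axis=0, ddof=1)
    if np.any(sigma == 0):
        j = int(np.flatnonzero(sigma == 0)[0])
        raise ValueError(
            f"zero variance at {inp.wavelengths[j]} nm (band {inp.band_ids[j]}); "
            "cannot standardize"
        )
    std = (inp.matrix - mu) / sigma
    return -std if inp.negate else std


def aquagram_by_configuration(std_matrix: np.ndarray, sample_table: pd.DataFrame,
                              band_ids: list[str]) -> list[AquagramProfile]:
    """Mean standardized profile per measurement configuration (UU, UP, PU,
    PP).  All four configurations must be present; with equal group sizes the
    four profiles average to zero at every band (pooled standardization)."""
    profiles = []
    cfgs = sample_table["configuration"]
    for cfg in CONFIGURATIONS:
        mask = (cfgs == cfg).to_numpy()
        if not mask.any():
            raise ValueError(f"configuration {cfg!r} has no samples")
        profiles.append(AquagramProfile(
            group_label=cfg,
            band_ids=list(band_ids),
            values=std_matrix[mask].mean(axis=0),
        ))
    return profiles


def aquagram_by_ssc_group(std_matrix: np.ndarray, sample_table: pd.DataFrame,
                          band_ids: list[str], configuration: str
                          ) -> list[AquagramProfile]:
    """Mean standardized profile per SSC group (Low, Medium, High) within one
    configuration.  Standardization stays pooled across the full sample set
    so panels are comparable across configurations."""
    mask_cfg = (sample_table["configuration"] == configuration).to_numpy()
    if not mask_cfg.any():
        raise ValueError(f"configuration {configuration!r} has no samples")
    sub_table = sample_table.loc[mask_cfg]
    if "ssc_group" in sub_table.columns:
        groups = sub_table["ssc_group"]
    else:
        groups = ssc_group_labels(sub_table["ssc"])
    sub = std_matrix[mask_cfg]
    profiles = []
    for g in SSC_GROUPS:
        mask_g = (groups == g).to_numpy()
        if not mask_g.any():
            raise ValueError(
                f"SSC group {g!r} is empty in configuration {configuration!r}")
        profiles.append(AquagramProfile(
            group_label=f"{configuration}:{g}",
            band_ids=list(band_ids),
            values=sub[mask_g].mean(axis=0),
        ))
    return profiles


def profiles_to_frame(profiles: list[AquagramProfile], negate: bool | None = None
                      ) -> pd.DataFrame:
    """Long-format table (group, band_id, value); optionally records the
    display sign convention in a ``negated_2d`` column."""
    rows = []
    for p in profiles:
        for b, v in zip(p.band_ids, p.values):
            row = {"group": p.group_label, "band_id": b, "value": v}
            if negate is not None:
                row["negated_2d"] = negate
            rows.append(row)
    return pd.DataFrame(rows)


def render_aquagram(profiles: list[AquagramProfile], path: str | Path,
                    title: str | None = None) -> Path:
    """Render profiles as a closed radar (spider) chart, axes C1..C12
    clockwise from the top.  Output is deterministic for fixed input."""
    import matplotlib.pyplot as plt

    if not profiles:
        raise ValueError("no profiles to render")
    band_ids = profiles[0].band_ids
    if len(band_ids) < 3:
        raise ValueError("a radar chart needs at least 3 bands (axes)")
    for p in profiles:
        if p.band_ids != band_ids:
            raise ValueError("all profiles must share the same bands")

    n = len(band_ids)
    # clockwise from 12 o'clock
    theta = np.pi / 2 - 2 * np.pi * np.arange(n) / n
    theta_closed = np.concatenate([theta, theta[:1]])

    fig = plt.figure(figsize=(6.4, 5.6))
    ax = fig.add_subplot(111, projection="polar")
    for p in profiles:
        vals = np.concatenate([p.values, p.values[:1]])
        ax.plot(theta_closed, vals, marker="o", markersize=3, linewidth=1.4,
                label=p.group_label)
    ax.set_xticks(theta)
    ax.set_xticklabels(band_ids)
    ax.set_title(title or "Aquagram")
    ax.legend(loc="upper right", bbox_to_anchor=(1.28, 1.1), fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120, format=path.suffix.lstrip(".") or "png",
                metadata={"Software": None})
    plt.close(fig)
    return path
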