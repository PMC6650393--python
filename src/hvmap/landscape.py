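"""Density and free-energy landscapes over the (dE, δdF) angle plane.

Pooled HVM points are turned into a 2D density by a linear-binned Gaussian
product-kernel estimate (the classic binned-KDE algorithm), converted to a
free-energy surface by minus-log scaling of the relative density, and
summarised by per-run density peaks and iso-free-energy contour polylines.

The free energy is unitless: F = −ln(density / max density), so the global
density mode sits exactly at F = 0 and one unit of F is an e-fold drop in
sampled density.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import contourpy
import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .mapping import HVMSeries

__all__ = [
    "LandscapeGrid",
    "PeakPosition",
    "binned_kde2d",
    "normal_reference_bandwidth",
    "to_free_energy",
    "peak_position",
    "pool_runs",
    "contour_polylines",
    "write_grid_tsv",
    "write_peaks_tsv",
]

#: free energy assigned to cells with exactly zero density (keeps grids finite)
ZERO_DENSITY_CAP = 20.0


@dataclass
class LandscapeGrid:
    """A regular grid over (dE, δdF) holding density or free energy.

    ``values[i, j]`` corresponds to ``(dE_grid[i], dF_grid[j])``.  Density
    grids integrate to 1 (trapezoid on the regular grid reduces to
    sum × cell area up to the boundary cells; the sum-based convention is
    used and enforced).
    """

    dE_grid: np.ndarray
    dF_grid: np.ndarray
    values: np.ndarray
    bandwidths: tuple[float, float]
    kind: str  # "density" | "free_energy"

    def cell_area(self) -> float:
        return float(
            (self.dE_grid[1] - self.dE_grid[0]) * (self.dF_grid[1] - self.dF_grid[0])
        )


@dataclass(frozen=True)
class PeakPosition:
    """Grid node of maximum density for one run."""

    run_id: str
    dE_phi: float
    dF_delta: float


def normal_reference_bandwidth(x: np.ndarray) -> float:
    """Per-axis normal-reference bandwidth for a 2D product kernel.

    h = sd · n^(−1/6), the d=2 normal-reference rate n^(−1/(d+4)).
    """
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return sd * len(x) ** (-1.0 / 6.0)


def _linear_bin(x: np.ndarray, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fractional bin indices and complementary weights for linear binning."""
    step = grid[1] - grid[0]
    pos = (x - grid[0]) / step
    i0 = np.clip(np.floor(pos).astype(int), 0, len(grid) - 2)
    w1 = np.clip(pos - i0, 0.0, 1.0)
    return i0, 1.0 - w1, w1


def binned_kde2d(
    points: np.ndarray,
    bandwidths: tuple[float, float] | None = None,
    gridsize: tuple[int, int] = (256, 256),
    pad_bandwidths: float = 3.0,
) -> LandscapeGrid:
    """Linear-binned Gaussian product-kernel density estimate on a grid.

    The grid spans the data range padded by ``pad_bandwidths`` bandwidths
    per axis.  Default bandwidths follow the per-axis normal-reference rule;
    the returned density is renormalised so that sum × cell area = 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (dE, dF)")
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points for a density estimate")
    if bandwidths is None:
        bandwidths = (
            normal_reference_bandwidth(pts[:, 0]),
            normal_reference_bandwidth(pts[:, 1]),
        )
    bw = (float(bandwidths[0]), float(bandwidths[1]))
    if min(bw) <= 0:
        raise ValueError(
            "non-positive bandwidth (all points identical on one axis?); "
            "pass explicit bandwidths"
        )
    nx, ny = gridsize
    gx = np.linspace(pts[:, 0].min() - pad_bandwidths * bw[0],
                     pts[:, 0].max() + pad_bandwidths * bw[0], nx)
    gy = np.linspace(pts[:, 1].min() - pad_bandwidths * bw[1],
                     pts[:, 1].max() + pad_bandwidths * bw[1], ny)

    # linear binning: each point spreads bilinear weights onto its 4 nodes
    ix, wx0, wx1 = _linear_bin(pts[:, 0], gx)
    iy, wy0, wy1 = _linear_bin(pts[:, 1], gy)
    counts = np.zeros((nx, ny))
    np.add.at(counts, (ix, iy), wx0 * wy0)
    np.add.at(counts, (ix, iy + 1), wx0 * wy1)
    np.add.at(counts, (ix + 1, iy), wx1 * wy0)
    np.add.at(counts, (ix + 1, iy + 1), wx1 * wy1)

    # separable Gaussian kernel sampled on grid offsets
    dx, dy = gx[1] - gx[0], gy[1] - gy[0]
    kx = _gauss_kernel(dx, bw[0], nx)
    ky = _gauss_kernel(dy, bw[1], ny)
    dens = fftconvolve(counts, np.outer(kx, ky), mode="same")
    dens = np.clip(dens, 0.0, None)
    total = dens.sum() * dx * dy
    if total <= 0:
        raise ValueError("degenerate density (zero total mass)")
    dens /= total
    return LandscapeGrid(dE_grid=gx, dF_grid=gy, values=dens,
                         bandwidths=bw, kind="density")


def _gauss_kernel(step: float, bw: float, n: int) -> np.ndarray:
    """1D Gaussian kernel sampled at grid offsets, truncated at 6 bandwidths."""
    half = min(int(np.ceil(6.0 * bw / step)), n - 1)
    u = np.arange(-half, half + 1) * step
    k = np.exp(-0.5 * (u / bw) ** 2)
    return k / (bw * np.sqrt(2.0 * np.pi))


def to_free_energy(density: LandscapeGrid) -> LandscapeGrid:
    """Minus-log scaling of relative density: F = −ln(d / d_max).

    The minimum is exactly 0 at the density mode; values are capped at
    ``ZERO_DENSITY_CAP`` (zero-density cells would otherwise be infinite,
    and the global cap keeps the surface monotone in density throughout).
    """
    if density.kind != "density":
        raise ValueError("input grid must be a density")
    d = density.values
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("all-zero density grid")
    with np.errstate(divide="ignore"):
        F = np.minimum(-np.log(d / dmax), ZERO_DENSITY_CAP) + 0.0  # kill -0.0
    return LandscapeGrid(
        dE_grid=density.dE_grid,
        dF_grid=density.dF_grid,
        values=F,
        bandwidths=density.bandwidths,
        kind="free_energy",
    )


def peak_position(grid: LandscapeGrid, run_id: str = "") -> PeakPosition:
    """Grid node of maximum density; ties break to smallest dE, then dF."""
    if grid.kind != "density":
        raise ValueError("peak detection runs on density grids")
    v = grid.values
    mx = v.max()
    ii, jj = np.nonzero(v == mx)
    order = np.lexsort((jj, ii))  # smallest dE index first, then dF
    i, j = int(ii[order[0]]), int(jj[order[0]])
    return PeakPosition(run_id=run_id, dE_phi=float(grid.dE_grid[i]),
                        dF_delta=float(grid.dF_grid[j]))


def pool_runs(
    series_list: Sequence[HVMSeries],
    bandwidths: tuple[float, float] | None = None,
    gridsize: tuple[int, int] = (256, 256),
) -> tuple[LandscapeGrid, list[PeakPosition]]:
    """Pooled free-energy surface plus per-run density peaks.

    All runs must map the same lobe.  The pooled surface is one KDE over the
    concatenated points (as when several trajectories are summed into one
    ensemble); each run additionally gets its own KDE and peak.
    """
    if not series_list:
        raise ValueError("need at least one series")
    lobes = {s.lobe for s in series_list}
    if len(lobes) > 1:
        raise ValueError(f"series mix different lobes: {sorted(lobes)}")
    pooled_pts = np.vstack([s.angles() for s in series_list])
    pooled = to_free_energy(binned_kde2d(pooled_pts, bandwidths, gridsize))
    peaks = [
        peak_position(binned_kde2d(s.angles(), bandwidths, gridsize), s.run_id)
        for s in series_list
    ]
    return pooled, peaks


def contour_polylines(
    grid: LandscapeGrid, levels: Sequence[float] | None = None
) -> dict[float, list[np.ndarray]]:
    """Iso-value contour polylines, one list of (m, 2) arrays per level.

    Default levels for free-energy grids are 1, 2, 3, … up to the largest
    finite value below the zero-density cap.
    """
    if levels is None:
        if grid.kind != "free_energy":
            raise ValueError("default levels exist only for free-energy grids")
        top = grid.values[grid.values < ZERO_DENSITY_CAP].max(initial=0.0)
        levels = list(range(1, int(np.floor(top)) + 1))
    gen = contourpy.contour_generator(
        x=grid.dF_grid, y=grid.dE_grid, z=grid.values,
        line_type=contourpy.LineType.Separate,
    )
    out: dict[float, list[np.ndarray]] = {}
    for lv in levels:
        # contourpy uses (x=columns, y=rows); swap back to (dE, dF) order
        out[float(lv)] = [line[:, ::-1] for line in gen.lines(float(lv))]
    return out


# ---------------------------------------------------------------------------
# TSV export

def write_grid_tsv(grid: LandscapeGrid, path: str | Path) -> None:
    """Long-format export: one row per grid node (dE, dF, value)."""
    ee, ff = np.meshgrid(grid.dE_grid, grid.dF_grid, indexing="ij")
    pd.DataFrame(
        {"dE_phi": ee.ravel(), "dF_delta": ff.ravel(), "value": grid.values.ravel()}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_peaks_tsv(peaks: Iterable[PeakPosition], path: str | Path) -> None:
    peaks = list(peaks)
    pd.DataFrame(
        {
            "run_id": [p.run_id for p in peaks],
            "dE_phi": [round(p.dE_phi, 2) for p in peaks],
            "dF_delta": [round(p.dF_delta, 2) for p in peaks],
        }
    ).to_csv(path, sep="\t", index=False)
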