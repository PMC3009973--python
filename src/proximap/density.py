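"""Protein-density grids over a 2D map projection.

A :class:`DensityGrid` rasterises a subset of embedded proteins onto a
regular grid in two modes:

* ``count`` — each protein falls in exactly one cell; cell values are
  protein counts (proteins per cell), and their sum equals the subset size;
* ``kde`` — an isotropic Gaussian kernel density estimate evaluated at the
  cell centres (a probability density: integrates to ~1 when the grid pads
  the data adequately).

Grids default to the bounding box of the FULL embedding (padded 5%), so a
background grid and a condition-cluster overlay share coordinates and can
be compared cell-by-cell — the overlay construction used for locating
condition clusters on a map projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage

from .embedding import Embedding2D


@dataclass
class DensityGrid:
    """Regular 2D grid of protein density over an embedding's extent.

    ``values[ix, iy]`` covers the cell with x in ``[x_edges[ix], x_edges[ix+1])``
    and y likewise (the closing edge of the final cell is closed, so
    boundary points are binned).  ``mode`` is ``"count"`` or ``"kde"``.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray
    mode: str
    bandwidth: float | None = None
    n_points: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def origin(self) -> tuple[float, float]:
        return float(self.x_edges[0]), float(self.y_edges[0])

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            float(self.x_edges[0]),
            float(self.x_edges[-1]),
            float(self.y_edges[0]),
            float(self.y_edges[-1]),
        )

    @property
    def resolution(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = (self.x_edges[:-1] + self.x_edges[1:]) / 2.0
        cy = (self.y_edges[:-1] + self.y_edges[1:]) / 2.0
        return cx, cy

    def integral(self) -> float:
        """Trapezoid-free Riemann integral (cell value x cell area)."""
        dx = np.diff(self.x_edges)[:, None]
        dy = np.diff(self.y_edges)[None, :]
        return float((self.values * dx * dy).sum())


def scott_bandwidth(points: np.ndarray) -> float:
    """Scott's rule for an isotropic 2D Gaussian kernel:
    h = n^(-1/6) * sqrt((var_x + var_y) / 2)."""
    n = len(points)
    if n < 2:
        return 1.0
    var = points.var(axis=0, ddof=1)
    scale = np.sqrt(var.mean())
    return float(n ** (-1.0 / 6.0) * (scale if scale > 0 else 1.0))


def _default_extent(embedding: Embedding2D, pad_frac: float = 0.05):
    xy = embedding.array()
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return lo - pad_frac * span, hi + pad_frac * span


def density_grid(
    embedding: Embedding2D,
    subset: Iterable[str] | None = None,
    resolution: tuple[int, int] = (256, 256),
    mode: str = "count",
    bandwidth: float | None = None,
    extent: tuple[float, float, float, float] | None = None,
) -> DensityGrid:
    """Density of the embedded ``subset`` on a regular grid.

    ``subset=None`` means all embedded proteins.  The grid extent defaults
    to the full embedding's bounding box padded by 5%, regardless of the
    subset, so grids of different subsets are overlayable.  In ``kde`` mode
    the bandwidth defaults to Scott's rule on the subset.
    """
    nx_, ny_ = resolution
    if nx_ < 2 or ny_ < 2:
        raise ValueError("resolution must be at least 2x2")
    ids = set(embedding.ids) if subset is None else set(subset) & set(embedding.ids)
    if not ids:
        raise ValueError("empty effective subset: no embedded proteins selected")
    pts = embedding.array(sorted(ids))
    # order by position, not by id, so grids are invariant to relabeling
    # (floating-point summation order matters for bit-reproducibility)
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]

    if extent is None:
        lo, hi = _default_extent(embedding)
    else:
        lo = np.array([extent[0], extent[2]], float)
        hi = np.array([extent[1], extent[3]], float)
    x_edges = np.linspace(lo[0], hi[0], nx_ + 1)
    y_edges = np.linspace(lo[1], hi[1], ny_ + 1)

    if mode == "count":
        values, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, y_edges])
        bw = None
    elif mode == "kde":
        bw = scott_bandwidth(pts) if bandwidth is None else float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be positive in kde mode")
        values = _gaussian_kde_grid(pts, x_edges, y_edges, bw)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return DensityGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        values=values,
        mode=mode,
        bandwidth=bw,
        n_points=len(pts),
        meta={"resolution": (nx_, ny_)},
    )


def _gaussian_kde_grid(
    pts: np.ndarray, x_edges: np.ndarray, y_edges: np.ndarray, h: float
) -> np.ndarray:
    """Isotropic-Gaussian kernel sum at cell centres, chunked over cells.

    density(c) = 1/(n 2 pi h^2) * sum_i exp(-|c - p_i|^2 / (2 h^2))
    """
    cx = (x_edges[:-1] + x_edges[1:]) / 2.0
    cy = (y_edges[:-1] + y_edges[1:]) / 2.0
    n = len(pts)
    norm = 1.0 / (n * 2.0 * np.pi * h * h)
    out = np.empty((len(cx), len(cy)))
    inv2h2 = 1.0 / (2.0 * h * h)
    # chunk over x-rows of cells to bound memory at n_cells_per_chunk * n points
    chunk = max(1, int(2_000_000 / max(n, 1)))
    for start in range(0, len(cx), chunk):
        gx = cx[start : start + chunk]
        dx2 = (gx[:, None] - pts[None, :, 0]) ** 2  # (chunk, n)
        dy2 = (cy[:, None] - pts[None, :, 1]) ** 2  # (ny, n)
        # sum over points of exp(-(dx2 + dy2) * inv2h2) for every (x, y) cell
        ex = np.exp(-dx2 * inv2h2)
        ey = np.exp(-dy2 * inv2h2)
        out[start : start + chunk, :] = norm * (ex @ ey.T)
    return out


def cluster_overlay(
    embedding: Embedding2D,
    background: Iterable[str],
    overlay: Iterable[str],
    resolution: tuple[int, int] = (256, 256),
    mode: str = "count",
    bandwidth: float | None = None,
) -> tuple[DensityGrid, DensityGrid]:
    """Background and overlay density grids on the SAME extent/resolution.

    The standard rendering input for locating a condition cluster on the
    map: the background grid shows the whole map's density, the overlay the
    condition's effectors.
    """
    lo, hi = _default_extent(embedding)
    extent = (float(lo[0]), float(hi[0]), float(lo[1]), float(hi[1]))
    bg = density_grid(embedding, background, resolution, mode, bandwidth, extent)
    ov = density_grid(embedding, overlay, resolution, mode, bandwidth, extent)
    return bg, ov


@dataclass
class PeakRegion:
    """A 4-connected run of high-density cells."""

    cells: list[tuple[int, int]]
    mass: float

    @property
    def top_left(self) -> tuple[int, int]:
        return min(self.cells)


def peak_regions(grid: DensityGrid, quantile: float = 0.9) -> list[PeakRegion]:
    """Connected regions of cells at or above a density quantile.

    The threshold is the given quantile of the POSITIVE cell values;
    regions are 4-connected components, sorted by total contained mass
    (descending), ties broken by top-left cell index.  An all-zero grid
    yields an empty list.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be strictly between 0 and 1")
    positive = grid.values[grid.values > 0]
    if positive.size == 0:
        return []
    threshold = float(np.quantile(positive, quantile))
    mask = grid.values >= threshold
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n_regions = ndimage.label(mask, structure=structure)
    regions = []
    for lab in range(1, n_regions + 1):
        idx = np.argwhere(labels == lab)
        cells = [(int(i), int(j)) for i, j in idx]
        mass = float(grid.values[labels == lab].sum())
        regions.append(PeakRegion(cells=cells, mass=mass))
    regions.sort(key=lambda r: (-r.mass, r.top_left))
    return regions


def regions_overlap(a: PeakRegion, b: PeakRegion) -> bool:
    return bool(set(a.cells) & set(b.cells))


def render_overlay(background: DensityGrid, overlay: DensityGrid, path: str) -> None:
    """Minimal figure: background density in grey, overlay in a warm map.

    Purely cosmetic; every analysis operates on the numeric grids.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ext = background.extent
    ax.imshow(background.values.T, origin="lower", extent=ext, cmap="Greys", aspect="auto")
    ov = np.ma.masked_where(overlay.values.T <= 0, overlay.values.T)
    ax.imshow(ov, origin="lower", extent=ext, cmap="hot", alpha=0.7, aspect="auto")
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    fig.savefig(path, dpi=120)
    plt.close(fig)
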