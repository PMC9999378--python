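"""Transverse-plane OI heatmaps, five-region partition and region statistics.

Element OI values are projected onto the plane of the growth plate along
its normal, interpolated to a square grid, and split into five regions:
a central disc (diameter = 50% of the grid width) and four sectors
(anterior / posterior / medial / lateral) separated by the square's
diagonals.  Left femurs are mapped with a side-aware lateral axis so maps
of both sides share one anatomical convention (anterior up, lateral
right); group reference maps average cellwise over femurs wherever more
than half of the group has valid data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import griddata

from gpfem._util import unit

REGIONS = ("anterior", "center", "lateral", "medial", "posterior")


@dataclass
class OIHeatmap:
    grid: np.ndarray  # (G, G) month^-1, NaN where invalid
    valid_mask: np.ndarray  # (G, G) bool
    extent: tuple  # (xmin, xmax, ymin, ymax) mm in the projection plane
    side: str = "right"
    mirrored: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.grid[self.valid_mask]


def projection_axes(frame: dict, normal=(0.0, 0.0, 1.0)):
    """In-plane axes (lateral -> +x of the grid, anterior -> +y).

    Using the side-aware anatomical lateral direction mirrors left femurs
    into the right-femur convention automatically.
    """
    n = unit(np.asarray(normal, float))
    ant = np.asarray(frame["anterior"], float)
    lat = np.asarray(frame["lateral"], float)
    u = lat - np.dot(lat, n) * n
    if np.linalg.norm(u) < 1e-9:
        raise ValueError("lateral axis is parallel to the plate normal")
    u = unit(u)
    v = ant - np.dot(ant, n) * n - np.dot(ant, u) * u
    if np.linalg.norm(v) < 1e-9:
        v = np.cross(n, u)
    v = unit(v)
    return u, v


def project_to_grid(oi_field, frame: dict, grid_size: int = 100, side: str = "right",
                    normal=(0.0, 0.0, 1.0)) -> OIHeatmap:
    """Interpolate element OI values onto a square grid in the plate plane.

    Linear barycentric interpolation inside the convex hull of the
    projected element centroids; cells outside are invalid (NaN).
    """
    pts = np.asarray(oi_field.centroids, float)
    vals = np.asarray(oi_field.oi, float)
    if len(pts) < 3:
        raise ValueError("need at least 3 element centroids")
    u, v = projection_axes(frame, normal)
    x = pts @ u
    y = pts @ v
    if np.linalg.matrix_rank(np.column_stack([x - x.mean(), y - y.mean()])) < 2:
        raise ValueError("projected centroids are collinear")
    cx, cy = 0.5 * (x.min() + x.max()), 0.5 * (y.min() + y.max())
    half = 0.5 * max(x.max() - x.min(), y.max() - y.min())
    g = np.linspace(-half, half, grid_size)
    GX, GY = np.meshgrid(cx + g, cy + g, indexing="xy")
    grid = griddata((x, y), vals, (GX, GY), method="linear")
    mask = np.isfinite(grid)
    return OIHeatmap(
        grid=grid,
        valid_mask=mask,
        extent=(cx - half, cx + half, cy - half, cy + half),
        side=side,
        mirrored=(side == "left"),
        meta=dict(n_elements=len(pts)),
    )


def partition_regions(grid_size: int) -> np.ndarray:
    """Region label map: center disc (diameter 50% of the width) plus four
    diagonal sectors; +x lateral, +y anterior.  Returns (G, G) strings."""
    if grid_size < 4:
        raise ValueError("grid_size must be >= 4")
    c = (grid_size - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(grid_size), np.arange(grid_size), indexing="ij")
    # with meshgrid(indexing='xy') grids, rows (axis 0) run along y
    dy = ii - c
    dx = jj - c
    labels = np.empty((grid_size, grid_size), dtype="U9")
    r = np.hypot(dx, dy)
    labels[:] = ""
    center = r <= 0.25 * grid_size
    lat = (np.abs(dx) >= np.abs(dy)) & (dx > 0)
    med = (np.abs(dx) >= np.abs(dy)) & (dx < 0)
    ant = (np.abs(dy) > np.abs(dx)) & (dy > 0)
    post = (np.abs(dy) > np.abs(dx)) & (dy < 0)
    labels[lat] = "lateral"
    labels[med] = "medial"
    labels[ant] = "anterior"
    labels[post] = "posterior"
    labels[(dx == 0) & (dy == 0)] = "lateral"  # exact midpoint (odd grids)
    labels[center] = "center"
    return labels


@dataclass
class RegionStats:
    region_means: dict
    normalized_means: dict
    argmax_region: str
    argmin_region: str
    oi_mean: float
    oi_median: float
    oi_range: float
    missing_regions: tuple = ()


def region_stats(heatmap: OIHeatmap, labels: np.ndarray | None = None) -> RegionStats:
    """Per-region means, range-normalized means and extreme regions.

    Normalized mean = (region mean - map min) / (map max - map min).
    Regions without valid cells are reported missing and excluded from the
    argmax/argmin; ties break alphabetically.
    """
    if labels is None:
        labels = partition_regions(heatmap.grid.shape[0])
    if labels.shape != heatmap.grid.shape:
        raise ValueError("label map does not match the heatmap grid")
    vals = heatmap.values
    if vals.size == 0:
        raise ValueError("heatmap has no valid cells")
    vmin, vmax = float(vals.min()), float(vals.max())
    span = vmax - vmin
    means, norm = {}, {}
    missing = []
    for region in REGIONS:
        m = (labels == region) & heatmap.valid_mask
        if not m.any():
            missing.append(region)
            continue
        mu = float(heatmap.grid[m].mean())
        means[region] = mu
        norm[region] = float((mu - vmin) / span) if span > 0 else 0.0
    if not means:
        raise ValueError("no region has valid cells")
    argmax = min(r for r in means if means[r] == max(means.values()))
    argmin = min(r for r in means if means[r] == min(means.values()))
    return RegionStats(
        region_means=means,
        normalized_means=norm,
        argmax_region=argmax,
        argmin_region=argmin,
        oi_mean=float(vals.mean()),
        oi_median=float(np.median(vals)),
        oi_range=span,
        missing_regions=tuple(missing),
    )


def reference_heatmap(heatmaps: list, group_n: int | None = None) -> OIHeatmap:
    """Cellwise group mean where strictly more than half the femurs have data.

    ``group_n`` defaults to the number of maps given.
    """
    if len(heatmaps) < 2:
        raise ValueError("need at least two heatmaps")
    shapes = {hm.grid.shape for hm in heatmaps}
    if len(shapes) != 1:
        raise ValueError("heatmaps have inconsistent grid sizes")
    group_n = group_n if group_n is not None else len(heatmaps)
    stack = np.stack([hm.grid for hm in heatmaps])
    masks = np.stack([hm.valid_mask for hm in heatmaps])
    counts = masks.sum(axis=0)
    valid = counts > group_n / 2.0
    with np.errstate(invalid="ignore"):
        mean = np.nansum(np.where(masks, stack, 0.0), axis=0) / np.maximum(counts, 1)
    grid = np.where(valid, mean, np.nan)
    return OIHeatmap(
        grid=grid,
        valid_mask=valid,
        extent=heatmaps[0].extent,
        side="right",
        mirrored=False,
        meta=dict(group_n=group_n, n_maps=len(heatmaps)),
    )


def render(heatmap: OIHeatmap, out_path) -> None:
    """PNG with min-max normalization, blue -> red colormap, transparent
    invalid cells."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    vals = heatmap.grid
    finite = heatmap.valid_mask
    if not finite.any():
        raise ValueError("cannot render an empty heatmap")
    vmin, vmax = np.nanmin(vals), np.nanmax(vals)
    span = vmax - vmin if vmax > vmin else 1.0
    norm = (vals - vmin) / span
    cmap = colormaps["bwr"]
    rgba = cmap(np.where(finite, norm, 0.0))
    rgba[..., 3] = np.where(finite, 1.0, 0.0)
    # grid rows run along +y (anterior); flip so anterior is up in the image
    plt.imsave(out_path, rgba[::-1], format="png")
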