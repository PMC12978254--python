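"""Kernel-density MN hotspot mapping and cell-type enrichment.

The spatial positions of cGAS+ MN detections in a tumor section are turned
into a probability density on a regular grid (product-Gaussian kernel,
per-axis normal-reference bandwidth), quantized into integer percentile bins,
and thresholded to define "CIN hotspots".  Fold enrichment of each cell type
is the ratio of its share of cells inside the hotspot to its share outside;
a sweep over the 25th-95th percentile thresholds with a one-sample t test of
fold enrichment against 1 across tumors summarizes cohort-level enrichment.

Percentiles are computed over grid nodes within the tissue mask (the convex
hull of cell centroids, dilated by one grid cell), and cells are mapped to
their nearest grid node so that enrichment counts are exactly reproducible by
brute-force counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DensityGrid",
    "project_points",
    "normal_reference_bandwidth",
    "estimate_kde",
    "quantize_density",
    "assign_cells_to_grid",
    "enrichment_at_threshold",
    "threshold_sweep",
    "sweep_cohort",
]

DEFAULT_THRESHOLDS = range(25, 96)
BANDWIDTH_FLOOR_UM = 2.0


@dataclass
class DensityGrid:
    """KDE evaluated on a regular grid with a tissue mask and percentiles."""

    x: np.ndarray  # (nx,) node coordinates, um
    y: np.ndarray  # (ny,)
    density: np.ndarray  # (ny, nx), integrates to ~1 over the field
    mask: np.ndarray  # (ny, nx) bool, tissue nodes
    percentile: np.ndarray | None = None  # (ny, nx) int 0..100, -1 off-tissue
    bandwidth: tuple[float, float] = (np.nan, np.nan)

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))


def project_points(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Apply a 2x3 affine transform [[a, b, tx], [c, d, ty]] to (n, 2) points.

    Registration of adjacent serial sections is assumed done elsewhere; this
    just projects coordinates with a supplied transform.
    """
    points = np.asarray(points, float)
    affine = np.asarray(affine, float)
    if affine.shape != (2, 3):
        raise ValueError("affine must be 2x3")
    return points @ affine[:, :2].T + affine[:, 2]


def normal_reference_bandwidth(v: np.ndarray, floor: float = BANDWIDTH_FLOOR_UM) -> float:
    """Per-axis normal-reference rule 1.06 * min(sd, IQR/1.34) * n^(-1/5).

    Uses the quartile-robust spread and floors the result (coincident points
    would otherwise give a zero bandwidth).
    """
    v = np.asarray(v, float)
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 1.06 * spread * len(v) ** (-0.2)
    if h < floor:
        warnings.warn(f"bandwidth {h:.3g} below floor; using {floor} um")
        h = floor
    return float(h)


def _tissue_mask(gx, gy, mask_points):
    from scipy.spatial import ConvexHull, QhullError
    import shapely

    pts = np.asarray(mask_points, float)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("degenerate cell cloud; tissue mask set to full field")
        return np.ones((len(gy), len(gx)), bool)
    poly = shapely.Polygon(pts[hull.vertices])
    pad = max(gx[1] - gx[0], gy[1] - gy[0])  # dilate by one grid cell
    poly = poly.buffer(pad)
    xx, yy = np.meshgrid(gx, gy)
    return shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)


def estimate_kde(
    mn_points: np.ndarray,
    field_bounds: tuple[float, float, float, float],
    grid_n: int = 100,
    bandwidth: tuple[float, float] | None = None,
    mask_points: np.ndarray | None = None,
    min_points: int = 11,
) -> DensityGrid:
    """Product-Gaussian KDE of MN positions on a ``grid_n`` x ``grid_n`` grid.

    ``field_bounds`` is (xmin, xmax, ymin, ymax).  Tumors with 10 or fewer MN
    are excluded from hotspot analysis upstream, hence the default
    ``min_points=11``.  ``mask_points`` (typically all cell centroids) define
    the tissue mask; without them the whole field is tissue.
    """
    pts = np.asarray(mn_points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("mn_points must be (n, 2)")
    if len(pts) < min_points:
        raise ValueError(f"need >= {min_points} MN points, got {len(pts)}")
    xmin, xmax, ymin, ymax = field_bounds
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("field_bounds must have positive extent")

    if bandwidth is None:
        bandwidth = (normal_reference_bandwidth(pts[:, 0]), normal_reference_bandwidth(pts[:, 1]))
    hx, hy = bandwidth
    gx = np.linspace(xmin, xmax, grid_n)
    gy = np.linspace(ymin, ymax, grid_n)
    # density(y, x) = mean_i phi_hx(x - xi) phi_hy(y - yi)
    kx = stats.norm.pdf((gx[None, :] - pts[:, 0][:, None]) / hx) / hx  # (n, nx)
    ky = stats.norm.pdf((gy[None, :] - pts[:, 1][:, None]) / hy) / hy  # (n, ny)
    density = (ky.T @ kx) / len(pts)  # (ny, nx)

    mask = (
        _tissue_mask(gx, gy, mask_points)
        if mask_points is not None
        else np.ones((grid_n, grid_n), bool)
    )
    return DensityGrid(x=gx, y=gy, density=density, mask=mask, bandwidth=(hx, hy))


def quantize_density(grid: DensityGrid) -> DensityGrid:
    """Assign each masked node its empirical percentile rank in 1% bins.

    Node percentile = ceil(100 * (#masked nodes with density <= node) / N),
    an integer in 1..100; off-tissue nodes get -1.  A strictly increasing
    density over 100 nodes maps to percentiles 1..100; a constant density
    puts every node in the top bin.
    """
    d = grid.density[grid.mask]
    n = len(d)
    order = np.argsort(d, kind="mergesort")
    # count of values <= each value, tie-aware
    sorted_d = d[order]
    count_le = np.searchsorted(sorted_d, d, side="right")
    pct = np.ceil(100.0 * count_le / n).astype(int)
    out = np.full(grid.density.shape, -1, dtype=int)
    out[grid.mask] = pct
    grid.percentile = out
    return grid


def assign_cells_to_grid(cells: pd.DataFrame, grid: DensityGrid) -> np.ndarray:
    """Percentile of each cell's nearest grid node (-1 if off-tissue).

    Nearest-node mapping (rather than interpolation) keeps hotspot membership
    a pure counting operation.
    """
    if grid.percentile is None:
        raise ValueError("grid has no percentiles; call quantize_density first")
    dx = grid.x[1] - grid.x[0]
    dy = grid.y[1] - grid.y[0]
    ix = np.clip(np.round((cells["x"].to_numpy() - grid.x[0]) / dx).astype(int), 0, len(grid.x) - 1)
    iy = np.clip(np.round((cells["y"].to_numpy() - grid.y[0]) / dy).astype(int), 0, len(grid.y) - 1)
    return grid.percentile[iy, ix]


def enrichment_at_threshold(
    cells: pd.DataFrame,
    grid: DensityGrid,
    threshold: int,
    cell_percentile: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fold enrichment of each cell type inside the >= ``threshold`` hotspot.

    FE(t) = [n(t, in) / n(all, in)] / [n(t, out) / n(all, out)].  A cell type
    is excluded (no record) at this threshold if it has no cells inside or no
    cells outside; an empty hotspot or remainder yields no records at all.
    """
    pct = assign_cells_to_grid(cells, grid) if cell_percentile is None else cell_percentile
    usable = pct >= 0
    inside = usable & (pct >= threshold)
    outside = usable & (pct < threshold)
    n_in, n_out = int(inside.sum()), int(outside.sum())
    records = []
    if n_in and n_out:
        ct = cells["cell_type"].to_numpy()
        for t in pd.unique(ct):
            t_in = int((inside & (ct == t)).sum())
            t_out = int((outside & (ct == t)).sum())
            if t_in == 0 or t_out == 0:
                continue
            fe = (t_in / n_in) / (t_out / n_out)
            records.append(
                dict(cell_type=t, threshold=int(threshold), n_inside=t_in,
                     n_outside=t_out, n_total_inside=n_in, n_total_outside=n_out,
                     fold_enrichment=fe)
            )
    return pd.DataFrame(
        records,
        columns=["cell_type", "threshold", "n_inside", "n_outside",
                 "n_total_inside", "n_total_outside", "fold_enrichment"],
    )


def threshold_sweep(
    cells: pd.DataFrame, grid: DensityGrid, thresholds=DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Per-tumor enrichment curve over percentile thresholds (default 25-95).

    Computed from a per-type histogram of cell percentiles, which gives the
    same counts as calling :func:`enrichment_at_threshold` per threshold
    (the per-threshold form is kept as the counting oracle in tests).
    """
    pct = assign_cells_to_grid(cells, grid)
    usable = pct >= 0
    ct = cells["cell_type"].to_numpy()[usable]
    pu = pct[usable]
    types = pd.unique(ct)
    thresholds = np.asarray(list(thresholds), int)
    # hist[t, b] = cells of type t at percentile b; suffix sums give n_inside
    hist = np.zeros((len(types), 101), dtype=np.int64)
    for i, t in enumerate(types):
        hist[i] = np.bincount(pu[ct == t], minlength=101)[:101]
    suffix = hist[:, ::-1].cumsum(axis=1)[:, ::-1]  # counts at pct >= b
    totals = hist.sum(axis=1)
    n_all = totals.sum()
    records = []
    for th in thresholds:
        n_in_t = suffix[:, th] if th <= 100 else np.zeros(len(types), np.int64)
        n_out_t = totals - n_in_t
        n_in, n_out = int(n_in_t.sum()), int(n_out_t.sum())
        if n_in == 0 or n_out == 0:
            continue
        for i, t in enumerate(types):
            if n_in_t[i] == 0 or n_out_t[i] == 0:
                continue
            fe = (n_in_t[i] / n_in) / (n_out_t[i] / n_out)
            records.append(
                dict(cell_type=t, threshold=int(th), n_inside=int(n_in_t[i]),
                     n_outside=int(n_out_t[i]), n_total_inside=n_in,
                     n_total_outside=n_out, fold_enrichment=fe)
            )
    return pd.DataFrame(
        records,
        columns=["cell_type", "threshold", "n_inside", "n_outside",
                 "n_total_inside", "n_total_outside", "fold_enrichment"],
    )


def _median_ci(v: np.ndarray, level: float = 0.95):
    """Distribution-free order-statistic CI for the median."""
    v = np.sort(np.asarray(v, float))
    n = len(v)
    if n < 2:
        return (np.nan, np.nan)
    lo = int(stats.binom.ppf((1 - level) / 2, n, 0.5))
    hi = int(stats.binom.ppf(1 - (1 - level) / 2, n, 0.5))
    return float(v[max(lo, 0)]), float(v[min(hi, n - 1)])


def sweep_cohort(per_tumor_sweeps: list[pd.DataFrame]) -> pd.DataFrame:
    """Cohort summary: per (cell_type, threshold) mean/median FE across tumors
    and a two-sided one-sample t test of fold enrichment against 1.

    Tumors lacking a record for a (type, threshold) simply do not contribute
    there.  With fewer than two contributing tumors the test is reported as
    missing (NaN).  Thresholds are tested marginally, as in the per-threshold
    heatmap display this mirrors; no multiplicity correction is applied.
    """
    tagged = [df.assign(tumor=i) for i, df in enumerate(per_tumor_sweeps)]
    allrec = pd.concat(tagged, ignore_index=True)
    rows = []
    for (t, th), sub in allrec.groupby(["cell_type", "threshold"], sort=True):
        fe = sub["fold_enrichment"].to_numpy()
        if len(fe) >= 2 and fe.std(ddof=1) > 0:
            tt = stats.ttest_1samp(fe, 1.0)
            t_stat, p = float(tt.statistic), float(tt.pvalue)
        elif len(fe) >= 2:
            t_stat, p = (0.0, 1.0) if np.allclose(fe, 1.0) else (np.nan, np.nan)
        else:
            t_stat, p = np.nan, np.nan
        lo, hi = _median_ci(fe)
        rows.append(
            dict(cell_type=t, threshold=th, n_tumors=len(fe),
                 mean_fe=float(fe.mean()), median_fe=float(np.median(fe)),
                 median_ci_low=lo, median_ci_high=hi, t_stat=t_stat, p=p)
        )
    return pd.DataFrame(rows)
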