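"""UAS plant-height map construction: DSM − DTM.

The digital terrain model is interpolated from a random subset of the DSM's
soil pixels (the study convention is roughly 40 % of them), by ordinary
kriging with an exponential variogram fitted to the empirical semivariance
by least squares. Kriging is an exact interpolator: predictions at sampled
cells reproduce the sampled elevations. Inverse-distance weighting (power 2)
is available as a fallback for degenerate sample layouts. The plant height
map is the cellwise difference DSM − DTM; nodata propagates and negative
values are preserved — percentile selection downstream is robust to a
negative tail and clamping would bias low percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import KDTree, distance

from .raster import Raster

#: Fraction of soil pixels sampled for interpolation by default.
DEFAULT_SOIL_FRACTION = 0.4

#: Variance floor for the fitted nugget (m^2).
NUGGET_FLOOR = 1e-6


@dataclass
class SoilSample:
    """Sampled soil cells of a DSM: grid indices, coordinates, elevations."""

    rows: np.ndarray
    cols: np.ndarray
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    fraction: float
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Variogram:
    """Exponential variogram: gamma(h) = nugget + sill * (1 - exp(-h / range))."""

    nugget: float
    sill: float
    range_: float

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.sill * (1.0 - np.exp(-h / self.range_))
        # gamma(0) = 0 by convention: the nugget applies only for h > 0,
        # which is what makes kriging exact at the sample locations.
        return np.where(h > 0, g, 0.0)


def sample_soil_pixels(
    dsm: Raster,
    soil_mask: Raster,
    fraction: float = DEFAULT_SOIL_FRACTION,
    seed: int | None = None,
) -> SoilSample:
    """Uniform random subset (without replacement) of the DSM's soil cells.

    The sample size is ``round(fraction * n_soil_cells)`` (at least 1);
    identical seeds give identical samples.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    dsm.require_congruent(soil_mask)
    soil = (soil_mask.values > 0) & ~dsm.nodata_mask()
    rows, cols = np.nonzero(soil)
    if rows.size == 0:
        raise ValueError("the soil mask selects no valid DSM cells")
    n = max(1, int(round(fraction * rows.size)))
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(rows.size, size=n, replace=False))
    rows, cols = rows[pick], cols[pick]
    xs, ys = dsm.cell_centers()
    return SoilSample(
        rows=rows,
        cols=cols,
        x=xs[cols],
        y=ys[rows],
        values=dsm.values[rows, cols],
        fraction=fraction,
        seed=seed,
    )


def fit_variogram(
    samples: SoilSample,
    n_bins: int = 18,
    max_pairs_points: int = 1200,
    seed: int = 0,
) -> Variogram:
    """Least-squares exponential variogram fit to the empirical semivariance.

    Pair distances are computed on at most ``max_pairs_points`` sample points
    (a fixed-seed subset for reproducibility), binned up to half the maximum
    pair distance, and the model is fitted to bin means. If the fit fails or
    the field is essentially constant, a small-sill default keeps downstream
    kriging well posed.
    """
    pts = np.column_stack((samples.x, samples.y))
    vals = samples.values
    if len(vals) > max_pairs_points:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(vals), size=max_pairs_points, replace=False)
        pts, vals = pts[keep], vals[keep]
    d = distance.pdist(pts)
    g = 0.5 * distance.pdist(vals[:, None], metric="sqeuclidean")
    span = float(d.max())
    if span == 0:
        return Variogram(NUGGET_FLOOR, max(float(vals.var()), NUGGET_FLOOR), 1.0)
    hmax = 0.5 * span
    edges = np.linspace(0, hmax, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    inside = d <= hmax
    counts = np.bincount(idx[inside], minlength=n_bins)
    sums_g = np.bincount(idx[inside], weights=g[inside], minlength=n_bins)
    sums_h = np.bincount(idx[inside], weights=d[inside], minlength=n_bins)
    ok = counts > 0
    h_emp = sums_h[ok] / counts[ok]
    g_emp = sums_g[ok] / counts[ok]
    var = max(float(vals.var()), NUGGET_FLOOR)
    if np.ptp(g_emp) <= 0 or h_emp.size < 3:
        return Variogram(NUGGET_FLOOR, var, max(hmax / 3.0, 1e-6))

    def model(h, nugget, sill, rng_):
        return nugget + sill * (1.0 - np.exp(-h / rng_))

    try:
        popt, _ = curve_fit(
            model,
            h_emp,
            g_emp,
            p0=(NUGGET_FLOOR, var, hmax / 3.0),
            bounds=([0.0, 1e-12, 1e-6], [var, 10 * var + 1.0, 10 * hmax]),
            maxfev=2000,
        )
        nugget, sill, rng_ = popt
    except Exception:
        nugget, sill, rng_ = NUGGET_FLOOR, var, hmax / 3.0
    return Variogram(max(float(nugget), NUGGET_FLOOR), float(sill), float(rng_))


def _check_span(samples: SoilSample, need_kriging: bool) -> None:
    if len(samples) < 4:
        raise ValueError("DTM interpolation needs at least 4 soil samples")
    pts = np.column_stack((samples.x, samples.y))
    centered = pts - pts.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-9)
    if rank < 2:
        msg = "soil samples are collinear in grid position"
        if need_kriging:
            raise ValueError(msg + "; kriging is ill posed (idw permitted)")


def interpolate_dtm(
    samples: SoilSample,
    template: Raster,
    method: str = "kriging",
    n_neighbors: int = 16,
    variogram: Variogram | None = None,
    chunk_cells: int = 4096,
) -> Raster:
    """Interpolate a full-grid terrain model from sampled soil elevations.

    ``kriging`` (default) is local ordinary kriging: each cell is predicted
    from its ``n_neighbors`` nearest samples under the fitted exponential
    variogram, solving the standard ordinary-kriging system with a Lagrange
    multiplier per cell (batched across cells). ``idw`` is inverse-distance
    weighting with power 2 over the same neighborhoods. Both reproduce the
    sampled elevations at the sampled cells.
    """
    _check_span(samples, need_kriging=method == "kriging")
    if method not in {"kriging", "idw"}:
        raise ValueError("method must be 'kriging' or 'idw'")
    xs, ys = template.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    targets = np.column_stack((gx.ravel(), gy.ravel()))
    spts = np.column_stack((samples.x, samples.y))
    svals = samples.values
    k = min(n_neighbors, len(svals))
    tree = KDTree(spts)
    dist_nb, idx_nb = tree.query(targets, k=k)
    if k == 1:
        dist_nb = dist_nb[:, None]
        idx_nb = idx_nb[:, None]
    out = np.empty(targets.shape[0])
    if np.ptp(svals) == 0:
        # constant field: any convex weighting returns the constant
        out[:] = svals[0]
        return template.like(out.reshape(template.shape), role="dtm")
    if method == "idw":
        with np.errstate(divide="ignore"):
            w = 1.0 / dist_nb**2
        exact = dist_nb[:, 0] < 1e-12
        wsum = np.where(np.isinf(w).any(axis=1), np.nan, w.sum(axis=1))
        out = (w * svals[idx_nb]).sum(axis=1) / wsum
        out[exact] = svals[idx_nb[exact, 0]]
        return template.like(out.reshape(template.shape), role="dtm")
    vg = fit_variogram(samples) if variogram is None else variogram
    n = targets.shape[0]
    for start in range(0, n, chunk_cells):
        sl = slice(start, min(start + chunk_cells, n))
        idx = idx_nb[sl]
        b = idx.shape[0]
        nb_pts = spts[idx]  # (b, k, 2)
        diff = nb_pts[:, :, None, :] - nb_pts[:, None, :, :]
        h_ss = np.sqrt((diff**2).sum(axis=-1))  # (b, k, k)
        gamma_ss = vg(h_ss)
        a = np.empty((b, k + 1, k + 1))
        a[:, :k, :k] = gamma_ss
        a[:, :k, k] = 1.0
        a[:, k, :k] = 1.0
        a[:, k, k] = 0.0
        rhs = np.empty((b, k + 1))
        rhs[:, :k] = vg(dist_nb[sl])
        rhs[:, k] = 1.0
        try:
            w = np.linalg.solve(a, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # near-duplicate neighbors: regularize off the gamma(0) diagonal
            a[:, :k, :k] += 1e-10 * (1 - np.eye(k))
            w = np.linalg.solve(a, rhs[..., None])[..., 0]
        out[sl] = (w[:, :k] * svals[idx]).sum(axis=1)
    return template.like(out.reshape(template.shape), role="dtm")


def height_map(dsm: Raster, dtm: Raster) -> Raster:
    """Plant height map: cellwise DSM − DTM on congruent grids.

    Nodata in either input propagates; negative differences are preserved.
    """
    dsm.require_congruent(dtm)
    bad = dsm.nodata_mask() | dtm.nodata_mask()
    vals = dsm.values - dtm.values
    vals[bad] = dsm.nodata
    return dsm.like(vals, role="height_map")
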