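"""Ordinary kriging of point habitat samples, and rugosity from bathymetry.

The interpolation pipeline is the classical one: an empirical semivariogram
binned over point pairs, a weighted least-squares fit of a parametric
variogram model, and local ordinary kriging (k nearest samples, weights
constrained to sum to one via a Lagrange multiplier).  With a zero nugget
the interpolator is exact at the sample locations.

A note on the nugget at lag zero: the fitted curve jumps to ``nugget`` as
h -> 0+, but the kriging system uses gamma(0) = 0 on its diagonal (the
semivariogram of a point with itself), which is what exactness requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import ArgumentError, DegenerateInputError
from .grids import KIND_PERCENT, PointSet, RasterGrid

VARIOGRAM_FORMS = ("spherical", "exponential", "gaussian")


def _structure(form: str, h: np.ndarray, rng: float) -> np.ndarray:
    """Unit-sill variogram structure g(h) with g(0)=0 and g(inf)=1."""
    hr = np.asarray(h, float) / rng
    if form == "spherical":
        g = np.where(hr < 1.0, 1.5 * hr - 0.5 * hr**3, 1.0)
    elif form == "exponential":
        g = 1.0 - np.exp(-3.0 * hr)
    elif form == "gaussian":
        g = 1.0 - np.exp(-3.0 * hr**2)
    else:
        raise ArgumentError(f"unknown variogram form {form!r}")
    return g


@dataclass
class VariogramModel:
    """A fitted parametric semivariogram."""

    model_form: str
    nugget: float
    partial_sill: float
    range: float
    bins: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model_form not in VARIOGRAM_FORMS:
            raise ArgumentError(f"unknown variogram form {self.model_form!r}")
        if self.nugget < 0 or self.partial_sill < 0 or not self.range > 0:
            raise ArgumentError("need nugget >= 0, partial_sill >= 0, range > 0")

    def __call__(self, h) -> np.ndarray:
        """gamma(h); exactly 0 at h == 0, nugget + psill*g elsewhere."""
        h = np.asarray(h, dtype=float)
        gamma = self.nugget + self.partial_sill * _structure(self.model_form, h, self.range)
        return np.where(h == 0.0, 0.0, gamma)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


def empirical_variogram(points: PointSet, attribute: str, n_bins: int = 12,
                        max_lag: float | None = None) -> list[tuple[float, float, int]]:
    """Binned empirical semivariances.

    Returns (lag center, semivariance, pair count) per bin; bins with no
    pairs carry NaN semivariance and count 0.  ``max_lag`` defaults to half
    the maximum pairwise distance.
    """
    if points.attributes is None or attribute not in points.attributes.columns:
        raise ArgumentError(f"points carry no attribute {attribute!r}")
    z = points.attributes[attribute].to_numpy(float)
    if len(points) < 2:
        raise DegenerateInputError("need at least 2 points")
    xy = np.column_stack([points.x, points.y])
    d = pdist(xy)
    if d.max() == 0:
        raise DegenerateInputError("all points coincident")
    if max_lag is None:
        max_lag = d.max() / 2.0
    if not max_lag > 0:
        raise ArgumentError("max_lag must be > 0")
    sq = pdist(np.column_stack([z]), metric="sqeuclidean")  # (z_i - z_j)^2
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    idx = np.digitize(d, edges[1:-1], right=False)
    inside = d <= max_lag
    out = []
    for b in range(n_bins):
        sel = inside & (idx == b)
        count = int(sel.sum())
        center = 0.5 * (edges[b] + edges[b + 1])
        if count:
            gamma = sq[sel].sum() / (2.0 * count)
            out.append((center, float(gamma), count))
        else:
            out.append((center, float("nan"), 0))
    return out


def fit_variogram(bins: list[tuple[float, float, int]],
                  model_form: str = "spherical", n_starts: int = 24,
                  seed: int = 0) -> VariogramModel:
    """Weighted least-squares variogram fit (weights = pair counts).

    Multi-start bounded optimization; the returned parameters minimize
    sum_b N_b * (gamma_model(h_b) - gamma_b)^2 over the explored starts.
    """
    data = [(h, g, n) for h, g, n in bins if n > 0 and np.isfinite(g)]
    if len(data) < 3:
        raise DegenerateInputError("need >= 3 nonempty variogram bins")
    h = np.array([b[0] for b in data])
    g = np.array([b[1] for b in data])
    w = np.sqrt(np.array([b[2] for b in data], float))
    gmax = max(g.max(), 1e-12)
    hmax = h.max()

    def residuals(theta):
        nug, psill, rng_ = theta
        model = nug + psill * _structure(model_form, h, rng_)
        return w * (model - g)

    lo = np.array([0.0, 0.0, hmax * 1e-3])
    hi = np.array([2.0 * gmax, 4.0 * gmax, 4.0 * hmax])
    rng = np.random.default_rng(seed)
    starts = [np.array([0.0, gmax, hmax / 2.0]),
              np.array([g[0], max(gmax - g[0], 1e-9), hmax])]
    starts += [lo + rng.random(3) * (hi - lo) for _ in range(n_starts - len(starts))]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise DegenerateInputError("variogram fit failed on all starts")
    nug, psill, rng_ = best.x
    return VariogramModel(model_form=model_form, nugget=float(nug),
                          partial_sill=float(psill), range=float(rng_),
                          bins=list(bins))


def variogram_objective(model: VariogramModel,
                        bins: list[tuple[float, float, int]]) -> float:
    """The weighted least-squares objective the fit minimizes."""
    total = 0.0
    for h, g, n in bins:
        if n > 0 and np.isfinite(g):
            m = model.nugget + model.partial_sill * _structure(model.model_form,
                                                               np.array([h]),
                                                               model.range)[0]
            total += n * (m - g) ** 2
    return total


def _dedupe_average(xy: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average attribute values at duplicated sample locations."""
    uniq, inv = np.unique(xy, axis=0, return_inverse=True)
    if uniq.shape[0] == xy.shape[0]:
        return xy, z
    sums = np.zeros(uniq.shape[0])
    counts = np.zeros(uniq.shape[0])
    np.add.at(sums, inv, z)
    np.add.at(counts, inv, 1.0)
    return uniq, sums / counts


def kriging_weights(sample_xy: np.ndarray, target_xy: np.ndarray,
                    variogram: VariogramModel) -> tuple[np.ndarray, float]:
    """Solve one ordinary kriging system; returns (weights, Lagrange mult)."""
    k = sample_xy.shape[0]
    A = np.ones((k + 1, k + 1))
    d = squareform(pdist(sample_xy))
    A[:k, :k] = variogram(d)
    A[k, k] = 0.0
    b = np.ones(k + 1)
    b[:k] = variogram(np.hypot(*(sample_xy - target_xy).T))
    sol = np.linalg.solve(A, b)
    return sol[:k], float(sol[k])


def krige(points: PointSet, attribute: str, variogram: VariogramModel,
          grid: RasterGrid, neighborhood_k: int = 12,
          clamp: tuple[float, float] | None = None) -> RasterGrid:
    """Ordinary kriging of a point attribute onto a target grid.

    Each valid cell is predicted from its ``neighborhood_k`` nearest samples
    (duplicated sample locations are averaged first).  ``clamp`` bounds the
    output, used to keep percent covers in [0, 100].
    """
    if neighborhood_k < 2:
        raise ArgumentError("neighborhood_k must be >= 2")
    if points.attributes is None or attribute not in points.attributes.columns:
        raise ArgumentError(f"points carry no attribute {attribute!r}")
    xy = np.column_stack([points.x, points.y])
    z = points.attributes[attribute].to_numpy(float)
    xy, z = _dedupe_average(xy, z)
    n = xy.shape[0]
    k = min(neighborhood_k, n)
    tree = cKDTree(xy)

    valid = ~grid.nodata_mask
    rr, cc = np.nonzero(valid)
    cx, cy = grid.cell_center(rr, cc)
    targets = np.column_stack([cx, cy])
    _, nbr = tree.query(targets, k=k)
    nbr = np.atleast_2d(nbr)
    if nbr.shape[0] != targets.shape[0]:
        nbr = nbr.reshape(targets.shape[0], k)

    pts = xy[nbr]                                   # (m, k, 2)
    diffs = pts[:, :, None, :] - pts[:, None, :, :]
    dmat = np.hypot(diffs[..., 0], diffs[..., 1])   # (m, k, k)
    m = targets.shape[0]
    A = np.ones((m, k + 1, k + 1))
    A[:, :k, :k] = variogram(dmat)
    A[:, k, k] = 0.0
    b = np.ones((m, k + 1))
    d0 = np.hypot(pts[..., 0] - targets[:, None, 0],
                  pts[..., 1] - targets[:, None, 1])
    b[:, :k] = variogram(d0)
    try:
        sol = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(
            "singular kriging system after duplicate averaging") from exc
    weights = sol[:, :k]
    pred = np.einsum("mk,mk->m", weights, z[nbr])
    if clamp is not None:
        pred = np.clip(pred, clamp[0], clamp[1])
    values = np.full(grid.shape, np.nan)
    values[rr, cc] = pred
    return grid.copy(values=np.where(valid, values, 0.0),
                     nodata_mask=~valid)


def krige_stack_layer(points: PointSet, attribute: str, grid: RasterGrid,
                      kind: str = KIND_PERCENT, model_form: str = "spherical",
                      n_bins: int = 12, neighborhood_k: int = 12) -> tuple[RasterGrid, VariogramModel]:
    """Convenience: empirical variogram -> WLS fit -> kriged surface."""
    bins = empirical_variogram(points, attribute, n_bins=n_bins)
    model = fit_variogram(bins, model_form=model_form)
    clamp = (0.0, 100.0) if kind == KIND_PERCENT else None
    return krige(points, attribute, model, grid, neighborhood_k, clamp=clamp), model


def derive_rugosity(depth: RasterGrid, window: int = 3) -> RasterGrid:
    """Terrain rugosity: true (3-D) surface area over planimetric area.

    The depth surface is triangulated over cell centers (each unit square of
    the lattice split into two triangles, 8 triangles per 3x3 window); per
    cell, the summed 3-D facet area within the window is divided by the
    planimetric window area.  Flat terrain gives exactly 1; a plane of
    constant slope s gives sqrt(1 + s^2).  Cells whose window is incomplete
    or touches nodata become nodata.
    """
    if window < 3 or window % 2 == 0:
        raise ArgumentError("window must be odd and >= 3")
    if window > min(depth.shape):
        raise ArgumentError("window larger than grid")
    s = depth.cell_size
    zval = np.where(depth.nodata_mask, np.nan, depth.values)
    z00 = zval[:-1, :-1]
    z01 = zval[:-1, 1:]
    z10 = zval[1:, :-1]
    z11 = zval[1:, 1:]
    # triangle (z00, z10, z01): area = s^2/2 * sqrt(1 + gx^2 + gy^2) with the
    # facet gradients given by the edge differences; same for (z11, z10, z01)
    a1 = 0.5 * s * s * np.sqrt(1.0 + ((z01 - z00) / s) ** 2 + ((z10 - z00) / s) ** 2)
    a2 = 0.5 * s * s * np.sqrt(1.0 + ((z11 - z10) / s) ** 2 + ((z11 - z01) / s) ** 2)
    square_area = a1 + a2                              # (n_rows-1, n_cols-1)

    half = (window - 1) // 2
    w = window - 1                                     # squares per window side
    n_rows, n_cols = depth.shape
    values = np.full(depth.shape, np.nan)

    def window_sum(field: np.ndarray) -> np.ndarray:
        csum = np.zeros((field.shape[0] + 1, field.shape[1] + 1))
        csum[1:, 1:] = np.cumsum(np.cumsum(field, axis=0), axis=1)
        return csum[w:, w:] - csum[w:, :-w] - csum[:-w, w:] + csum[:-w, :-w]

    out_rows = n_rows - 2 * half
    out_cols = n_cols - 2 * half
    if out_rows > 0 and out_cols > 0:
        bad = ~np.isfinite(square_area)
        total = window_sum(np.where(bad, 0.0, square_area))[:out_rows, :out_cols]
        n_bad = window_sum(bad.astype(float))[:out_rows, :out_cols]
        total = np.where(n_bad > 0, np.nan, total)
        values[half:n_rows - half, half:n_cols - half] = total / (w * s) ** 2
    mask = ~np.isfinite(values)
    # guard against round-off dipping a flat surface fractionally below 1
    values = np.where(mask, 0.0, np.maximum(values, 1.0))
    return depth.copy(values=values, nodata_mask=mask)
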