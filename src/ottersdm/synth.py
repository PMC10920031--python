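"""Synthetic landscapes, survey designs, and virtual species with known truth.

The generators emulate the features of a kriged benthic habitat landscape:
smooth spatially autocorrelated percent-cover surfaces, a strictly negative
bathymetry layer, a rugosity ratio derived from bathymetry, parallel strip
transects as the surveyed (available) space, and presence cells drawn from a
known exponential-of-linear-predictor intensity restricted to that space.
Every generator is a pure function of its seed and arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from .errors import ArgumentError, DegenerateInputError
from .grids import (
    KIND_DEPTH,
    KIND_PERCENT,
    KIND_RATIO,
    BackgroundSet,
    CellSet,
    CovariateStack,
    PointSet,
    PresenceSet,
    RasterGrid,
    SurveyDomain,
)

#: bathymetry range of the synthetic bay, meters below datum
DEPTH_RANGE = (-170.0, -1.0)

#: canonical covariate list of the benthic habitat table: seven substrate
#: percent covers (modified Wentworth scale), four algal percent covers,
#: bathymetry, and rugosity
HABITAT_ATTRIBUTES = [
    ("boulder", KIND_PERCENT),
    ("cobble", KIND_PERCENT),
    ("pebble", KIND_PERCENT),
    ("gravel", KIND_PERCENT),
    ("shell_litter", KIND_PERCENT),
    ("sand", KIND_PERCENT),
    ("mud", KIND_PERCENT),
    ("understory_kelp", KIND_PERCENT),
    ("macroalgae", KIND_PERCENT),
    ("filamentous_algae", KIND_PERCENT),
    ("coralline_algae", KIND_PERCENT),
    ("bathymetry", KIND_DEPTH),
    ("rugosity", KIND_RATIO),
]


@dataclass
class SimulationTruth:
    """The generating model of a virtual species, kept for recovery tests."""

    true_coefficients: dict[str, float]
    intensity_surface: RasterGrid
    seed: int


def _smooth_field(rng: np.random.Generator, n_rows: int, n_cols: int,
                  smoothness: float) -> np.ndarray:
    """Gaussian white noise convolved with a Gaussian kernel, rank-rescaled
    to uniform [0, 1] margins. ``smoothness`` is the correlation length in
    cells; ``inf`` yields a constant field at the range midpoint."""
    if not smoothness > 0:
        raise ArgumentError("smoothness must be > 0")
    if np.isinf(smoothness):
        return np.full((n_rows, n_cols), 0.5)
    noise = rng.standard_normal((n_rows, n_cols))
    smooth = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    order = np.argsort(smooth.ravel(), kind="stable")
    ranks = np.empty(smooth.size)
    ranks[order] = np.arange(smooth.size)
    denom = max(smooth.size - 1, 1)
    return (ranks / denom).reshape(n_rows, n_cols)


def gen_landscape(seed: int, n_rows: int, n_cols: int, cell_size: float,
                  attribute_specs: list[tuple[str, str, float]],
                  origin_x: float = 0.0, origin_y: float = 0.0) -> CovariateStack:
    """Generate a stack of smooth random covariate layers.

    ``attribute_specs`` is a list of (name, kind, smoothness) with kind one
    of 'percent_cover', 'depth', 'ratio'.  Percent covers are rescaled to
    [0, 100], depth to the synthetic bathymetric range (strictly negative),
    and ratio layers to [1, 3].
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ArgumentError("grid dimensions must be positive")
    rng = np.random.default_rng(seed)
    layers: dict[str, RasterGrid] = {}
    kinds: dict[str, str] = {}
    for name, kind, smoothness in attribute_specs:
        u = _smooth_field(rng, n_rows, n_cols, smoothness)
        if kind == KIND_PERCENT:
            vals = 100.0 * u
        elif kind == KIND_DEPTH:
            lo, hi = DEPTH_RANGE
            vals = lo + (hi - lo) * u
        elif kind == KIND_RATIO:
            vals = 1.0 + 2.0 * u
        else:
            raise ArgumentError(f"unknown attribute kind {kind!r}")
        layers[name] = RasterGrid(values=vals, cell_size=cell_size,
                                  origin_x=origin_x, origin_y=origin_y,
                                  nodata_mask=np.zeros((n_rows, n_cols), bool))
        kinds[name] = kind
    return CovariateStack(layers=layers, kinds=kinds)


def gen_default_stack(seed: int, n_rows: int = 60, n_cols: int = 60,
                      cell_size: float = 131.0, smoothness: float = 4.0) -> CovariateStack:
    """The full 13-attribute benthic landscape at the survey cell resolution.

    Rugosity is derived from the synthetic bathymetry (surface-area ratio)
    rather than drawn independently, mirroring how it is computed from real
    bathymetry; border cells without a full derivation window get nodata.
    """
    from .kriging import derive_rugosity  # local import to avoid a cycle

    specs = [(name, kind, smoothness) for name, kind in HABITAT_ATTRIBUTES
             if name != "rugosity"]
    stack = gen_landscape(seed, n_rows, n_cols, cell_size, specs)
    rug = derive_rugosity(stack.layers["bathymetry"], window=3)
    layers = dict(stack.layers)
    kinds = dict(stack.kinds)
    layers["rugosity"] = rug
    kinds["rugosity"] = KIND_RATIO
    return CovariateStack(layers=layers, kinds=kinds)


def gen_survey_design(stack: CovariateStack, transect_spacing_cells: int,
                      transect_width_cells: int) -> SurveyDomain:
    """Parallel north-south strip transects spanning the grid.

    Strips of ``transect_width_cells`` columns repeat every
    ``transect_spacing_cells`` columns, starting at column 0 (the aerial
    design: 400 m wide strips every 4 km, here expressed in cells).
    """
    grid = stack.grid
    width, spacing = int(transect_width_cells), int(transect_spacing_cells)
    if not (spacing >= width >= 1):
        raise ArgumentError("need spacing >= width >= 1")
    if width > grid.n_cols:
        raise ArgumentError("transect width exceeds grid extent")
    s = grid.cell_size
    y0 = grid.origin_y
    y1 = grid.origin_y + grid.n_rows * s
    polygons = []
    for start in range(0, grid.n_cols, spacing):
        stop = min(start + width, grid.n_cols)
        x0 = grid.origin_x + start * s
        x1 = grid.origin_x + stop * s
        polygons.append(box(x0, y0, x1, y1))
    return SurveyDomain(polygons=polygons)


def _scaled_covariates(stack: CovariateStack, rows, cols,
                       names: list[str]) -> np.ndarray:
    """Min-max scale covariate values over the given cells, one column each."""
    X = stack.values_at_cells(rows, cols, names)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def gen_species(stack: CovariateStack, domain: SurveyDomain,
                true_coefficients: dict[str, float], n_presences: int,
                seed: int) -> tuple[PresenceSet, SimulationTruth]:
    """Sample presence cells from a known habitat-driven intensity.

    Cells are drawn without replacement from the survey domain with
    probability proportional to ``exp(sum_j beta_j * z_j)`` where ``z_j``
    are the min-max scaled covariates over domain cells.
    """
    if n_presences < 1:
        raise ArgumentError("n_presences must be >= 1")
    names = list(true_coefficients)
    for name in names:
        if name not in stack.layers:
            raise ArgumentError(f"unknown covariate {name!r} in true_coefficients")
    grid = stack.grid
    rows, cols = domain.cells(grid, valid_mask=~stack.nodata_mask)
    if rows.size == 0:
        raise DegenerateInputError("survey domain contains no valid cells")
    if n_presences > rows.size:
        raise ArgumentError(
            f"n_presences={n_presences} exceeds {rows.size} domain cells")
    Z = _scaled_covariates(stack, rows, cols, names)
    beta = np.array([true_coefficients[n] for n in names])
    eta = Z @ beta
    logw = eta - eta.max()
    rng = np.random.default_rng(seed)
    # Gumbel-max trick: top-n keys give an exact weighted sample without
    # replacement with selection probability proportional to exp(logw)
    keys = logw + rng.gumbel(size=rows.size)
    take = np.argpartition(-keys, n_presences - 1)[:n_presences]
    take = take[np.argsort(-keys[take])]

    intensity = np.zeros(grid.shape)
    w = np.exp(logw)
    intensity[rows, cols] = w / w.sum()
    mask = np.ones(grid.shape, bool)
    mask[rows, cols] = False
    truth = SimulationTruth(
        true_coefficients=dict(true_coefficients),
        intensity_surface=grid.copy(values=intensity, nodata_mask=mask),
        seed=seed,
    )
    return (PresenceSet(rows=rows[take], cols=cols[take], grid=grid,
                        role="presence"), truth)


def sample_background(domain: SurveyDomain, stack: CovariateStack, n: int,
                      seed: int) -> BackgroundSet:
    """Sample ``n`` distinct available cells uniformly from the domain."""
    grid = stack.grid
    rows, cols = domain.cells(grid, valid_mask=~stack.nodata_mask)
    if rows.size == 0:
        raise DegenerateInputError("survey domain contains no valid cells")
    if n > rows.size:
        raise ArgumentError(f"n={n} exceeds {rows.size} available domain cells")
    rng = np.random.default_rng(seed)
    take = rng.choice(rows.size, size=n, replace=False)
    return BackgroundSet(rows=rows[take], cols=cols[take], grid=grid,
                         role="background")


def gen_habitat_samples(seed: int, n_sites: int = 300, n_rows: int = 60,
                        n_cols: int = 60, cell_size: float = 131.0,
                        smoothness: float = 4.0) -> PointSet:
    """Synthetic drop-camera habitat samples (stand-in for the real survey
    table, which this package does not ship).

    Emulates the compositional structure of benthic percent-cover data:
    the six minority substrate classes are smooth independent surfaces and
    mud — the ubiquitous, dominant class — is (up to observation noise) the
    complement of their summed cover, which is what makes mud the canonical
    multicollinearity offender in a stepwise VIF screen.  Algal covers,
    bathymetry, and rugosity vary independently of the closure.
    """
    if n_sites < 20:
        raise ArgumentError("need at least 20 sites")
    rng = np.random.default_rng(seed)
    substrates = ["boulder", "cobble", "pebble", "gravel", "shell_litter", "sand"]
    algae = ["understory_kelp", "macroalgae", "filamentous_algae", "coralline_algae"]
    specs = [(n, KIND_PERCENT, smoothness) for n in substrates + algae]
    specs += [("bathymetry", KIND_DEPTH, smoothness)]
    stack = gen_landscape(int(rng.integers(2**31)), n_rows, n_cols, cell_size, specs)
    from .kriging import derive_rugosity

    rug = derive_rugosity(stack.layers["bathymetry"], window=3)
    valid = ~rug.nodata_mask
    rr, cc = np.nonzero(valid)
    take = rng.choice(rr.size, size=n_sites, replace=False)
    rows, cols = rr[take], cc[take]
    x, y = stack.grid.cell_center(rows, cols)
    # jitter within the cell so sites are generic point locations
    x = x + rng.uniform(-0.4, 0.4, n_sites) * cell_size
    y = y + rng.uniform(-0.4, 0.4, n_sites) * cell_size

    table = {}
    for name in substrates:
        table[name] = stack.layers[name].values[rows, cols] * 0.15  # cover in [0, 15]
    minor_total = sum(table[name] for name in substrates)
    mud = 100.0 - minor_total + rng.normal(0.0, 2.0, n_sites)
    table["mud"] = np.clip(mud, 0.0, 100.0)
    for name in algae:
        table[name] = stack.layers[name].values[rows, cols] * 0.6  # cover in [0, 60]
    table["bathymetry"] = stack.layers["bathymetry"].values[rows, cols]
    table["rugosity"] = rug.values[rows, cols]
    order = [s for s, _ in HABITAT_ATTRIBUTES]
    attrs = pd.DataFrame({name: table[name] for name in order})
    return PointSet(x=x, y=y, attributes=attrs, role="habitat_sample")
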