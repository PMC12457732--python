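"""Virtual species and synthetic environment generation.

The generator produces aligned multi-variable raster stacks with spatial
structure (linear lat/lon gradients plus Gaussian-smoothed noise) and virtual
species whose true suitability is a product of independent Gaussian response
curves. Sampling occurrences from a known suitability surface lets every
downstream stage — variable pruning, model fitting, ensembling, thresholding,
change accounting — be validated against a ground truth that real occurrence
data never provides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Raster, RasterGrid, RasterStack


class ConfigurationError(ValueError):
    """Invalid synthetic-data specification."""


class SamplingError(RuntimeError):
    """Occurrence sampling cannot satisfy the request."""


@dataclass(frozen=True)
class SyntheticEnvironmentSpec:
    """Recipe for a synthetic environmental stack.

    Parameters
    ----------
    n_vars
        Number of environmental variables (named ``env1`` .. ``env{n}``).
    grid_shape
        (rows, cols), both >= 2.
    extent
        (west, south, east, north) in decimal degrees, inside WGS 84 bounds;
        must give square cells for the grid shape. Default: a South-America-
        like box anchored at (-75, -20) with 0.5 degree cells (finer if the
        grid would overflow the valid latitude range).
    spatial_smoothness
        Standard deviation, in cells, of the Gaussian filter applied to the
        white-noise component. 0 = unsmoothed noise.
    correlated_pairs
        Triples (var_i, var_j, target_rho): var_j is rebuilt as a copula-style
        mixture with var_i so the realized Spearman correlation lands within
        about +/-0.1 of target_rho.
    seed
        All fields are deterministic functions of this seed.
    """

    n_vars: int
    grid_shape: tuple[int, int]
    extent: tuple[float, float, float, float] | None = None
    spatial_smoothness: float = 2.0
    correlated_pairs: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vars < 1:
            raise ConfigurationError("n_vars must be >= 1")
        rows, cols = self.grid_shape
        if rows < 2 or cols < 2:
            raise ConfigurationError("grid_shape must be at least 2 x 2")
        if self.extent is None:
            cell = min(0.5, 100.0 / rows, 100.0 / cols)
            object.__setattr__(self, "extent",
                               (-75.0, -20.0, -75.0 + cols * cell, -20.0 + rows * cell))
        w, s, e, n = self.extent
        if not (-180.0 <= w < e <= 180.0 and -90.0 <= s < n <= 90.0):
            raise ConfigurationError("extent must be a valid box inside [-180,180] x [-90,90]")
        if self.spatial_smoothness < 0:
            raise ConfigurationError("spatial_smoothness must be nonnegative")
        names = {f"env{i + 1}" for i in range(self.n_vars)}
        seen_targets: set[str] = set()
        for vi, vj, rho in self.correlated_pairs:
            if vi not in names or vj not in names or vi == vj:
                raise ConfigurationError(f"bad correlated pair ({vi}, {vj})")
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError("target rho must be in [-1, 1]")
            if vj in seen_targets:
                raise ConfigurationError(f"variable {vj} is the target of two pairs")
            seen_targets.add(vj)
        # normalize to tuple so the spec is hashable regardless of input container
        object.__setattr__(self, "correlated_pairs", tuple((a, b, float(r)) for a, b, r in self.correlated_pairs))
        object.__setattr__(self, "grid_shape", tuple(self.grid_shape))
        object.__setattr__(self, "extent", tuple(float(x) for x in self.extent))


@dataclass(frozen=True)
class VirtualSpeciesSpec:
    """A species with a known Gaussian-product niche.

    optima / breadths are per-variable maps (same keys); breadths are the
    sigma of each Gaussian response, in the variable's units.
    """

    species_id: str
    optima: dict[str, float]
    breadths: dict[str, float]
    n_presences: int = 100
    sampling_mode: str = "probabilistic"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.optima) != set(self.breadths):
            raise ConfigurationError("optima and breadths must share the same variable keys")
        if not self.optima:
            raise ConfigurationError("at least one niche variable required")
        if any(s <= 0 for s in self.breadths.values()):
            raise ConfigurationError("all niche breadths must be > 0")
        if self.n_presences < 1:
            raise ConfigurationError("n_presences must be >= 1")
        if self.sampling_mode not in ("probabilistic", "top_cells"):
            raise ConfigurationError(f"unknown sampling_mode {self.sampling_mode!r}")


def _standardize(field2d: np.ndarray) -> np.ndarray:
    sd = field2d.std()
    if sd == 0:
        return np.zeros_like(field2d)
    return (field2d - field2d.mean()) / sd


def _latent_field(rng: np.random.Generator, shape: tuple[int, int], smooth: float,
                  lat_n: np.ndarray, lon_n: np.ndarray) -> np.ndarray:
    """One standardized field: lat/lon gradient + smoothed Gaussian noise."""
    a_lat, a_lon = rng.uniform(-1.0, 1.0, size=2)
    noise = rng.standard_normal(shape)
    if smooth > 0:
        noise = ndimage.gaussian_filter(noise, sigma=smooth, mode="nearest")
    noise = _standardize(noise)
    return _standardize(a_lat * lat_n + a_lon * lon_n + noise)


def generate_environment(spec: SyntheticEnvironmentSpec) -> RasterStack:
    """Build a deterministic synthetic environmental stack.

    Each variable is offset + 10 * z where z is a standardized latent field.
    For a correlated pair (i, j, rho) the latent field of j is replaced by
    ``r*z_i + sqrt(1-r^2)*z_j`` with the Pearson mixing weight
    ``r = 2 sin(pi * rho / 6)`` — the Gaussian-copula relation between
    Pearson and Spearman correlation — so the realized rank correlation
    tracks the target.
    """
    rows, cols = spec.grid_shape
    w, s, e, n = spec.extent
    grid = RasterGrid(n_rows=rows, n_cols=cols, west=w, south=s, east=e, north=n)
    rng = np.random.default_rng(spec.seed)

    lat = grid.lat_centers()[:, None] * np.ones((1, cols))
    lon = np.ones((rows, 1)) * grid.lon_centers()[None, :]
    lat_n, lon_n = _standardize(lat), _standardize(lon)

    names = [f"env{i + 1}" for i in range(spec.n_vars)]
    latents = {name: _latent_field(rng, (rows, cols), spec.spatial_smoothness, lat_n, lon_n)
               for name in names}
    for vi, vj, rho in spec.correlated_pairs:
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        mixed = r * latents[vi] + np.sqrt(max(0.0, 1.0 - r * r)) * latents[vj]
        latents[vj] = _standardize(mixed)

    variables = {name: 20.0 * (i + 1) + 10.0 * latents[name] for i, name in enumerate(names)}
    return RasterStack(grid=grid, variables=variables, period_label="present",
                       source_model_label="observed")


def true_suitability(env: RasterStack, vs: VirtualSpeciesSpec) -> Raster:
    """Ground-truth suitability: product of Gaussian responses.

    S(cell) = prod_v exp(-(e_v - mu_v)^2 / (2 sigma_v^2)); S in (0, 1] with
    S = 1 exactly when every variable sits at its optimum.
    """
    missing = [v for v in vs.optima if v not in env.variables]
    if missing:
        raise ConfigurationError(f"environment lacks niche variables: {missing}")
    log_s = np.zeros(env.grid.shape)
    for v, mu in vs.optima.items():
        sigma = vs.breadths[v]
        log_s = log_s - (env.variables[v] - mu) ** 2 / (2.0 * sigma**2)
    suit = np.exp(log_s)
    suit[~env.mask] = np.nan
    return Raster(grid=env.grid, values=suit)


def perturb_environment(stack: RasterStack, shifts: dict[str, float],
                        period_label: str, source_model_label: str = "observed") -> RasterStack:
    """Additively shift variables to emulate a climate-scenario stack."""
    variables = {name: arr + shifts.get(name, 0.0) for name, arr in stack.variables.items()}
    return RasterStack(grid=stack.grid, variables=variables,
                       period_label=period_label, source_model_label=source_model_label)


def sample_occurrences(suit: Raster, vs: VirtualSpeciesSpec) -> pd.DataFrame:
    """Draw presence records from a suitability surface.

    probabilistic mode draws ``n_presences`` distinct cells with inclusion
    probability proportional to suitability; top_cells takes the
    highest-suitability cells, ties broken by row-major order. Records are
    placed at cell centers with source = "synthetic".
    """
    values = suit.values.ravel()
    valid = ~np.isnan(values)
    positive = np.flatnonzero(valid & (values > 0))
    n = vs.n_presences
    if n > positive.size:
        raise SamplingError(
            f"requested {n} presences but only {positive.size} cells have positive suitability")

    if vs.sampling_mode == "top_cells":
        s = values[positive]
        order = np.lexsort((positive, -s))  # primary: descending suitability; ties: row-major
        chosen = positive[order[:n]]
    else:
        rng = np.random.default_rng(vs.seed)
        p = values[positive] / values[positive].sum()
        chosen = rng.choice(positive, size=n, replace=False, p=p)
        chosen = np.sort(chosen)

    rows, cols = suit.grid.unflatten(chosen)
    lons, lats = [], []
    for r, c in zip(rows, cols):
        lon, lat = suit.grid.cell_center(int(r), int(c))
        lons.append(lon)
        lats.append(lat)
    return pd.DataFrame({
        "species": vs.species_id,
        "longitude": lons,
        "latitude": lats,
        "source": "synthetic",
    })
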