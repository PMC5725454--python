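"""Self-consistent synthetic ocean world for tracer-inversion diagnostics.

This module builds a small latitude(-longitude)-depth box ocean with

* a mass-conserving advective-diffusive transport operator driven by a
  prescribed meridional overturning streamfunction (subtropical downwelling,
  equatorial and subpolar upwelling),
* a known "truth" biological scenario: surface-intensified net DOC
  production balanced by slow first-order interior consumption, and
  surface nitrate uptake balanced by relaxation toward a deep reservoir,
* steady-state DOC-like and nitrate-like tracer fields obtained by a
  forward solve of the same linear physics used by the diagnostics,
* sparse, noisy, surface-biased observations of those fields, and
* ancillary surface fields (SST, NPP, picoplankton fraction, satellite-style
  carbon export) with the covariance structure the downstream regression
  analysis assumes.

Because the truth is known exactly, every downstream stage (gap-filling,
restoring inversion, export solve, Monte Carlo, regional regression) can be
tested as a parameter-recovery problem.

Units: concentrations µmol kg⁻¹, rates µmol kg⁻¹ yr⁻¹, transport yr⁻¹,
depths m (positive downward), masses kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "Grid",
    "TransportMatrix",
    "TruthScenario",
    "ObservationSet",
    "AncillaryFields",
    "Scenario",
    "ConfigurationError",
    "AssemblyError",
    "ScenarioError",
    "build_grid",
    "build_transport",
    "transport_ensemble",
    "forward_steady_state",
    "sample_observations",
    "generate_ancillary",
    "make_scenario",
    "DEFAULT_LAYER_BOTTOMS",
]

EARTH_RADIUS_M = 6.371e6
SECONDS_PER_YEAR = 3.15576e7  # Julian year
SV_TO_M3_PER_YEAR = 1.0e6 * SECONDS_PER_YEAR
DEFAULT_DENSITY = 1025.0  # kg m⁻³

#: 24 layer bottoms (m); the first two interfaces, 36 m and 74 m, are the
#: surface-partition depths used throughout the diagnostics.
DEFAULT_LAYER_BOTTOMS = (
    36.0, 74.0, 120.0, 175.0, 240.0, 320.0, 420.0, 540.0,
    680.0, 840.0, 1020.0, 1220.0, 1440.0, 1680.0, 1940.0, 2220.0,
    2520.0, 2840.0, 3180.0, 3540.0, 3920.0, 4320.0, 4740.0, 5180.0,
)

DEFAULT_BASINS_3 = ("Atlantic", "Pacific", "Indian")


class ConfigurationError(ValueError):
    """Invalid grid or scenario configuration."""


class AssemblyError(RuntimeError):
    """Transport operator violated a conservation invariant after assembly."""


class ScenarioError(RuntimeError):
    """A truth scenario produced an unphysical or unsolvable system."""


# --------------------------------------------------------------------------
# Grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Box geometry of the synthetic ocean.

    Boxes are ordered column-major: ``index = icol * nz + iz`` with
    ``icol = ilat * n_lon + ilon`` and ``iz`` increasing downward.
    """

    lat_edges: np.ndarray          # (n_lat+1,) deg
    basins: tuple[str, ...]        # per lon slice
    layer_bottoms: np.ndarray      # (nz,) m
    density: np.ndarray            # (n_box,) kg m⁻³
    euphotic_depth: np.ndarray     # (n_col,) m

    # ---- sizes -----------------------------------------------------------
    @property
    def n_lat(self) -> int:
        return len(self.lat_edges) - 1

    @property
    def n_lon(self) -> int:
        return len(self.basins)

    @property
    def nz(self) -> int:
        return len(self.layer_bottoms)

    @property
    def n_col(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def n_box(self) -> int:
        return self.n_col * self.nz

    # ---- geometry --------------------------------------------------------
    @property
    def lat(self) -> np.ndarray:
        """Latitude of box centers, deg (n_lat,)."""
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def layer_tops(self) -> np.ndarray:
        return np.concatenate([[0.0], self.layer_bottoms[:-1]])

    @property
    def thickness(self) -> np.ndarray:
        return self.layer_bottoms - self.layer_tops

    @property
    def z_center(self) -> np.ndarray:
        return 0.5 * (self.layer_tops + self.layer_bottoms)

    @property
    def col_lat(self) -> np.ndarray:
        """Latitude per column (n_col,)."""
        return np.repeat(self.lat, self.n_lon)

    @property
    def col_basin(self) -> np.ndarray:
        """Basin label per column (n_col,)."""
        return np.tile(np.asarray(self.basins, dtype=object), self.n_lat)

    @property
    def box_area(self) -> np.ndarray:
        """Horizontal footprint per column, m² (n_col,)."""
        phi = np.deg2rad(self.lat_edges)
        band = EARTH_RADIUS_M**2 * (2.0 * np.pi / self.n_lon) * np.diff(np.sin(phi))
        return np.repeat(band, self.n_lon)

    @property
    def volume(self) -> np.ndarray:
        """Box volumes, m³ (n_box,)."""
        return np.outer(self.box_area, self.thickness).ravel()

    @property
    def mass(self) -> np.ndarray:
        """Box seawater masses, kg (n_box,)."""
        return self.volume * self.density

    @property
    def box_depth(self) -> np.ndarray:
        """Center depth per box, m (n_box,)."""
        return np.tile(self.z_center, self.n_col)

    @property
    def box_layer(self) -> np.ndarray:
        """Layer index per box (n_box,)."""
        return np.tile(np.arange(self.nz), self.n_col)

    @property
    def box_col(self) -> np.ndarray:
        """Column index per box (n_box,)."""
        return np.repeat(np.arange(self.n_col), self.nz)

    @property
    def box_lat(self) -> np.ndarray:
        return self.col_lat[self.box_col]

    @property
    def box_basin(self) -> np.ndarray:
        return self.col_basin[self.box_col]

    @property
    def bottom_depth(self) -> float:
        return float(self.layer_bottoms[-1])

    def box_index(self, icol: int | np.ndarray, iz: int | np.ndarray) -> np.ndarray:
        return np.asarray(icol) * self.nz + np.asarray(iz)

    def column_of(self, ilat: int, ilon: int) -> int:
        return ilat * self.n_lon + ilon

    def to_column(self, per_box: np.ndarray) -> np.ndarray:
        """Reshape a flat per-box array to (n_col, nz)."""
        return np.asarray(per_box).reshape(self.n_col, self.nz)


def _default_euphotic_depth(lat: np.ndarray) -> np.ndarray:
    """Deep euphotic zone in the clear subtropical gyres, shallow elsewhere."""
    return 45.0 + 55.0 * np.exp(-(((np.abs(lat) - 30.0) / 18.0) ** 2))


def build_grid(
    n_lat: int = 36,
    n_lon: int = 3,
    layer_bottoms: Sequence[float] | None = None,
    density: float | np.ndarray = DEFAULT_DENSITY,
    lat_extent: float = 80.0,
    basins: Sequence[str] | None = None,
    euphotic_depth: np.ndarray | Callable[[np.ndarray], np.ndarray] | None = None,
) -> Grid:
    """Build a flat-bottomed latitude(-longitude)-depth box grid.

    Parameters
    ----------
    n_lat, n_lon
        Number of latitude bands (≥ 4) between ``±lat_extent`` and of
        longitude sectors (each sector is one "basin").
    layer_bottoms
        Increasing depths of layer bottoms (m).  The defaults place the
        bottoms of layers 1 and 2 at 36 m and 74 m, the two fixed
        surface-partition depths; any custom list must keep those two
        interfaces.
    density
        Seawater density, scalar or per box (kg m⁻³).
    euphotic_depth
        Per-column euphotic depth (m), or a callable of column latitude;
        defaults to a subtropical-maximum profile.
    """
    if n_lat < 4:
        raise ConfigurationError(f"n_lat must be >= 4, got {n_lat}")
    if n_lon < 1:
        raise ConfigurationError(f"n_lon must be >= 1, got {n_lon}")
    bottoms = np.asarray(
        DEFAULT_LAYER_BOTTOMS if layer_bottoms is None else layer_bottoms, dtype=float
    )
    if bottoms.ndim != 1 or len(bottoms) < 2:
        raise ConfigurationError("layer_bottoms must be a 1-D sequence of >= 2 depths")
    if not np.all(np.diff(bottoms) > 0) or bottoms[0] <= 0:
        raise ConfigurationError(f"layer_bottoms must be positive and strictly increasing: {bottoms}")
    for required in (36.0, 74.0):
        if not np.any(np.isclose(bottoms, required)):
            raise ConfigurationError(
                f"layer_bottoms must contain the {required:g} m surface interface"
            )

    if basins is None:
        basins = DEFAULT_BASINS_3 if n_lon == 3 else tuple(f"basin{j}" for j in range(n_lon))
    basins = tuple(basins)
    if len(basins) != n_lon:
        raise ConfigurationError("len(basins) must equal n_lon")

    lat_edges = np.linspace(-lat_extent, lat_extent, n_lat + 1)
    n_box = n_lat * n_lon * len(bottoms)
    rho = np.broadcast_to(np.asarray(density, dtype=float), (n_box,)).copy()
    if np.any(rho <= 0):
        raise ConfigurationError("density must be positive")

    lat_centers = np.repeat(0.5 * (lat_edges[:-1] + lat_edges[1:]), n_lon)
    if euphotic_depth is None:
        zeu = np.minimum(_default_euphotic_depth(lat_centers), bottoms[-1])
    elif callable(euphotic_depth):
        zeu = np.asarray(euphotic_depth(lat_centers), dtype=float)
    else:
        zeu = np.broadcast_to(np.asarray(euphotic_depth, dtype=float), (n_lat * n_lon,)).copy()
    if np.any(zeu <= 0) or np.any(zeu > bottoms[-1]):
        raise ConfigurationError("euphotic_depth must lie within the water column")

    return Grid(
        lat_edges=lat_edges,
        basins=basins,
        layer_bottoms=bottoms,
        density=rho,
        euphotic_depth=zeu,
    )


# --------------------------------------------------------------------------
# Transport
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportMatrix:
    """Sparse advective-diffusive operator ``T`` (yr⁻¹) over all boxes.

    ``dC/dt = T @ C`` for a concentration vector in µmol kg⁻¹.  Invariants
    (checked at assembly): ``mass.T @ T == 0`` (total tracer mass conserved),
    ``T @ 1 == 0`` (uniform fields are steady), off-diagonals ≥ 0.
    """

    T: sp.csr_matrix
    grid: Grid
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_box(self) -> int:
        return self.T.shape[0]


def _streamfunction(grid: Grid, overturning_sv: float) -> np.ndarray:
    """Volume-transport streamfunction (m³ yr⁻¹) on (lat-edge, interface) nodes.

    The single harmonic ``sin(3π φ̂)`` in normalized latitude gives upwelling
    at the equator and near ±55° and downwelling centered on ±30°.  The
    vertical shape vanishes at the surface and the bottom and concentrates
    the cells in the upper ocean (e-folding 500 m), as wind-driven
    overturning does, so convergence and divergence are felt at the
    74 m export depth.
    """
    lat_hat = grid.lat_edges / grid.lat_edges[-1]          # (n_lat+1,) in [-1, 1]
    interfaces = np.concatenate([[0.0], grid.layer_bottoms])
    zeta = (1.0 - np.exp(-interfaces / 500.0)) / (1.0 - np.exp(-interfaces[-1] / 500.0))
    psi0 = overturning_sv * SV_TO_M3_PER_YEAR
    return psi0 * np.outer(np.sin(3.0 * np.pi * lat_hat), np.sin(np.pi * zeta))


def _check_invariants(T: sp.spmatrix, mass: np.ndarray, rtol: float = 1e-10) -> None:
    A = abs(T)
    scale_col = (mass @ A).max()
    scale_row = np.asarray(A.sum(axis=1)).ravel().max()
    if scale_row == 0.0:  # zero operator: trivially conservative
        return
    col_defect = np.abs(mass @ T).max() / scale_col
    row_defect = np.abs(T @ np.ones(T.shape[0])).max() / scale_row
    if col_defect > rtol or row_defect > rtol:
        raise AssemblyError(
            f"transport assembly violated conservation: mass-column defect "
            f"{col_defect:.3e}, row-sum defect {row_defect:.3e} (rtol {rtol:g})"
        )
    off = T - sp.diags(T.diagonal())
    if off.nnz and off.min() < -1e-13 * scale_row:
        raise AssemblyError("negative off-diagonal transport entry (non-monotone stencil)")


def build_transport(
    grid: Grid,
    overturning_sv: float = 20.0,
    kh: float = 1.0e3,
    kv: float = 2.0e-5,
    zonal_mixing_factor: float = 0.25,
    psi_noise: float = 0.0,
    diffusivity_factor: float = 1.0,
    seed: int | None = None,
) -> TransportMatrix:
    """Assemble the transport operator from a streamfunction and diffusivities.

    Parameters
    ----------
    overturning_sv
        Peak meridional overturning (Sv).  Zero disables advection.
    kh, kv
        Isopycnal (horizontal, m² s⁻¹) and diapycnal (vertical, m² s⁻¹)
        diffusivities.  Zero disables diffusion.
    zonal_mixing_factor
        Zonal diffusivity as a fraction of ``kh``; keeps longitude sectors
        ("basins") weakly connected.
    psi_noise
        Node-wise multiplicative perturbation amplitude of the streamfunction
        (used by :func:`transport_ensemble`).  Fluxes are differences of the
        perturbed streamfunction, so mass conservation survives exactly.
    """
    if overturning_sv < 0 or kh < 0 or kv < 0:
        raise ConfigurationError("overturning and diffusivities must be >= 0")

    n_lat, n_lon, nz = grid.n_lat, grid.n_lon, grid.nz
    mass = grid.mass
    rho0 = float(grid.density.mean())  # reference density for the mass streamfunction
    rng = np.random.default_rng(seed)

    psi = _streamfunction(grid, overturning_sv)
    if psi_noise > 0.0:
        psi = psi * (1.0 + psi_noise * rng.uniform(-1.0, 1.0, size=psi.shape))
    kh_eff = kh * diffusivity_factor
    kv_eff = kv * diffusivity_factor

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add_entries(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=float))

    def add_advection(i_from: np.ndarray, i_to: np.ndarray, flux_mass: np.ndarray):
        """Upwind transfer of water mass flux (kg yr⁻¹), signed from→to."""
        pos = flux_mass >= 0
        donor = np.where(pos, i_from, i_to)
        recv = np.where(pos, i_to, i_from)
        f = np.abs(flux_mass)
        keep = f > 0
        donor, recv, f = donor[keep], recv[keep], f[keep]
        add_entries(recv, donor, f / mass[recv])
        add_entries(donor, donor, -f / mass[donor])

    def add_exchange(i_a: np.ndarray, i_b: np.ndarray, g_mass: np.ndarray):
        """Symmetric diffusive exchange with conductance g (kg yr⁻¹)."""
        keep = g_mass > 0
        a, b, g = i_a[keep], i_b[keep], g_mass[keep]
        add_entries(a, b, g / mass[a])
        add_entries(a, a, -g / mass[a])
        add_entries(b, a, g / mass[b])
        add_entries(b, b, -g / mass[b])

    icol_grid = np.arange(n_lat * n_lon).reshape(n_lat, n_lon)

    # -- advection from the streamfunction (per lon slice) ------------------
    if overturning_sv > 0:
        # vertical faces: interface k (1..nz-1) between layers k-1 (above) and k
        for k in range(1, nz):
            f_up = (psi[1:, k] - psi[:-1, k]) / n_lon        # (n_lat,) m³ yr⁻¹, + up
            for j in range(n_lon):
                cols_j = icol_grid[:, j]
                lower = grid.box_index(cols_j, k)
                upper = grid.box_index(cols_j, k - 1)
                add_advection(lower, upper, f_up * rho0)
        # meridional faces: lat edge i (1..n_lat-1) between bands i-1 and i
        for i in range(1, n_lat):
            f_north = (psi[i, 1:] - psi[i, :-1]) / n_lon     # (nz,) m³ yr⁻¹, + north
            for j in range(n_lon):
                south = grid.box_index(icol_grid[i - 1, j], np.arange(nz))
                north = grid.box_index(icol_grid[i, j], np.arange(nz))
                add_advection(south, north, f_north * rho0)

    # -- diffusion -----------------------------------------------------------
    area_col = grid.box_area
    thick = grid.thickness
    zc = grid.z_center
    dphi = np.deg2rad(np.diff(grid.lat_edges))
    dy = EARTH_RADIUS_M * dphi  # (n_lat,) meridional box extent

    if kv_eff > 0:
        for k in range(1, nz):
            dz = zc[k] - zc[k - 1]
            g = kv_eff * SECONDS_PER_YEAR * area_col / dz * rho0  # (n_col,)
            cols_all = np.arange(n_lat * n_lon)
            add_exchange(grid.box_index(cols_all, k - 1), grid.box_index(cols_all, k), g)

    if kh_eff > 0:
        dlam = 2.0 * np.pi / n_lon
        for i in range(1, n_lat):
            width = EARTH_RADIUS_M * dlam * np.cos(np.deg2rad(grid.lat_edges[i]))
            dist = 0.5 * (dy[i - 1] + dy[i])
            g_k = kh_eff * SECONDS_PER_YEAR * width * thick / dist * rho0  # (nz,)
            for j in range(n_lon):
                south = grid.box_index(icol_grid[i - 1, j], np.arange(nz))
                north = grid.box_index(icol_grid[i, j], np.arange(nz))
                add_exchange(south, north, g_k)

    if kh_eff > 0 and zonal_mixing_factor > 0 and n_lon >= 2:
        # adjacent lon sectors, wrapping into a ring when n_lon >= 3
        pairs = [(j, j + 1) for j in range(n_lon - 1)]
        if n_lon >= 3:
            pairs.append((n_lon - 1, 0))
        for i in range(n_lat):
            dx = (2.0 * np.pi / n_lon) * EARTH_RADIUS_M * np.cos(np.deg2rad(grid.lat[i]))
            face = dy[i] * thick  # (nz,) m²
            g_k = zonal_mixing_factor * kh_eff * SECONDS_PER_YEAR * face / dx * rho0
            for ja, jb in pairs:
                a = grid.box_index(icol_grid[i, ja], np.arange(nz))
                b = grid.box_index(icol_grid[i, jb], np.arange(nz))
                add_exchange(a, b, g_k)

    if rows:
        T = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(grid.n_box, grid.n_box),
        ).tocsr()
    else:
        T = sp.csr_matrix((grid.n_box, grid.n_box))

    _check_invariants(T, mass)
    params = dict(
        overturning_sv=overturning_sv, kh=kh, kv=kv,
        zonal_mixing_factor=zonal_mixing_factor, psi_noise=psi_noise,
        diffusivity_factor=diffusivity_factor,
    )
    return TransportMatrix(T=T, grid=grid, params=params, seed=seed)


def transport_ensemble(
    grid: Grid,
    n_members: int = 10,
    seed: int = 0,
    amplitude: float = 0.1,
    **params,
) -> list[TransportMatrix]:
    """Ensemble of perturbed circulations emulating alternative data constraints.

    Each member perturbs the streamfunction node-wise and the diffusivities
    globally by ``±amplitude`` (default ±10%).  Fluxes are re-derived from the
    perturbed streamfunction, so every member satisfies the conservation
    invariants exactly.
    """
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n_members):
        member_seed = int(rng.integers(0, 2**31 - 1))
        dfac = 1.0 + amplitude * float(np.random.default_rng(member_seed + 1).uniform(-1, 1))
        members.append(
            build_transport(
                grid, psi_noise=amplitude, diffusivity_factor=dfac,
                seed=member_seed, **params,
            )
        )
    return members


# --------------------------------------------------------------------------
# Truth scenarios and forward solves
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthScenario:
    """Known biological truth of the synthetic world.

    ``j_prod`` is the prescribed DOC production (µmol C kg⁻¹ yr⁻¹, zero below
    the production depth); ``uptake`` the prescribed nitrate uptake
    (µmol N kg⁻¹ yr⁻¹, ≥ 0, same support).  Interior closure is first-order:
    DOC anomalies decay at ``lam_doc`` toward a constant refractory floor,
    and nitrate relaxes at ``lam_no3`` toward a prescribed nutricline profile
    (remineralization), which keeps the forward operator invertible.
    """

    j_prod: np.ndarray          # (n_box,) µmol C kg⁻¹ yr⁻¹
    uptake: np.ndarray          # (n_box,) µmol N kg⁻¹ yr⁻¹ (magnitude of uptake)
    lam_doc: float              # yr⁻¹
    lam_no3: float              # yr⁻¹
    background_doc: np.ndarray  # (n_box,) µmol kg⁻¹ refractory floor
    background_no3: np.ndarray  # (n_box,) µmol kg⁻¹ relaxation nutricline
    production_depth: float     # m; j_prod and uptake vanish below this
    seed: int | None = None

    def net_production(self, doc: np.ndarray) -> np.ndarray:
        """Net DOC source per box: production minus first-order consumption."""
        return self.j_prod - self.lam_doc * (np.asarray(doc) - self.background_doc)

    def net_uptake(self, no3: np.ndarray) -> np.ndarray:
        """Net nitrate uptake per box: uptake minus regeneration."""
        return self.uptake + self.lam_no3 * (np.asarray(no3) - self.background_no3)


def nitrate_relaxation_profile(
    grid: Grid,
    deep_no3: float = 30.0,
    nutricline_scale: float = 150.0,
) -> np.ndarray:
    """Climatological nitrate structure the regeneration closure relaxes toward.

    An exponential nutricline whose surface end-member rises toward the
    poles (weakly stratified high latitudes), so subpolar surface waters stay
    nutrient-rich while the subtropical target is low enough for uptake to
    carve oligotrophic gyres.
    """
    lat_hat = np.abs(grid.box_lat) / grid.lat_edges[-1]
    surface = deep_no3 * (0.10 + 0.80 * lat_hat**1.5)
    return surface + (deep_no3 - surface) * (1.0 - np.exp(-grid.box_depth / nutricline_scale))


def _zonal_modulation(grid: Grid) -> np.ndarray:
    """Deterministic basin-contrast pattern per column, in [-1, 1]."""
    ilon = np.tile(np.arange(grid.n_lon), grid.n_lat)
    return np.cos(2.0 * np.pi * ilon / max(grid.n_lon, 1) + grid.col_lat / 40.0)


def _production_pattern(grid: Grid) -> np.ndarray:
    """Horizontal production shape: subtropical maxima at ±28°."""
    lat = grid.col_lat
    return 0.3 + np.exp(-(((np.abs(lat) - 28.0) / 14.0) ** 2))


def default_truth(
    grid: Grid,
    production_scale: float = 5.0,
    uptake_scale: float = 4.2,
    doc_layer_weights: tuple[float, float] = (0.75, 0.25),
    no3_layer_weights: tuple[float, float] = (0.25, 0.75),
    production_modulation: float = 0.08,
    uptake_modulation: float = 0.008,
    lam_doc: float = 0.1,
    lam_no3: float = 0.25,
    background_doc: float = 40.0,
    deep_no3: float = 30.0,
    nutricline_scale: float = 150.0,
    seed: int | None = None,
) -> TruthScenario:
    """Default truth of the reference world.

    DOC production peaks in the subtropical gyres and is surface-intensified
    (layer weights 0.75/0.25 over the two layers above 74 m), while nitrate
    uptake is deeper (0.35/0.65, a crude deep-chlorophyll-maximum), so the
    production:uptake ratio decreases with the depth of the surface
    definition.  The nitrate relaxation target follows an exponential
    nutricline from ``surface_no3`` to ``deep_no3``.
    """
    pattern = _production_pattern(grid)
    mod = _zonal_modulation(grid)
    prod_col = pattern * (1.0 + production_modulation * mod)
    upt_col = pattern * (1.0 + uptake_modulation * mod)

    j_prod = np.zeros((grid.n_col, grid.nz))
    uptake = np.zeros((grid.n_col, grid.nz))
    j_prod[:, 0] = production_scale * prod_col * doc_layer_weights[0] / 0.5
    j_prod[:, 1] = production_scale * prod_col * doc_layer_weights[1] / 0.5
    uptake[:, 0] = uptake_scale * upt_col * no3_layer_weights[0] / 0.5
    uptake[:, 1] = uptake_scale * upt_col * no3_layer_weights[1] / 0.5

    bg_no3 = nitrate_relaxation_profile(grid, deep_no3, nutricline_scale)
    return TruthScenario(
        j_prod=j_prod.ravel(),
        uptake=uptake.ravel(),
        lam_doc=lam_doc,
        lam_no3=lam_no3,
        background_doc=np.full(grid.n_box, background_doc),
        background_no3=bg_no3,
        production_depth=74.0,
        seed=seed,
    )


def forward_steady_state(
    transport: TransportMatrix,
    truth: TruthScenario,
    tracer: str = "doc",
    rtol: float = 1e-8,
) -> np.ndarray:
    """Steady-state tracer field of the truth scenario.

    Solves ``0 = T C + S - λ (C - background)`` where ``S = j_prod`` for DOC
    and ``S = -uptake`` for nitrate; returns ``C = background + anomaly``.
    """
    if tracer not in ("doc", "no3"):
        raise ValueError(f"tracer must be 'doc' or 'no3', got {tracer!r}")
    lam = truth.lam_doc if tracer == "doc" else truth.lam_no3
    if lam <= 0:
        raise ScenarioError(
            "first-order interior rate must be positive: a zero rate leaves the "
            "steady state defined only up to a constant (pin a reference box "
            "or use lam > 0)"
        )
    source = truth.j_prod if tracer == "doc" else -truth.uptake
    background = truth.background_doc if tracer == "doc" else truth.background_no3

    n = transport.n_box
    A = (sp.diags(np.full(n, lam)) - transport.T).tocsc()
    rhs = source + transport.T @ background
    anomaly = splu(A).solve(rhs)
    resid = np.linalg.norm(transport.T @ anomaly + rhs - lam * anomaly)
    scale = np.linalg.norm(rhs)
    if scale > 0 and resid / scale > rtol:
        raise ScenarioError(f"forward solve residual {resid / scale:.3e} exceeds rtol {rtol:g}")
    C = background + anomaly
    if C.min() < 0:
        raise ScenarioError(
            f"forward {tracer} field went negative (min {C.min():.3g}); reduce "
            "uptake_scale or raise the background concentration"
        )
    return C


# --------------------------------------------------------------------------
# Observations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservationSet:
    """Sparse noisy point observations on grid boxes."""

    box_index: np.ndarray      # (n_obs,) int
    values: np.ndarray         # (n_obs,) µmol kg⁻¹
    fraction: float
    noise_sd: float
    withheld_basins: tuple[str, ...]
    seed: int | None

    def __len__(self) -> int:
        return len(self.box_index)


def sample_observations(
    field_values: np.ndarray,
    grid: Grid,
    fraction: float = 0.05,
    noise_sd: float = 2.0,
    withheld_basins: Sequence[str] = (),
    surface_bias_scale: float | None = 500.0,
    noise_surface_amplification: float = 1.0,
    seed: int | None = None,
) -> ObservationSet:
    """Sample sparse noisy observations of a per-box field.

    ``fraction`` is the expected fraction of boxes observed.  When
    ``surface_bias_scale`` is set, sampling probability decays with depth as
    ``exp(-z / scale)`` (renormalized), emulating the upper-ocean bias of real
    DOC data sets.  ``noise_surface_amplification`` > 1 scales the noise sd
    from ``noise_sd`` in the deep ocean up to ``noise_sd * amplification`` at
    the surface (e-folding 300 m), mirroring the depth structure of real
    measurement/representativeness error.  Deterministic under a fixed seed.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    values = np.asarray(field_values, dtype=float)
    if values.shape != (grid.n_box,):
        raise ConfigurationError("field must be a flat per-box array")

    rng = np.random.default_rng(seed)
    if surface_bias_scale:
        w = np.exp(-grid.box_depth / surface_bias_scale)
        p = np.minimum(fraction * w / w.mean(), 1.0)
    else:
        p = np.full(grid.n_box, fraction)
    if fraction == 1.0 and noise_sd == 0.0:
        keep = np.ones(grid.n_box, dtype=bool)
    else:
        keep = rng.uniform(size=grid.n_box) < p

    withheld = tuple(withheld_basins)
    unknown = set(withheld) - set(grid.basins)
    if unknown:
        raise ConfigurationError(f"unknown basins to withhold: {sorted(unknown)}")
    if withheld:
        keep &= ~np.isin(grid.box_basin, withheld)
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        raise ScenarioError("no observations remain after sampling/basin withholding")

    obs = values[idx].copy()
    if noise_sd > 0:
        sd = noise_sd * (
            1.0 + (noise_surface_amplification - 1.0) * np.exp(-grid.box_depth[idx] / 300.0)
        )
        obs = obs + sd * rng.standard_normal(len(idx))
    return ObservationSet(
        box_index=idx, values=obs, fraction=fraction, noise_sd=noise_sd,
        withheld_basins=withheld, seed=seed,
    )


# --------------------------------------------------------------------------
# Ancillary surface fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AncillaryFields:
    """Satellite-style surface fields per column plus the nitrate climatology."""

    sst: np.ndarray        # °C (n_col,)
    npp: np.ndarray        # gC m⁻² yr⁻¹ (n_col,)
    f_pico: np.ndarray     # [0, 1] (n_col,)
    c_export: np.ndarray   # gC m⁻² yr⁻¹ (n_col,)
    no3_clim: np.ndarray   # µmol kg⁻¹ (n_box,)
    seed: int | None = None


def default_pe_ratio(sst: np.ndarray, npp: np.ndarray) -> np.ndarray:
    """Built-in export ratio: monotone decreasing in SST, capped at 0.42."""
    return 0.42 * np.exp(-np.asarray(sst) / 20.0)


def default_export_algorithms(n_variants: int = 9):
    """Synthetic stand-ins for the satellite export-algorithm family.

    Returns ``n_variants`` callables ``(npp, sst) -> export`` that scale the
    built-in export ratio by factors spread ±20% around one, emulating the
    spread among empirical NPP/export algorithm combinations.
    """
    factors = np.linspace(0.8, 1.2, n_variants)
    def make(f):
        return lambda npp, sst: f * default_pe_ratio(sst, npp) * np.asarray(npp)
    return [make(f) for f in factors]


def generate_ancillary(
    grid: Grid,
    no3: np.ndarray,
    seed: int | None = None,
    npp_scale: float = 400.0,
    npp_noise: float = 0.05,
) -> AncillaryFields:
    """Ancillary fields with the covariances the regional analysis assumes.

    NPP follows nutrient availability and light (high at the equator and in
    the subpolar gyres, low in the subtropics); the export ratio decreases
    with SST; the picoplankton fraction decreases with NPP, hence correlates
    negatively with nitrate.
    """
    rng = np.random.default_rng(seed)
    lat = grid.col_lat
    # small basin-dependent offset (Atlantic/Pacific/Indian contrast)
    sst = -1.0 + 29.0 * np.cos(np.deg2rad(lat)) ** 2 + 0.8 * _zonal_modulation(grid)

    no3_col = grid.to_column(np.asarray(no3))
    # thickness-weighted nitrate over the top 74 m (layers 1-2)
    w = grid.thickness[:2]
    no3_mean = no3_col[:, :2] @ w / w.sum()
    light = 0.3 + 0.7 * np.cos(np.deg2rad(lat)) ** 2
    npp = npp_scale * light * no3_mean / (no3_mean + 1.0)
    if npp_noise > 0:
        npp = npp * (1.0 + npp_noise * rng.uniform(-1, 1, size=npp.shape))
    npp = np.maximum(npp, 1.0)

    c_export = default_pe_ratio(sst, npp) * npp
    # picoplankton dominate stratified oligotrophic columns
    f_pico = np.clip(
        0.12 + 0.62 * np.exp(-no3_mean / 2.5)
        + 0.02 * rng.uniform(-1, 1, size=no3_mean.shape),
        0.0, 1.0,
    )
    return AncillaryFields(
        sst=sst, npp=npp, f_pico=f_pico, c_export=c_export,
        no3_clim=np.asarray(no3), seed=seed,
    )


# --------------------------------------------------------------------------
# The bundled default scenario
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A complete synthetic world: geometry, physics, truth, tracers, ancillary."""

    grid: Grid
    transport: TransportMatrix
    truth: TruthScenario
    doc: np.ndarray           # (n_box,) steady-state DOC, µmol kg⁻¹
    no3: np.ndarray           # (n_box,) steady-state nitrate, µmol kg⁻¹
    ancillary: AncillaryFields
    seed: int

    @property
    def temperature(self) -> np.ndarray:
        """A 3-D temperature field (°C per box) consistent with the SST."""
        sst_box = self.ancillary.sst[self.grid.box_col]
        return 2.0 + (sst_box - 2.0) * np.exp(-self.grid.box_depth / 800.0)

    def predictor_fields(self) -> dict[str, np.ndarray]:
        """Default ANN predictor fields on the full grid (all per box)."""
        g = self.grid
        return {
            "no3": self.no3,
            "temperature": self.temperature,
            "depth": g.box_depth,
            "euphotic_depth": g.euphotic_depth[g.box_col],
            "latitude_abs": np.abs(g.box_lat),
        }


def make_scenario(
    seed: int = 0,
    n_lat: int = 36,
    n_lon: int = 3,
    layer_bottoms: Sequence[float] | None = None,
    overturning_sv: float = 20.0,
    kh: float = 1.0e3,
    kv: float = 2.0e-5,
    **truth_kwargs,
) -> Scenario:
    """Build the reference synthetic world used by the test battery.

    Identical seeds reproduce bit-identical scenarios.
    """
    rng = np.random.default_rng(seed)
    grid = build_grid(n_lat=n_lat, n_lon=n_lon, layer_bottoms=layer_bottoms)
    transport = build_transport(grid, overturning_sv=overturning_sv, kh=kh, kv=kv)
    truth = default_truth(grid, seed=seed, **truth_kwargs)
    doc = forward_steady_state(transport, truth, "doc")
    no3 = forward_steady_state(transport, truth, "no3")
    ancillary = generate_ancillary(grid, no3, seed=int(rng.integers(0, 2**31 - 1)))
    return Scenario(
        grid=grid, transport=transport, truth=truth,
        doc=doc, no3=no3, ancillary=ancillary, seed=seed,
    )
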