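"""Steady-state restoring inversion for surface biological sources and sinks.

Given a transport matrix ``T`` (yr⁻¹) partitioned at a chosen surface depth,

    [dC_s/dt]   [T_ss T_si] [C_s]   [J]
    [dC_i/dt] = [T_is T_ii] [C_i] + [L] = 0,

the interior concentration is pinned to observations and the surface row is
closed by restoring the modeled surface concentration to observations with a
timescale τ:

    T_ss C_s + T_si C_i,obs + J = 0,
    J = (C_s,obs - C_s)/τ          (net DOC production, NDP)
    J = -(C_s - C_s,obs)/τ         (i.e. net nitrate uptake J_up = (C_s - C_s,obs)/τ)

so the diagnosed flux is the restoring tendency needed to hold the observed
surface field against circulation.  The linear system ``(T_ss - I/τ) C_s =
-T_si C_i,obs - C_s,obs/τ`` is strictly diagonally dominant for any
conservative ``T`` and τ > 0 and is solved by sparse direct factorization.

Supported surface definitions: the base of layer 1 (36 m), the base of layer
2 (74 m), or per column the base of the deepest layer not deeper than the
column's maximum euphotic depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .synthetic_ocean import ConfigurationError, Grid, TransportMatrix

__all__ = [
    "SurfacePartition",
    "RestoringSolution",
    "FluxField",
    "partition_matrix",
    "solve_restoring",
    "to_areal_flux",
    "diagnose_profile",
    "DEFAULT_TAU_YEARS",
    "ATOMIC_WEIGHT",
    "SolverError",
]

#: Midpoint of the 3-9 month restoring range used for uncertainty propagation.
DEFAULT_TAU_YEARS = 0.5

ATOMIC_WEIGHT = {"C": 12.011, "N": 14.007}  # g mol⁻¹

SURFACE_DEFINITIONS = ("36m", "74m", "euphotic")


class SolverError(RuntimeError):
    """A linear solve failed or exceeded its residual tolerance."""


@dataclass(frozen=True)
class SurfacePartition:
    """Index split of grid boxes into surface and interior, with the four
    transport blocks that tile ``T`` exactly."""

    definition: str
    grid: Grid
    surface_index: np.ndarray       # (n_s,) box indices, ascending
    interior_index: np.ndarray      # (n_i,) box indices, ascending
    n_surface_layers: np.ndarray    # (n_col,) layers counted as surface
    T_ss: sp.csr_matrix
    T_si: sp.csr_matrix
    T_is: sp.csr_matrix
    T_ii: sp.csr_matrix

    @property
    def n_surface(self) -> int:
        return len(self.surface_index)

    @property
    def surface_depth_per_column(self) -> np.ndarray:
        """Depth of the surface/interior interface per column (m)."""
        return self.grid.layer_bottoms[self.n_surface_layers - 1]

    def split(self, per_box: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a flat per-box field into (surface, interior) sub-vectors."""
        v = np.asarray(per_box)
        if v.shape != (self.grid.n_box,):
            raise ConfigurationError(
                f"expected a per-box field of length {self.grid.n_box}, got {v.shape}"
            )
        return v[self.surface_index], v[self.interior_index]

    def scatter_surface(self, surface_values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Embed a surface-subset vector back into a full per-box array."""
        out = np.full(self.grid.n_box, fill, dtype=float)
        out[self.surface_index] = surface_values
        return out

    def surface_column(self, surface_values: np.ndarray) -> np.ndarray:
        """Column index of each entry of a surface-subset vector."""
        return self.grid.box_col[self.surface_index]


def _surface_layer_count(grid: Grid, definition: str | float) -> np.ndarray:
    """Number of whole layers per column belonging to the surface."""
    bottoms = grid.layer_bottoms
    if isinstance(definition, str) and definition.endswith("m"):
        definition = float(definition[:-1])
    if definition == "euphotic":
        # base of the deepest layer not deeper than the column's euphotic max;
        # a euphotic depth shallower than layer 1 still keeps layer 1
        n = np.searchsorted(bottoms, grid.euphotic_depth + 1e-9, side="right")
        return np.maximum(n, 1).astype(int)
    depth = float(definition)
    matches = np.isclose(bottoms, depth)
    if not matches.any():
        raise ConfigurationError(
            f"surface definition {depth:g} m does not coincide with a layer "
            f"interface (layer bottoms: {bottoms.tolist()})"
        )
    return np.full(grid.n_col, int(np.flatnonzero(matches)[0]) + 1)


def partition_matrix(
    transport: TransportMatrix,
    surface_definition: str | float = "74m",
) -> SurfacePartition:
    """Partition ``T`` into surface/interior blocks at a surface definition.

    ``surface_definition`` is ``"36m"``, ``"74m"``, a layer-interface depth in
    meters, or ``"euphotic"`` (per-column euphotic maximum).  Reassembling the
    four blocks reproduces ``T`` exactly.
    """
    grid = transport.grid
    n_layers = _surface_layer_count(grid, surface_definition)
    is_surface = grid.box_layer < n_layers[grid.box_col]
    s_idx = np.flatnonzero(is_surface)
    i_idx = np.flatnonzero(~is_surface)
    T = transport.T.tocsr()
    label = surface_definition if isinstance(surface_definition, str) else f"{surface_definition:g}m"
    return SurfacePartition(
        definition=label,
        grid=grid,
        surface_index=s_idx,
        interior_index=i_idx,
        n_surface_layers=n_layers,
        T_ss=T[np.ix_(s_idx, s_idx)].tocsr(),
        T_si=T[np.ix_(s_idx, i_idx)].tocsr(),
        T_is=T[np.ix_(i_idx, s_idx)].tocsr(),
        T_ii=T[np.ix_(i_idx, i_idx)].tocsr(),
    )


@dataclass(frozen=True)
class RestoringSolution:
    """Solution of the surface restoring model for one tracer and partition.

    ``j`` is the diagnosed net flux on surface boxes with the tracer's sign
    convention: net production ``(C_s,obs - C_s)/τ`` for DOC, net uptake
    ``(C_s - C_s,obs)/τ`` for nitrate; both are positive where biology removes
    the discrepancy that circulation would otherwise create.
    """

    partition: SurfacePartition
    tracer_kind: str                # "doc" | "nitrate"
    tau: float                      # yr
    c_s: np.ndarray                 # modeled surface concentration (n_s,)
    c_s_obs: np.ndarray             # (n_s,)
    c_i_obs: np.ndarray             # (n_i,)
    j: np.ndarray                   # (n_s,) µmol kg⁻¹ yr⁻¹
    residual: float                 # relative linear-system residual

    @property
    def j_full(self) -> np.ndarray:
        """Diagnosed flux embedded in a full per-box array (zero interior)."""
        return self.partition.scatter_surface(self.j)


def solve_restoring(
    partition: SurfacePartition,
    c_s_obs: np.ndarray,
    c_i_obs: np.ndarray,
    tau: float = DEFAULT_TAU_YEARS,
    tracer_kind: str = "doc",
    rtol: float = 1e-10,
) -> RestoringSolution:
    """Solve the restoring model for the modeled surface field and net flux.

    ``c_s_obs``/``c_i_obs`` may be given either as full per-box fields (both
    equal-length ``n_box`` vectors, split internally) or as surface- and
    interior-subset vectors.
    """
    if tau <= 0:
        raise ConfigurationError(f"restoring timescale must be positive, got {tau}")
    if tracer_kind not in ("doc", "nitrate"):
        raise ConfigurationError(f"tracer_kind must be 'doc' or 'nitrate', got {tracer_kind!r}")

    n_box = partition.grid.n_box
    c_s_obs = np.asarray(c_s_obs, dtype=float)
    c_i_obs = np.asarray(c_i_obs, dtype=float)
    if c_s_obs.shape == (n_box,):
        c_s_obs = c_s_obs[partition.surface_index]
    if c_i_obs.shape == (n_box,) and len(partition.interior_index) != n_box:
        c_i_obs = c_i_obs[partition.interior_index]
    n_s = partition.n_surface
    if c_s_obs.shape != (n_s,) or c_i_obs.shape != (len(partition.interior_index),):
        raise ConfigurationError("observed fields do not match the partition index sets")
    if not (np.all(np.isfinite(c_s_obs)) and np.all(np.isfinite(c_i_obs))):
        raise ConfigurationError("observed fields must be finite")

    A = (partition.T_ss - sp.identity(n_s, format="csr") / tau).tocsc()
    rhs = -(partition.T_si @ c_i_obs) - c_s_obs / tau
    try:
        c_s = splu(A).solve(rhs)
    except RuntimeError as exc:  # pragma: no cover - dominance precludes this
        raise SolverError(
            f"restoring solve failed for tau={tau}, definition="
            f"{partition.definition}: {exc}"
        ) from exc
    scale = np.linalg.norm(rhs)
    resid = np.linalg.norm(A @ c_s - rhs) / scale if scale > 0 else 0.0
    if resid > rtol:
        raise SolverError(f"restoring solve residual {resid:.3e} exceeds rtol {rtol:g}")

    j_production = (c_s_obs - c_s) / tau
    j = j_production if tracer_kind == "doc" else -j_production
    return RestoringSolution(
        partition=partition, tracer_kind=tracer_kind, tau=tau,
        c_s=c_s, c_s_obs=c_s_obs, c_i_obs=c_i_obs, j=j, residual=float(resid),
    )


@dataclass(frozen=True)
class FluxField:
    """A diagnosed molar rate with its areal and global conversions.

    areal[col] = Σ_layers j·ρ·Δz·M·1e-6   (g m⁻² yr⁻¹)
    global_pg  = Σ_cols areal·area·1e-15  (Pg yr⁻¹)
    """

    molar: np.ndarray          # (n_s,) µmol kg⁻¹ yr⁻¹ on surface boxes
    areal: np.ndarray          # (n_col,) g m⁻² yr⁻¹
    global_pg: float           # Pg yr⁻¹
    element: str
    partition: SurfacePartition

    @property
    def molar_full(self) -> np.ndarray:
        return self.partition.scatter_surface(self.molar)


def to_areal_flux(
    j: np.ndarray | RestoringSolution,
    partition: SurfacePartition | None = None,
    element: str = "C",
) -> FluxField:
    """Convert a diagnosed molar rate to areal (g m⁻² yr⁻¹) and global
    (Pg yr⁻¹) fluxes using per-box density and surface-layer thicknesses."""
    if isinstance(j, RestoringSolution):
        partition = j.partition
        element_default = "C" if j.tracer_kind == "doc" else "N"
        if element is None:
            element = element_default
        j = j.j
    if partition is None:
        raise ConfigurationError("a SurfacePartition is required")
    if element not in ATOMIC_WEIGHT:
        raise ConfigurationError(f"element must be one of {sorted(ATOMIC_WEIGHT)}")
    grid = partition.grid
    j = np.asarray(j, dtype=float)
    if j.shape == (grid.n_box,):
        j = j[partition.surface_index]
    if j.shape != (partition.n_surface,):
        raise ConfigurationError("flux vector does not match the partition surface set")

    atomic = ATOMIC_WEIGHT[element]
    idx = partition.surface_index
    rho = grid.density[idx]
    dz = grid.thickness[grid.box_layer[idx]]
    contrib = j * rho * dz * atomic * 1e-6  # g m⁻² yr⁻¹ per surface box
    areal = np.zeros(grid.n_col)
    np.add.at(areal, grid.box_col[idx], contrib)
    global_pg = float(np.sum(areal * grid.box_area) * 1e-15)
    return FluxField(molar=j, areal=areal, global_pg=global_pg, element=element,
                     partition=partition)


@dataclass(frozen=True)
class ProfileDiagnostics:
    """Restoring solutions for DOC and nitrate at several surface definitions."""

    solutions: Mapping[str, dict[str, RestoringSolution]]
    failures: Mapping[str, Exception] = field(default_factory=dict)

    def ndp(self, definition: str) -> RestoringSolution:
        return self.solutions[definition]["doc"]

    def uptake(self, definition: str) -> RestoringSolution:
        return self.solutions[definition]["nitrate"]


def diagnose_profile(
    transport: TransportMatrix,
    c_obs_doc: np.ndarray,
    c_obs_no3: np.ndarray,
    tau: float = DEFAULT_TAU_YEARS,
    definitions: tuple[str, ...] = SURFACE_DEFINITIONS,
) -> ProfileDiagnostics:
    """Run the DOC and nitrate inversions at several surface definitions.

    A solver failure at one definition is recorded in ``failures`` without
    aborting the others.
    """
    solutions: dict[str, dict[str, RestoringSolution]] = {}
    failures: dict[str, Exception] = {}
    for definition in definitions:
        try:
            part = partition_matrix(transport, definition)
            solutions[definition] = {
                "doc": solve_restoring(part, c_obs_doc, c_obs_doc, tau, "doc"),
                "nitrate": solve_restoring(part, c_obs_no3, c_obs_no3, tau, "nitrate"),
            }
        except Exception as exc:  # noqa: BLE001 - propagate per definition
            failures[definition] = exc
    if not solutions:
        raise SolverError(f"all surface definitions failed: {failures}")
    return ProfileDiagnostics(solutions=solutions, failures=failures)
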