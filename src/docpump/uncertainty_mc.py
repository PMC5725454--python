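"""Monte Carlo propagation of mapping, circulation, and timescale uncertainty.

Each run draws, independently and with replacement, one mapped DOC field
from the ensemble pool, one circulation matrix from the perturbed-transport
pool, and a restoring timescale τ uniform on its range (default 3-9 months),
then repeats the production (NDP), nitrate-uptake, and export (NDX) solves.
Per-box means and standard deviations are accumulated streaming (Welford),
and every run's draws and global/band integrals are logged so that ratio
uncertainties can be formed from *paired* draws rather than from ratios of
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .synthetic_ocean import ConfigurationError, TransportMatrix
from .surface_diagnostics import (
    ATOMIC_WEIGHT,
    SurfacePartition,
    partition_matrix,
    solve_restoring,
    to_areal_flux,
)
from .export_flux import DEFAULT_K, solve_export

__all__ = [
    "MCConfig",
    "MCInputs",
    "MCSummary",
    "run_mc",
    "summarize_ratio_uncertainty",
]


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings.

    ``n_runs`` defaults to a desk-scale 200; production analyses use 2000
    (the estimator is identical, only the Monte Carlo error shrinks).
    τ is drawn uniformly on ``tau_range`` (years; default 3-9 months).
    """

    n_runs: int = 200
    tau_range: tuple[float, float] = (0.25, 0.75)
    surface_definition: str = "74m"
    export_depth: float = 74.0
    k: float = DEFAULT_K
    max_failure_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ConfigurationError("n_runs must be >= 2")
        lo, hi = self.tau_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid tau_range {self.tau_range}")


@dataclass(frozen=True)
class MCInputs:
    """Input pools: mapped DOC fields, circulations, and the fixed nitrate
    climatology; optional column masks define reporting bands/regions."""

    transport_pool: Sequence[TransportMatrix]
    doc_pool: np.ndarray                    # (n_fields, n_box)
    no3_field: np.ndarray                   # (n_box,)
    band_masks: Mapping[str, np.ndarray] = field(default_factory=dict)  # per-column bool
    c_export: np.ndarray | None = None      # (n_col,) gC m⁻² yr⁻¹, fixed denominator


class _Welford:
    def __init__(self, n: int):
        self.count = 0
        self.mean = np.zeros(n)
        self.m2 = np.zeros(n)
        self.min = np.full(n, np.inf)
        self.max = np.full(n, -np.inf)

    def update(self, x: np.ndarray) -> None:
        self.count += 1
        d = x - self.mean
        self.mean += d / self.count
        self.m2 += d * (x - self.mean)
        np.minimum(self.min, x, out=self.min)
        np.maximum(self.max, x, out=self.max)

    @property
    def sd(self) -> np.ndarray:
        if self.count < 2:
            return np.zeros_like(self.mean)
        return np.sqrt(self.m2 / (self.count - 1))


@dataclass(frozen=True)
class MCSummary:
    """Streaming summary of the Monte Carlo ensemble.

    Per-box statistics for NDP, nitrate uptake (both embedded full-grid,
    zero in the interior) and per-column NDX, plus a per-run log of draws
    and global/band integrals (global fluxes in Pg yr⁻¹ of the element)."""

    ndp_mean: np.ndarray
    ndp_sd: np.ndarray
    uptake_mean: np.ndarray
    uptake_sd: np.ndarray
    ndx_mean: np.ndarray
    ndx_sd: np.ndarray
    run_log: pd.DataFrame
    config: MCConfig
    n_failures: int

    @property
    def n_runs(self) -> int:
        return len(self.run_log)


def _band_integrals(
    flux_areal: np.ndarray, grid, band_masks: Mapping[str, np.ndarray]
) -> dict[str, float]:
    out = {}
    for name, mask in band_masks.items():
        out[name] = float(np.sum(flux_areal[mask] * grid.box_area[mask]) * 1e-15)
    return out


def run_mc(config: MCConfig, inputs: MCInputs) -> MCSummary:
    """Run the Monte Carlo loop; reproducible under ``config.seed``.

    Any single-run solver failure is skipped and logged; more than
    ``max_failure_fraction`` of runs failing aborts the analysis.
    """
    pool_T = list(inputs.transport_pool)
    doc_pool = np.atleast_2d(np.asarray(inputs.doc_pool, dtype=float))
    if not pool_T or doc_pool.shape[0] < 1:
        raise ConfigurationError("transport and DOC pools must be non-empty")
    grid = pool_T[0].grid
    no3 = np.asarray(inputs.no3_field, dtype=float)

    # per-matrix caches: surface partition (τ-independent blocks)
    partitions: list[SurfacePartition] = [
        partition_matrix(T, config.surface_definition) for T in pool_T
    ]

    rng = np.random.default_rng(config.seed)
    lo, hi = config.tau_range
    acc_ndp = _Welford(grid.n_box)
    acc_upt = _Welford(grid.n_box)
    acc_ndx = _Welford(grid.n_col)

    records: list[dict] = []
    failures = 0
    max_failures = max(int(config.max_failure_fraction * config.n_runs), 1)
    for run in range(config.n_runs):
        i_field = int(rng.integers(doc_pool.shape[0]))
        i_matrix = int(rng.integers(len(pool_T)))
        tau = float(rng.uniform(lo, hi)) if hi > lo else lo
        try:
            part = partitions[i_matrix]
            sol_doc = solve_restoring(part, doc_pool[i_field], doc_pool[i_field], tau, "doc")
            sol_no3 = solve_restoring(part, no3, no3, tau, "nitrate")
            ndp = to_areal_flux(sol_doc, element="C")
            upt = to_areal_flux(sol_no3, element="N")
            export = solve_export(
                pool_T[i_matrix], sol_doc.j_full, config.export_depth, config.k
            )
        except Exception:  # noqa: BLE001 - individual runs may fail
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"{failures} of {run + 1} Monte Carlo runs failed "
                    f"(> {config.max_failure_fraction:.0%} allowed)"
                )
            continue

        acc_ndp.update(sol_doc.j_full)
        acc_upt.update(sol_no3.j_full)
        acc_ndx.update(export.ndx)
        rec = {
            "run": run, "field_idx": i_field, "matrix_idx": i_matrix, "tau": tau,
            "ndp_global_pgc": ndp.global_pg,
            "uptake_global_pgn": upt.global_pg,
            "ndx_global_pgc": export.global_pg,
        }
        for name, v in _band_integrals(ndp.areal, grid, inputs.band_masks).items():
            rec[f"ndp_pgc_{name}"] = v
        for name, v in _band_integrals(upt.areal, grid, inputs.band_masks).items():
            rec[f"uptake_pgn_{name}"] = v
        for name, v in _band_integrals(export.areal, grid, inputs.band_masks).items():
            rec[f"ndx_pgc_{name}"] = v
        if inputs.c_export is not None:
            for name, v in _band_integrals(
                np.asarray(inputs.c_export), grid, inputs.band_masks
            ).items():
                rec[f"cexport_pgc_{name}"] = v
        records.append(rec)

    if not records:
        raise RuntimeError("all Monte Carlo runs failed")
    return MCSummary(
        ndp_mean=acc_ndp.mean, ndp_sd=acc_ndp.sd,
        uptake_mean=acc_upt.mean, uptake_sd=acc_upt.sd,
        ndx_mean=acc_ndx.mean, ndx_sd=acc_ndx.sd,
        run_log=pd.DataFrame.from_records(records),
        config=config, n_failures=failures,
    )


_DRAW_COLUMNS = ["run", "field_idx", "matrix_idx", "tau"]


def summarize_ratio_uncertainty(
    mc_numerator: MCSummary,
    mc_denominator: MCSummary,
    numerator_prefix: str = "ndp_pgc",
    denominator_prefix: str = "uptake_pgn",
    mol_ratio: bool = True,
) -> pd.DataFrame:
    """Per-band ratio mean ± sd formed run-by-run from paired draws.

    Both summaries must come from the same run log (identical draws); the
    ratio is computed per run and then summarized, which preserves the
    correlation between numerator and denominator.  With ``mol_ratio`` the
    Pg-element integrals are converted to molar units before dividing
    (mol C : mol N for a production:uptake ratio).
    """
    log_n, log_d = mc_numerator.run_log, mc_denominator.run_log
    if len(log_n) != len(log_d) or not log_n[_DRAW_COLUMNS].equals(log_d[_DRAW_COLUMNS]):
        raise ConfigurationError(
            "ratio uncertainty requires paired draws: the two summaries do not "
            "share an identical run log"
        )
    num_cols = [c for c in log_n.columns if c.startswith(numerator_prefix + "_")]
    rows = []
    for nc in num_cols:
        band = nc[len(numerator_prefix) + 1:]
        dc = f"{denominator_prefix}_{band}"
        if dc not in log_d.columns:
            continue
        num = log_n[nc].to_numpy()
        den = log_d[dc].to_numpy()
        if mol_ratio:
            num = num / _prefix_atomic_weight(numerator_prefix)
            den = den / _prefix_atomic_weight(denominator_prefix)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den != 0, num / den, np.nan)
        rows.append({
            "band": band,
            "ratio_mean": float(np.nanmean(ratio)),
            "ratio_sd": float(np.nanstd(ratio, ddof=1)) if len(ratio) > 1 else 0.0,
            "n": int(np.isfinite(ratio).sum()),
        })
    return pd.DataFrame(rows).set_index("band")


def _prefix_atomic_weight(prefix: str) -> float:
    if prefix.endswith("pgc"):
        return ATOMIC_WEIGHT["C"]
    if prefix.endswith("pgn"):
        return ATOMIC_WEIGHT["N"]
    return 1.0
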