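"""Regionalization, flux-ratio diagnostics, and the export-efficiency MLR.

The surface ocean is split into ten regions by basin and by the
depth-integrated mean nitrate over the top 74 m: oligotrophic subtropical
gyres (mean NO₃⁻ < 0.5 µmol kg⁻¹) per basin (STP, STA, STI), tropical bands
per basin (TP, TA, TI), northern subpolar Pacific and Atlantic (NP, NA), and
the Sub-Antarctic vs Antarctic zones split at 20 µmol kg⁻¹ (SAZ, AAZ).
Regional export-efficiency ratios (NDP:C export etc.) are ratios of
regionally aggregated fluxes, never means of pointwise ratios, and the
multilinear regression of NDP:C export on F_pico and log₁₀(NO₃⁻) follows
the no-intercept form with standardized-coefficient comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_ocean import ConfigurationError, Grid

__all__ = [
    "REGION_NAMES",
    "RegionSet",
    "MLRResult",
    "depth_mean_no3",
    "regionalize",
    "zonal_means",
    "regional_means",
    "satellite_cexport",
    "efficiency_ratios",
    "fit_mlr",
]

REGION_NAMES = ("AAZ", "SAZ", "STP", "STA", "STI", "TP", "TA", "TI", "NP", "NA")

_BASIN_CODE = {"Pacific": "P", "Atlantic": "A", "Indian": "I"}

#: floor applied before log10 of nitrate (µmol kg⁻¹); configurable in fit input prep
NO3_LOG_FLOOR = 0.01


def depth_mean_no3(
    no3_field: np.ndarray,
    grid: Grid,
    z_top: float = 0.0,
    z_bottom: float = 74.0,
) -> np.ndarray:
    """Thickness-weighted vertical mean per column between two interfaces.

    The layer interfaces must tile ``[z_top, z_bottom]`` exactly (they do on
    the default grid for 0-74 m)."""
    tops, bottoms = grid.layer_tops, grid.layer_bottoms
    inside = (tops >= z_top - 1e-9) & (bottoms <= z_bottom + 1e-9)
    if not inside.any():
        raise ConfigurationError(f"no layers between {z_top} and {z_bottom} m")
    covered = np.sum(grid.thickness[inside])
    if not np.isclose(covered, z_bottom - z_top):
        raise ConfigurationError(
            f"layers do not tile [{z_top}, {z_bottom}] m exactly "
            f"(covered {covered:g} m)"
        )
    v = grid.to_column(np.asarray(no3_field, dtype=float))
    w = grid.thickness[inside]
    return v[:, inside] @ w / w.sum()


@dataclass(frozen=True)
class RegionSet:
    """Exhaustive region labels over surface columns with the thresholds used."""

    labels: np.ndarray                  # (n_col,) str
    thresholds: dict
    basin_map: np.ndarray               # (n_col,) str
    no3_mean: np.ndarray                # (n_col,) µmol kg⁻¹ used for the split

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels), key=lambda r: REGION_NAMES.index(r)
                            if r in REGION_NAMES else len(REGION_NAMES)))

    def mask(self, region: str) -> np.ndarray:
        return self.labels == region


def _basin_code(basin: str) -> str:
    return _BASIN_CODE.get(basin, basin[:1].upper())


def regionalize(
    no3_mean: np.ndarray,
    grid: Grid,
    basin_map: np.ndarray | None = None,
    oligotrophic_threshold: float = 0.5,
    antarctic_threshold: float = 20.0,
    southern_boundary: float = -44.0,
    northern_boundary: float = 44.0,
) -> RegionSet:
    """Label every surface column with one of the ten nutrient/basin regions.

    The 0.5 µmol kg⁻¹ marker separates the oligotrophic gyres (ST*) from
    tropical/northern/southern waters; the Southern-sector SAZ/AAZ split is
    at 20 µmol kg⁻¹.  A boundary value goes to the high-nutrient side.  A
    synthetic basin sector spanning all latitudes has no northern Indian
    analogue, so high-northern Indian columns fold into TI.
    """
    no3_mean = np.asarray(no3_mean, dtype=float)
    if basin_map is None:
        basin_map = grid.col_basin.astype(str)
    basin_map = np.asarray(basin_map)
    if no3_mean.shape != (grid.n_col,) or basin_map.shape != (grid.n_col,):
        raise ConfigurationError("no3_mean and basin_map must be per-column arrays")
    if not np.all(np.isfinite(no3_mean)):
        raise ConfigurationError("no3_mean must be finite at every column")
    bad = [b for b in np.unique(basin_map) if not str(b).strip()]
    if bad:
        raise ConfigurationError("every column needs a basin label")

    lat = grid.col_lat
    labels = np.empty(grid.n_col, dtype=object)
    for i in range(grid.n_col):
        code = _basin_code(str(basin_map[i]))
        if no3_mean[i] < oligotrophic_threshold:
            labels[i] = f"ST{code}"
        elif lat[i] < southern_boundary:
            labels[i] = "AAZ" if no3_mean[i] >= antarctic_threshold else "SAZ"
        elif lat[i] > northern_boundary:
            labels[i] = f"N{code}" if code in ("P", "A") else f"T{code}"
        else:
            labels[i] = f"T{code}"
    return RegionSet(
        labels=labels.astype(str),
        thresholds={
            "oligotrophic": oligotrophic_threshold,
            "antarctic": antarctic_threshold,
            "southern_boundary": southern_boundary,
            "northern_boundary": northern_boundary,
            "note": "0.5 marks the oligotrophic gyre edge, not nutrient limitation",
        },
        basin_map=basin_map.astype(str),
        no3_mean=no3_mean,
    )


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    s = weights.sum()
    if s <= 0:
        raise ConfigurationError("weights must be nonnegative and not all zero")
    return float(np.sum(values * weights) / s)


def zonal_means(
    fields: Mapping[str, np.ndarray],
    grid: Grid,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Area-weighted (or custom-weighted) zonal means of per-column fields."""
    w = grid.box_area if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ConfigurationError("weights must be nonnegative")
    ilat = np.repeat(np.arange(grid.n_lat), grid.n_lon)
    out = {}
    for name, v in fields.items():
        v = np.asarray(v, dtype=float)
        num = np.bincount(ilat, weights=v * w, minlength=grid.n_lat)
        den = np.bincount(ilat, weights=w, minlength=grid.n_lat)
        out[name] = np.where(den > 0, num / den, np.nan)
    return pd.DataFrame(out, index=pd.Index(grid.lat, name="lat"))


def regional_means(
    fields: Mapping[str, np.ndarray],
    weights: np.ndarray,
    region_set: RegionSet,
) -> pd.DataFrame:
    """Weighted regional means (e.g. export-weighted MLR predictors).

    Weights are normalized within each region; an all-zero-weight region is
    an error."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ConfigurationError("weights must be nonnegative")
    rows = {}
    for region in region_set.names:
        m = region_set.mask(region)
        rows[region] = {
            name: _weighted_mean(np.asarray(v, dtype=float)[m], weights[m])
            for name, v in fields.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("region")


def satellite_cexport(
    npp_fields: np.ndarray | Sequence[np.ndarray],
    sst: np.ndarray,
    algorithms: Sequence[Callable[[np.ndarray, np.ndarray], np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Apply every (NPP map, export algorithm) combination and average.

    ``npp_fields`` is one map or a stack of maps; ``algorithms`` are
    callables ``(npp, sst) -> export``.  Returns ``(mean_map, stack)`` with
    the per-combination maps retained.
    """
    if len(algorithms) < 1:
        raise ConfigurationError("at least one export algorithm is required")
    npp_stack = np.atleast_2d(np.asarray(npp_fields, dtype=float))
    sst = np.asarray(sst, dtype=float)
    maps = [np.asarray(alg(npp, sst), dtype=float)
            for npp in npp_stack for alg in algorithms]
    stack = np.stack(maps)
    return stack.mean(axis=0), stack


def efficiency_ratios(
    fluxes: Mapping[str, np.ndarray],
    region_set: RegionSet,
    grid: Grid,
    pairs: Sequence[tuple[str, str]] = (
        ("ndp", "cexport"), ("ndx", "cexport"), ("ndp", "npp"), ("ndx", "npp"),
    ),
    include_global: bool = True,
) -> pd.DataFrame:
    """Ratios of regionally aggregated (area-integrated) fluxes.

    All fields are per-column areal fluxes in consistent units.  A zero
    regional denominator yields NaN (undefined), never infinity.
    """
    area = grid.box_area
    regions = list(region_set.names) + (["global"] if include_global else [])
    rows = []
    for region in regions:
        m = np.ones(grid.n_col, bool) if region == "global" else region_set.mask(region)
        rec = {"region": region}
        totals = {name: float(np.sum(np.asarray(v)[m] * area[m])) for name, v in fluxes.items()}
        for num, den in pairs:
            if num not in totals or den not in totals:
                continue
            rec[f"{num}:{den}"] = totals[num] / totals[den] if totals[den] != 0 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("region")


@dataclass(frozen=True)
class MLRResult:
    """No-intercept multilinear regression summary.

    Standardized coefficients are ``raw * sd(predictor)/sd(response)``; their
    ratio compares the relative importance of the first two predictors."""

    params: pd.Series
    bse: pd.Series
    standardized: pd.Series
    standardized_ratio: float
    r2: float
    n: int
    prediction: pd.DataFrame     # fitted values with 95% CI bounds
    model: object = field(repr=False, default=None)

    def equation(self) -> str:
        terms = [f"{c:+.3f}(±{s:.3f})·{name}"
                 for name, c, s in zip(self.params.index, self.params, self.bse)]
        return " ".join(terms).lstrip("+")


def fit_mlr(
    response: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
    include_intercept: bool = False,
    condition_limit: float = 1e8,
) -> MLRResult:
    """Least-squares fit of a regional response on regional predictors.

    Defaults to the no-intercept form.  Collinear predictors (design
    condition number above ``condition_limit``) raise with diagnostics.
    95% confidence bounds of the prediction are returned per region.
    """
    y = np.asarray(response, dtype=float)
    X = predictors.astype(float)
    if len(y) != len(X):
        raise ConfigurationError("response and predictors must align")
    if len(y) <= X.shape[1] + int(include_intercept):
        raise ConfigurationError(
            f"need more regions ({len(y)}) than parameters ({X.shape[1]})"
        )
    design = sm.add_constant(X) if include_intercept else X
    cond = np.linalg.cond(design.to_numpy())
    if cond > condition_limit:
        raise ConfigurationError(
            f"collinear predictors: design condition number {cond:.3g} exceeds "
            f"{condition_limit:g}; columns: {list(design.columns)}"
        )
    fit = sm.OLS(y, design).fit()
    pred = fit.get_prediction(design).summary_frame(alpha=0.05)
    prediction = pd.DataFrame(
        {
            "fitted": pred["mean"].to_numpy(),
            "ci_low": pred["mean_ci_lower"].to_numpy(),
            "ci_high": pred["mean_ci_upper"].to_numpy(),
        },
        index=predictors.index,
    )
    names = [c for c in design.columns if c != "const"]
    sd_y = float(np.std(y, ddof=1))
    standardized = pd.Series(
        {c: fit.params[c] * float(np.std(X[c].to_numpy(), ddof=1)) / sd_y for c in names}
    )
    ratio = (
        float(standardized.iloc[0] / standardized.iloc[1])
        if len(standardized) >= 2 and standardized.iloc[1] != 0 else np.nan
    )
    return MLRResult(
        params=fit.params[names], bse=fit.bse[names], standardized=standardized,
        standardized_ratio=ratio, r2=float(fit.rsquared), n=len(y),
        prediction=prediction, model=fit,
    )
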