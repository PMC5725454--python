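"""Ensemble neural-network gap-filling of sparse tracer observations.

Sparse point observations of a tracer (DOC here) are mapped onto the full
grid by an ensemble of small feed-forward networks: one hidden sigmoid layer
(default 15 units) and a linear output, each member trained on an
independent random 70% of the observations with the remaining 30% held out
for validation.  The ensemble prediction is the arithmetic mean of the
member predictions, and the member spread provides a per-box uncertainty
that propagates spatially correlated mapping errors into the downstream
Monte Carlo.

Training uses an L2-regularized quasi-Newton (L-BFGS) fit of the
sum-of-squares loss with per-predictor z-score standardization computed from
each member's training subset.  Validation subsets never influence the
weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .synthetic_ocean import ConfigurationError, Grid, ObservationSet

__all__ = [
    "ANNConfig",
    "ANNMember",
    "ANNEnsemble",
    "FitStats",
    "PredictedField",
    "EnsembleError",
    "assemble_predictors",
    "train_member",
    "train_ensemble",
    "predict_field",
    "holdout_stats",
    "rmse_depth_profile",
    "basin_exclusion_validation",
    "ensemble_to_dict",
    "ensemble_from_dict",
]

logger = logging.getLogger(__name__)

MIN_OBSERVATIONS = 50


class EnsembleError(RuntimeError):
    """Too few ensemble members survived training."""


@dataclass(frozen=True)
class ANNConfig:
    """Hyperparameters of the gap-filling ensemble.

    ``n_hidden`` may be anywhere in the 10-20 range typical for this family
    of mapping problems; 15 is the default.  ``regularization_strength`` is
    the L2 penalty of the quasi-Newton fit.
    """

    n_hidden: int = 15
    n_members: int = 20
    train_fraction: float = 0.70
    predictor_names: tuple[str, ...] | None = None
    regularization_strength: float = 1e-2
    max_iterations: int = 10_000
    min_validation_r2: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.n_hidden < 1 or self.n_members < 1:
            raise ConfigurationError("n_hidden and n_members must be >= 1")


@dataclass(frozen=True)
class ANNMember:
    """One trained network with its standardization and split bookkeeping."""

    model: MLPRegressor
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    train_rows: np.ndarray       # row indices into the observation set
    val_rows: np.ndarray
    validation_r2: float
    converged: bool
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X) - self.x_mean) / self.x_scale
        return self.model.predict(Z) * self.y_scale + self.y_mean


@dataclass(frozen=True)
class ANNEnsemble:
    """A retained set of members; prediction is their arithmetic mean."""

    members: tuple[ANNMember, ...]
    config: ANNConfig
    predictor_names: tuple[str, ...]
    train_min: np.ndarray        # per-predictor training range (all members)
    train_max: np.ndarray

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        return np.stack([m.predict(X) for m in self.members])


@dataclass(frozen=True)
class FitStats:
    """Predicted-vs-observed regression summary (slope from OLS of predicted
    on observed), coefficient of determination and RMSE in µmol kg⁻¹."""

    slope: float
    r2: float
    rmse: float
    n: int

    def __str__(self) -> str:
        return f"slope={self.slope:.3f}, R^2={self.r2:.3f}, RMSE={self.rmse:.2f} (n={self.n})"


@dataclass(frozen=True)
class PredictedField:
    """Full-coverage mapped field with ensemble spread and extrapolation mask."""

    values: np.ndarray            # (n_box,) ensemble-mean prediction
    spread: np.ndarray            # (n_box,) member standard deviation
    extrapolation_mask: np.ndarray  # (n_box,) True outside the training hull
    member_fields: np.ndarray     # (n_members, n_box)


class _WeightsModel:
    """Minimal stand-in for a fitted network restored from saved weights:
    one logistic hidden layer and a linear output."""

    def __init__(self, coefs: list[np.ndarray], intercepts: list[np.ndarray]):
        self.coefs_ = [np.asarray(c, dtype=float) for c in coefs]
        self.intercepts_ = [np.asarray(b, dtype=float) for b in intercepts]

    def predict(self, X: np.ndarray) -> np.ndarray:
        h = 1.0 / (1.0 + np.exp(-(X @ self.coefs_[0] + self.intercepts_[0])))
        return (h @ self.coefs_[1] + self.intercepts_[1]).ravel()


def ensemble_to_dict(ensemble: ANNEnsemble) -> dict:
    """Serialize an ensemble (weights, scalers, config, seeds) to plain data."""
    return {
        "config": {
            "n_hidden": ensemble.config.n_hidden,
            "n_members": ensemble.config.n_members,
            "train_fraction": ensemble.config.train_fraction,
            "regularization_strength": ensemble.config.regularization_strength,
            "max_iterations": ensemble.config.max_iterations,
            "min_validation_r2": ensemble.config.min_validation_r2,
            "seed": ensemble.config.seed,
        },
        "predictor_names": list(ensemble.predictor_names),
        "train_min": ensemble.train_min.tolist(),
        "train_max": ensemble.train_max.tolist(),
        "members": [
            {
                "seed": m.seed,
                "validation_r2": None if not np.isfinite(m.validation_r2) else float(m.validation_r2),
                "x_mean": m.x_mean.tolist(),
                "x_scale": m.x_scale.tolist(),
                "y_mean": m.y_mean,
                "y_scale": m.y_scale,
                "coefs": [c.tolist() for c in m.model.coefs_],
                "intercepts": [np.asarray(b).tolist() for b in m.model.intercepts_],
            }
            for m in ensemble.members
        ],
    }


def ensemble_from_dict(payload: dict) -> ANNEnsemble:
    """Restore an ensemble saved by :func:`ensemble_to_dict`."""
    cfg = ANNConfig(predictor_names=tuple(payload["predictor_names"]), **payload["config"])
    members = tuple(
        ANNMember(
            model=_WeightsModel(m["coefs"], m["intercepts"]),
            x_mean=np.asarray(m["x_mean"]), x_scale=np.asarray(m["x_scale"]),
            y_mean=m["y_mean"], y_scale=m["y_scale"],
            train_rows=np.empty(0, int), val_rows=np.empty(0, int),
            validation_r2=np.nan if m["validation_r2"] is None else m["validation_r2"],
            converged=True, seed=m["seed"],
        )
        for m in payload["members"]
    )
    return ANNEnsemble(
        members=members, config=cfg,
        predictor_names=tuple(payload["predictor_names"]),
        train_min=np.asarray(payload["train_min"]),
        train_max=np.asarray(payload["train_max"]),
    )


def assemble_predictors(
    grid: Grid,
    fields: dict[str, np.ndarray],
    predictor_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Build the per-box predictor table.

    Each field must be per box (``n_box``) or per column (``n_col``,
    broadcast down the water column).  Any NaN at a wet box is an error that
    names the offending boxes rather than being imputed silently.
    """
    names = tuple(predictor_names) if predictor_names else tuple(fields)
    missing = [n for n in names if n not in fields]
    if missing:
        raise ConfigurationError(f"missing predictor fields: {missing}")
    data = {}
    for name in names:
        v = np.asarray(fields[name], dtype=float)
        if v.shape == (grid.n_col,):
            v = v[grid.box_col]
        if v.shape != (grid.n_box,):
            raise ConfigurationError(
                f"predictor {name!r} has shape {v.shape}, expected ({grid.n_box},) or ({grid.n_col},)"
            )
        bad = np.flatnonzero(~np.isfinite(v))
        if bad.size:
            raise ConfigurationError(
                f"predictor {name!r} is not finite at boxes {bad[:10].tolist()}"
                + ("..." if bad.size > 10 else "")
            )
        data[name] = v
    return pd.DataFrame(data, index=pd.RangeIndex(grid.n_box, name="box"))


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan


def train_member(
    observations: ObservationSet,
    predictors: pd.DataFrame,
    config: ANNConfig,
    member_seed: int,
) -> ANNMember:
    """Train one network on a random ``train_fraction`` of the observations.

    Reproducible under ``member_seed``; the validation subset is used only
    to score the member, never for weight updates.
    """
    n = len(observations)
    if n < MIN_OBSERVATIONS:
        raise ConfigurationError(f"need >= {MIN_OBSERVATIONS} observations, got {n}")
    X_all = predictors.to_numpy()[observations.box_index]
    y_all = np.asarray(observations.values, dtype=float)

    rng = np.random.default_rng(member_seed)
    order = rng.permutation(n)
    n_train = max(int(round(config.train_fraction * n)), 1)
    train_rows, val_rows = order[:n_train], order[n_train:]

    x_mean = X_all[train_rows].mean(axis=0)
    x_scale = X_all[train_rows].std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean = float(y_all[train_rows].mean())
    y_scale = float(y_all[train_rows].std()) or 1.0

    model = MLPRegressor(
        hidden_layer_sizes=(config.n_hidden,),
        activation="logistic",
        solver="lbfgs",
        alpha=config.regularization_strength,
        max_iter=config.max_iterations,
        random_state=int(member_seed) % (2**32),
        tol=1e-6,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(
            (X_all[train_rows] - x_mean) / x_scale,
            (y_all[train_rows] - y_mean) / y_scale,
        )
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)

    member = ANNMember(
        model=model, x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        train_rows=train_rows, val_rows=val_rows, validation_r2=np.nan,
        converged=converged, seed=member_seed,
    )
    if len(val_rows):
        val_r2 = _r2(y_all[val_rows], member.predict(X_all[val_rows]))
        member = replace(member, validation_r2=val_r2)
        if not np.isfinite(val_r2):
            member = replace(member, converged=False)
    if not member.converged:
        logger.warning("ANN member seed=%d did not converge (validation R^2=%.3f)",
                       member_seed, member.validation_r2)
    return member


def train_ensemble(
    observations: ObservationSet,
    predictors: pd.DataFrame,
    config: ANNConfig | None = None,
) -> ANNEnsemble:
    """Train the full ensemble, dropping non-converged members.

    With ``config.min_validation_r2`` set, members below that validation
    score are also dropped.  Fewer than half the requested members surviving
    is an :class:`EnsembleError`.
    """
    config = config or ANNConfig()
    names = config.predictor_names or tuple(predictors.columns)
    predictors = predictors[list(names)]
    rng = np.random.default_rng(config.seed)
    member_seeds = rng.integers(0, 2**31 - 1, size=config.n_members)

    members = []
    for s in member_seeds:
        m = train_member(observations, predictors, config, int(s))
        if not m.converged:
            continue
        if config.min_validation_r2 is not None and m.validation_r2 < config.min_validation_r2:
            logger.warning("dropping member seed=%d: validation R^2=%.3f < %.3f",
                           m.seed, m.validation_r2, config.min_validation_r2)
            continue
        members.append(m)
    if len(members) < max(config.n_members // 2, 1):
        raise EnsembleError(
            f"only {len(members)}/{config.n_members} members survived training"
        )
    X_obs = predictors.to_numpy()[observations.box_index]
    return ANNEnsemble(
        members=tuple(members), config=config, predictor_names=tuple(names),
        train_min=X_obs.min(axis=0), train_max=X_obs.max(axis=0),
    )


def predict_field(
    ensemble: ANNEnsemble,
    predictors: pd.DataFrame,
    floor_at_zero: bool = False,
) -> PredictedField:
    """Map the ensemble over all boxes of the predictor table.

    Boxes outside the axis-aligned range of the training predictors are
    still predicted but flagged in the extrapolation mask.  ``floor_at_zero``
    clips negative concentrations in the reported field (never do this
    before computing validation statistics).
    """
    X = predictors[list(ensemble.predictor_names)].to_numpy()
    fields = ensemble.member_predictions(X)
    mean = fields.mean(axis=0)
    spread = fields.std(axis=0) if len(fields) > 1 else np.zeros(X.shape[0])
    mask = np.any((X < ensemble.train_min) | (X > ensemble.train_max), axis=1)
    if floor_at_zero:
        mean = np.maximum(mean, 0.0)
        fields = np.maximum(fields, 0.0)
    return PredictedField(values=mean, spread=spread, extrapolation_mask=mask,
                          member_fields=fields)


def holdout_stats(predicted: np.ndarray, observed: np.ndarray) -> FitStats:
    """Predicted-vs-observed statistics: OLS slope of predicted on observed,
    R², and RMSE."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ConfigurationError("predicted and observed must be equal-length vectors")
    if len(observed) < 3:
        raise ConfigurationError("need at least 3 pairs")
    if np.ptp(observed) == 0:
        raise ConfigurationError("observed values have zero variance")
    fit = stats.linregress(observed, predicted)
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    return FitStats(slope=float(fit.slope), r2=_r2(observed, predicted),
                    rmse=rmse, n=len(observed))


def rmse_depth_profile(
    predicted_field: np.ndarray,
    observations: ObservationSet,
    grid: Grid,
) -> pd.Series:
    """Per-layer RMSE between a mapped field and the observations."""
    err = np.asarray(predicted_field)[observations.box_index] - observations.values
    layer = grid.box_layer[observations.box_index]
    return (
        pd.DataFrame({"layer": layer, "sq": err**2})
        .groupby("layer")["sq"].mean().pow(0.5).rename("rmse")
    )


def basin_exclusion_validation(
    observations: ObservationSet,
    predictors: pd.DataFrame,
    grid: Grid,
    config: ANNConfig | None = None,
    basin: str = "Indian",
) -> FitStats:
    """Leave-one-basin-out validation of the mapping.

    Trains an ensemble on all observations outside ``basin`` and scores the
    prediction against the excluded basin's observations only.
    """
    config = config or ANNConfig()
    obs_basin = grid.box_basin[observations.box_index]
    held = obs_basin == basin
    if basin not in grid.basins or not held.any():
        raise ConfigurationError(f"no observations in basin {basin!r}")
    train_obs = ObservationSet(
        box_index=observations.box_index[~held],
        values=observations.values[~held],
        fraction=observations.fraction,
        noise_sd=observations.noise_sd,
        withheld_basins=observations.withheld_basins + (basin,),
        seed=observations.seed,
    )
    ensemble = train_ensemble(train_obs, predictors, config)
    X_held = predictors[list(ensemble.predictor_names)].to_numpy()[observations.box_index[held]]
    predicted = ensemble.member_predictions(X_held).mean(axis=0)
    return holdout_stats(predicted, observations.values[held])
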