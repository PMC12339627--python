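"""Penalized linear regression (LASSO / elastic net) with leave-one-out CV.

The estimator minimises, over (beta0, beta) in R^(p+1),

    (1/2N) sum_i (y_i - beta0 - x_i' beta)^2  +  lambda * P_alpha(beta),
    P_alpha(beta) = sum_j [ (1 - alpha)/2 * beta_j^2 + alpha * |beta_j| ],

with alpha = 1 (pure LASSO) by default. Features are standardized to zero
mean and unit standard deviation (population form, denominator N) and the
response is centred before fitting; coefficients are reported back in the
original feature units.

The solver is cyclic coordinate descent on the Gram matrix
G = X'X / N, c = X'y / N (numba-compiled), which makes a full 100-point
regularization path cheap enough to nest 10-fold penalty selection inside
every leave-one-out fold.

Usage follows the model/results idiom::

    model = LassoRegression.from_feature_table(table, outcome="AL")
    res = model.fit_cv(seed=0)          # penalty chosen by 10-fold CV
    loo = model.fit_loo(LassoConfig(seed=0))
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .exceptions import (
    ConvergenceError,
    DegenerateInputError,
    SchemaError,
    ValidationError,
)
from .io import FEATURE_NAMES

__all__ = [
    "DesignMatrix",
    "LassoModel",
    "LassoConfig",
    "LooResult",
    "standardize",
    "soft_threshold",
    "lasso_objective",
    "lambda_grid",
    "fit_lasso",
    "kkt_violation",
    "cv_lambda_curve",
    "loo_predictions",
    "predict",
    "model_to_dict",
    "model_from_dict",
    "LassoRegression",
    "LassoResults",
    "LooResults",
]

DEFAULT_TOL = 1e-8
DEFAULT_MAX_SWEEPS = 100_000


# ---------------------------------------------------------------------------
# design matrix and standardization


@dataclass(frozen=True)
class DesignMatrix:
    """Standardized design: z-scored columns, centred response, stored stats."""

    Xs: np.ndarray  # (n, p) standardized
    yc: np.ndarray  # (n,) centred
    feature_names: tuple[str, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float

    @property
    def n(self) -> int:
        return self.Xs.shape[0]

    @property
    def p(self) -> int:
        return self.Xs.shape[1]


def standardize(
    X: np.ndarray, y: np.ndarray, feature_names: list[str] | None = None
) -> DesignMatrix:
    """Column-wise z-scores (sd with denominator N) and centred response.

    A constant feature column has no scale and is rejected with an error
    naming the column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D array")
    n, p = X.shape
    if n != len(y):
        raise ValidationError(f"X has {n} rows but y has {len(y)} values")
    if n < 3:
        raise ValidationError(f"need at least 3 observations, got {n}")
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{j}" for j in range(p)
    )
    if len(names) != p:
        raise ValidationError("feature_names length does not match X columns")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)  # population sd, consistent with the 1/2N loss
    zero = np.flatnonzero(x_sd == 0.0)
    if zero.size:
        raise DegenerateInputError(
            f"constant feature column(s): {', '.join(names[j] for j in zero)}"
        )
    y_mean = float(y.mean())
    return DesignMatrix(
        Xs=(X - x_mean) / x_sd,
        yc=y - y_mean,
        feature_names=names,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
    )


# ---------------------------------------------------------------------------
# objective and solver primitives


def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0) — the scalar l1 proximal operator."""
    if gamma < 0:
        raise ValidationError("soft_threshold requires gamma >= 0")
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def lasso_objective(
    beta0: float, beta: np.ndarray, dm: DesignMatrix, lam: float, alpha: float = 1.0
) -> float:
    """Penalized least-squares objective on the standardized scale."""
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    beta = np.asarray(beta, dtype=float)
    resid = dm.yc - beta0 - dm.Xs @ beta
    loss = 0.5 * float(resid @ resid) / dm.n
    penalty = float(np.sum(0.5 * (1.0 - alpha) * beta ** 2 + alpha * np.abs(beta)))
    return loss + lam * penalty


def lambda_grid(
    dm: DesignMatrix, n_lambdas: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max = max_j |<x_j, y>| / N."""
    lam_max = float(np.max(np.abs(dm.Xs.T @ dm.yc)) / dm.n)
    if lam_max == 0.0:
        raise DegenerateInputError("lambda_max is zero: response uncorrelated with all features")
    return lam_max * min_ratio ** (np.arange(n_lambdas) / (n_lambdas - 1))


@njit(cache=True)
def _cd_solve(G, c, l1, l2, beta, max_sweeps, tol):  # pragma: no cover - compiled
    p = G.shape[0]
    last = np.inf
    for sweep in range(max_sweeps):
        max_change = 0.0
        for j in range(p):
            bj = beta[j]
            gj = 0.0
            for k in range(p):
                gj += G[j, k] * beta[k]
            rho = c[j] - gj + G[j, j] * bj
            if rho > l1:
                bnew = (rho - l1) / (G[j, j] + l2)
            elif rho < -l1:
                bnew = (rho + l1) / (G[j, j] + l2)
            else:
                bnew = 0.0
            change = abs(bnew - bj)
            if change > max_change:
                max_change = change
            beta[j] = bnew
        last = max_change
        if max_change < tol:
            return sweep + 1, last
    return max_sweeps, last


@njit(cache=True)
def _cd_path(G, c, l1s, l2s, max_sweeps, tol):  # pragma: no cover - compiled
    n_lam = l1s.shape[0]
    p = G.shape[0]
    betas = np.zeros((n_lam, p))
    sweeps = np.zeros(n_lam, np.int64)
    beta = np.zeros(p)
    for t in range(n_lam):
        s, _ = _cd_solve(G, c, l1s[t], l2s[t], beta, max_sweeps, tol)
        sweeps[t] = s
        betas[t] = beta.copy()
    return betas, sweeps


def _gram(dm: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    G = (dm.Xs.T @ dm.Xs) / dm.n
    c = (dm.Xs.T @ dm.yc) / dm.n
    return G, c


# ---------------------------------------------------------------------------
# fitted model container


@dataclass(frozen=True)
class LassoModel:
    """A fitted penalized linear model, coefficients in original feature units."""

    intercept: float
    coef: np.ndarray  # (p,) original units
    lam: float
    alpha: float
    feature_names: tuple[str, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    beta_std: np.ndarray  # coefficients on the standardized scale
    n_sweeps: int = 0

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coef, index=list(self.feature_names))


def fit_lasso(
    dm: DesignMatrix,
    lam: float,
    alpha: float = 1.0,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    beta_init: np.ndarray | None = None,
) -> LassoModel:
    """Fit by cyclic coordinate descent; converged when the largest absolute
    coefficient change in a sweep falls below *tol*."""
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    G, c = _gram(dm)
    beta = np.zeros(dm.p) if beta_init is None else np.array(beta_init, dtype=float)
    sweeps, last = _cd_solve(G, c, lam * alpha, lam * (1.0 - alpha), beta,
                             max_sweeps, tol)
    if sweeps >= max_sweeps and last >= tol:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_sweeps} sweeps "
            f"(last max coefficient change {last:.3e})"
        )
    coef = beta / dm.x_sd
    intercept = dm.y_mean - float(coef @ dm.x_mean)
    return LassoModel(
        intercept=intercept,
        coef=coef,
        lam=float(lam),
        alpha=float(alpha),
        feature_names=dm.feature_names,
        x_mean=dm.x_mean.copy(),
        x_sd=dm.x_sd.copy(),
        y_mean=dm.y_mean,
        beta_std=beta,
        n_sweeps=int(sweeps),
    )


def kkt_violation(model: LassoModel, dm: DesignMatrix) -> float:
    """Largest violation of the stationarity (KKT) conditions at the solution."""
    r = dm.yc - dm.Xs @ model.beta_std
    grad = dm.Xs.T @ r / dm.n - model.lam * (1.0 - model.alpha) * model.beta_std
    l1 = model.lam * model.alpha
    active = model.beta_std != 0.0
    v_active = np.abs(grad[active] - l1 * np.sign(model.beta_std[active]))
    v_zero = np.maximum(np.abs(grad[~active]) - l1, 0.0)
    parts = np.concatenate([v_active, v_zero])
    return float(parts.max()) if parts.size else 0.0


def predict(model: LassoModel, fv) -> float | np.ndarray:
    """Predict in original units; named inputs are matched by feature name."""
    if isinstance(fv, pd.DataFrame):
        X = _reorder_named(fv, model.feature_names).to_numpy(dtype=float)
        return model.intercept + X @ model.coef
    if isinstance(fv, pd.Series):
        x = _reorder_named(fv.to_frame().T, model.feature_names).to_numpy(dtype=float)[0]
        return float(model.intercept + x @ model.coef)
    arr = np.asarray(fv, dtype=float)
    if arr.ndim == 1:
        if arr.shape[0] != len(model.feature_names):
            raise SchemaError(
                f"expected {len(model.feature_names)} features, got {arr.shape[0]}"
            )
        return float(model.intercept + arr @ model.coef)
    if arr.shape[1] != len(model.feature_names):
        raise SchemaError(
            f"expected {len(model.feature_names)} features, got {arr.shape[1]}"
        )
    return model.intercept + arr @ model.coef


def _reorder_named(df: pd.DataFrame, names: tuple[str, ...]) -> pd.DataFrame:
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise SchemaError(f"missing feature(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in names]
    if extra:
        raise SchemaError(f"unexpected feature(s): {', '.join(map(str, extra))}")
    return df.loc[:, list(names)]


def model_to_dict(model: LassoModel) -> dict:
    return {
        "intercept": model.intercept,
        "coef": model.coef.tolist(),
        "beta_std": model.beta_std.tolist(),
        "lambda": model.lam,
        "alpha": model.alpha,
        "feature_names": list(model.feature_names),
        "x_mean": model.x_mean.tolist(),
        "x_sd": model.x_sd.tolist(),
        "y_mean": model.y_mean,
    }


def model_from_dict(doc: dict) -> LassoModel:
    return LassoModel(
        intercept=float(doc["intercept"]),
        coef=np.asarray(doc["coef"], dtype=float),
        beta_std=np.asarray(doc["beta_std"], dtype=float),
        lam=float(doc["lambda"]),
        alpha=float(doc["alpha"]),
        feature_names=tuple(doc["feature_names"]),
        x_mean=np.asarray(doc["x_mean"], dtype=float),
        x_sd=np.asarray(doc["x_sd"], dtype=float),
        y_mean=float(doc["y_mean"]),
    )


# ---------------------------------------------------------------------------
# cross-validated penalty selection and leave-one-out prediction


@dataclass(frozen=True)
class LassoConfig:
    """Solver and cross-validation settings."""

    alpha: float = 1.0
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    inner_folds: int = 10
    seed: int = 0
    single_lambda: bool = False
    tol: float = DEFAULT_TOL
    max_sweeps: int = DEFAULT_MAX_SWEEPS


def _fold_assignment(n: int, n_folds: int, seed_key) -> np.ndarray:
    rng = np.random.default_rng(seed_key)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    folds[perm] = np.arange(n) % n_folds
    return folds


def _path_predictions(dm: DesignMatrix, grid: np.ndarray, X_new: np.ndarray,
                      cfg: LassoConfig) -> np.ndarray:
    """Original-unit predictions of X_new for every penalty on the grid."""
    G, c = _gram(dm)
    betas, sweeps = _cd_path(G, c, grid * cfg.alpha, grid * (1.0 - cfg.alpha),
                             cfg.max_sweeps, cfg.tol)
    coefs = betas / dm.x_sd  # (n_lam, p) original units
    intercepts = dm.y_mean - coefs @ dm.x_mean
    return X_new @ coefs.T + intercepts  # (n_new, n_lam)


def cv_lambda_curve(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    cfg: LassoConfig,
    seed_key,
    feature_names=None,
) -> tuple[np.ndarray, float]:
    """K-fold CV curve of mean squared prediction error over a penalty grid.

    Returns (cv_curve, chosen_lambda); ties within 1e-12 of the minimum go
    to the largest (most parsimonious) penalty.
    """
    n = len(y)
    folds = _fold_assignment(n, cfg.inner_folds, seed_key)
    sse = np.zeros(len(grid))
    for f in range(cfg.inner_folds):
        test = folds == f
        if not test.any():
            continue
        dm = standardize(X[~test], y[~test], feature_names)
        preds = _path_predictions(dm, grid, X[test], cfg)
        sse += ((preds - y[test, None]) ** 2).sum(axis=0)
    curve = sse / n
    # grid is descending, so the first index within tolerance is the largest lambda
    chosen_idx = int(np.flatnonzero(curve <= curve.min() + 1e-12)[0])
    return curve, float(grid[chosen_idx])


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out predictions plus the full-data ("final optimal") model."""

    loo_predictions: np.ndarray
    lambda_grid: np.ndarray
    cv_curve: np.ndarray  # full-data K-fold curve
    chosen_lambda: float  # penalty of the full-data final model
    final_model: LassoModel
    per_row_lambda: np.ndarray
    config: LassoConfig


def loo_predictions(
    X: np.ndarray,
    y: np.ndarray,
    cfg: LassoConfig | None = None,
    feature_names=None,
) -> LooResult:
    """Leave-one-out cross-validated predictions.

    Each observation is predicted by a model fitted on the other N - 1 rows;
    within each fold the penalty is selected by an inner 10-fold CV on those
    rows (or, in ``single_lambda`` mode, fixed at the penalty chosen once on
    the full data). Also fits the final model on all N rows at its
    CV-chosen penalty. Fully deterministic given ``cfg.seed``.
    """
    cfg = cfg or LassoConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 10:
        raise ValidationError(f"leave-one-out needs at least 10 rows, got {n}")

    dm_full = standardize(X, y, feature_names)
    grid_full = lambda_grid(dm_full, cfg.n_lambdas, cfg.lambda_min_ratio)
    curve_full, chosen_full = cv_lambda_curve(
        X, y, grid_full, cfg, seed_key=[cfg.seed, n], feature_names=feature_names
    )
    final_model = fit_lasso(dm_full, chosen_full, cfg.alpha, cfg.tol, cfg.max_sweeps)

    preds = np.empty(n)
    lams = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        Xi, yi = X[keep], y[keep]
        dm_i = standardize(Xi, yi, feature_names)
        if cfg.single_lambda:
            lam_i = chosen_full
        else:
            grid_i = lambda_grid(dm_i, cfg.n_lambdas, cfg.lambda_min_ratio)
            _, lam_i = cv_lambda_curve(
                Xi, yi, grid_i, cfg, seed_key=[cfg.seed, i], feature_names=feature_names
            )
        model_i = fit_lasso(dm_i, lam_i, cfg.alpha, cfg.tol, cfg.max_sweeps)
        preds[i] = predict(model_i, X[i])
        lams[i] = lam_i
        keep[i] = True
    return LooResult(
        loo_predictions=preds,
        lambda_grid=grid_full,
        cv_curve=curve_full,
        chosen_lambda=chosen_full,
        final_model=final_model,
        per_row_lambda=lams,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# model / results wrappers


class LassoRegression:
    """Penalized linear regression model bound to a data set.

    Parameters
    ----------
    y : array-like, shape (n,)
        Response in original units (e.g. axial length in mm).
    X : array-like or DataFrame, shape (n, p)
        Feature matrix; a DataFrame supplies feature names.
    alpha : float
        Elastic-net mixing parameter; 1.0 is the pure LASSO.
    """

    def __init__(self, y, X, feature_names=None, alpha: float = 1.0):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        self.alpha = float(alpha)
        self.design = standardize(self.X, self.y, feature_names)
        self.feature_names = self.design.feature_names

    @classmethod
    def from_feature_table(
        cls, table: pd.DataFrame, outcome: str, alpha: float = 1.0
    ) -> "LassoRegression":
        """Build from a 42-parameter feature table with an RE or AL label column."""
        if outcome not in table.columns:
            raise SchemaError(f"outcome column {outcome!r} not in table")
        missing = [f for f in FEATURE_NAMES if f not in table.columns]
        if missing:
            raise SchemaError(f"feature table missing column(s): {', '.join(missing)}")
        return cls(
            y=table[outcome].to_numpy(dtype=float),
            X=table.loc[:, list(FEATURE_NAMES)],
            alpha=alpha,
        )

    @property
    def lambda_max(self) -> float:
        return float(lambda_grid(self.design, n_lambdas=2)[0])

    def lambda_grid(self, n_lambdas: int = 100, min_ratio: float = 1e-4) -> np.ndarray:
        return lambda_grid(self.design, n_lambdas, min_ratio)

    def fit(self, lam: float, tol: float = DEFAULT_TOL,
            max_sweeps: int = DEFAULT_MAX_SWEEPS) -> "LassoResults":
        return LassoResults(self, fit_lasso(self.design, lam, self.alpha, tol, max_sweeps))

    def fit_path(self, grid: np.ndarray | None = None) -> pd.DataFrame:
        """Coefficients (original units) along the penalty path, one row per lambda."""
        grid = self.lambda_grid() if grid is None else np.asarray(grid, dtype=float)
        cfg = LassoConfig(alpha=self.alpha)
        G, c = _gram(self.design)
        betas, _ = _cd_path(G, c, grid * cfg.alpha, grid * (1.0 - cfg.alpha),
                            cfg.max_sweeps, cfg.tol)
        coefs = betas / self.design.x_sd
        out = pd.DataFrame(coefs, columns=list(self.feature_names))
        out.insert(0, "lambda", grid)
        return out

    def fit_cv(self, n_folds: int = 10, seed: int = 0,
               grid: np.ndarray | None = None) -> "LassoResults":
        """Fit at the penalty minimising K-fold CV error (largest lambda on ties)."""
        grid = self.lambda_grid() if grid is None else np.asarray(grid, dtype=float)
        cfg = LassoConfig(alpha=self.alpha, inner_folds=n_folds, seed=seed)
        curve, chosen = cv_lambda_curve(
            self.X, self.y, grid, cfg, seed_key=[seed, len(self.y)],
            feature_names=self.feature_names,
        )
        res = LassoResults(self, fit_lasso(self.design, chosen, self.alpha))
        res.cv_curve = curve
        res.cv_grid = grid
        return res

    def fit_loo(self, cfg: LassoConfig | None = None) -> "LooResults":
        cfg = cfg or LassoConfig(alpha=self.alpha)
        if cfg.alpha != self.alpha:
            cfg = replace(cfg, alpha=self.alpha)
        return LooResults(self, loo_predictions(self.X, self.y, cfg, self.feature_names))


class LassoResults:
    """Fitted-model results: coefficients, penalty, diagnostics, prediction."""

    def __init__(self, model: LassoRegression | None, fitted: LassoModel):
        self.model = model
        self.fitted = fitted
        self.cv_curve: np.ndarray | None = None
        self.cv_grid: np.ndarray | None = None

    @property
    def params(self) -> pd.Series:
        return self.fitted.params

    @property
    def intercept(self) -> float:
        return self.fitted.intercept

    @property
    def lam(self) -> float:
        return self.fitted.lam

    @property
    def alpha(self) -> float:
        return self.fitted.alpha

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.fitted.coef))

    def predict(self, data) -> float | np.ndarray:
        return predict(self.fitted, data)

    def fittedvalues(self) -> np.ndarray:
        if self.model is None:
            raise ValidationError("results not bound to a model with data")
        return predict(self.fitted, self.model.X)

    def max_kkt_violation(self) -> float:
        if self.model is None:
            raise ValidationError("results not bound to a model with data")
        return kkt_violation(self.fitted, self.model.design)

    def objective(self) -> float:
        if self.model is None:
            raise ValidationError("results not bound to a model with data")
        return lasso_objective(0.0, self.fitted.beta_std, self.model.design,
                               self.fitted.lam, self.fitted.alpha)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(model_to_dict(self.fitted), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "LassoResults":
        with open(path) as fh:
            return cls(model=None, fitted=model_from_dict(json.load(fh)))

    def summary(self) -> str:
        f = self.fitted
        lines = [
            "Penalized linear regression (coordinate descent)",
            f"  alpha (l1 mixing): {f.alpha:.3f}    lambda: {f.lam:.6g}",
            f"  nonzero coefficients: {self.nnz} / {len(f.coef)}",
            f"  intercept: {f.intercept:.6g}",
            "",
            f"  {'feature':<16}{'coef (orig units)':>20}",
        ]
        for name, b in zip(f.feature_names, f.coef):
            shown = f"{b:.6g}" if b != 0.0 else "N.S."
            lines.append(f"  {name:<16}{shown:>20}")
        return "\n".join(lines)


class LooResults:
    """Leave-one-out cross-validation results."""

    def __init__(self, model: LassoRegression, result: LooResult):
        self.model = model
        self.result = result
        self.final = LassoResults(model, result.final_model)

    @property
    def loo_predictions(self) -> np.ndarray:
        return self.result.loo_predictions

    @property
    def chosen_lambda(self) -> float:
        return self.result.chosen_lambda

    @property
    def cv_curve(self) -> np.ndarray:
        return self.result.cv_curve

    @property
    def lambda_grid(self) -> np.ndarray:
        return self.result.lambda_grid

    def summary(self) -> str:
        p = self.loo_predictions
        lines = [
            "Leave-one-out cross-validation",
            f"  n: {len(p)}    final lambda: {self.chosen_lambda:.6g}",
            f"  LOO predictions: mean {p.mean():.4g}, sd {p.std(ddof=1):.4g}",
            f"  final model nonzero coefficients: {self.final.nnz}",
        ]
        return "\n".join(lines)
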