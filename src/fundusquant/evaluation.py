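"""Cohort eligibility filtering, prediction-accuracy metrics, and reports.

Eligibility follows the refraction window of the source cohort: eyes whose
refractive error exceeds +5 D or is below -8 D are removed (strict
inequalities, boundary values kept; both thresholds configurable).

Accuracy of leave-one-out predictions is summarised by the mean absolute
error with the standard deviation of the absolute errors, and by Pearson's
correlation between actual and predicted values with a two-sided p-value
from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom. The
per-feature report lists the final-model coefficient (``N.S.`` when the
penalty excluded the feature) next to the univariate Pearson correlation of
that feature with the outcome.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, SchemaError, ValidationError
from .io import FEATURE_NAMES
from .lasso import LooResults

__all__ = [
    "apply_eligibility",
    "mean_absolute_error",
    "pearson_correlation",
    "PredictionReport",
    "build_report",
]

RE_UPPER_DEFAULT = 5.0
RE_LOWER_DEFAULT = -8.0


def apply_eligibility(
    table: pd.DataFrame,
    re_hi: float = RE_UPPER_DEFAULT,
    re_lo: float = RE_LOWER_DEFAULT,
) -> tuple[pd.DataFrame, int]:
    """Remove rows with RE > re_hi or RE < re_lo (boundary values kept).

    Returns the filtered table and the number of rows removed.
    """
    if "RE" not in table.columns:
        raise SchemaError("eligibility filter requires an 'RE' column")
    keep = ~((table["RE"] > re_hi) | (table["RE"] < re_lo))
    filtered = table.loc[keep].reset_index(drop=True)
    return filtered, int((~keep).sum())


def mean_absolute_error(actual, predicted) -> tuple[float, float]:
    """Mean absolute error and the sample sd (denominator n-1) of the absolute errors."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if len(a) != len(p):
        raise ValidationError(f"length mismatch: {len(a)} vs {len(p)}")
    if len(a) < 2:
        raise ValidationError("need at least 2 paired values")
    abs_err = np.abs(a - p)
    return float(abs_err.mean()), float(abs_err.std(ddof=1))


def pearson_correlation(a, b) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value from the t distribution."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValidationError(f"length mismatch: {len(a)} vs {len(b)}")
    n = len(a)
    if n < 3:
        raise ValidationError("Pearson correlation needs at least 3 pairs")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise DegenerateInputError("Pearson correlation undefined for a constant vector")
    da, db = a - a.mean(), b - b.mean()
    ssa, ssb = float(da @ da), float(db @ db)
    if ssa == 0.0 or ssb == 0.0:
        raise DegenerateInputError("Pearson correlation undefined for a constant vector")
    r = float(da @ db / np.sqrt(ssa * ssb))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


@dataclass
class PredictionReport:
    """Accuracy summary for one outcome (RE or AL) plus a per-feature table."""

    outcome: str
    n: int
    actual_mean: float
    actual_sd: float
    predicted_mean: float
    predicted_sd: float
    mae: float
    mae_sd: float
    pearson_r: float
    p_value: float
    feature_table: pd.DataFrame  # columns: feature, coefficient, selected, r, p
    scatter: pd.DataFrame  # columns: eye_id, actual, predicted

    def summary(self) -> str:
        unit = "D" if self.outcome == "RE" else "mm"
        r_txt = "undefined" if np.isnan(self.pearson_r) else f"{self.pearson_r:.3f}"
        sig = ""
        if not np.isnan(self.p_value):
            sig = " (p < 0.001)" if self.p_value < 1e-3 else f" (p = {self.p_value:.3g})"
        lines = [
            f"Prediction of {self.outcome} from 42 fundus parameters "
            f"(leave-one-out cross-validation, n = {self.n})",
            f"  actual:    {self.actual_mean:.2f} +/- {self.actual_sd:.2f} {unit}",
            f"  predicted: {self.predicted_mean:.2f} +/- {self.predicted_sd:.2f} {unit}",
            f"  mean absolute error: {self.mae:.2f} {unit} (SD {self.mae_sd:.2f})",
            f"  Pearson r(actual, predicted): {r_txt}{sig}",
            f"  features selected by the final model: "
            f"{int(self.feature_table['selected'].sum())} / {len(self.feature_table)}",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "outcome": self.outcome,
            "n": self.n,
            "actual_mean": self.actual_mean,
            "actual_sd": self.actual_sd,
            "predicted_mean": self.predicted_mean,
            "predicted_sd": self.predicted_sd,
            "mae": self.mae,
            "mae_sd": self.mae_sd,
            "pearson_r": None if np.isnan(self.pearson_r) else self.pearson_r,
            "p_value": None if np.isnan(self.p_value) else self.p_value,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    def feature_csv(self, path: str | Path) -> None:
        out = self.feature_table.copy()
        out["coefficient"] = [
            "N.S." if not sel else f"{c:.6g}"
            for sel, c in zip(out["selected"], out["coefficient"])
        ]
        out.drop(columns="selected").to_csv(path, index=False)

    def scatter_csv(self, path: str | Path) -> None:
        self.scatter.to_csv(path, index=False)


def build_report(loo: LooResults, table: pd.DataFrame, outcome: str) -> PredictionReport:
    """Assemble a PredictionReport from LOO results and the feature table they
    were computed on (after eligibility filtering).

    A degenerate final model (constant predictions, e.g. the all-null model)
    yields NaN correlation with a warning; the MAE remains defined.
    """
    if outcome not in table.columns:
        raise SchemaError(f"outcome column {outcome!r} not in table")
    actual = table[outcome].to_numpy(dtype=float)
    predicted = np.asarray(loo.loo_predictions, dtype=float)
    if len(actual) != len(predicted):
        raise ValidationError(
            f"table has {len(actual)} rows but LOO produced {len(predicted)} predictions"
        )
    if len(actual) < 3:
        raise ValidationError("report needs at least 3 eyes")
    mae, mae_sd = mean_absolute_error(actual, predicted)
    try:
        r, p = pearson_correlation(actual, predicted)
    except DegenerateInputError as exc:
        warnings.warn(f"correlation undefined: {exc}", stacklevel=2)
        r, p = float("nan"), float("nan")

    coef = loo.final.params
    rows = []
    for name in FEATURE_NAMES:
        fr, fp = pearson_correlation(table[name].to_numpy(dtype=float), actual)
        rows.append(
            {
                "feature": name,
                "coefficient": float(coef[name]),
                "selected": bool(coef[name] != 0.0),
                "r": fr,
                "p": fp,
            }
        )
    feature_table = pd.DataFrame(rows)
    scatter = pd.DataFrame(
        {
            "eye_id": table["eye_id"].to_numpy() if "eye_id" in table.columns
            else np.arange(len(actual)),
            "actual": actual,
            "predicted": predicted,
        }
    )
    return PredictionReport(
        outcome=outcome,
        n=len(actual),
        actual_mean=float(actual.mean()),
        actual_sd=float(actual.std(ddof=1)),
        predicted_mean=float(predicted.mean()),
        predicted_sd=float(predicted.std(ddof=1)),
        mae=mae,
        mae_sd=mae_sd,
        pearson_r=r,
        p_value=p,
        feature_table=feature_table,
        scatter=scatter,
    )
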