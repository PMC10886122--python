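"""Per-modality brain-age prediction and BrainAGE computation.

The predictor is an L1-penalized (Lasso) linear regression of
chronological age on one modality's standardized IDPs, with the penalty
chosen from a fixed grid by cross-validated mean absolute error.  Raw
predictions regress toward the training-set mean age, so predicted age
is *age-bias corrected* using the training-set regression of predicted
on chronological age,

    corrected = raw - alpha - beta * age,

where alpha and beta are the intercept and slope of that regression.
In the default ``residual`` mode this corrected value is itself the
brain-age gap (BrainAGE): its training-set mean is exactly 0 and it is
exactly uncorrelated with age (ordinary-least-squares orthogonality).
The ``rescale`` mode instead maps raw predictions back onto the age
scale, (raw - alpha)/beta, and BrainAGE = corrected - age.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .cohort_io import Cohort

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "BrainAgeModel",
    "BrainAgeResult",
    "split_cohort",
    "fit_brainage_model",
    "apply_bias_correction",
    "compute_brainage",
    "predict_brainage",
    "evaluate_mae",
]

# Penalty grid searched for the Lasso regularization strength.
DEFAULT_ALPHA_GRID: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)

CORRECTION_MODES = ("residual", "rescale", "none")


class ModelError(ValueError):
    pass


def split_cohort(
    cohort: Cohort, train_fraction: float = 0.40, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Random disjoint train/test partition (default 40% train / 60% test).

    The train size is floor(fraction * n); rows keep their cohort order
    within each part.  Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ModelError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n = cohort.n_subjects
    if n < 2:
        raise ModelError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)  # both parts nonempty
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return cohort.subset(train_idx), cohort.subset(test_idx)


@dataclass
class BrainAgeModel:
    """A fitted sparse linear brain-age predictor for one modality.

    ``penalty`` is the selected Lasso alpha; ``bias_alpha``/``bias_beta``
    are the intercept/slope of the training regression of raw predicted
    age on chronological age (the age-bias correction line) — named
    distinctly from the Lasso penalty to avoid the alpha/alpha clash.
    """

    modality: str
    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    penalty: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    dropped_features: tuple[str, ...]
    bias_alpha: float
    bias_beta: float
    correction_mode: str = "residual"
    cv_mae_by_alpha: dict = field(default_factory=dict)

    def predict_raw(self, cohort: Cohort) -> np.ndarray:
        X = cohort.data.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        Xs = (X - self.feature_means) / self.feature_sds
        return Xs @ self.coefficients + self.intercept

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    # -- persistence ----------------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "modality": self.modality,
            "feature_names": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "penalty": self.penalty,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "dropped_features": list(self.dropped_features),
            "bias_alpha": self.bias_alpha,
            "bias_beta": self.bias_beta,
            "correction_mode": self.correction_mode,
            "cv_mae_by_alpha": {str(k): v for k, v in self.cv_mae_by_alpha.items()},
        }
        path.write_text(json.dumps(doc, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "BrainAgeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            modality=d["modality"],
            feature_names=tuple(d["feature_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            penalty=float(d["penalty"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            dropped_features=tuple(d["dropped_features"]),
            bias_alpha=float(d["bias_alpha"]),
            bias_beta=float(d["bias_beta"]),
            correction_mode=d["correction_mode"],
            cv_mae_by_alpha={float(k): v for k, v in d["cv_mae_by_alpha"].items()},
        )


@dataclass
class BrainAgeResult:
    """Per-subject predictions for one modality."""

    modality: str
    subject_ids: np.ndarray
    chronological_age: np.ndarray
    predicted_raw: np.ndarray
    corrected_value: np.ndarray
    brainage: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "age": self.chronological_age,
                f"predicted_raw_{self.modality}": self.predicted_raw,
                f"corrected_{self.modality}": self.corrected_value,
                f"brainage_{self.modality}": self.brainage,
            }
        )

    def brainage_series(self) -> pd.Series:
        return pd.Series(self.brainage, index=self.subject_ids)


def _fit_lasso(X: np.ndarray, y: np.ndarray, alpha: float) -> Lasso:
    model = Lasso(alpha=alpha, max_iter=20000, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def fit_brainage_model(
    train: Cohort,
    modality: str,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    correction_mode: str = "residual",
) -> BrainAgeModel:
    """Fit the Lasso brain-age model for one modality on the training cohort.

    Features are standardized with training statistics (constant columns
    dropped).  The penalty is selected by ``cv_folds``-fold CV minimizing
    MAE over ``alpha_grid``; ties go to the larger penalty.  The bias
    line (alpha, beta) is then an OLS fit of raw in-sample predictions
    on chronological age.
    """
    if cv_folds < 2:
        raise ModelError("cv_folds must be >= 2")
    if correction_mode not in CORRECTION_MODES:
        raise ModelError(f"unknown correction_mode {correction_mode!r}")
    if modality not in train.schema.modality_blocks:
        raise ModelError(f"unknown modality {modality!r}")
    if train.n_subjects < cv_folds:
        raise ModelError("training cohort smaller than cv_folds")

    cols = list(train.schema.modality_blocks[modality])
    X_all = train.data.loc[:, cols].to_numpy(dtype=float)
    y = train.data[train.schema.age_column].to_numpy(dtype=float)

    sds = X_all.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.any():
        raise ModelError(f"all features constant in modality {modality!r}")
    dropped = tuple(c for c, k in zip(cols, keep) if not k)
    cols = [c for c, k in zip(cols, keep) if k]
    X = X_all[:, keep]
    means, sds = X.mean(axis=0), X.std(axis=0, ddof=0)
    Xs = (X - means) / sds

    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(Xs))
    cv_mae: dict[float, float] = {}
    for alpha in alpha_grid:
        errs = []
        for tr, te in folds:
            m = _fit_lasso(Xs[tr], y[tr], alpha)
            errs.append(np.mean(np.abs(m.predict(Xs[te]) - y[te])))
        cv_mae[float(alpha)] = float(np.mean(errs))
    best = min(cv_mae.values())
    # ties (within float identity) resolved toward stronger regularization
    penalty = max(a for a, e in cv_mae.items() if e <= best + 1e-12)

    final = _fit_lasso(Xs, y, penalty)
    raw_train = final.predict(Xs)
    # bias line: raw predicted ~ alpha + beta * age on the training set
    beta, alpha_b = np.polyfit(y, raw_train, 1)

    return BrainAgeModel(
        modality=modality,
        feature_names=tuple(cols),
        coefficients=np.asarray(final.coef_, dtype=float),
        intercept=float(final.intercept_),
        penalty=float(penalty),
        feature_means=means,
        feature_sds=sds,
        dropped_features=dropped,
        bias_alpha=float(alpha_b),
        bias_beta=float(beta),
        correction_mode=correction_mode,
        cv_mae_by_alpha=cv_mae,
    )


def apply_bias_correction(
    model: BrainAgeModel, predicted_raw: np.ndarray, age: np.ndarray
) -> np.ndarray:
    """Remove the regression-toward-the-mean age bias from raw predictions.

    residual : raw - alpha - beta*age  (a deviation; used directly as BrainAGE)
    rescale  : (raw - alpha) / beta    (a corrected predicted age)
    none     : raw unchanged
    """
    predicted_raw = np.asarray(predicted_raw, dtype=float)
    age = np.asarray(age, dtype=float)
    if predicted_raw.shape != age.shape:
        raise ModelError("predicted and age vectors are not aligned")
    mode = model.correction_mode
    if mode == "residual":
        return predicted_raw - model.bias_alpha - model.bias_beta * age
    if mode == "rescale":
        if abs(model.bias_beta) < 1e-8:
            raise ModelError("bias slope too close to 0 for rescale mode")
        return (predicted_raw - model.bias_alpha) / model.bias_beta
    if mode == "none":
        return predicted_raw
    raise ModelError(f"unknown correction_mode {mode!r}")


def compute_brainage(
    predicted: np.ndarray, age: np.ndarray, mode: str = "residual"
) -> np.ndarray:
    """Brain-age gap from (corrected) predictions.

    In ``residual`` mode the corrected value already *is* the gap; in
    ``rescale``/``none`` modes BrainAGE = predicted age - chronological age.
    """
    predicted = np.asarray(predicted, dtype=float)
    age = np.asarray(age, dtype=float)
    if predicted.shape != age.shape:
        raise ModelError("predicted and age vectors are not aligned")
    if mode == "residual":
        return predicted.copy()
    if mode in ("rescale", "none"):
        return predicted - age
    raise ModelError(f"unknown correction_mode {mode!r}")


def predict_brainage(model: BrainAgeModel, cohort: Cohort) -> BrainAgeResult:
    """Raw prediction -> bias correction -> BrainAGE, for one cohort."""
    age = cohort.data[cohort.schema.age_column].to_numpy(dtype=float)
    raw = model.predict_raw(cohort)
    corrected = apply_bias_correction(model, raw, age)
    gap = compute_brainage(corrected, age, mode=model.correction_mode)
    return BrainAgeResult(
        modality=model.modality,
        subject_ids=cohort.subject_ids.to_numpy(),
        chronological_age=age,
        predicted_raw=raw,
        corrected_value=corrected,
        brainage=gap,
    )


def evaluate_mae(predicted: np.ndarray, age: np.ndarray) -> float:
    """Mean absolute error, years."""
    predicted = np.asarray(predicted, dtype=float)
    age = np.asarray(age, dtype=float)
    if predicted.shape != age.shape:
        raise ModelError("predicted and age vectors are not aligned")
    if predicted.size == 0:
        raise ModelError("cannot compute MAE of empty vectors")
    return float(np.mean(np.abs(predicted - age)))
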