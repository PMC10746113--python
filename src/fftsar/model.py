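"""PLSR modeling and leave-one-out cross-validation.

Half-life y (minutes) is regressed on extended-descriptor features by
partial least squares (mean-centered X and y, no variance scaling).
Model quality is reported as

    cvRMSE = sqrt( sum_i (y_i - yhat_i)^2 / S )          [minutes]
    R^2    = squared Pearson correlation of (y, yhat)    [0..1]

where yhat_i is the LOOCV prediction of sample i: the model fit on the
other S-1 samples.  cvRMSE drives model selection; R^2 reports
predictive concordance.  With only a dozen or two variants, LOOCV is
the only affordable and unbiased-enough validation scheme.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .aaindex import IndexPool
from .descriptors import feature_matrix
from .mutations import Variant
from .spectra import SpectrumOptions

#: default component cap; small-n datasets bound usable components anyway.
DEFAULT_MAX_COMPONENTS = 5


class ModelError(ValueError):
    """Degenerate input or infeasible component count."""


@dataclass(frozen=True)
class SarDataset:
    """Variants with measured half-lives, all sequences equal length."""

    variants: tuple[Variant, ...]
    name: str = ""

    def __post_init__(self):
        if len(self.variants) < 3:
            raise ModelError(
                f"dataset needs >= 3 variants for cross-validation, got {len(self.variants)}"
            )
        lengths = {len(v.sequence) for v in self.variants}
        if len(lengths) != 1:
            raise ModelError(f"sequences must share one length, got lengths {sorted(lengths)}")
        for v in self.variants:
            if v.half_life is None or not np.isfinite(v.half_life) or v.half_life <= 0:
                raise ModelError(f"variant {v.label} lacks a finite positive half-life")

    @property
    def n(self) -> int:
        return len(self.variants)

    @property
    def sequences(self) -> list[str]:
        return [v.sequence for v in self.variants]

    @property
    def labels(self) -> list[str]:
        return [v.label for v in self.variants]

    @property
    def y(self) -> np.ndarray:
        return np.array([v.half_life for v in self.variants], dtype=float)

    @property
    def seq_length(self) -> int:
        return len(self.variants[0].sequence)


@dataclass(frozen=True)
class ModelFit:
    """LOOCV result for one descriptor on one dataset."""

    accessions: tuple[str, ...]
    loocv_predictions: np.ndarray
    cvrmse: float
    r2: float
    n_components: int
    train_r2: float = float("nan")

    @property
    def label(self) -> str:
        return "-".join(self.accessions)


def compute_cvrmse(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Root-mean-squared error of the prediction vector (minutes)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or len(y) < 1:
        raise ModelError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def compute_r2(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Squared Pearson correlation between measured and predicted values."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or len(y) < 2:
        raise ModelError("need two equal-length vectors of length >= 2")
    yc = y - y.mean()
    hc = y_hat - y_hat.mean()
    denom = np.sum(yc**2) * np.sum(hc**2)
    if denom == 0:
        raise ModelError("R^2 undefined: zero variance in y or y_hat")
    return float(np.sum(yc * hc) ** 2 / denom)


class PLSPredictor:
    """Fitted mean-centered PLS regression; predicts half-life in minutes."""

    def __init__(self, coef: np.ndarray, x_mean: np.ndarray, y_mean: float, n_components: int):
        self.coef = np.asarray(coef, dtype=float).ravel()
        self.x_mean = np.asarray(x_mean, dtype=float)
        self.y_mean = float(y_mean)
        self.n_components = int(n_components)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "n_components": self.n_components,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSPredictor":
        return cls(np.array(d["coef"]), np.array(d["x_mean"]), d["y_mean"], d["n_components"])


def max_feasible_components(n_train: int, n_features: int) -> int:
    return max(1, min(n_train - 1, n_features))


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSPredictor:
    """Fit PLS regression of y on X with the given latent-variable count.

    Deterministic; X and y are mean-centered, columns are not
    variance-scaled (amplitude magnitudes are comparable across
    frequency bins and carry signal).  If X has no variance after
    centering the predictor falls back to the training mean.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ModelError(f"X has {X.shape[0]} rows but y has {len(y)} values")
    if len(y) < 2:
        raise ModelError("need at least 2 training samples")
    if np.ptp(y) == 0:
        raise ModelError("zero-variance response: nothing to regress")
    cap = max_feasible_components(len(y), X.shape[1])
    if not (1 <= n_components <= cap):
        raise ModelError(
            f"n_components={n_components} infeasible; maximum here is {cap}"
        )
    x_mean = X.mean(axis=0)
    if not np.any(X - x_mean):
        return PLSPredictor(np.zeros(X.shape[1]), x_mean, float(y.mean()), 0)
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # y residual may deflate to ~0 on exact fits
        pls.fit(X, y)
    return PLSPredictor(pls.coef_.ravel(), x_mean, float(y.mean()), n_components)


def resolve_n_components(
    policy: int | str,
    n_train: int,
    n_features: int,
) -> int:
    """Map an n_components policy to a concrete count for a training fold.

    ``"auto"`` (default policy) gives min(5, n_train - 1, n_features);
    an integer is clipped to the feasible maximum.
    """
    cap = max_feasible_components(n_train, n_features)
    if policy == "auto":
        return min(DEFAULT_MAX_COMPONENTS, cap)
    n = int(policy)
    if n < 1:
        raise ModelError(f"n_components must be >= 1, got {n}")
    return min(n, cap)


def loocv_predict(X: np.ndarray, y: np.ndarray, n_components: int | str = "auto") -> np.ndarray:
    """LOOCV prediction vector: sample i predicted by a fit on the rest."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        ncomp = resolve_n_components(n_components, n - 1, X.shape[1])
        model = fit_pls(X[mask], y[mask], ncomp)
        preds[i] = model.predict(X[i : i + 1])[0]
    return preds


def sweep_n_components(X: np.ndarray, y: np.ndarray, max_components: int = 8) -> int:
    """Pick the component count (1..max feasible) minimizing LOOCV cvRMSE."""
    cap = min(max_components, max_feasible_components(len(y) - 1, np.atleast_2d(X).shape[1]))
    best_n, best_err = 1, np.inf
    for n in range(1, cap + 1):
        err = compute_cvrmse(y, loocv_predict(X, y, n))
        if err < best_err:
            best_n, best_err = n, err
    return best_n


def loocv_evaluate(
    dataset: SarDataset,
    accessions: Sequence[str],
    pool: IndexPool,
    n_components: int | str = "auto",
    options: SpectrumOptions | None = None,
    X: np.ndarray | None = None,
) -> ModelFit:
    """LOOCV a descriptor on a dataset; returns predictions, cvRMSE, R^2.

    ``X`` short-circuits feature building when the caller already holds
    the (variants x features) matrix (the selection strategies cache
    per-index spectra).  ``n_components`` may be an integer, ``"auto"``,
    or ``"sweep"`` (inner LOOCV over 1..8 minimizing cvRMSE).
    """
    if X is None:
        X = feature_matrix(dataset.sequences, accessions, pool, options)
    y = dataset.y
    if n_components == "sweep":
        n_components = sweep_n_components(X, y)
    preds = loocv_predict(X, y, n_components)
    ncomp_used = resolve_n_components(
        n_components if n_components != "sweep" else "auto", dataset.n - 1, X.shape[1]
    )
    full = fit_pls(X, y, resolve_n_components(n_components, dataset.n, X.shape[1]))
    train_r2 = compute_r2(y, full.predict(X)) if np.ptp(full.predict(X)) > 0 else float("nan")
    return ModelFit(
        accessions=tuple(accessions),
        loocv_predictions=preds,
        cvrmse=compute_cvrmse(y, preds),
        r2=compute_r2(y, preds),
        n_components=ncomp_used,
        train_r2=train_r2,
    )


def save_model(
    path: str | Path,
    fit: ModelFit,
    predictor: PLSPredictor,
    block_lengths: Sequence[int],
    options: SpectrumOptions | None = None,
    dataset_name: str = "",
) -> None:
    """Persist a fitted model as a JSON sidecar for bit-for-bit replay."""
    options = options or SpectrumOptions()
    payload = {
        "format": "fftsar-model/1",
        "accessions": list(fit.accessions),
        "block_lengths": list(block_lengths),
        "spectrum": {
            "mode": options.mode,
            "drop_dc": options.drop_dc,
            "zscore_index": options.zscore_index,
        },
        "predictor": predictor.to_dict(),
        "loocv": {
            "cvrmse": fit.cvrmse,
            "r2": fit.r2,
            "n_components": fit.n_components,
            "predictions": fit.loocv_predictions.tolist(),
        },
        "dataset": dataset_name,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> dict:
    """Load a persisted model; returns the payload with a live predictor."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "fftsar-model/1":
        raise ModelError(f"{path}: not a fftsar model artifact")
    payload["predictor"] = PLSPredictor.from_dict(payload["predictor"])
    payload["spectrum_options"] = SpectrumOptions(**payload["spectrum"])
    return payload


def fit_full_model(
    dataset: SarDataset,
    accessions: Sequence[str],
    pool: IndexPool,
    n_components: int | str = "auto",
    options: SpectrumOptions | None = None,
) -> tuple[ModelFit, PLSPredictor, list[int]]:
    """LOOCV-evaluate a descriptor and fit the final predictor on all data."""
    from .descriptors import make_ext_seq

    desc0 = make_ext_seq(dataset.sequences[0], accessions, pool, options)
    X = feature_matrix(dataset.sequences, accessions, pool, options)
    fit = loocv_evaluate(dataset, accessions, pool, n_components, options, X=X)
    if n_components == "sweep":
        ncomp = fit.n_components
    else:
        ncomp = resolve_n_components(n_components, dataset.n, X.shape[1])
    predictor = fit_pls(X, dataset.y, ncomp)
    return fit, predictor, list(desc0.block_lengths)
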