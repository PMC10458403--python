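"""Perceptron chaos sensor: a single-hidden-layer net approximating FuzzyEn.

The sensor maps an ISI window of length NL straight to an entropy value:
NL inputs, NH sigmoid hidden units, one linear output neuron,

    y = b_out + sum_h w_out[h] * sigmoid(b_in[h] + w_in[h] . (x - mu)),

where mu is a stored normalization constant (the grand mean of the
training data, or 0 when training on raw values).  Subtracting mu is
decisive in practice: raw ISI values (~32 time units) push the sigmoids
deep into saturation, and a single-hidden-neuron model then learns
nothing, while the same model on centered data tracks the entropy well.

The module follows the model/results idiom: :class:`ChaosSensor` holds
data and configuration, ``fit()`` returns a :class:`ChaosSensorResults`
carrying the learned :class:`SensorWeights`, goodness-of-fit metrics and
a ``summary()``; ``cross_validate()`` returns per-fold metrics.
Optimization is delegated to scikit-learn's MLPRegressor (squared-error
loss, adam) and the learned weights are then carried in the package's
own container with an independent forward pass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .datasets import WindowedDataset

__all__ = [
    "SensorWeights", "TrainingConfig", "EvalReport",
    "ChaosSensor", "ChaosSensorResults", "CrossValidationResults",
    "train_sensor", "predict_entropy", "k_fold_cross_validate",
    "train_test_cross", "regression_metrics", "build_equal_weight_model",
    "smooth_predictions", "save_model", "load_model",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class SensorWeights:
    """All parameters of the trained sensor.

    w_in : (nh, nl) input-to-hidden weights; b_in : (nh,) hidden biases.
    w_out : (nh,) hidden-to-output weights; b_out : output bias.
    norm_const : constant subtracted from raw inputs at inference.
    """

    nl: int
    nh: int
    norm_const: float
    w_in: np.ndarray
    b_in: np.ndarray
    w_out: np.ndarray
    b_out: float

    def __post_init__(self) -> None:
        w_in = np.asarray(self.w_in, dtype=float)
        b_in = np.asarray(self.b_in, dtype=float)
        w_out = np.asarray(self.w_out, dtype=float)
        if w_in.shape != (self.nh, self.nl):
            raise ValueError(f"w_in must be ({self.nh}, {self.nl}), got {w_in.shape}")
        if b_in.shape != (self.nh,) or w_out.shape != (self.nh,):
            raise ValueError("b_in and w_out must have shape (nh,)")
        if not np.isfinite(self.norm_const):
            raise ValueError("norm_const must be finite")
        object.__setattr__(self, "w_in", w_in)
        object.__setattr__(self, "b_in", b_in)
        object.__setattr__(self, "w_out", w_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Forward pass on already-centered inputs (no norm_const applied)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.nl:
            raise ValueError(f"window length {x.shape[1]} != NL={self.nl}")
        hidden = _sigmoid(x @ self.w_in.T + self.b_in)
        return hidden @ self.w_out + self.b_out

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Entropy predictions for raw (un-normalized) windows."""
        w = np.atleast_2d(np.asarray(windows, dtype=float))
        return self.forward(w - self.norm_const)

    def to_dict(self) -> dict:
        return {
            "nl": self.nl, "nh": self.nh, "norm_const": self.norm_const,
            "w_in": self.w_in.tolist(), "b_in": self.b_in.tolist(),
            "w_out": self.w_out.tolist(), "b_out": self.b_out,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorWeights":
        missing = {"nl", "nh", "norm_const", "w_in", "b_in", "w_out", "b_out"} - set(d)
        if missing:
            raise ValueError(f"model schema missing fields: {sorted(missing)}")
        return cls(
            nl=int(d["nl"]), nh=int(d["nh"]),
            norm_const=float(d["norm_const"]),
            w_in=np.asarray(d["w_in"], dtype=float),
            b_in=np.asarray(d["b_in"], dtype=float),
            w_out=np.asarray(d["w_out"], dtype=float),
            b_out=float(d["b_out"]),
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Architecture and optimizer settings.

    nh : hidden-layer size (1, 50 and 150 are the studied gradations).
    k : folds for cross-validation.
    normalize : center inputs by the training grand mean before fitting.
    max_epochs / batch_size / tol : adam settings; conventional regression
        defaults at this data scale.
    """

    nh: int = 50
    k: int = 10
    seed: int = 0
    normalize: bool = True
    max_epochs: int = 500
    batch_size: int = 200
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.nh < 1:
            raise ValueError("nh must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class EvalReport:
    """Regression metrics; ``per_fold`` is filled by cross-validation."""

    r2: float
    rmse: float
    mape: float
    per_fold: pd.DataFrame | None = None


def regression_metrics(
    y_true: Sequence[float], y_pred: Sequence[float]
) -> tuple[float, float, float]:
    """(R^2, RMSE, MAPE%) of predictions against targets.

    R^2 = 1 - SS_res/SS_tot (negative when worse than the mean
    predictor); MAPE excludes entries whose true value is exactly 0.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1 or yt.size == 0:
        raise ValueError("y_true and y_pred must be equal-length 1-D and non-empty")
    ss_tot = float(((yt - yt.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: y_true has zero variance")
    r2 = 1.0 - float(((yt - yp) ** 2).sum()) / ss_tot
    rmse = float(np.sqrt(np.mean((yt - yp) ** 2)))
    nz = yt != 0
    mape = float(np.mean(np.abs((yt[nz] - yp[nz]) / yt[nz])) * 100.0) if nz.any() else float("nan")
    return r2, rmse, mape


class ChaosSensor:
    """Perceptron sensor model bound to a windowed dataset.

    Parameters
    ----------
    windows, targets : training matrix (n, NL) in raw ISI units and the
        FuzzyEn targets.
    config : architecture/optimizer settings.
    """

    def __init__(
        self,
        windows: np.ndarray,
        targets: np.ndarray,
        config: TrainingConfig = TrainingConfig(),
    ) -> None:
        self.windows = np.atleast_2d(np.asarray(windows, dtype=float))
        self.targets = np.asarray(targets, dtype=float)
        if self.windows.shape[0] != self.targets.size or self.targets.size == 0:
            raise ValueError("windows and targets disagree in length or are empty")
        self.config = config

    @classmethod
    def from_dataset(
        cls, ds: WindowedDataset, config: TrainingConfig = TrainingConfig()
    ) -> "ChaosSensor":
        """Bind to a dataset, undoing any normalization already applied
        so that ``config.normalize`` alone decides the centering."""
        return cls(ds.windows + ds.normalization, ds.targets, config)

    @property
    def nl(self) -> int:
        return self.windows.shape[1]

    def _make_estimator(self, seed: int, n_rows: int) -> MLPRegressor:
        c = self.config
        return MLPRegressor(
            hidden_layer_sizes=(c.nh,),
            activation="logistic",
            solver="adam",
            batch_size=min(c.batch_size, n_rows),
            max_iter=c.max_epochs,
            tol=c.tol,
            random_state=seed,
        )

    def _fit_weights(self, x: np.ndarray, y: np.ndarray, norm: float, seed: int):
        est = self._make_estimator(seed, x.shape[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(x - norm, y)
        if not np.isfinite(est.loss_):
            raise FloatingPointError("non-finite training loss")
        weights = SensorWeights(
            nl=self.nl,
            nh=self.config.nh,
            norm_const=norm,
            w_in=est.coefs_[0].T.copy(),
            b_in=est.intercepts_[0].copy(),
            w_out=est.coefs_[1].ravel().copy(),
            b_out=float(est.intercepts_[1][0]),
        )
        return weights, est

    def fit(self, seed: int | None = None) -> "ChaosSensorResults":
        """Train on all rows; reproducible for a fixed seed."""
        seed = self.config.seed if seed is None else seed
        norm = float(self.windows.mean()) if self.config.normalize else 0.0
        weights, est = self._fit_weights(self.windows, self.targets, norm, seed)
        r2, rmse, mape = regression_metrics(self.targets, weights.predict(self.windows))
        return ChaosSensorResults(
            model=self,
            weights=weights,
            eval_report=EvalReport(r2, rmse, mape),
            n_epochs=est.n_iter_,
            loss=float(est.loss_),
        )

    def cross_validate(self, seed: int | None = None) -> "CrossValidationResults":
        """K-fold CV: every row is tested exactly once; splits are shuffled
        with the run seed.  All folds share the dataset's grand-mean
        normalization constant."""
        seed = self.config.seed if seed is None else seed
        k = self.config.k
        if k > self.windows.shape[0]:
            raise ValueError(f"k={k} exceeds n_rows={self.windows.shape[0]}")
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        rows = []
        oof = np.full(self.targets.size, np.nan)
        # the normalization constant is a property of the dataset (its
        # grand mean), applied once before splitting
        norm = float(self.windows.mean()) if self.config.normalize else 0.0
        for fold, (tr, te) in enumerate(kf.split(self.windows)):
            weights, _ = self._fit_weights(
                self.windows[tr], self.targets[tr], norm, seed + fold
            )
            pred = weights.predict(self.windows[te])
            oof[te] = pred
            r2, rmse, mape = regression_metrics(self.targets[te], pred)
            rows.append({"fold": fold, "r2": r2, "rmse": rmse,
                         "mape": mape, "n_test": te.size})
        per_fold = pd.DataFrame(rows)
        report = EvalReport(
            r2=float(per_fold["r2"].mean()),
            rmse=float(per_fold["rmse"].mean()),
            mape=float(per_fold["mape"].mean()),
            per_fold=per_fold,
        )
        return CrossValidationResults(model=self, eval_report=report,
                                      oof_predictions=oof)


@dataclass(frozen=True)
class ChaosSensorResults:
    """Fitted sensor: learned weights plus in-sample fit quality."""

    model: ChaosSensor
    weights: SensorWeights
    eval_report: EvalReport
    n_epochs: int
    loss: float

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Entropy predictions for raw windows."""
        return self.weights.predict(windows)

    def simplify_equal_weights(self) -> "ChaosSensorResults":
        """Equal-weight variant (NH=1 only): replace all input weights by
        their common average; see :func:`build_equal_weight_model`."""
        weights = build_equal_weight_model(self.weights)
        r2, rmse, mape = regression_metrics(
            self.model.targets, weights.predict(self.model.windows)
        )
        return replace(self, weights=weights,
                       eval_report=EvalReport(r2, rmse, mape))

    def save(self, path: str | Path) -> None:
        save_model(self.weights, path)

    def summary(self) -> str:
        w, e = self.weights, self.eval_report
        lines = [
            "Chaos sensor (perceptron) fit",
            "=" * 38,
            f"inputs (NL)          {w.nl:>12d}",
            f"hidden units (NH)    {w.nh:>12d}",
            f"normalization const  {w.norm_const:>12.5f}",
            f"epochs run           {self.n_epochs:>12d}",
            f"final loss           {self.loss:>12.6f}",
            "-" * 38,
            f"in-sample R^2        {e.r2:>12.4f}",
            f"in-sample RMSE       {e.rmse:>12.4f}",
            f"in-sample MAPE (%)   {e.mape:>12.2f}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class CrossValidationResults:
    """K-fold evaluation: per-fold metrics and out-of-fold predictions."""

    model: ChaosSensor
    eval_report: EvalReport
    oof_predictions: np.ndarray

    @property
    def r2(self) -> float:
        return self.eval_report.r2

    def summary(self) -> str:
        e = self.eval_report
        lines = [
            f"{self.model.config.k}-fold cross-validation "
            f"(NH={self.model.config.nh}, "
            f"normalize={self.model.config.normalize})",
            "=" * 44,
            e.per_fold.to_string(index=False,
                                 float_format=lambda v: f"{v:.4f}"),
            "-" * 44,
            f"mean R^2  {e.r2:.4f}   mean RMSE {e.rmse:.4f}   "
            f"mean MAPE {e.mape:.2f}%",
        ]
        return "\n".join(lines)


def train_sensor(ds: WindowedDataset, cfg: TrainingConfig) -> SensorWeights:
    """Fit on the full dataset; returns the learned weights."""
    return ChaosSensor.from_dataset(ds, cfg).fit().weights


def predict_entropy(model: SensorWeights, window: Sequence[float]) -> float | np.ndarray:
    """Sensor output for one raw window (or a matrix of windows)."""
    w = np.asarray(window, dtype=float)
    out = model.predict(w)
    return float(out[0]) if w.ndim == 1 else out


def k_fold_cross_validate(ds: WindowedDataset, cfg: TrainingConfig) -> EvalReport:
    """K-fold CV metrics (mean over folds plus the per-fold table)."""
    return ChaosSensor.from_dataset(ds, cfg).cross_validate().eval_report


def train_test_cross(
    train_ds: WindowedDataset, test_ds: WindowedDataset, cfg: TrainingConfig
) -> EvalReport:
    """Fit on one dataset, evaluate on another.

    When ``cfg.normalize`` each set is centered by its OWN grand mean --
    the per-dataset constants are nearly equal for the standard builds,
    and a deployed sensor knows only its own input statistics.
    """
    if train_ds.nl != test_ds.nl:
        raise ValueError(f"window length mismatch: {train_ds.nl} vs {test_ds.nl}")
    result = ChaosSensor.from_dataset(train_ds, cfg).fit()
    raw_test = test_ds.windows + test_ds.normalization
    shift = float(raw_test.mean()) if cfg.normalize else 0.0
    pred = result.weights.forward(raw_test - shift)
    r2, rmse, mape = regression_metrics(test_ds.targets, pred)
    return EvalReport(r2, rmse, mape)


def build_equal_weight_model(trained: SensorWeights) -> SensorWeights:
    """Replace the NL input weights of an NH=1 model by their mean.

    The simplified sensor then depends only on the window mean: it
    averages the series and maps the average linearly (through one
    sigmoid) to entropy.
    """
    if trained.nh != 1:
        raise ValueError(f"equal-weight simplification requires NH=1, got NH={trained.nh}")
    return replace(trained, w_in=np.full_like(trained.w_in, trained.w_in.mean()))


def smooth_predictions(values: Sequence[float], window: int = 20) -> np.ndarray:
    """Trailing moving average; the first window-1 entries average the
    available prefix so the output aligns index-for-index with the input."""
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(values, dtype=float)
    c = np.concatenate([[0.0], np.cumsum(v)])
    n = v.size
    idx = np.arange(n)
    lo = np.maximum(idx - window + 1, 0)
    return (c[idx + 1] - c[lo]) / (idx + 1 - lo)


def save_model(model: SensorWeights, path: str | Path) -> None:
    """JSON serialization of all weights and the normalization constant."""
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path: str | Path) -> SensorWeights:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    return SensorWeights.from_dict(d)
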