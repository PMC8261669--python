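"""Five-level injury-score classification with an LM-trained network.

A 5-input, 10-hidden-neuron (tanh), 1-linear-output feedforward network
is trained as a regression on the injury score (1–5) by the
Levenberg–Marquardt algorithm: each epoch builds the Jacobian of the
residuals with respect to all 71 parameters and solves the damped normal
equations (JᵀJ + μI)Δ = Jᵀr, decreasing μ after an accepted step and
increasing it (and retrying) after a rejected one.  The continuous
output is binned to the five levels; the first bin starts at 0 and runs
to 1.5, each further bin is one unit wide, and everything at or above
4.5 maps to level 5.  Continuous outputs also support ranked selection
of the most tolerant fraction of plots.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

N_INPUTS, N_HIDDEN = 5, 10
N_PARAMS = N_INPUTS * N_HIDDEN + N_HIDDEN + N_HIDDEN + 1  # 71

#: upper bin edges of the output categorization; the first interval is
#: [0, 1.5) -> 1, then unit-wide bins, and [4.5, inf) -> 5
BIN_EDGES = (1.5, 2.5, 3.5, 4.5)


@dataclass
class FNNConfig:
    """Training hyperparameters (μ is the LM damping parameter)."""

    hidden_sizes: int = N_HIDDEN
    train_fcn: str = "levenberg_marquardt"
    epochs_max: int = 1000
    goal: float = 0.0
    max_fail: int = 6
    min_grad: float = 1e-7
    mu0: float = 1e-3
    mu_dec: float = 0.1
    mu_inc: float = 10.0
    mu_max: float = 1e10
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.mu0 < self.mu_max:
            raise ValueError("require 0 < mu0 < mu_max")
        if not self.mu_dec < 1 < self.mu_inc:
            raise ValueError("require mu_dec < 1 < mu_inc")
        if self.hidden_sizes != N_HIDDEN:
            raise ValueError("architecture is fixed at 5-10-1")


class FeatureScaler:
    """Per-feature affine map of the training min/max onto [−1, 1].

    Values outside the training range extrapolate (no clipping); a
    constant feature maps to 0 with a warning.  The inverse map recovers
    raw values exactly on non-constant features.
    """

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=np.float64)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        if np.any(self.max_ == self.min_):
            logger.warning("constant feature(s) %s mapped to 0",
                           np.where(self.max_ == self.min_)[0].tolist())
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.max_ - self.min_
        safe = np.where(span == 0, 1.0, span)
        out = 2.0 * (np.asarray(X, dtype=np.float64) - self.min_) / safe - 1.0
        return np.where(span == 0, 0.0, out)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        span = self.max_ - self.min_
        return (np.asarray(Xs, dtype=np.float64) + 1.0) / 2.0 * span + self.min_


@dataclass
class Split:
    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray
    seed: int


def split_dataset(ids, test_frac: float = 0.10, val_frac: float = 0.10,
                  seed: int = 0) -> Split:
    """Random 90/10 train/test split with a validation carve-out.

    Test size = floor(test_frac · n); the validation set for early
    stopping is floor(val_frac · remaining) taken from the training
    partition.  Deterministic given the seed.
    """
    ids = np.asarray(ids)
    n = ids.size
    if n < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B117]))
    perm = rng.permutation(n)
    n_test = int(math.floor(test_frac * n))
    n_val = int(math.floor(val_frac * (n - n_test)))
    test = ids[perm[:n_test]]
    val = ids[perm[n_test:n_test + n_val]]
    train = ids[perm[n_test + n_val:]]
    return Split(train_ids=train, val_ids=val, test_ids=test, seed=seed)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray):
    w1 = theta[:N_INPUTS * N_HIDDEN].reshape(N_HIDDEN, N_INPUTS)
    b1 = theta[50:60]
    w2 = theta[60:70]
    b2 = theta[70]
    return w1, b1, w2, b2


def _forward(theta: np.ndarray, X: np.ndarray):
    w1, b1, w2, b2 = _unpack(theta)
    hidden = np.tanh(X @ w1.T + b1)
    return hidden @ w2 + b2, hidden


def network_jacobian(theta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Jacobian of network outputs w.r.t. all 71 parameters, shape (n, 71)."""
    w1, b1, w2, b2 = _unpack(theta)
    hidden = np.tanh(X @ w1.T + b1)          # (n, 10)
    dtanh = (1.0 - hidden ** 2) * w2         # (n, 10)
    J = np.empty((X.shape[0], N_PARAMS))
    J[:, :50] = (dtanh[:, :, None] * X[:, None, :]).reshape(X.shape[0], 50)
    J[:, 50:60] = dtanh
    J[:, 60:70] = hidden
    J[:, 70] = 1.0
    return J


@dataclass
class TrainedFNN:
    theta: np.ndarray
    scaler: FeatureScaler
    config: FNNConfig
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)
    stop_reason: str = ""

    def predict_scaled(self, Xs: np.ndarray) -> np.ndarray:
        out, _ = _forward(self.theta, np.asarray(Xs, dtype=np.float64))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta": self.theta.tolist(),
            "scaler_min": self.scaler.min_.tolist(),
            "scaler_max": self.scaler.max_.tolist(),
            "config": self.config.__dict__,
            "stop_reason": self.stop_reason,
            "trace": self.trace.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedFNN":
        payload = json.loads(Path(path).read_text())
        scaler = FeatureScaler()
        scaler.min_ = np.asarray(payload["scaler_min"])
        scaler.max_ = np.asarray(payload["scaler_max"])
        return cls(theta=np.asarray(payload["theta"]), scaler=scaler,
                   config=FNNConfig(**payload["config"]),
                   trace=pd.DataFrame(payload["trace"]),
                   stop_reason=payload["stop_reason"])


def _mse(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    out, _ = _forward(theta, X)
    return float(np.mean((y - out) ** 2))


def lm_train(X_train: np.ndarray, y_train: np.ndarray,
             X_val: np.ndarray | None, y_val: np.ndarray | None,
             config: FNNConfig | None = None,
             scaler: FeatureScaler | None = None) -> TrainedFNN:
    """Levenberg–Marquardt training of the 5-10-1 network.

    Inputs are expected already scaled to roughly [−1, 1]; targets are the
    injury scores as real numbers.  Stops on the epoch budget, the
    performance goal, a vanishing gradient, μ exceeding μ_max, or
    ``max_fail`` consecutive validation failures (the weights with the
    best validation loss are restored).  Deterministic given the seed.
    """
    config = config or FNNConfig()
    config.validate()
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train, dtype=np.float64).ravel()
    has_val = X_val is not None and len(X_val) > 0
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF2B]))
    theta = rng.uniform(-0.5, 0.5, N_PARAMS)

    mu = config.mu0
    loss = _mse(theta, X, y)
    best_val = math.inf
    best_theta = theta.copy()
    fails = 0
    rows = []
    stop = ""
    epoch = 0
    while epoch < config.epochs_max:
        if loss <= config.goal:
            stop = "goal"
            break
        out, _ = _forward(theta, X)
        r = y - out
        J = network_jacobian(theta, X)
        grad = 2.0 * J.T @ r / X.shape[0]
        if np.linalg.norm(grad) < config.min_grad:
            stop = "min_grad"
            break
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = False
        while mu <= config.mu_max:
            try:
                delta = linalg.solve(JtJ + mu * np.eye(N_PARAMS), Jtr,
                                     assume_a="pos")
            except linalg.LinAlgError:
                mu *= config.mu_inc
                continue
            candidate = theta + delta
            cand_loss = _mse(candidate, X, y)
            if cand_loss < loss:
                theta, loss = candidate, cand_loss
                mu = max(mu * config.mu_dec, np.finfo(float).tiny)
                accepted = True
                break
            mu *= config.mu_inc
        if not accepted:
            stop = "mu_max"
            break
        epoch += 1
        val_loss = _mse(theta, X_val, np.asarray(y_val).ravel()) if has_val \
            else math.nan
        rows.append({"epoch": epoch, "loss": loss, "mu": mu,
                     "val_loss": val_loss})
        if has_val:
            if val_loss < best_val:
                best_val = val_loss
                best_theta = theta.copy()
                fails = 0
            else:
                fails += 1
                if fails >= config.max_fail:
                    stop = "max_fail"
                    theta = best_theta
                    break
    if not stop:
        stop = "epochs_max" if epoch >= config.epochs_max else "goal"
    if has_val and stop not in ("max_fail",) and best_val < _mse(
            theta, X_val, np.asarray(y_val).ravel()):
        theta = best_theta
    logger.info("LM training stopped after %d epochs (%s)", epoch, stop)
    return TrainedFNN(theta=theta, scaler=scaler or FeatureScaler(),
                      config=config, trace=pd.DataFrame(rows), stop_reason=stop)


# ---------------------------------------------------------------------------
# prediction, binning, evaluation
# ---------------------------------------------------------------------------

def predict_continuous(model: TrainedFNN, features: np.ndarray) -> np.ndarray:
    """Raw (unclipped) network outputs for raw feature rows."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.shape[1] != N_INPUTS:
        raise ValueError(f"expected {N_INPUTS} features, got {features.shape[1]}")
    return model.predict_scaled(model.scaler.transform(features))


def bin_fis(raw: np.ndarray | float) -> np.ndarray | int:
    """Categorize continuous outputs to integer injury levels 1–5.

    Bins: [0, 1.5)→1, [1.5, 2.5)→2, [2.5, 3.5)→3, [3.5, 4.5)→4,
    [4.5, ∞)→5.  Negative outputs (possible from the linear output
    neuron) are clipped to level 1.  Non-finite input raises.
    """
    arr = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite network output")
    levels = np.digitize(arr, BIN_EDGES) + 1
    out = levels.astype(int)
    return int(out) if np.isscalar(raw) else out


def accuracy(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Percent of test samples classified correctly."""
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    if predicted.size == 0 or predicted.shape != observed.shape:
        raise ValueError("label vectors must be non-empty and equal length")
    return 100.0 * float(np.mean(predicted == observed))


@dataclass
class ConfusionTable:
    counts: np.ndarray  # (5, 5): predicted level x observed level
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts,
                          index=[f"pred_{i}" for i in range(1, 6)],
                          columns=[f"obs_{i}" for i in range(1, 6)])
        df["total"] = df.sum(axis=1)
        df.loc["total"] = df.sum(axis=0)
        return df


def confusion(predicted: np.ndarray, observed: np.ndarray) -> ConfusionTable:
    """5×5 confusion counts (rows: predicted, cols: observed)."""
    predicted = np.asarray(predicted, dtype=int)
    observed = np.asarray(observed, dtype=int)
    for v in (predicted, observed):
        if v.size and (v.min() < 1 or v.max() > 5):
            raise ValueError("labels must lie in 1–5")
    counts = np.zeros((5, 5), dtype=int)
    np.add.at(counts, (predicted - 1, observed - 1), 1)
    return ConfusionTable(counts=counts, accuracy=accuracy(predicted, observed))


def select_top_fraction(raw_outputs: np.ndarray, plot_ids, fraction: float
                        ) -> list:
    """Most-tolerant selection: the ceil(fraction·n) lowest raw outputs.

    Lower predicted score means less injury; ties are broken by plot id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    raw_outputs = np.asarray(raw_outputs, dtype=np.float64)
    plot_ids = list(plot_ids)
    k = int(math.ceil(fraction * len(plot_ids)))
    order = sorted(range(len(plot_ids)),
                   key=lambda i: (raw_outputs[i], str(plot_ids[i])))
    return [plot_ids[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# per-height convenience wrapper
# ---------------------------------------------------------------------------

def train_fis_classifier(features: pd.DataFrame, seed: int = 0,
                         config: FNNConfig | None = None) -> dict:
    """Split, scale, train and evaluate on a per-height feature table.

    Invalid (empty-canopy) records are excluded before splitting.  Returns
    the trained model, the split, raw test outputs, the confusion table
    and the test accuracy.
    """
    from .features import FEATURE_COLUMNS
    df = features[features["valid"]].reset_index(drop=True)
    config = config or FNNConfig(seed=seed)
    if config.seed != seed:
        config = FNNConfig(**{**config.__dict__, "seed": seed})
    split = split_dataset(df.index.to_numpy(), seed=seed)
    Xall = df.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
    yall = df["fis"].to_numpy(dtype=np.float64)
    scaler = FeatureScaler().fit(Xall[split.train_ids])
    model = lm_train(scaler.transform(Xall[split.train_ids]), yall[split.train_ids],
                     scaler.transform(Xall[split.val_ids]), yall[split.val_ids],
                     config=config, scaler=scaler)
    raw = predict_continuous(model, Xall[split.test_ids])
    pred = bin_fis(raw)
    table = confusion(pred, df.loc[split.test_ids, "fis"].to_numpy(dtype=int))
    return {"model": model, "split": split, "raw_test_outputs": raw,
            "predicted": pred,
            "observed": df.loc[split.test_ids, "fis"].to_numpy(dtype=int),
            "test_plot_ids": df.loc[split.test_ids, "plot_id"].tolist(),
            "confusion": table, "accuracy": table.accuracy}
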