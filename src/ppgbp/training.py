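"""Training protocol: AdamW on joint-MSE with optional importance weights.

The protocol mirrors large-scale practice for waveform BP regression:
mean-squared error summed over the two outputs, AdamW, an effective
batch assembled by gradient accumulation from micro-batches, a fixed
epoch budget, and selection of the parameter snapshot with the best
validation score (mean of the SBP and DBP validation MAEs).

The public surface is a pair of scikit-learn style estimators
(:class:`NeuralBPRegressor`, :class:`MedianBaselineRegressor`); the
module-level :func:`train` / :func:`median_baseline` functions are thin
wrappers that operate on a SegmentStore + DatasetSplit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .models import ModelSpec, Regressor, build_model
from .nn import AdamW, Tensor

__all__ = [
    "TrainConfig", "TrainResult", "MedianBaseline", "TrainingError",
    "weighted_mse_loss", "train", "find_learning_rate", "select_rate_from_curve",
    "median_baseline", "baseline_predict",
    "NeuralBPRegressor", "MedianBaselineRegressor", "desk_scale_config",
]


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 50
    effective_batch: int = 512   # assembled by gradient accumulation
    micro_batch: int = 64
    weight_decay: float = 0.01
    renormalize_weights: bool = False  # optional mean-1 rescaling of weights
    init_output_bias: bool = True      # start head bias at train label means
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.effective_batch % self.micro_batch:
            raise ValueError("effective_batch must be divisible by micro_batch")


def desk_scale_config(**overrides) -> TrainConfig:
    """Small-budget preset for CPU-scale experiments."""
    base = TrainConfig(epochs=5, effective_batch=128, micro_batch=32)
    return replace(base, **overrides)


@dataclass
class TrainResult:
    model: Regressor
    history: list[dict]          # per-epoch {train_loss, val_score}
    best_epoch: int              # argmin of val_score
    config: TrainConfig


@dataclass(frozen=True)
class MedianBaseline:
    median_sbp: float
    median_dbp: float


# ----------------------------------------------------------------------
def weighted_mse_loss(pred, ref, w_sbp=None, w_dbp=None):
    """mean_i [ w_sbp_i (pred_sbp_i - ref_sbp_i)^2
               + w_dbp_i (pred_dbp_i - ref_dbp_i)^2 ].

    With unit weights this is the plain joint MSE (sum of the two
    per-output MSEs).  ``pred`` may be an autodiff Tensor (training
    path, returns a Tensor) or an ndarray (returns a float).
    """
    ref = np.asarray(ref, dtype=np.float64)
    n = ref.shape[0]
    pred_n = pred.shape[0] if hasattr(pred, "shape") else len(pred)
    if pred_n != n:
        raise ValueError(f"pred has {pred_n} rows, ref has {n}")
    w_sbp = np.ones(n) if w_sbp is None else np.asarray(w_sbp, dtype=np.float64)
    w_dbp = np.ones(n) if w_dbp is None else np.asarray(w_dbp, dtype=np.float64)
    if len(w_sbp) != n or len(w_dbp) != n:
        raise ValueError("weight vectors must match the number of samples")
    if (w_sbp < 0).any() or (w_dbp < 0).any():
        raise ValueError("weights must be nonnegative")
    W = np.stack([w_sbp, w_dbp], axis=1)
    if isinstance(pred, Tensor):
        err = pred - Tensor(ref.astype(np.float32))
        return (err * err * Tensor(W.astype(np.float32))).sum(axis=1).mean()
    err = np.asarray(pred, dtype=np.float64) - ref
    return float((W * err * err).sum(axis=1).mean())


def _val_score(model: Regressor, Xval, yval, micro_batch: int) -> float:
    """Mean of SBP-MAE and DBP-MAE on the validation set (mmHg)."""
    preds = []
    for lo in range(0, len(Xval), micro_batch):
        preds.append(model.predict_batch(Xval[lo:lo + micro_batch]))
    p = np.concatenate(preds)
    return float(np.abs(p - yval).mean(axis=0).mean())


def _fit_loop(model: Regressor, Xtr, ytr, Wtr, Xval, yval,
              config: TrainConfig, val_scorer=None) -> TrainResult:
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.init_output_bias:
        # learn deviations from the label means instead of the absolute
        # offset (~120/65 mmHg), which Adam's bounded step would need
        # thousands of updates to reach from zero
        model.net.head.bias.data[...] = ytr.mean(axis=0).astype(np.float32)
    opt = AdamW(model.net.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    n = len(Xtr)
    history: list[dict] = []
    best = (np.inf, None, -1)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        pos = 0
        opt.zero_grad()
        while pos < n:
            group = order[pos: pos + config.effective_batch]
            pos += config.effective_batch
            # accumulate micro-batch gradients into one effective batch
            for mlo in range(0, len(group), config.micro_batch):
                mb = group[mlo: mlo + config.micro_batch]
                out = model.forward(Xtr[mb], training=True)
                loss = weighted_mse_loss(out, ytr[mb], Wtr[mb, 0], Wtr[mb, 1])
                scaled = loss * (len(mb) / len(group))
                scaled.backward()
                losses.append(float(loss.data))
                if not np.isfinite(losses[-1]):
                    raise TrainingError(
                        f"non-finite training loss at epoch {epoch}")
            opt.step()
            opt.zero_grad()
        if val_scorer is not None:
            score = float(val_scorer(model, epoch))
        else:
            score = _val_score(model, Xval, yval, config.micro_batch)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_score": score})
        if score < best[0]:
            best = (score, model.net.state_dict(), epoch)
    if best[1] is not None:
        model.net.load_state_dict(best[1])
    return TrainResult(model=model, history=history, best_epoch=best[2],
                       config=config)


# ----------------------------------------------------------------------
class NeuralBPRegressor(RegressorMixin, BaseEstimator):
    """Joint SBP/DBP waveform regressor (scikit-learn estimator API).

    Parameters
    ----------
    architecture : str
        One of lenet1d, xresnet1d50, xresnet1d101, inception1d, ssm.
    scale : float
        Channel-width multiplier; < 1 shrinks models for CPU budgets.
    learning_rate, epochs, effective_batch, micro_batch, weight_decay :
        AdamW / accumulation protocol knobs.
    normalize : bool
        Per-segment z-score inside the model (default on).
    init_output_bias : bool
        Initialize the head bias at the training label means so the
        network learns deviations rather than the absolute offset.
    renormalize_weights : bool
        Optionally rescale importance weights to mean 1 (off by
        default: the floored ratio rule is used as-given).
    seed : int
        Controls initialization and batch shuffling.

    Attributes
    ----------
    model_ : Regressor           fitted network (best validation snapshot)
    history_ : list of dict      per-epoch train loss / validation score
    best_epoch_ : int            epoch whose snapshot was kept
    """

    def __init__(self, architecture: str = "lenet1d", scale: float = 1.0,
                 learning_rate: float = 1e-3, epochs: int = 50,
                 effective_batch: int = 512, micro_batch: int = 64,
                 weight_decay: float = 0.01, normalize: bool = True,
                 init_output_bias: bool = True,
                 renormalize_weights: bool = False, seed: int = 0):
        self.architecture = architecture
        self.scale = scale
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.effective_batch = effective_batch
        self.micro_batch = micro_batch
        self.weight_decay = weight_decay
        self.normalize = normalize
        self.init_output_bias = init_output_bias
        self.renormalize_weights = renormalize_weights
        self.seed = seed

    # -- estimator API --------------------------------------------------
    def fit(self, X, y, sample_weight=None, X_val=None, y_val=None,
            val_scorer=None):
        """Fit on waveforms X (n, L) and labels y (n, 2) = [SBP, DBP].

        ``sample_weight`` may be (n,) (shared by both outputs) or (n, 2)
        with separate SBP/DBP importance weights.  ``X_val``/``y_val``
        drive best-epoch selection; without them the training set is
        scored instead (discouraged, but defined).
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must have shape (n, 2) = [sbp, dbp]")
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("X and y must be nonempty and of equal length")
        W = self._weights(sample_weight, len(X))
        config = TrainConfig(
            learning_rate=self.learning_rate, epochs=self.epochs,
            effective_batch=self.effective_batch, micro_batch=self.micro_batch,
            weight_decay=self.weight_decay,
            renormalize_weights=self.renormalize_weights,
            init_output_bias=self.init_output_bias, seed=self.seed)
        spec = ModelSpec(architecture=self.architecture, scale=self.scale,
                         normalize=self.normalize)
        model = build_model(spec, seed=self.seed)
        if X_val is None:
            X_val, y_val = X, y
        result = _fit_loop(model, X, y, W, np.asarray(X_val, dtype=np.float32),
                           np.asarray(y_val, dtype=np.float64), config,
                           val_scorer=val_scorer)
        self.model_ = result.model
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.n_features_in_ = X.shape[1]
        return self

    def _weights(self, sample_weight, n) -> np.ndarray:
        if sample_weight is None:
            return np.ones((n, 2))
        W = np.asarray(sample_weight, dtype=np.float64)
        if W.ndim == 1:
            W = np.stack([W, W], axis=1)
        if W.shape != (n, 2):
            raise ValueError("sample_weight must have shape (n,) or (n, 2)")
        if self.renormalize_weights:
            W = W / W.mean(axis=0, keepdims=True)
        return W

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        out = []
        for lo in range(0, len(X), self.micro_batch):
            out.append(self.model_.predict_batch(X[lo:lo + self.micro_batch]))
        return np.concatenate(out)


class MedianBaselineRegressor(RegressorMixin, BaseEstimator):
    """Constant predictor: per-output training-label median."""

    def fit(self, X, y, sample_weight=None):
        y = np.asarray(y, dtype=np.float64)
        if y.size == 0:
            raise ValueError("cannot fit a median baseline on empty labels")
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must have shape (n, 2) = [sbp, dbp]")
        self.baseline_ = MedianBaseline(median_sbp=float(np.median(y[:, 0])),
                                        median_dbp=float(np.median(y[:, 1])))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "baseline_")
        n = len(X)
        return np.tile([self.baseline_.median_sbp, self.baseline_.median_dbp],
                       (n, 1))


# ----------------------------------------------------------------------
# store/split-level wrappers
# ----------------------------------------------------------------------

def _site_matrix(store, indices) -> tuple[np.ndarray, np.ndarray]:
    indices = np.asarray(indices, dtype=np.intp)
    lens = {len(store.signals[i]) for i in indices}
    if len(lens) > 1:
        raise ValueError("training indices span sites with different segment "
                         "lengths; train per length group")
    X = np.stack([store.signals[i] for i in indices])
    y = np.stack([store.sbp[indices], store.dbp[indices]], axis=1)
    return X.astype(np.float32), y


def train(model: Regressor, store, split, config: TrainConfig,
          weights=None, val_scorer=None) -> TrainResult:
    """Optimize ``model`` on split.train, selecting the best epoch by the
    validation score.  ``weights`` is an optional (n_train, 2) array (or
    WeightVector) of per-sample SBP/DBP importance weights."""
    if len(split.train) == 0 or len(split.val) == 0:
        raise ValueError("split must have nonempty train and val parts")
    config.validate()
    Xtr, ytr = _site_matrix(store, split.train)
    Xval, yval = _site_matrix(store, split.val)
    if weights is None:
        W = np.ones((len(Xtr), 2))
    else:
        if hasattr(weights, "w_sbp"):
            W = np.stack([weights.w_sbp, weights.w_dbp], axis=1)
        else:
            W = np.asarray(weights, dtype=np.float64)
        if W.shape != (len(Xtr), 2):
            raise ValueError(
                f"weights shape {W.shape} != (n_train={len(Xtr)}, 2)")
        if config.renormalize_weights:
            W = W / W.mean(axis=0, keepdims=True)
    return _fit_loop(model, Xtr, ytr, W, Xval, yval, config,
                     val_scorer=val_scorer)


def select_rate_from_curve(rates, losses) -> tuple[float, bool]:
    """Rate one decade below the explosion point of a range test.

    Explosion = first rate whose loss exceeds 4x the best loss seen so
    far (or is non-finite).  Returns (rate, exploded).  Without an
    explosion the maximum rate is returned with ``exploded=False``.
    """
    rates = np.asarray(rates, dtype=float)
    losses = np.asarray(losses, dtype=float)
    if rates.size == 0:
        raise ValueError("empty sweep")
    best = np.inf
    for rate, loss in zip(rates, losses):
        if not np.isfinite(loss) or loss > 4.0 * best:
            return float(rate / 10.0), True
        best = min(best, loss)
    return float(rates[-1]), False


def find_learning_rate(model: Regressor, store, split, sweep,
                       micro_batch: int = 32, seed: int = 0) -> float:
    """Short range test: one pass over geometrically increasing rates,
    returning the rate one decade below the loss explosion."""
    sweep = np.sort(np.asarray(list(sweep), dtype=float))
    if sweep.size == 0:
        raise ValueError("empty sweep")
    if sweep.size == 1:
        return float(sweep[0])
    Xtr, ytr = _site_matrix(store, split.train)
    rng = np.random.default_rng(seed)
    opt = AdamW(model.net.parameters(), lr=float(sweep[0]))
    losses = []
    for rate in sweep:
        opt.lr = float(rate)
        mb = rng.choice(len(Xtr), size=min(micro_batch, len(Xtr)), replace=False)
        out = model.forward(Xtr[mb], training=True)
        loss = weighted_mse_loss(out, ytr[mb])
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    rate, exploded = select_rate_from_curve(sweep, losses)
    if not exploded:
        warnings.warn("learning-rate range test saw no loss explosion; "
                      "returning the maximum sweep rate", stacklevel=2)
    return rate


def median_baseline(train_sbp, train_dbp) -> MedianBaseline:
    train_sbp = np.asarray(train_sbp, dtype=float)
    train_dbp = np.asarray(train_dbp, dtype=float)
    if train_sbp.size == 0 or train_dbp.size == 0:
        raise ValueError("cannot compute a median baseline on empty labels")
    return MedianBaseline(median_sbp=float(np.median(train_sbp)),
                          median_dbp=float(np.median(train_dbp)))


def baseline_predict(baseline: MedianBaseline, n: int):
    """Constant-prediction skeleton (refs to be filled by the caller)."""
    return (np.full(n, baseline.median_sbp), np.full(n, baseline.median_dbp))
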