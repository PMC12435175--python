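"""Regression model surface: spec, construction, batched prediction.

All architectures share one contract: a univariate waveform of any
length >= 64 samples in, one jointly predicted (SBP, DBP) pair out.
Per-segment z-score normalization is applied inside the model (on by
default), which is why the synthetic cohorts encode BP in shape rather
than amplitude.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import MIN_INPUT_LEN, Tensor, build_backbone
from .store import SegmentStore

__all__ = ["ModelSpec", "Regressor", "build_model", "predict",
           "save_model", "load_model", "MIN_INPUT_LEN"]


@dataclass(frozen=True)
class ModelSpec:
    architecture: str = "lenet1d"
    scale: float = 1.0          # global width multiplier (desk-scale knob)
    normalize: bool = True      # per-segment z-score before the network

    def validate(self) -> None:
        from .nn.architectures import ARCHITECTURES
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; "
                             f"choose from {sorted(ARCHITECTURES)}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


class Regressor:
    """A (possibly trained) network satisfying the forward contract."""

    def __init__(self, net, spec: ModelSpec, seed: int):
        self.net = net
        self.spec = spec
        self.seed = seed

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def _prepare(self, X: np.ndarray) -> Tensor:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2:
            raise ValueError(f"expected a (batch, length) array, got shape {X.shape}")
        if X.shape[1] < MIN_INPUT_LEN:
            raise ValueError(
                f"input length {X.shape[1]} below minimum {MIN_INPUT_LEN}")
        if self.spec.normalize:
            mu = X.mean(axis=1, keepdims=True)
            sd = X.std(axis=1, keepdims=True)
            X = (X - mu) / np.maximum(sd, 1e-8)
        return Tensor(X[:, None, :])

    def forward(self, X: np.ndarray, training: bool = False) -> Tensor:
        """Graph-building forward pass (used by the trainer)."""
        self.net.train(training)
        return self.net(self._prepare(X))

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False).data.astype(np.float64)


def build_model(spec: ModelSpec, seed: int = 0) -> Regressor:
    """Deterministically initialized, untrained regressor."""
    spec.validate()
    rng = np.random.default_rng(seed)
    return Regressor(build_backbone(spec.architecture, spec.scale, rng), spec, seed)


def predict(model: Regressor, store: SegmentStore, batch_size: int = 64):
    """Per-segment predictions in store order, batched within each site
    (segment length is uniform per site).  Returns a PredictionSet."""
    from .evaluation import PredictionSet

    if store.n == 0:
        raise ValueError("cannot predict on an empty store")
    pred = np.zeros((store.n, 2))
    for site in np.unique(store.site_id):
        idx = np.flatnonzero(store.site_id == site)
        L = len(store.signals[idx[0]])
        if L < MIN_INPUT_LEN:
            raise ValueError(
                f"site {site!r} segment length {L} below minimum {MIN_INPUT_LEN}")
        X = np.stack(store.signals[idx].tolist())
        for lo in range(0, len(idx), batch_size):
            sl = idx[lo:lo + batch_size]
            pred[sl] = model.predict_batch(X[lo:lo + batch_size])
    return PredictionSet(pred_sbp=pred[:, 0], pred_dbp=pred[:, 1],
                         ref_sbp=store.sbp.copy(), ref_dbp=store.dbp.copy(),
                         indices=np.arange(store.n),
                         model_id=model.spec.architecture)


def save_model(model: Regressor, path) -> None:
    """Single-file checkpoint: parameters + buffers + embedded spec."""
    state = model.net.state_dict()
    meta = {"spec": asdict(model.spec), "seed": model.seed}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_model(path) -> Regressor:
    with np.load(path if str(path).endswith(".npz") else f"{path}.npz") as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        state = {k: f[k] for k in f.files if k != "__meta__"}
    model = build_model(ModelSpec(**meta["spec"]), seed=meta["seed"])
    model.net.load_state_dict(state)
    return model
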