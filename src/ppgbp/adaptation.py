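"""Label-distribution machinery for sample-based domain adaptation.

Source and target label distributions are summarized as normalized
histograms on a shared mmHg grid.  A training sample falling in bin *i*
receives the importance weight::

    w_i = max(tau, h_target_i / h_train_i)   if h_train_i > 0
    w_i = tau                                otherwise

with the floor ``tau`` (default 1) preventing any training sample from
being effectively discarded.  Separate weights are derived from the SBP
and DBP distributions for the respective output losses.  Only the
*distribution* of target labels is ever used -- never individual
target labels paired with target samples.

The earth mover's distance between two label histograms (1-D
Wasserstein-1, in mmHg) serves as the dataset-similarity measure that
the benchmark correlates with out-of-distribution error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelHistogram", "WeightVector", "default_bin_edges",
           "fit_histogram", "importance_weights", "make_weight_vector", "emd"]

DEFAULT_BIN_WIDTH = 5.0  # mmHg; balances ratio stability and resolution


def default_bin_edges(lo: float = 20.0, hi: float = 260.0,
                      width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    return np.arange(lo, hi + width / 2, width, dtype=float)


@dataclass
class LabelHistogram:
    """Normalized label histogram; ``empty`` flags an all-zero mass."""

    bin_edges: np.ndarray
    mass: np.ndarray
    empty: bool = False

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if len(self.mass) != len(self.bin_edges) - 1:
            raise ValueError("len(mass) must equal len(bin_edges) - 1")
        if (self.mass < 0).any():
            raise ValueError("histogram mass must be nonnegative")
        if not self.empty and abs(self.mass.sum() - 1.0) > 1e-12:
            raise ValueError("histogram mass must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.mass)

    def bin_index(self, values) -> np.ndarray:
        """Half-open bins [e_k, e_{k+1}), last bin closed; out-of-range
        values are clipped into the extreme bins."""
        values = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.bin_edges, values, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class WeightVector:
    """Per-training-sample importance weights for the two outputs."""

    w_sbp: np.ndarray
    w_dbp: np.ndarray
    tau: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.w_sbp = np.asarray(self.w_sbp, dtype=float)
        self.w_dbp = np.asarray(self.w_dbp, dtype=float)
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for w in (self.w_sbp, self.w_dbp):
            if not np.isfinite(w).all():
                raise ValueError("weights must be finite")
            if (w < self.tau).any():
                raise ValueError("every weight must be >= tau")

    def as_matrix(self) -> np.ndarray:
        return np.stack([self.w_sbp, self.w_dbp], axis=1)


# ----------------------------------------------------------------------
def fit_histogram(values, bin_edges) -> LabelHistogram:
    """Count into half-open bins and normalize; values outside the edge
    range are clipped into the extreme bins.  Empty input yields an
    all-zero histogram flagged ``empty``."""
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(bin_edges) < 2 or (np.diff(bin_edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return LabelHistogram(bin_edges, np.zeros(len(bin_edges) - 1), empty=True)
    if not np.isfinite(values).all():
        raise ValueError("labels must be finite")
    clipped = np.clip(values, bin_edges[0], bin_edges[-1])
    counts, _ = np.histogram(clipped, bins=bin_edges)
    return LabelHistogram(bin_edges, counts / counts.sum())


def importance_weights(train_values, train_hist: LabelHistogram,
                       target_hist: LabelHistogram, tau: float = 1.0) -> np.ndarray:
    """Floored density-ratio weights, one per training value."""
    if not np.array_equal(train_hist.bin_edges, target_hist.bin_edges):
        raise ValueError("histograms must share bin edges")
    if tau <= 0:
        raise ValueError("tau must be positive")
    idx = train_hist.bin_index(train_values)
    h_tr = train_hist.mass[idx]
    h_te = target_hist.mass[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(h_tr > 0, h_te / np.where(h_tr > 0, h_tr, 1.0), 0.0)
    return np.where(h_tr > 0, np.maximum(tau, ratio), tau)


def make_weight_vector(train_sbp, train_dbp, target_sbp, target_dbp,
                       bin_edges=None, tau: float = 1.0) -> WeightVector:
    """Per-output weights from the SBP and DBP label distributions.

    ``target_sbp``/``target_dbp`` may be label sequences or pre-built
    LabelHistograms -- the target enters only through its distribution.
    """
    bin_edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges)
    for name, arr in (("train_sbp", train_sbp), ("train_dbp", train_dbp)):
        if np.asarray(arr).size == 0:
            raise ValueError(f"{name} must be nonempty")
    h_tr_s = fit_histogram(train_sbp, bin_edges)
    h_tr_d = fit_histogram(train_dbp, bin_edges)
    h_te_s = target_sbp if isinstance(target_sbp, LabelHistogram) \
        else fit_histogram(target_sbp, bin_edges)
    h_te_d = target_dbp if isinstance(target_dbp, LabelHistogram) \
        else fit_histogram(target_dbp, bin_edges)
    return WeightVector(
        w_sbp=importance_weights(train_sbp, h_tr_s, h_te_s, tau),
        w_dbp=importance_weights(train_dbp, h_tr_d, h_te_d, tau),
        tau=tau,
        provenance={"n_train": int(np.asarray(train_sbp).size),
                    "bin_width": float(np.diff(bin_edges).mean()),
                    "tau": float(tau)})


def emd(hist_a: LabelHistogram, hist_b: LabelHistogram) -> float:
    """1-D Wasserstein-1 distance between two label histograms (mmHg):
    sum over bins of |CDF_a - CDF_b| times the (uniform) bin width."""
    if not np.array_equal(hist_a.bin_edges, hist_b.bin_edges):
        raise ValueError("histograms must share bin edges")
    widths = np.diff(hist_a.bin_edges)
    if not np.allclose(widths, widths[0]):
        raise NotImplementedError("emd requires uniform bin widths")
    diff = np.cumsum(hist_a.mass - hist_b.mass)
    return float(np.abs(diff).sum() * widths[0])
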