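"""Evaluation suite: MAE, Bland-Altman agreement, paired bootstrap.

MAE is the primary metric referenced by BP device standards.  The
Bland-Altman analysis reports the bias (mean of prediction - reference
differences) and the limits of agreement (1.96 times the sample SD of
the differences).  Statistical comparison between two models on the
same test set uses a paired percentile bootstrap of the MAE difference:
the same resampled segment multiset is applied to both models in each
of the (default 1000) iterations, and a model is flagged significantly
worse than the reference when the 95% interval of MAE(other) -
MAE(reference) lies strictly above zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PredictionSet", "EvalReport", "BootstrapResult",
           "mae", "bland_altman", "bootstrap_mae_difference",
           "evaluate", "tabulate"]


@dataclass
class PredictionSet:
    """Paired predictions and references for one (model, test set)."""

    pred_sbp: np.ndarray
    pred_dbp: np.ndarray
    ref_sbp: np.ndarray
    ref_dbp: np.ndarray
    indices: np.ndarray | None = None
    model_id: str = ""
    test_set_id: str = ""

    def __post_init__(self):
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.pred_sbp, self.pred_dbp, self.ref_sbp, self.ref_dbp)]
        self.pred_sbp, self.pred_dbp, self.ref_sbp, self.ref_dbp = arrays
        n = len(self.pred_sbp)
        if any(len(a) != n for a in arrays):
            raise ValueError("prediction/reference arrays must share length")
        if n and not all(np.isfinite(a).all() for a in arrays):
            raise ValueError("non-finite prediction or reference values")

    @property
    def n(self) -> int:
        return len(self.pred_sbp)

    def resample(self, idx: np.ndarray) -> "PredictionSet":
        return PredictionSet(self.pred_sbp[idx], self.pred_dbp[idx],
                             self.ref_sbp[idx], self.ref_dbp[idx],
                             model_id=self.model_id,
                             test_set_id=self.test_set_id)


@dataclass(frozen=True)
class EvalReport:
    mae_sbp: float
    mae_dbp: float
    bias_sbp: float
    bias_dbp: float
    loa_sbp: float
    loa_dbp: float
    n: int


@dataclass(frozen=True)
class BootstrapResult:
    mean_diff: float       # mean over iterations of MAE(other) - MAE(reference)
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    significantly_worse: bool  # CI strictly above 0


# ----------------------------------------------------------------------
def mae(pred, ref) -> float:
    """(1/n) * sum_i |pred_i - ref_i| in mmHg."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    if pred.size == 0:
        raise ValueError("mae of empty arrays is undefined")
    return float(np.abs(pred - ref).mean())


def bland_altman(pred, ref) -> tuple[float, float]:
    """(bias, loa): mean difference and 1.96 x sample SD (ddof=1)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    if pred.size < 2:
        raise ValueError("Bland-Altman needs at least 2 paired values")
    d = pred - ref
    return float(d.mean()), float(1.96 * d.std(ddof=1))


def bootstrap_mae_difference(reference_preds: PredictionSet,
                             other_preds: PredictionSet,
                             n_boot: int = 1000, alpha: float = 0.05,
                             seed: int = 0,
                             outputs: tuple[str, ...] = ("sbp", "dbp")
                             ) -> dict[str, BootstrapResult]:
    """Paired percentile bootstrap of MAE(other) - MAE(reference).

    Both sets must evaluate the same test segments; each iteration draws
    one index multiset with replacement and applies it to both models.
    """
    if reference_preds.n != other_preds.n or not (
            np.array_equal(reference_preds.ref_sbp, other_preds.ref_sbp)
            and np.array_equal(reference_preds.ref_dbp, other_preds.ref_dbp)):
        raise ValueError("prediction sets must share the same test references")
    n = reference_preds.n
    rng = np.random.default_rng(seed)
    abs_err = {
        "sbp": (np.abs(other_preds.pred_sbp - other_preds.ref_sbp),
                np.abs(reference_preds.pred_sbp - reference_preds.ref_sbp)),
        "dbp": (np.abs(other_preds.pred_dbp - other_preds.ref_dbp),
                np.abs(reference_preds.pred_dbp - reference_preds.ref_dbp)),
    }
    idx = rng.integers(0, n, size=(n_boot, n))
    results = {}
    for out in outputs:
        e_other, e_ref = abs_err[out]
        diffs = e_other[idx].mean(axis=1) - e_ref[idx].mean(axis=1)
        lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
        results[out] = BootstrapResult(
            mean_diff=float(diffs.mean()), ci_low=float(lo), ci_high=float(hi),
            n_boot=n_boot, seed=seed, significantly_worse=bool(lo > 0))
    return results


def evaluate(preds: PredictionSet) -> EvalReport:
    bias_s, loa_s = bland_altman(preds.pred_sbp, preds.ref_sbp)
    bias_d, loa_d = bland_altman(preds.pred_dbp, preds.ref_dbp)
    return EvalReport(mae_sbp=mae(preds.pred_sbp, preds.ref_sbp),
                      mae_dbp=mae(preds.pred_dbp, preds.ref_dbp),
                      bias_sbp=bias_s, bias_dbp=bias_d,
                      loa_sbp=loa_s, loa_dbp=loa_d, n=preds.n)


def tabulate(reports: list[tuple[dict, EvalReport]]) -> pd.DataFrame:
    """One row per (metadata, report) pair, in stable metadata order.

    ``metadata`` supplies identifying columns such as train_site,
    scenario, arch, weighted, test_set, seed.
    """
    rows = []
    for meta, rep in reports:
        row = dict(meta)
        row.update(mae_sbp=rep.mae_sbp, mae_dbp=rep.mae_dbp,
                   bias_sbp=rep.bias_sbp, bias_dbp=rep.bias_dbp,
                   loa_sbp=rep.loa_sbp, loa_dbp=rep.loa_dbp, n=rep.n)
        rows.append(row)
    df = pd.DataFrame(rows)
    meta_cols = [c for c in df.columns
                 if c not in ("mae_sbp", "mae_dbp", "bias_sbp", "bias_dbp",
                              "loa_sbp", "loa_dbp", "n")]
    return df.sort_values(meta_cols).reset_index(drop=True) if meta_cols else df
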